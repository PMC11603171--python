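"""Synthetic finger-tapping cohorts with known ground truth.

Each simulated participant carries latent learning-curve parameters: block
accuracy follows a saturated-logarithmic curve

    acc(g) = clip(a0 + b * ln(min(g, x_p)), 0, 1) + noise

over the global training-block index g, where ``x_p`` is the plateau block
(accuracy stops improving there), and speed improves monotonically as
``s0 + speed_gain * ln(g)``.  The baseline and catch blocks present
different sequences, so their expectation sits at the sequence-unspecific
level (a0, s0).

Participants are drawn from four latent archetypes matching the learner
tiers the analysis recovers: optimal learners plateau within the six
day-1 blocks (the *high* tier almost immediately, the *low* tier towards
the end of day 1), suboptimal learners plateau on later days (the *low*
tier latest, with the largest total gain and the weakest baseline).
Archetype parameter ranges are chosen so that baseline ability (a0, s0)
separates the optimal from the suboptimal class — the premise of the
baseline-feature classifier — while every tier occurs in every age band.

Anodal-tDCS effects are injected only in the verum arm and only on
accuracy: suboptimal learners get an accuracy boost after the first
training block with their plateau pulled into day 1 (rapid early
optimisation), optimal-high learners get a day-1 accuracy detriment.
Speed is unaffected by stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import (
    AGE_BANDS,
    AgeGroup,
    Arm,
    BlockRecord,
    BlockType,
    Dataset,
    KeypressEvent,
    ParticipantProfile,
    Tier,
)

#: the nine-digit displayed sequence, over four buttons
SEQUENCE = (4, 1, 3, 2, 4, 2, 3, 1, 4)

BLOCK_DURATION_S = 90.0
BLOCKS_PER_DAY = 6
#: catch block is presented halfway through the six training blocks
CATCH_AFTER_BLOCK = 3


@dataclass(frozen=True)
class LatentLearnerParams:
    """Generative analogue of the fitted logarithmic accuracy curve.

    Noise SDs of ``None`` (the default) are derived per block from the
    press counts the block is expected to contain: block accuracy is a
    mean over n ~ 150-180 presses, so its sampling SD is the binomial
    floor sqrt(p(1-p)/n); correct-press counts are Poisson-like, giving a
    speed SD of sqrt(speed/duration).  Explicit values override both.
    """

    a0: float  # sequence-unspecific base accuracy
    b_true: float  # accuracy gain per ln(block)
    x_p: int  # plateau block (global index); >= 1
    s0: float  # base speed, correct presses / s
    speed_gain: float  # presses/s per ln(block)
    noise_sd_acc: float | None = None
    noise_sd_speed: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.a0 <= 1.0:
            raise ValueError("a0 must be in [0, 1]")
        if self.x_p < 1:
            raise ValueError("x_p must be >= 1")
        if self.a0 + self.b_true * np.log(self.x_p) > 1.0 + 1e-12:
            raise ValueError("plateau accuracy a0 + b*ln(x_p) exceeds 1")
        for sd in (self.noise_sd_acc, self.noise_sd_speed):
            if sd is not None and sd < 0:
                raise ValueError("noise SDs must be >= 0")
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")

    def acc_sd(self, acc_mu: float, spd_mu: float) -> float:
        """Accuracy noise SD for a block with the given expectations."""
        if self.noise_sd_acc is not None:
            return self.noise_sd_acc
        if acc_mu <= 0.0 or acc_mu >= 1.0:
            return 0.0
        n_exp = max(BLOCK_DURATION_S * spd_mu / acc_mu, 1.0)
        return float(np.sqrt(acc_mu * (1.0 - acc_mu) / n_exp))

    def speed_sd(self, spd_mu: float) -> float:
        """Speed noise SD for a block with the given expected speed."""
        if self.noise_sd_speed is not None:
            return self.noise_sd_speed
        return float(np.sqrt(max(spd_mu, 0.0) / BLOCK_DURATION_S))


@dataclass(frozen=True)
class StimEffectSpec:
    """Injected differential stimulation effects (verum arm only).

    ``suboptimal_day1_boost`` is added to verum suboptimal learners'
    accuracy after training block 1, with their plateau pulled into day 1;
    ``optimal_high_day1_detriment`` is subtracted from verum optimal-high
    learners' accuracy on day-1 blocks 2..6.  Speed is never affected.
    """

    suboptimal_day1_boost: float = 0.10
    optimal_high_day1_detriment: float = 0.05
    speed_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.suboptimal_day1_boost < 0:
            raise ValueError("boost must be >= 0")
        if self.optimal_high_day1_detriment < 0:
            raise ValueError("detriment must be >= 0")
        if self.speed_effect != 0.0:
            raise ValueError("stimulation does not affect speed")


#: per-tier latent parameter ranges: (a0 range, b range, x_p range, s0 range)
#: calibrated so the bending-point criterion (epsilon=0.05 over 30 blocks)
#: agrees with the generative plateau day in the noiseless limit
TIER_ARCHETYPES: dict[Tier, dict[str, tuple[float, float]]] = {
    Tier.OPTIMAL_HIGH: {
        "a0": (0.78, 0.92), "b": (0.02, 0.06), "x_p": (1, 2), "s0": (1.4, 2.0),
    },
    Tier.OPTIMAL_LOW: {
        "a0": (0.62, 0.78), "b": (0.04, 0.08), "x_p": (3, 4), "s0": (1.2, 1.6),
    },
    Tier.SUBOPTIMAL_HIGH: {
        "a0": (0.44, 0.56), "b": (0.10, 0.14), "x_p": (10, 18), "s0": (0.8, 1.0),
    },
    Tier.SUBOPTIMAL_LOW: {
        "a0": (0.30, 0.42), "b": (0.10, 0.16), "x_p": (20, 30), "s0": (0.5, 0.8),
    },
}

_TIER_ORDER = (
    Tier.OPTIMAL_HIGH,
    Tier.OPTIMAL_LOW,
    Tier.SUBOPTIMAL_HIGH,
    Tier.SUBOPTIMAL_LOW,
)

#: default mixing weights P(tier | age band); learner quality skews with
#: age but every tier is reachable from every band
DEFAULT_MIXING = {
    AgeGroup.YOUNG: (0.45, 0.25, 0.20, 0.10),
    AgeGroup.MIDDLE: (0.25, 0.25, 0.25, 0.25),
    AgeGroup.OLDER: (0.10, 0.20, 0.30, 0.40),
}

#: sampled age ranges per band (older capped for sampling purposes)
AGE_SAMPLING_RANGES = {
    AgeGroup.YOUNG: (18.0, 30.0),
    AgeGroup.MIDDLE: (50.0, 65.0),
    AgeGroup.OLDER: (66.0, 80.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for a synthetic cohort.

    ``n_per_cell`` participants are drawn per (age band x arm) cell; the
    latent tier of each participant is drawn from ``mixing`` for their
    band.  Defaults give 90 participants, 60 of whom are unstimulated
    (placebo or none) and available for classifier training.
    """

    n_per_cell: int = 10
    arms: tuple[Arm, ...] = (Arm.NONE, Arm.PLACEBO, Arm.VERUM)
    mixing: dict[AgeGroup, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MIXING)
    )
    n_days: int = 5
    #: None derives block-level noise from expected press counts
    noise_sd_acc: float | None = None
    noise_sd_speed: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if self.n_days not in (5, 10):
            raise ValueError("n_days must be 5 or 10")
        for band, weights in self.mixing.items():
            w = np.asarray(weights, dtype=float)
            if len(w) != 4 or (w < 0).any() or (w > 1).any():
                raise ValueError(f"mixing weights for {band} must be 4 values in [0,1]")
            if w.sum() <= 0:
                raise ValueError(f"mixing weights for {band} are all zero")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"mixing weights for {band} must sum to 1")


def sample_learner_params(
    tier: Tier, rng: np.random.Generator,
    noise_sd_acc: float | None = None, noise_sd_speed: float | None = None,
) -> LatentLearnerParams:
    """Draw latent parameters from a tier archetype."""
    arch = TIER_ARCHETYPES[tier]
    a0 = rng.uniform(*arch["a0"])
    b = rng.uniform(*arch["b"])
    lo, hi = arch["x_p"]
    x_p = int(rng.integers(int(lo), int(hi) + 1))
    s0 = rng.uniform(*arch["s0"])
    speed_gain = rng.uniform(0.10, 0.30)
    return LatentLearnerParams(
        a0=a0, b_true=b, x_p=x_p, s0=s0, speed_gain=speed_gain,
        noise_sd_acc=noise_sd_acc, noise_sd_speed=noise_sd_speed,
    )


def sample_cohort(
    spec: CohortSpec,
) -> list[tuple[ParticipantProfile, LatentLearnerParams, Tier]]:
    """Sample a cohort; returns (profile, latent params, ground-truth tier).

    Deterministic given ``spec.rng_seed``.  The ground-truth learner class
    follows from the tier (optimal-* tiers plateau within day 1).
    """
    rng = np.random.default_rng(spec.rng_seed)
    cohort: list[tuple[ParticipantProfile, LatentLearnerParams, Tier]] = []
    idx = 0
    for band in (AgeGroup.YOUNG, AgeGroup.MIDDLE, AgeGroup.OLDER):
        weights = np.asarray(spec.mixing[band], dtype=float)
        weights = weights / weights.sum()
        for arm in spec.arms:
            for _ in range(spec.n_per_cell):
                idx += 1
                tier = _TIER_ORDER[rng.choice(4, p=weights)]
                age = float(rng.uniform(*AGE_SAMPLING_RANGES[band]))
                profile = ParticipantProfile(
                    participant_id=f"S{idx:04d}",
                    age_years=round(age, 1),
                    age_group=band,
                    arm=arm,
                    dataset=Dataset.SYNTHETIC,
                )
                params = sample_learner_params(
                    tier, rng, spec.noise_sd_acc, spec.noise_sd_speed
                )
                cohort.append((profile, params, tier))
    return cohort


def expected_accuracy(
    params: LatentLearnerParams,
    g: np.ndarray,
    *,
    arm: Arm = Arm.NONE,
    true_tier: Tier | None = None,
    effect: StimEffectSpec | None = None,
) -> np.ndarray:
    """Noise-free expected accuracy at global training blocks ``g``.

    Verum-arm effects: suboptimal learners have their plateau capped at
    block 6 (pulled to day 1) and gain ``suboptimal_day1_boost`` from
    block 2 onwards (acquired skill persists across days); optimal-high
    learners lose ``optimal_high_day1_detriment`` on day-1 blocks 2..6.
    """
    g = np.asarray(g, dtype=float)
    x_p = float(params.x_p)
    shift = np.zeros_like(g)
    if effect is not None and arm is Arm.VERUM and true_tier is not None:
        if (true_tier in (Tier.SUBOPTIMAL_HIGH, Tier.SUBOPTIMAL_LOW)
                and effect.suboptimal_day1_boost > 0):
            x_p = min(x_p, float(BLOCKS_PER_DAY))
            shift = np.where(g >= 2, effect.suboptimal_day1_boost, 0.0)
        elif (true_tier is Tier.OPTIMAL_HIGH
                and effect.optimal_high_day1_detriment > 0):
            day1 = (g >= 2) & (g <= BLOCKS_PER_DAY)
            shift = np.where(day1, -effect.optimal_high_day1_detriment, 0.0)
    mu = params.a0 + params.b_true * np.log(np.minimum(g, x_p)) + shift
    return np.clip(mu, 0.0, 1.0)


def expected_speed(params: LatentLearnerParams, g: np.ndarray) -> np.ndarray:
    """Noise-free expected speed; monotone in g, identical across arms."""
    g = np.asarray(g, dtype=float)
    return np.maximum(params.s0 + params.speed_gain * np.log(g), 0.0)


def _truncnorm_01(mu: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise around mu, resampled into [0, 1] (block accuracy is a
    mean over many presses, approximately normal but bounded)."""
    if sd == 0:
        return np.asarray(mu, dtype=float).copy()
    out = rng.normal(mu, sd)
    bad = (out < 0) | (out > 1)
    # rejection resampling; the truncation region is wide so this converges fast
    for _ in range(100):
        if not bad.any():
            break
        out[bad] = rng.normal(np.asarray(mu)[bad], sd)
        bad = (out < 0) | (out > 1)
    return np.clip(out, 0.0, 1.0)


def generate_blocks(
    profile: ParticipantProfile,
    params: LatentLearnerParams,
    effect: StimEffectSpec | None = None,
    n_days: int = 5,
    *,
    true_tier: Tier | None = None,
    rng: np.random.Generator | None = None,
) -> list[BlockRecord]:
    """Generate one participant's block table.

    Emits one baseline block (day 1, index 0), six training blocks per day
    (indices 1..6) and one catch block per day (index 7, presented halfway
    through the session).  Baseline and catch blocks use different
    sequences, so their expectation is the sequence-unspecific level
    (a0, s0) with no training trend.
    """
    if n_days not in (5, 10):
        raise ValueError("n_days must be 5 or 10")
    if rng is None:
        rng = np.random.default_rng(0)
    records: list[BlockRecord] = []

    def emit(day: int, index: int, btype: BlockType, acc_mu: float, spd_mu: float) -> None:
        acc = float(_truncnorm_01(np.array([acc_mu]), params.acc_sd(acc_mu, spd_mu), rng)[0])
        spd = max(float(rng.normal(spd_mu, params.speed_sd(spd_mu))), 0.0)
        n_presses = int(round(BLOCK_DURATION_S * spd / acc)) if acc > 0 else 0
        records.append(
            BlockRecord(
                participant_id=profile.participant_id,
                day=day,
                block_index=index,
                block_type=btype,
                speed=spd,
                accuracy=acc,
                n_presses=n_presses,
            )
        )

    g_all = np.arange(1, n_days * BLOCKS_PER_DAY + 1)
    acc_mu = expected_accuracy(
        params, g_all, arm=profile.arm, true_tier=true_tier, effect=effect
    )
    spd_mu = expected_speed(params, g_all)

    emit(1, 0, BlockType.BASELINE, params.a0, params.s0)
    for day in range(1, n_days + 1):
        for block in range(1, BLOCKS_PER_DAY + 1):
            g = (day - 1) * BLOCKS_PER_DAY + block
            emit(day, block, BlockType.TRAINING, float(acc_mu[g - 1]), float(spd_mu[g - 1]))
            if block == CATCH_AFTER_BLOCK:
                # catch block occurs halfway through training; it carries
                # index 7 so (day, block_index) is unique within a day
                emit(day, 7, BlockType.CATCH, params.a0, params.s0)
    return records


def generate_cohort_blocks(
    spec: CohortSpec, effect: StimEffectSpec | None = None
) -> tuple[list[ParticipantProfile], list[BlockRecord], "pd.DataFrame"]:
    """Sample a cohort and its full block table.

    Returns (profiles, block records, ground-truth table).  The truth table
    has one row per participant with the latent parameters and true tier,
    for use by test harnesses and recovery experiments.
    """
    import pandas as pd

    cohort = sample_cohort(spec)
    root = np.random.default_rng(spec.rng_seed)
    # one independent child stream per participant, spawned deterministically
    streams = root.spawn(len(cohort))
    profiles: list[ParticipantProfile] = []
    blocks: list[BlockRecord] = []
    truth_rows = []
    for (profile, params, tier), rng in zip(cohort, streams):
        profiles.append(profile)
        blocks.extend(
            generate_blocks(
                profile, params, effect, spec.n_days, true_tier=tier, rng=rng
            )
        )
        truth_rows.append(
            {
                "participant_id": profile.participant_id,
                "true_tier": tier.value,
                "true_class": "optimal" if tier in (Tier.OPTIMAL_HIGH, Tier.OPTIMAL_LOW) else "suboptimal",
                "a0": params.a0,
                "b_true": params.b_true,
                "x_p": params.x_p,
                "s0": params.s0,
                "speed_gain": params.speed_gain,
            }
        )
    return profiles, blocks, pd.DataFrame(truth_rows)


def generate_keypresses(
    participant_id: str,
    day: int,
    block_index: int,
    target_speed: float,
    target_accuracy: float,
    duration_s: float = BLOCK_DURATION_S,
    rng: np.random.Generator | None = None,
) -> list[KeypressEvent]:
    """Simulate a keypress stream hitting target block-level scores.

    ``target_speed`` is *correct* presses per second, so the total press
    rate is ``speed / accuracy``; press count is Poisson at that rate,
    press times are an ordered uniform sample over the block, each press
    is correct with probability ``target_accuracy`` and the expected key
    follows the repeating nine-digit sequence.
    """
    if target_speed < 0:
        raise ValueError("target speed must be >= 0")
    if not 0.0 < target_accuracy <= 1.0:
        raise ValueError("target accuracy must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(0)
    n = int(rng.poisson(duration_s * target_speed / target_accuracy))
    times = np.sort(rng.uniform(0.0, duration_s, size=n))
    correct = rng.random(n) < target_accuracy
    events: list[KeypressEvent] = []
    for i in range(n):
        expected = SEQUENCE[i % len(SEQUENCE)]
        if correct[i]:
            pressed = expected
        else:
            wrong = [k for k in (1, 2, 3, 4) if k != expected]
            pressed = int(wrong[rng.integers(0, 3)])
        events.append(
            KeypressEvent(
                participant_id=participant_id,
                day=day,
                block_index=block_index,
                press_time_s=float(times[i]),
                key_pressed=int(pressed),
                key_expected=int(expected),
            )
        )
    return events


def zeroed_effects() -> StimEffectSpec:
    """Null stimulation: verum and placebo cohorts are exchangeable."""
    return StimEffectSpec(suboptimal_day1_boost=0.0, optimal_high_day1_detriment=0.0)
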