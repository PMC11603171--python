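"""Performance dynamics and differential stimulation-effect statistics.

The unit of behavioral change is the *dynamics ratio*: each training
block's score divided by the score of the first training block, so every
series starts at exactly 1 and values above 1 mean improvement relative
to block 1.  Baseline and catch blocks never enter ratios or fits.

Group curves aggregate ratios per learner tier and stimulation arm; the
95% band comes from a seeded nonparametric bootstrap over participants of
the fitted log-curve.

The differential stimulation effect is tested per tier with a linear
mixed model, ratio ~ arm x day (cell-means coding) with a random
intercept per participant, fit by REML.  The day-1 verum-vs-placebo
contrast on the estimated marginal means is the primary test, with
Satterthwaite degrees of freedom, two-tailed p values, and a family
correction across tiers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import RandomInterceptFit, contrast_test, fit_random_intercept, wald_f_test
from .types import Arm, BlockType, Tier

log = logging.getLogger(__name__)

METRICS = ("accuracy", "speed")


def compute_dynamics(
    blocks: pd.DataFrame, metric: str = "accuracy", blocks_per_session: int = 6
) -> pd.DataFrame:
    """Per-participant block ratios relative to the first training block.

    Returns a long table (participant_id, g, value, ratio); only training
    blocks enter.  Participants whose first-block value is not positive
    are excluded with a logged reason.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    train = blocks[blocks["block_type"] == BlockType.TRAINING.value].copy()
    train["g"] = (train["day"] - 1) * blocks_per_session + train["block_index"]
    out = []
    for pid, sub in train.groupby("participant_id", sort=True):
        sub = sub.sort_values("g")
        first = sub[sub["g"] == 1]
        if len(first) != 1 or first[metric].iloc[0] <= 0:
            log.warning(
                "participant %s excluded from %s dynamics: first training "
                "block missing or non-positive", pid, metric,
            )
            continue
        ref = float(first[metric].iloc[0])
        df = pd.DataFrame(
            {
                "participant_id": pid,
                "g": sub["g"].to_numpy(),
                "value": sub[metric].to_numpy(dtype=float),
            }
        )
        df["ratio"] = df["value"] / ref
        out.append(df)
    if not out:
        return pd.DataFrame(columns=["participant_id", "g", "value", "ratio"])
    return pd.concat(out, ignore_index=True)


def aggregate_group_curve(
    dynamics: pd.DataFrame,
    assignment: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(tier, arm) mean ratio per block with a bootstrap band.

    ``assignment`` maps participant_id to tier and arm.  The 95% band is
    the percentile interval, over ``n_boot`` seeded resamples of
    participants, of the fitted log-curve ratio = a + b*ln(g); groups of
    one participant get means but a flagged (NaN) band.
    """
    df = dynamics.merge(assignment[["participant_id", "tier", "arm"]],
                        on="participant_id")
    rng = np.random.default_rng(seed)
    rows = []
    for (tier, arm), sub in df.groupby(["tier", "arm"], sort=True):
        pids = np.sort(sub["participant_id"].unique())
        n = len(pids)
        if n == 0:
            raise ValueError(f"empty group {tier}/{arm}")
        gs = np.sort(sub["g"].unique())
        means = sub.groupby("g")["ratio"].mean()
        wide = sub.pivot_table(index="participant_id", columns="g",
                               values="ratio").loc[pids, gs]
        logg = np.log(gs.astype(float))
        Xd = np.column_stack([np.ones_like(logg), logg])
        if n >= 2:
            band = np.empty((n_boot, len(gs)))
            for b in range(n_boot):
                take = rng.integers(0, n, size=n)
                ym = wide.to_numpy()[take].mean(axis=0)
                coef, *_ = np.linalg.lstsq(Xd, ym, rcond=None)
                band[b] = Xd @ coef
            lo = np.percentile(band, 2.5, axis=0)
            hi = np.percentile(band, 97.5, axis=0)
        else:
            lo = hi = np.full(len(gs), np.nan)
        for j, g in enumerate(gs):
            rows.append(
                {"tier": tier, "arm": arm, "g": int(g), "n": n,
                 "mean_ratio": float(means.loc[g]),
                 "band_lo": float(lo[j]), "band_hi": float(hi[j])}
            )
    return pd.DataFrame(rows)


@dataclass
class MixedModelFit:
    """Fitted arm x time cell-means mixed model for one tier's ratios.

    The time axis is day for the omnibus model or block within a window;
    estimated marginal means are direct functions of the cell means.
    """

    fit: RandomInterceptFit
    arms: list[str]
    times: list[int]
    cells: list[tuple[str, int]]  # column order of the cell-means design
    time_col: str = "day"

    def cell_row(self, arm: str, time: int) -> np.ndarray:
        row = np.zeros(len(self.cells))
        row[self.cells.index((arm, time))] = 1.0
        return row

    def emm_row(self, arm: str, times: list[int] | None = None) -> np.ndarray:
        """EMM of an arm: cell means averaged over the given times."""
        if times is None:
            times = self.times
        return np.mean([self.cell_row(arm, t) for t in times], axis=0)


def _long_table(dynamics: pd.DataFrame, assignment: pd.DataFrame,
                blocks_per_session: int = 6) -> pd.DataFrame:
    df = dynamics.merge(assignment[["participant_id", "tier", "arm"]],
                        on="participant_id")
    df["day"] = (df["g"] - 1) // blocks_per_session + 1
    # g = 1 is the reference block (ratio identically 1); it carries no
    # information about change and would deflate the residual variance
    return df[df["g"] > 1].copy()


def fit_mixed_model(
    long: pd.DataFrame, time_col: str = "day"
) -> tuple[MixedModelFit, pd.DataFrame]:
    """Fit ratio ~ arm x time + (1 | participant) by REML.

    ``long`` needs columns participant_id, arm, ratio and the time column
    (day for the omnibus model, or block g within a window).  Fixed
    effects use cell-means coding, so estimated marginal means are direct
    functions of model coefficients.  Returns the fit handle and a table
    of Type-III style omnibus F tests (arm, time, arm x time) with
    Satterthwaite-based df.  A singular fit (intercept variance
    collapsing to zero) degrades to a fixed-effects model with residual
    df, flagged in the output.
    """
    arms = sorted(long["arm"].unique())
    times = sorted(int(t) for t in long[time_col].unique())
    cells = list(itertools.product(arms, times))
    idx = {c: j for j, c in enumerate(cells)}
    X = np.zeros((len(long), len(cells)))
    for r, (a, t) in enumerate(zip(long["arm"], long[time_col])):
        X[r, idx[(a, int(t))]] = 1.0
    fit = fit_random_intercept(
        X, long["ratio"].to_numpy(dtype=float),
        long["participant_id"].to_numpy(),
    )
    if fit.singular:
        log.warning("singular mixed fit: random-intercept variance ~ 0; "
                    "using fixed-effects (residual) inference")
    handle = MixedModelFit(fit=fit, arms=arms, times=times, cells=cells,
                           time_col=time_col)

    omni = []
    nA, nT = len(arms), len(times)
    if nA > 1:
        # arm main effect: EMM differences between consecutive arms
        L = np.zeros((nA - 1, len(cells)))
        for i in range(nA - 1):
            for t in times:
                L[i, idx[(arms[i], t)]] += 1.0 / nT
                L[i, idx[(arms[i + 1], t)]] -= 1.0 / nT
        omni.append({"term": "arm", **wald_f_test(fit, L)})
    if nT > 1:
        L = np.zeros((nT - 1, len(cells)))
        for i in range(nT - 1):
            for a in arms:
                L[i, idx[(a, times[i])]] += 1.0 / nA
                L[i, idx[(a, times[i + 1])]] -= 1.0 / nA
        omni.append({"term": time_col, **wald_f_test(fit, L)})
    if nA > 1 and nT > 1:
        L = np.zeros(((nA - 1) * (nT - 1), len(cells)))
        r = 0
        for i in range(nA - 1):
            for j in range(nT - 1):
                L[r, idx[(arms[i], times[j])]] += 1.0
                L[r, idx[(arms[i + 1], times[j])]] -= 1.0
                L[r, idx[(arms[i], times[j + 1])]] -= 1.0
                L[r, idx[(arms[i + 1], times[j + 1])]] += 1.0
                r += 1
        omni.append({"term": f"arm:{time_col}", **wald_f_test(fit, L)})
    return handle, pd.DataFrame(omni)


def arm_contrast(
    model: MixedModelFit,
    arm_hi: str = Arm.VERUM.value,
    arm_lo: str = Arm.PLACEBO.value,
    times: list[int] | None = None,
) -> dict:
    """EMM contrast between two arms, averaged over the given times.

    Effect size d standardizes the estimate by the total SD
    sqrt(tau2 + sigma2).
    """
    if arm_hi not in model.arms or arm_lo not in model.arms:
        raise ValueError(f"arms {arm_hi}/{arm_lo} not both present in model")
    L = model.emm_row(arm_hi, times) - model.emm_row(arm_lo, times)
    res = contrast_test(model.fit, L)
    total_sd = float(np.sqrt(model.fit.tau2 + model.fit.sigma2))
    res["d"] = res["estimate"] / total_sd if total_sd > 0 else np.nan
    return res


def day1_contrast(model: MixedModelFit, arm_hi: str = Arm.VERUM.value,
                  arm_lo: str = Arm.PLACEBO.value) -> dict:
    """Verum-vs-placebo contrast of the day-1 estimated marginal mean.

    Day-1 change is the mean ratio over the day-1 blocks after the
    reference block; subtracting 1 (the reference) cancels in the arm
    difference.  Works on either time axis: at day 1 of a day-level
    model, or averaged over the day-1 blocks of a block-level model.
    """
    if model.time_col == "day":
        times = [1]
    else:
        times = [t for t in model.times if 2 <= t <= 6]
    return arm_contrast(model, arm_hi, arm_lo, times)


def family_adjust(pvals: list[float]) -> list[float]:
    """Family correction across tier contrasts.

    Each tier contributes one contrast from its own model, so the family
    consists of independent comparisons; the adjustment is the Sidak form
    1 - (1-p)^k, which the Tukey machinery degrades to for non-pairwise
    families.  A singleton family is returned unadjusted.
    """
    k = len(pvals)
    if k <= 1:
        return list(pvals)
    return [float(1.0 - (1.0 - p) ** k) if np.isfinite(p) else p for p in pvals]


def posthoc_day1_contrasts(
    dynamics: pd.DataFrame,
    assignment: pd.DataFrame,
    blocks_per_session: int = 6,
    tiers: list[str] | None = None,
) -> pd.DataFrame:
    """Per-tier day-1 verum-vs-placebo contrasts with family adjustment.

    Fits one mixed model per tier on the day-1 window (the blocks after
    the reference block) and tests the arm EMM difference there.  The
    day-1 window is used because ratio residual variance grows with the
    ratio level over days; pooling later days would miscalibrate the
    day-1 standard error.  Tiers lacking either arm are skipped with a
    note.  Returns a table with contrast, estimate, t, df, d, p, p_adj.
    """
    long_all = _long_table(dynamics, assignment, blocks_per_session)
    long_all = long_all[long_all["day"] == 1]
    if tiers is None:
        tiers = [t.value for t in Tier if t.value in set(long_all["tier"])]
    rows = []
    for tier in tiers:
        sub = long_all[long_all["tier"] == tier]
        have = set(sub["arm"].unique())
        if not {Arm.VERUM.value, Arm.PLACEBO.value} <= have:
            log.warning("tier %s skipped: arms present = %s", tier, sorted(have))
            continue
        sub = sub[sub["arm"].isin([Arm.VERUM.value, Arm.PLACEBO.value])]
        # block-level time axis within day 1: the within-day learning
        # trend is fixed structure, not residual noise
        model, _ = fit_mixed_model(sub, time_col="g")
        res = day1_contrast(model)
        rows.append(
            {
                "contrast": f"{tier}: verum - placebo, day 1",
                "tier": tier,
                "estimate": res["estimate"],
                "se": res["se"],
                "t": res["t"],
                "df": res["df"],
                "d": res["d"],
                "p": res["p"],
                "df_method": res["df_method"],
            }
        )
    out = pd.DataFrame(
        rows, columns=["contrast", "tier", "estimate", "se", "t", "df", "d",
                       "p", "df_method"],
    )
    if len(out):
        out["p_adj"] = family_adjust(list(out["p"]))
    else:
        out["p_adj"] = []
    return out
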