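"""Core domain types shared across the pipeline.

The unit of observation is a 90-second tapping *block*.  A training day
consists of six training blocks plus one "catch" block (a different
sequence, probing sequence-unspecific learning); the first day additionally
starts with a single "baseline" block performed before any training.
Training blocks are indexed 1..6 within a day and carry a global index
``g = (day - 1) * 6 + block_index`` used by every downstream fit; baseline
and catch blocks are excluded from ``g``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields


class AgeGroup(str, enum.Enum):
    YOUNG = "young"
    MIDDLE = "middle"
    OLDER = "older"


class Arm(str, enum.Enum):
    """Stimulation arm: active (verum) anodal tDCS, placebo, or none."""

    VERUM = "verum"
    PLACEBO = "placebo"
    NONE = "none"


class Dataset(str, enum.Enum):
    MODELING = "modeling"
    VALIDATION = "validation"
    SYNTHETIC = "synthetic"


class BlockType(str, enum.Enum):
    BASELINE = "baseline"
    TRAINING = "training"
    CATCH = "catch"


class LearnerClass(str, enum.Enum):
    """Optimal: accuracy plateau reached within day-1 training blocks."""

    OPTIMAL = "optimal"
    SUBOPTIMAL = "suboptimal"


class Tier(str, enum.Enum):
    """Median-split halves of each learner class.

    Within the optimal class the *high* tier sits furthest below the 50%
    boundary (closest to the optimum); within the suboptimal class the
    *low* tier sits furthest above it (least efficient learners).
    """

    OPTIMAL_HIGH = "optimal-high"
    OPTIMAL_LOW = "optimal-low"
    SUBOPTIMAL_HIGH = "suboptimal-high"
    SUBOPTIMAL_LOW = "suboptimal-low"


#: study age bands, in years (inclusive lower, inclusive upper)
AGE_BANDS = {
    AgeGroup.YOUNG: (18.0, 30.0),
    AgeGroup.MIDDLE: (50.0, 65.0),
    AgeGroup.OLDER: (65.0, math.inf),
}


def age_group_for(age_years: float) -> AgeGroup:
    """Map an age in years to the study band; total over positive ages.

    Bands: young 18-30, middle 50-65, older >65.  Ages falling in the gaps
    (<18, 30-50) are assigned to the nearest band boundary so the mapping
    is total for synthetic cohorts.
    """
    if age_years <= 0 or not math.isfinite(age_years):
        raise ValueError(f"age must be positive and finite, got {age_years}")
    if age_years <= 40.0:
        return AgeGroup.YOUNG
    if age_years <= 65.0:
        return AgeGroup.MIDDLE
    return AgeGroup.OLDER


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    age_years: float
    age_group: AgeGroup
    arm: Arm
    dataset: Dataset = Dataset.SYNTHETIC

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValueError(f"{self.participant_id}: age must be positive")


@dataclass(frozen=True)
class KeypressEvent:
    """A single button press within a block.

    Keys are 1..4; the expected key follows the displayed nine-digit
    sequence.  Times are seconds from block onset.
    """

    participant_id: str
    day: int
    block_index: int
    press_time_s: float
    key_pressed: int
    key_expected: int

    def __post_init__(self) -> None:
        if not 1 <= self.key_pressed <= 4 or not 1 <= self.key_expected <= 4:
            raise ValueError("keys must be in 1..4")
        if self.press_time_s < 0:
            raise ValueError("press time must be non-negative")


@dataclass(frozen=True)
class BlockRecord:
    """Block-level performance: speed (correct presses/s) and accuracy
    (correct presses / total presses)."""

    participant_id: str
    day: int
    block_index: int
    block_type: BlockType
    speed: float
    accuracy: float
    n_presses: int = 0

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError(f"{self.participant_id}: day must be >= 1")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError(
                f"{self.participant_id} day {self.day} block {self.block_index}: "
                f"accuracy {self.accuracy} outside [0, 1]"
            )
        if self.speed < 0:
            raise ValueError(
                f"{self.participant_id} day {self.day} block {self.block_index}: "
                f"negative speed {self.speed}"
            )
        if self.n_presses < 0:
            raise ValueError("n_presses must be >= 0")

    @property
    def global_block(self) -> int | None:
        """Global training-block index g, or None for baseline/catch."""
        if self.block_type is not BlockType.TRAINING:
            return None
        return (self.day - 1) * 6 + self.block_index


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    The classification threshold is fixed at 0.5 by the probability-map
    construction (probabilities above 50% are suboptimal) and is not
    configurable.
    """

    blocks_per_session: int = 6
    n_days: int = 5
    bending_epsilon: float = 0.05
    n_cv_splits: int = 10
    test_fraction: float = 0.2
    rng_seed: int = 0

    #: fixed by construction, not configurable
    threshold: float = field(default=0.5, init=False)

    def __post_init__(self) -> None:
        if self.blocks_per_session <= 0:
            raise ValueError("blocks_per_session must be positive")
        if self.n_days not in (5, 10):
            raise ValueError(f"n_days must be 5 or 10, got {self.n_days}")
        if self.bending_epsilon <= 0:
            raise ValueError("bending_epsilon must be positive")
        if self.n_cv_splits <= 0:
            raise ValueError("n_cv_splits must be positive")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError(
                f"test_fraction must be in (0, 1), got {self.test_fraction}"
            )
        if self.rng_seed < 0:
            raise ValueError("rng_seed must be non-negative")

    @property
    def n_training_blocks(self) -> int:
        return self.blocks_per_session * self.n_days

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls) if f.init]
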