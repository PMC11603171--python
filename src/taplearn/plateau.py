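"""Logarithmic learning-curve fits and plateau (bending point) detection.

Each participant's training-block accuracy is fit with

    accuracy(g) = a + b * ln(g)

over the global training-block index g (baseline and catch blocks are
excluded: they present different sequences).  The *bending point* is the
block after which the fitted remaining gain becomes negligible:

    bend = smallest g such that  b * ln(N / g) < epsilon

with N the total number of training blocks and epsilon an absolute
accuracy threshold (default 0.05).  In closed form, ``bend = N *
exp(-epsilon / b)`` (clipped to [1, N]); a non-positive slope bends at
block 1.  Participants whose bending point falls within the first
training day are labeled *optimal* learners, all others *suboptimal* —
the ground-truth labels the baseline-feature classifier is trained on.

This remaining-gain criterion is a deliberate operationalization: pure
shape criteria (maximum curvature, normalized knee) are degenerate for
the two-parameter log family, whose normalized shape does not depend on
b.  The threshold form is monotone in b, closed-form invertible, and
configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .types import BlockType, LearnerClass, PipelineConfig

#: minimum training blocks required to fit and label a participant
MIN_BLOCKS = 4


class UnlabelableError(ValueError):
    """Raised when a participant cannot be given a learner label."""


@dataclass(frozen=True)
class LearningCurveFit:
    a: float  # intercept, accuracy units
    b: float  # slope per ln(block)
    rss: float
    n_blocks_used: int


@dataclass(frozen=True)
class PlateauResult:
    bend_block: float  # global training-block coordinate, in [1, N]
    bend_session: int  # ceil(bend_block / blocks_per_session)
    label: LearnerClass


def fit_log_curve(
    g: Iterable[int] | np.ndarray, accuracy: Iterable[float] | np.ndarray
) -> LearningCurveFit:
    """Least-squares fit of accuracy = a + b*ln(g).

    Closed-form simple linear regression on the transformed abscissa.
    A constant series yields b = 0 exactly.
    """
    g = np.asarray(list(g), dtype=float)
    y = np.asarray(list(accuracy), dtype=float)
    if g.shape != y.shape:
        raise ValueError("g and accuracy must have equal length")
    mask = np.isfinite(y)
    g, y = g[mask], y[mask]
    if len(g) < MIN_BLOCKS:
        raise UnlabelableError(
            f"need at least {MIN_BLOCKS} training blocks with defined accuracy, "
            f"got {len(g)}"
        )
    if (g < 1).any():
        raise ValueError("global block index must be >= 1")
    x = np.log(g)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("all blocks share one index; cannot fit a slope")
    b = float(xc @ (y - y.mean()) / sxx)
    if np.ptp(y) == 0.0:
        b = 0.0  # constant series: exact zero, no float dust
    a = float(y.mean() - b * x.mean())
    resid = y - (a + b * x)
    return LearningCurveFit(a=a, b=b, rss=float(resid @ resid), n_blocks_used=len(g))


def detect_bending_block(
    fit: LearningCurveFit,
    n_blocks: int,
    epsilon: float = 0.05,
    blocks_per_session: int = 6,
) -> PlateauResult:
    """Locate the bending point of a fitted log curve and label it.

    The bend is where the fitted remaining gain b*ln(N/g) first drops
    below epsilon: ``N * exp(-epsilon/b)``, clipped to [1, N].  Slope
    b <= 0 bends immediately at block 1.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if n_blocks < blocks_per_session:
        raise ValueError("n_blocks must cover at least one session")
    if fit.b <= 0:
        bend = 1.0
    else:
        bend = min(max(n_blocks * math.exp(-epsilon / fit.b), 1.0), float(n_blocks))
    session = int(math.ceil(bend / blocks_per_session))
    label = LearnerClass.OPTIMAL if session == 1 else LearnerClass.SUBOPTIMAL
    return PlateauResult(bend_block=bend, bend_session=session, label=label)


def label_cohort(
    blocks: pd.DataFrame, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit, detect and label every participant in a block table.

    ``blocks`` needs columns participant_id, day, block_index, block_type,
    accuracy.  Returns (labels, unlabelable): one row per labeled
    participant with the fit and plateau result, and a table of excluded
    participants with reasons.  A participant must have at least
    ``MIN_BLOCKS`` day-1 training blocks; the fit itself uses the training
    blocks of all days.
    """
    if config is None:
        config = PipelineConfig()
    if len(blocks) == 0:
        raise ValueError("empty block table")
    bp = config.blocks_per_session
    n_total = config.n_training_blocks
    train = blocks[blocks["block_type"] == BlockType.TRAINING.value].copy()
    train["g"] = (train["day"] - 1) * bp + train["block_index"]

    rows, skipped = [], []
    for pid, sub in train.groupby("participant_id", sort=True):
        day1 = sub[sub["day"] == 1]
        if len(day1) < MIN_BLOCKS:
            skipped.append(
                {"participant_id": pid,
                 "reason": f"only {len(day1)} day-1 training blocks (< {MIN_BLOCKS})"}
            )
            continue
        try:
            fit = fit_log_curve(sub["g"].to_numpy(), sub["accuracy"].to_numpy())
        except UnlabelableError as exc:
            skipped.append({"participant_id": pid, "reason": str(exc)})
            continue
        plateau = detect_bending_block(
            fit, n_blocks=n_total, epsilon=config.bending_epsilon,
            blocks_per_session=bp,
        )
        rows.append(
            {
                "participant_id": pid,
                "a": fit.a,
                "b": fit.b,
                "rss": fit.rss,
                "n_blocks_used": fit.n_blocks_used,
                "bend_block": plateau.bend_block,
                "bend_session": plateau.bend_session,
                "label": plateau.label.value,
            }
        )
    labels = pd.DataFrame(
        rows,
        columns=["participant_id", "a", "b", "rss", "n_blocks_used",
                 "bend_block", "bend_session", "label"],
    )
    unlabelable = pd.DataFrame(skipped, columns=["participant_id", "reason"])
    return labels, unlabelable
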