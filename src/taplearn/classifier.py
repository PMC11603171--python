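"""Baseline-feature classifier and likelihood-to-benefit map.

Five raw features per participant — age, and speed/accuracy in the
baseline block and in the first training block — are standardized,
expanded with all degree-2 monomials (20 features), and separated by a
linear maximum-margin (support-vector) classifier.  Model selection runs
ten stratified Monte-Carlo 80/20 splits over a small regularization grid
and keeps the regularization with the best held-out F1 for the
suboptimal (positive) class.

Each individual's signed distance to the separating hyperplane is mapped
to a probability with a Platt-style sigmoid fitted by maximum likelihood
on the training distances.  Probabilities above 0.5 are classified
suboptimal — these individuals have an above-chance likelihood to
benefit from anodal tDCS.  The Platt intercept is absorbed into the
reported distance, so the hyperplane side, the 0.5 probability cut and
the predicted class coincide exactly.  Finally each class is split into
a high and a low tier at the training-set median probability of that
class; the optimal-high tier sits furthest below 50% (closest to the
optimum), the suboptimal-low tier furthest above (least efficient,
largest expected benefit).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.preprocessing import PolynomialFeatures
from sklearn.svm import SVC

from .types import BlockType, LearnerClass, PipelineConfig, Tier

log = logging.getLogger(__name__)

RAW_FEATURES = [
    "age_years",
    "baseline_speed",
    "baseline_accuracy",
    "block1_speed",
    "block1_accuracy",
]

#: regularization grid for model selection
C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)

N_EXPANDED = 20  # 5 linear + 5 squares + C(5,2) cross terms


@dataclass
class TrainedStratifier:
    """Frozen stratification model; prediction never mutates it."""

    feature_names: list[str]
    center: np.ndarray  # (5,) per-feature mean
    scale: np.ndarray  # (5,) per-feature SD
    weights: np.ndarray  # (20,) hyperplane normal, unit norm
    offset: float  # calibrated: distance 0 <=> probability 0.5
    platt_a: float  # sigmoid slope, < 0; p = 1/(1 + exp(a * distance))
    class_medians: dict[str, float]  # training-set median probability per class
    training_f1: float  # F1 on the full training set (feature separability)
    cv_f1: float  # mean held-out F1 of the selected model
    C: float  # selected regularization

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("center", "scale", "weights"):
            d[k] = [float(v) for v in d[k]]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrainedStratifier":
        d = json.loads(text)
        for k in ("center", "scale", "weights"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def extract_features(blocks: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """One feature row per participant from the baseline block and the
    first day-1 training block; participants missing either are excluded
    with a logged reason."""
    day1 = blocks[blocks["day"] == 1]
    if len(day1) == 0:
        raise ValueError("no day-1 blocks in table")
    base = day1[day1["block_type"] == BlockType.BASELINE.value]
    blk1 = day1[
        (day1["block_type"] == BlockType.TRAINING.value) & (day1["block_index"] == 1)
    ]
    rows = []
    for _, prof in profiles.iterrows():
        pid = prof["participant_id"]
        b = base[base["participant_id"] == pid]
        t = blk1[blk1["participant_id"] == pid]
        if len(b) != 1 or len(t) != 1:
            log.warning(
                "participant %s excluded from features: baseline blocks=%d, "
                "first training blocks=%d", pid, len(b), len(t),
            )
            continue
        rows.append(
            {
                "participant_id": pid,
                "age_years": float(prof["age_years"]),
                "baseline_speed": float(b["speed"].iloc[0]),
                "baseline_accuracy": float(b["accuracy"].iloc[0]),
                "block1_speed": float(t["speed"].iloc[0]),
                "block1_accuracy": float(t["accuracy"].iloc[0]),
            }
        )
    return pd.DataFrame(rows, columns=["participant_id"] + RAW_FEATURES)


def _poly() -> PolynomialFeatures:
    return PolynomialFeatures(degree=2, include_bias=False)


def expand_features(
    X: np.ndarray, center: np.ndarray, scale: np.ndarray
) -> np.ndarray:
    """Center/scale the 5 raw features, then emit all degree-1 and
    degree-2 monomials (20 columns, canonical order: linear terms first,
    then squares and cross terms)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(RAW_FEATURES):
        raise ValueError(f"expected {len(RAW_FEATURES)} raw features, got {X.shape[1]}")
    if center is None or scale is None:
        raise ValueError("scaling has not been fitted")
    Z = (X - center) / scale
    out = _poly().fit_transform(Z)
    assert out.shape[1] == N_EXPANDED
    return out


def _fit_platt(distances: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood sigmoid p = 1/(1+exp(A*d + B)) with Platt's
    smoothed targets (keeps A finite when classes are separable)."""
    d = np.asarray(distances, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(theta: np.ndarray) -> float:
        a, b = theta
        z = a * d + b
        # stable log(1+exp(z)) and z + log(1+exp(-z))
        log1pez = np.logaddexp(0.0, z)
        return float(np.sum(t * log1pez + (1 - t) * (log1pez - z)))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    a, b = float(res.x[0]), float(res.x[1])
    if a >= 0:
        raise ValueError(
            "sigmoid slope is not negative: distances do not separate the "
            "classes in the required orientation"
        )
    return a, b


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """F1 for the suboptimal (positive = 1) class."""
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def _fit_svc(X: np.ndarray, y: np.ndarray, C: float) -> SVC:
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    return clf


def train_stratifier(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> TrainedStratifier:
    """Fit the full stratification model on labeled, unstimulated data.

    ``features`` from :func:`extract_features`; ``labels`` with columns
    participant_id and label (optimal/suboptimal).  Verum-stimulated
    participants must not be present (pass the unstimulated subset).
    Deterministic given ``config.rng_seed``.
    """
    if config is None:
        config = PipelineConfig()
    if "arm" in features.columns and (features["arm"] == "verum").any():
        raise ValueError("training features must not include verum participants")
    df = features.merge(labels[["participant_id", "label"]], on="participant_id")
    if len(df) < 10:
        raise ValueError(f"need >= 10 labeled participants, got {len(df)}")
    y = (df["label"] == LearnerClass.SUBOPTIMAL.value).to_numpy(dtype=int)
    if y.min() == y.max():
        raise ValueError("both learner classes must be present to train")
    X = df[RAW_FEATURES].to_numpy(dtype=float)

    # ten stratified Monte-Carlo 80/20 splits, redrawn (seeded) if a side
    # of a split ends up with fewer than 2 of either class
    def make_splits(seed: int):
        for attempt in range(20):
            sss = StratifiedShuffleSplit(
                n_splits=config.n_cv_splits,
                test_size=config.test_fraction,
                random_state=(seed + attempt) % (2**31),
            )
            splits = list(sss.split(X, y))
            ok = all(
                min(np.bincount(y[tr], minlength=2).min(),
                    np.bincount(y[te], minlength=2).min()) >= 1
                for tr, te in splits
            )
            if ok:
                if attempt:
                    log.info("splits redrawn %d time(s) to cover both classes", attempt)
                return splits
        raise ValueError("could not draw class-covering splits")

    splits = make_splits(config.rng_seed)
    mean_f1 = {}
    for C in C_GRID:
        scores = []
        for tr, te in splits:
            center, scale = X[tr].mean(axis=0), X[tr].std(axis=0)
            scale = np.where(scale == 0, 1.0, scale)
            clf = _fit_svc(expand_features(X[tr], center, scale), y[tr], C)
            pred = clf.predict(expand_features(X[te], center, scale))
            scores.append(_f1(y[te], pred))
        mean_f1[C] = float(np.mean(scores))
    best_C = max(C_GRID, key=lambda c: (mean_f1[c], -c))

    # refit the selected model on all training data
    center, scale = X.mean(axis=0), X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    Xe = expand_features(X, center, scale)
    clf = _fit_svc(Xe, y, best_C)
    w = clf.coef_.ravel()
    norm = float(np.linalg.norm(w))
    weights = w / norm
    offset_raw = float(clf.intercept_[0]) / norm
    dist_raw = Xe @ weights + offset_raw  # signed distance, suboptimal side > 0

    platt_a, platt_b = _fit_platt(dist_raw, y)
    # absorb the sigmoid intercept into the hyperplane offset: the reported
    # distance is measured from the 50%-probability boundary, so
    # distance > 0  <=>  probability > 0.5  <=>  class = suboptimal
    offset = offset_raw + platt_b / platt_a

    dist = Xe @ weights + offset
    prob = 1.0 / (1.0 + np.exp(platt_a * dist))
    pred_sub = prob > 0.5
    medians = {
        LearnerClass.OPTIMAL.value: float(np.median(prob[~pred_sub]))
        if (~pred_sub).any() else float("nan"),
        LearnerClass.SUBOPTIMAL.value: float(np.median(prob[pred_sub]))
        if pred_sub.any() else float("nan"),
    }
    training_f1 = _f1(y, pred_sub.astype(int))
    return TrainedStratifier(
        feature_names=list(RAW_FEATURES),
        center=center,
        scale=scale,
        weights=weights,
        offset=offset,
        platt_a=platt_a,
        class_medians=medians,
        training_f1=training_f1,
        cv_f1=mean_f1[best_C],
        C=best_C,
    )


def assign_tier(probability: float, class_medians: dict[str, float]) -> Tier:
    """Median-split tier within the predicted class.

    Optimal class (p <= 0.5): below the class median is *optimal-high*
    (closer to the optimum).  Suboptimal class (p > 0.5): above the class
    median is *suboptimal-low* (least efficient).  A probability exactly
    at the median goes to the tier nearer 0.5.
    """
    if probability > 0.5:
        med = class_medians[LearnerClass.SUBOPTIMAL.value]
        return Tier.SUBOPTIMAL_LOW if probability > med else Tier.SUBOPTIMAL_HIGH
    med = class_medians[LearnerClass.OPTIMAL.value]
    return Tier.OPTIMAL_HIGH if probability < med else Tier.OPTIMAL_LOW


def predict_likelihood(
    stratifier: TrainedStratifier, features: pd.DataFrame
) -> pd.DataFrame:
    """Apply a frozen stratifier to new participants.

    Returns participant_id, distance (signed, suboptimal side positive),
    probability (likelihood to benefit from stimulation), predicted_class
    and tier.  Never refits anything.
    """
    X = features[RAW_FEATURES].to_numpy(dtype=float)
    Xe = expand_features(X, stratifier.center, stratifier.scale)
    dist = Xe @ stratifier.weights + stratifier.offset
    prob = 1.0 / (1.0 + np.exp(stratifier.platt_a * dist))
    out = pd.DataFrame(
        {
            "participant_id": features["participant_id"].to_numpy(),
            "distance": dist,
            "probability": prob,
        }
    )
    out["predicted_class"] = np.where(
        out["probability"] > 0.5,
        LearnerClass.SUBOPTIMAL.value,
        LearnerClass.OPTIMAL.value,
    )
    out["tier"] = [
        assign_tier(p, stratifier.class_medians).value for p in out["probability"]
    ]
    return out
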