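"""Stratifier: feature extraction, polynomial expansion, model selection,
Platt calibration and tier assignment."""

import numpy as np
import pandas as pd
import pytest

from taplearn import classifier, dataio, plateau
from taplearn.classifier import (
    TrainedStratifier,
    assign_tier,
    expand_features,
    extract_features,
    predict_likelihood,
    train_stratifier,
    _fit_platt,
)
from taplearn.types import PipelineConfig, Tier


def feature_frame(X, ids=None):
    X = np.atleast_2d(X)
    df = pd.DataFrame(X, columns=classifier.RAW_FEATURES)
    df.insert(0, "participant_id",
              ids if ids is not None else [f"P{i}" for i in range(len(X))])
    return df


def blob_training_set(n=40, sep=6.0, seed=0):
    """Two well-separated Gaussian blobs in raw feature space."""
    rng = np.random.default_rng(seed)
    half = n // 2
    opt = rng.normal([25, 1.8, 0.8, 1.9, 0.85], 0.3, size=(half, 5))
    sub = rng.normal([70, 0.7, 0.4, 0.8, 0.45], 0.3, size=(half, 5))
    sub[:, 0] += sep  # age pushed further out for clean separation
    X = np.vstack([opt, sub])
    feats = feature_frame(X)
    labels = pd.DataFrame(
        {"participant_id": feats["participant_id"],
         "label": ["optimal"] * half + ["suboptimal"] * half}
    )
    return feats, labels


class TestExtractFeatures:
    def test_vector_contents(self):
        blocks = pd.DataFrame(
            [
                {"participant_id": "A", "day": 1, "block_index": 0,
                 "block_type": "baseline", "speed": 1.5, "accuracy": 0.7},
                {"participant_id": "A", "day": 1, "block_index": 1,
                 "block_type": "training", "speed": 1.8, "accuracy": 0.8},
            ]
        )
        profiles = pd.DataFrame(
            [{"participant_id": "A", "age_years": 70.0, "age_group": "older",
              "arm": "none", "dataset": "synthetic"}]
        )
        feats = extract_features(blocks, profiles)
        assert list(feats.iloc[0][classifier.RAW_FEATURES]) == [
            70.0, 1.5, 0.7, 1.8, 0.8
        ]

    def test_missing_baseline_excluded(self, small_cohort_frames):
        blocks, profiles, _ = small_cohort_frames
        pid = profiles["participant_id"].iloc[0]
        trimmed = blocks[~((blocks["participant_id"] == pid)
                           & (blocks["block_type"] == "baseline"))]
        feats = extract_features(trimmed, profiles)
        assert pid not in set(feats["participant_id"])
        assert len(feats) == len(profiles) - 1


class TestExpandFeatures:
    def test_dimension_is_twenty(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 5))
        out = expand_features(X, np.zeros(5), np.ones(5))
        assert out.shape == (7, 20)

    def test_unit_vector_two_nonzeros(self):
        out = expand_features(
            np.array([[1.0, 0, 0, 0, 0]]), np.zeros(5), np.ones(5)
        )[0]
        nonzero = np.flatnonzero(out)
        assert len(nonzero) == 2
        assert out[nonzero[0]] == 1.0 and out[nonzero[1]] == 1.0

    def test_zero_vector_all_zero(self):
        out = expand_features(np.zeros((1, 5)), np.zeros(5), np.ones(5))
        assert not out.any()

    def test_unfitted_scaling_rejected(self):
        with pytest.raises(ValueError):
            expand_features(np.zeros((1, 5)), None, None)


class TestPlatt:
    def test_symmetric_toy_crosses_half_at_zero(self):
        d = np.array([-1.0] * 10 + [1.0] * 10)
        y = np.array([0] * 10 + [1] * 10)
        a, b = _fit_platt(d, y)
        # independent oracle: brute-force grid minimization of the
        # smoothed Bernoulli NLL
        t = np.where(y == 1, 11 / 12, 1 / 12)
        grid_a = np.linspace(-8, -0.05, 400)
        grid_b = np.linspace(-2, 2, 401)
        nll = np.array(
            [
                [
                    np.sum(t * np.logaddexp(0, ga * d + gb)
                           + (1 - t) * (np.logaddexp(0, ga * d + gb) - ga * d - gb))
                    for gb in grid_b
                ]
                for ga in grid_a
            ]
        )
        ia, ib = np.unravel_index(nll.argmin(), nll.shape)
        assert a == pytest.approx(grid_a[ia], abs=0.05)
        assert b == pytest.approx(grid_b[ib], abs=0.05)
        p0 = 1 / (1 + np.exp(a * 0 + b))
        assert p0 == pytest.approx(0.5, abs=1e-6)

    def test_orientation_enforced(self):
        d = np.array([-1.0] * 5 + [1.0] * 5)
        y = np.array([1] * 5 + [0] * 5)  # inverted labels
        with pytest.raises(ValueError):
            _fit_platt(d, y)


class TestTrainStratifier:
    def test_separable_blobs_perfect_f1(self):
        feats, labels = blob_training_set()
        model = train_stratifier(feats, labels, PipelineConfig(rng_seed=0))
        assert model.training_f1 == 1.0

    def test_same_seed_identical_weights(self):
        feats, labels = blob_training_set()
        m1 = train_stratifier(feats, labels, PipelineConfig(rng_seed=5))
        m2 = train_stratifier(feats, labels, PipelineConfig(rng_seed=5))
        assert np.array_equal(m1.weights, m2.weights)
        assert m1.offset == m2.offset and m1.platt_a == m2.platt_a

    def test_single_class_rejected(self):
        feats, labels = blob_training_set()
        labels["label"] = "optimal"
        with pytest.raises(ValueError):
            train_stratifier(feats, labels, PipelineConfig())

    def test_verum_features_rejected(self):
        feats, labels = blob_training_set()
        feats = feats.assign(arm="verum")
        with pytest.raises(ValueError, match="verum"):
            train_stratifier(feats, labels, PipelineConfig())

    def test_tiny_cohort_rejected(self):
        feats, labels = blob_training_set(n=8)
        with pytest.raises(ValueError, match="10"):
            train_stratifier(feats, labels, PipelineConfig())

    def test_json_round_trip(self):
        feats, labels = blob_training_set()
        model = train_stratifier(feats, labels, PipelineConfig(rng_seed=1))
        restored = TrainedStratifier.from_json(model.to_json())
        preds_a = predict_likelihood(model, feats)
        preds_b = predict_likelihood(restored, feats)
        pd.testing.assert_frame_equal(preds_a, preds_b)


class TestPredictionInvariants:
    @pytest.fixture
    def model_and_features(self, small_cohort_frames, config):
        blocks, profiles, _ = small_cohort_frames
        labels, _ = plateau.label_cohort(blocks, config)
        feats = extract_features(blocks, profiles)
        model = train_stratifier(feats, labels, config)
        return model, feats

    def test_probability_strictly_monotone_in_distance(self, model_and_features):
        model, feats = model_and_features
        preds = predict_likelihood(model, feats).sort_values("distance")
        assert preds["probability"].is_monotonic_increasing
        d = preds["probability"].diff().dropna()
        assert (d[preds["distance"].diff().dropna() > 0] > 0).all()

    def test_class_flips_exactly_at_half_and_hyperplane(self, model_and_features):
        model, feats = model_and_features
        preds = predict_likelihood(model, feats)
        assert (
            (preds["predicted_class"] == "suboptimal")
            == (preds["probability"] > 0.5)
        ).all()
        assert (
            (preds["predicted_class"] == "suboptimal") == (preds["distance"] > 0)
        ).all()

    def test_zero_distance_is_half(self, model_and_features):
        model, _ = model_and_features
        p0 = 1 / (1 + np.exp(model.platt_a * 0.0))
        assert p0 == 0.5

    def test_training_tier_sizes_balanced(self, model_and_features):
        model, feats = model_and_features
        preds = predict_likelihood(model, feats)
        for cls, tiers in [
            ("optimal", (Tier.OPTIMAL_HIGH.value, Tier.OPTIMAL_LOW.value)),
            ("suboptimal", (Tier.SUBOPTIMAL_HIGH.value, Tier.SUBOPTIMAL_LOW.value)),
        ]:
            sub = preds[preds["predicted_class"] == cls]
            counts = sub["tier"].value_counts()
            assert abs(counts.get(tiers[0], 0) - counts.get(tiers[1], 0)) <= 1

    def test_prediction_never_mutates_model(self, model_and_features, stim_cohort_frames):
        model, _ = model_and_features
        blocks, profiles, _ = stim_cohort_frames
        before = model.to_json()
        verum = profiles[profiles["arm"] == "verum"]
        feats = extract_features(blocks, verum)
        predict_likelihood(model, feats)
        assert model.to_json() == before


class TestAssignTier:
    MEDIANS = {"optimal": 0.2, "suboptimal": 0.75}

    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.05, Tier.OPTIMAL_HIGH),
            (0.3, Tier.OPTIMAL_LOW),
            (0.6, Tier.SUBOPTIMAL_HIGH),
            (0.9, Tier.SUBOPTIMAL_LOW),
        ],
    )
    def test_median_split(self, p, expected):
        assert assign_tier(p, self.MEDIANS) is expected

    def test_ties_go_to_tier_nearer_half(self):
        assert assign_tier(0.2, self.MEDIANS) is Tier.OPTIMAL_LOW
        assert assign_tier(0.75, self.MEDIANS) is Tier.SUBOPTIMAL_HIGH

    def test_spec_example_quartet(self):
        medians = {"optimal": 0.2, "suboptimal": 0.75}
        probs = [0.6, 0.7, 0.8, 0.9]
        tiers = [assign_tier(p, medians) for p in probs]
        assert tiers == [Tier.SUBOPTIMAL_HIGH, Tier.SUBOPTIMAL_HIGH,
                         Tier.SUBOPTIMAL_LOW, Tier.SUBOPTIMAL_LOW]
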