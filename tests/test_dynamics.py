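"""Dynamics ratios, group curves, and mixed-model contrasts.

The Satterthwaite implementation is cross-checked against lmerTest (R)
as an independent oracle on a small fixture.
"""

import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from taplearn import dynamics as dyn
from taplearn.lmm import contrast_test, fit_random_intercept
from taplearn.dynamics import (
    aggregate_group_curve,
    compute_dynamics,
    day1_contrast,
    family_adjust,
    fit_mixed_model,
    posthoc_day1_contrasts,
)


def block_rows(pid, values, metric="accuracy"):
    rows = []
    for i, v in enumerate(values, start=1):
        day = (i - 1) // 6 + 1
        rows.append(
            {"participant_id": pid, "day": day,
             "block_index": (i - 1) % 6 + 1, "block_type": "training",
             "speed": v if metric == "speed" else 1.0,
             "accuracy": v if metric == "accuracy" else 0.5}
        )
    return rows


class TestComputeDynamics:
    def test_ratio_arithmetic(self):
        blocks = pd.DataFrame(block_rows("A", [0.5, 0.6, 0.75, 0.5]))
        d = compute_dynamics(blocks, "accuracy")
        assert list(d["ratio"]) == pytest.approx([1.0, 1.2, 1.5, 1.0])

    def test_first_block_ratio_exactly_one(self):
        rng = np.random.default_rng(0)
        blocks = pd.DataFrame(
            sum((block_rows(f"P{i}", rng.uniform(0.2, 0.9, 30)) for i in range(5)), [])
        )
        d = compute_dynamics(blocks, "accuracy")
        assert (d[d["g"] == 1]["ratio"] == 1.0).all()

    def test_constant_series_all_ones(self):
        blocks = pd.DataFrame(block_rows("A", [0.4] * 12))
        d = compute_dynamics(blocks, "accuracy")
        assert (d["ratio"] == 1.0).all()

    def test_zero_first_block_excluded(self):
        blocks = pd.DataFrame(
            block_rows("A", [0.0, 0.5, 0.6]) + block_rows("B", [0.5, 0.5, 0.6])
        )
        d = compute_dynamics(blocks, "accuracy")
        assert set(d["participant_id"]) == {"B"}

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            compute_dynamics(pd.DataFrame(block_rows("A", [0.5])), "errors")

    def test_catch_and_baseline_never_enter(self):
        rows = block_rows("A", [0.5, 0.6, 0.7])
        rows.append({"participant_id": "A", "day": 1, "block_index": 0,
                     "block_type": "baseline", "speed": 9.0, "accuracy": 0.01})
        rows.append({"participant_id": "A", "day": 1, "block_index": 7,
                     "block_type": "catch", "speed": 9.0, "accuracy": 0.99})
        d = compute_dynamics(pd.DataFrame(rows), "accuracy")
        assert len(d) == 3
        assert list(d["ratio"]) == pytest.approx([1.0, 1.2, 1.4])


class TestGroupCurve:
    def assignment(self, pids, tier="optimal-high", arm="placebo"):
        return pd.DataFrame(
            {"participant_id": pids, "tier": tier, "arm": arm}
        )

    def test_identical_participants_zero_width_band(self):
        blocks = pd.DataFrame(
            block_rows("A", [0.5, 0.6, 0.7, 0.8]) + block_rows("B", [0.5, 0.6, 0.7, 0.8])
        )
        d = compute_dynamics(blocks, "accuracy")
        curve = aggregate_group_curve(d, self.assignment(["A", "B"]), n_boot=50)
        assert np.allclose(curve["band_hi"] - curve["band_lo"], 0.0)

    def test_single_participant_band_flagged(self):
        blocks = pd.DataFrame(block_rows("A", [0.5, 0.6, 0.7, 0.8]))
        d = compute_dynamics(blocks, "accuracy")
        curve = aggregate_group_curve(d, self.assignment(["A"]), n_boot=50)
        assert curve["band_lo"].isna().all()
        assert (curve["n"] == 1).all()

    def test_same_seed_identical_bands(self):
        rng = np.random.default_rng(1)
        blocks = pd.DataFrame(
            sum((block_rows(f"P{i}", rng.uniform(0.3, 0.9, 12)) for i in range(6)), [])
        )
        d = compute_dynamics(blocks, "accuracy")
        a = aggregate_group_curve(d, self.assignment([f"P{i}" for i in range(6)]),
                                  n_boot=100, seed=9)
        b = aggregate_group_curve(d, self.assignment([f"P{i}" for i in range(6)]),
                                  n_boot=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_invariant_to_participant_order(self):
        rng = np.random.default_rng(2)
        blocks = pd.DataFrame(
            sum((block_rows(f"P{i}", rng.uniform(0.3, 0.9, 6)) for i in range(4)), [])
        )
        d = compute_dynamics(blocks, "accuracy")
        fwd = aggregate_group_curve(d, self.assignment([f"P{i}" for i in range(4)]),
                                    n_boot=10, seed=0)
        rev = aggregate_group_curve(
            d.iloc[::-1].reset_index(drop=True),
            self.assignment([f"P{i}" for i in range(3, -1, -1)]),
            n_boot=10, seed=0,
        )
        assert np.allclose(fwd["mean_ratio"], rev["mean_ratio"])


def synthetic_long(seed=3, n_per_arm=10, arm_effect=0.0):
    """Participant-clustered two-arm long table with known structure."""
    rng = np.random.default_rng(seed)
    rows = []
    for arm in ("placebo", "verum"):
        for i in range(n_per_arm):
            pid = f"{arm[:1]}{i}"
            u = rng.normal(0, 0.3)
            for day in range(1, 4):
                for rep in range(3):
                    y = 1.0 + (arm_effect if arm == "verum" else 0.0)
                    y += 0.05 * day + u + rng.normal(0, 0.2)
                    rows.append({"participant_id": pid, "arm": arm,
                                 "day": day, "ratio": y})
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_identical_arms_zero_estimate(self):
        base = synthetic_long(seed=4, n_per_arm=8)
        placebo = base[base["arm"] == "placebo"]
        mirrored = placebo.assign(
            arm="verum",
            participant_id=placebo["participant_id"] + "_v",
        )
        model, _ = fit_mixed_model(pd.concat([placebo, mirrored]))
        res = day1_contrast(model)
        assert res["estimate"] == pytest.approx(0.0, abs=1e-10)

    def test_recovers_injected_arm_effect(self):
        model, omni = fit_mixed_model(synthetic_long(seed=5, arm_effect=0.5))
        res = day1_contrast(model)
        assert res["estimate"] == pytest.approx(0.5, abs=0.25)
        assert res["p"] < 0.01
        arm_row = omni[omni["term"] == "arm"].iloc[0]
        assert arm_row["p"] < 0.01

    def test_singular_fit_flagged_with_residual_df(self):
        # every participant has the same mean: between-participant
        # variance is exactly zero, so the intercept variance collapses
        rows = []
        for i in range(20):
            arm = "placebo" if i < 10 else "verum"
            for day, y in [(1, 1.0), (2, 1.1), (3, 0.9)]:
                rows.append({"participant_id": f"P{i}", "arm": arm,
                             "day": day, "ratio": y})
        model, _ = fit_mixed_model(pd.DataFrame(rows))
        assert model.fit.singular
        res = day1_contrast(model)
        assert res["df_method"] == "residual"

    def test_satterthwaite_against_lmerTest_oracle(self, tmp_path):
        long = synthetic_long(seed=7, arm_effect=0.3)
        csv = tmp_path / "long.csv"
        long.to_csv(csv, index=False)
        rscript = textwrap.dedent(
            f"""
            suppressMessages({{library(lmerTest); library(jsonlite)}})
            d <- read.csv("{csv}")
            m <- lmer(ratio ~ arm + (1 | participant_id), data = d, REML = TRUE)
            co <- summary(m)$coefficients["armverum", ]
            cat(toJSON(list(est = co[["Estimate"]], se = co[["Std. Error"]],
                            df = co[["df"]], t = co[["t value"]],
                            p = co[["Pr(>|t|)"]]), auto_unbox = TRUE, digits = 12))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        oracle = json.loads(out.stdout)

        # same model on our side: arm cell means, contrast verum - placebo
        X = np.column_stack(
            [(long["arm"] == "placebo").to_numpy(float),
             (long["arm"] == "verum").to_numpy(float)]
        )
        fit = fit_random_intercept(X, long["ratio"].to_numpy(),
                                   long["participant_id"].to_numpy())
        res = contrast_test(fit, np.array([-1.0, 1.0]))
        assert res["estimate"] == pytest.approx(oracle["est"], rel=1e-5)
        assert res["se"] == pytest.approx(oracle["se"], rel=1e-3)
        assert res["df"] == pytest.approx(oracle["df"], rel=0.02)
        assert res["p"] == pytest.approx(oracle["p"], rel=0.02)


class TestPosthocContrasts:
    def test_identical_arms_null_contrast(self):
        rng = np.random.default_rng(8)
        blocks, assign = [], []
        for arm in ("placebo", "verum"):
            for i in range(6):
                pid = f"{arm}{i}"
                # same generative stream for both arms
                vals = 0.5 + 0.02 * np.arange(12) + \
                    np.random.default_rng(100 + i).normal(0, 0.02, 12)
                blocks.extend(block_rows(pid, vals))
                assign.append({"participant_id": pid, "tier": "optimal-low",
                               "arm": arm})
        d = compute_dynamics(pd.DataFrame(blocks), "accuracy")
        con = posthoc_day1_contrasts(d, pd.DataFrame(assign))
        assert len(con) == 1
        assert con["estimate"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert con["p_adj"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_singleton_family_unadjusted(self):
        assert family_adjust([0.04]) == [0.04]

    def test_family_adjustment_monotone_and_bounded(self):
        ps = [0.01, 0.04, 0.5, 0.9]
        adj = family_adjust(ps)
        assert all(a >= p for a, p in zip(adj, ps))
        assert all(0 <= a <= 1 for a in adj)
        assert adj[0] == pytest.approx(1 - 0.99**4)

    def test_missing_arm_tier_skipped(self):
        blocks, assign = [], []
        for i in range(4):
            blocks.extend(block_rows(f"P{i}", [0.5, 0.55, 0.6] * 2))
            assign.append({"participant_id": f"P{i}",
                           "tier": "suboptimal-low", "arm": "placebo"})
        d = compute_dynamics(pd.DataFrame(blocks), "accuracy")
        con = posthoc_day1_contrasts(d, pd.DataFrame(assign))
        assert len(con) == 0
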