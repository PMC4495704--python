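import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from procsev.derivation import fit_logistic
from procsev.errors import ConfigError, ZeroMarginError
from procsev.validation import (c_statistic, calibration_by_index,
                                discrimination_slope, hosmer_lemeshow, idi,
                                omega_statistic, run_validation)


def brute_force_auc(p, y):
    """All-pairs oracle: concordant + half ties over events x non-events."""
    p = np.asarray(p, float)
    y = np.asarray(y, bool)
    pos, neg = p[y], p[~y]
    total = 0.0
    for u in pos:
        for v in neg:
            total += 1.0 if u > v else (0.5 if u == v else 0.0)
    return total / (len(pos) * len(neg))


class TestCStatistic:
    def test_perfect_separation_gives_one(self):
        auc, _ = c_statistic([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        auc, _ = c_statistic([0.3] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == 0.5

    def test_four_point_example(self):
        auc, _ = c_statistic([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    @settings(max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.integers(10, 500))
    def test_matches_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        p = rng.choice(np.round(rng.random(20), 2), size=n)  # force ties
        y = rng.random(n) < 0.3
        if y.all() or not y.any():
            y[0] = ~y[0]
        auc, _ = c_statistic(p, y)
        assert auc == pytest.approx(brute_force_auc(p, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        p = rng.random(300)
        y = rng.random(300) < p
        a1, _ = c_statistic(p, y)
        a2, _ = c_statistic(np.exp(3 * p), y)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_delong_ci_matches_independent_implementation(self):
        """DeLong variance cross-checked against a direct computation of the
        structural components."""
        rng = np.random.default_rng(2)
        p = rng.random(400)
        y = rng.random(400) < p
        auc, (lo, hi) = c_statistic(p, y)
        pos, neg = p[y], p[~y]
        v10 = np.array([(np.sum(u > neg) + 0.5 * np.sum(u == neg)) / len(neg)
                        for u in pos])
        v01 = np.array([(np.sum(pos > v) + 0.5 * np.sum(pos == v)) / len(pos)
                        for v in neg])
        se = np.sqrt(np.var(v10, ddof=1) / len(pos)
                     + np.var(v01, ddof=1) / len(neg))
        assert lo == pytest.approx(auc - 1.96 * se, abs=1e-10)
        assert hi == pytest.approx(auc + 1.96 * se, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            c_statistic([0.1, 0.2], [1, 1])


class TestIdi:
    def test_equal_models_give_zero(self):
        p = [0.2, 0.4, 0.6, 0.8]
        y = [0, 0, 1, 1]
        est, _ = idi(p, p, y)
        assert est == 0.0

    def test_hand_computed_slopes(self):
        p_old = [0.2, 0.2, 0.6, 0.6]
        p_new = [0.1, 0.3, 0.5, 0.9]
        y = [0, 0, 1, 1]
        assert discrimination_slope(p_new, y) == pytest.approx(0.5)
        assert discrimination_slope(p_old, y) == pytest.approx(0.4)
        est, (lo, hi) = idi(p_new, p_old, y)
        assert est == pytest.approx(0.1)
        assert lo < est < hi

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        p1, p2 = rng.random(100), rng.random(100)
        y = rng.integers(0, 2, 100)
        assert idi(p1, p2, y)[0] == pytest.approx(-idi(p2, p1, y)[0],
                                                  abs=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            idi([0.1, 0.2], [0.1], [0, 1])


def _omega_frame(n=6000, seed=4):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame({
        "diagnosis": rng.choice(["acute_myocardial_infarction", "pneumonia"],
                                n),
        "sex": rng.choice(["male", "female"], n),
        "age_category": rng.choice(["<60", "80-89"], n),
        "cci_category": rng.choice(["0", "2"], n),
        "severity_index": rng.integers(-5, 20, n),
    })
    lp = -2.5 + 0.12 * frame["severity_index"] \
        + 0.8 * (frame["age_category"] == "80-89")
    frame["death"] = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    return frame


class TestOmega:
    def test_hand_computed_variance_ratio(self):
        """Contributions (0,2,4) vs (0,1,2) give a sample-variance ratio of
        exactly 4."""
        frame = pd.DataFrame({
            "a": [0, 1, 2], "b": [0, 1, 2],
            "diagnosis": ["pneumonia"] * 3,
            "sex": ["male"] * 3,
            "age_category": ["<60"] * 3,
            "cci_category": ["0"] * 3,
            "death": [0, 0, 1],
        })
        from procsev.derivation import FittedModel, TermEstimate
        # hand-built model: beta_a = 2, beta_b = 1 on the same column values
        model = FittedModel(
            terms={"intercept": TermEstimate(0, 1, 0, 1),
                   "a": TermEstimate(2.0, 1, 2, 0.05),
                   "b": TermEstimate(1.0, 1, 1, 0.3)},
            covariates=(), extra_columns=("a", "b"), loglike=0.0, n=3,
            n_iter=1, params=np.array([0.0, 2.0, 1.0]),
            term_order=["intercept", "a", "b"])
        om, _ = omega_statistic(model, frame, ["a"], ["b"], n_boot=0)
        assert om == pytest.approx(4.0)

    def test_identical_contributions_give_one(self):
        """Two groups with identical columns and coefficients contribute
        identically, so the variance ratio is exactly 1."""
        frame = _omega_frame()
        frame["index_copy"] = frame["severity_index"]
        from procsev.derivation import FittedModel, TermEstimate
        est = TermEstimate(0.12, 0.01, 12, 0.0)
        model = FittedModel(
            terms={"intercept": TermEstimate(-2.5, 0.1, -25, 0.0),
                   "severity_index": est, "index_copy": est},
            covariates=(), extra_columns=("severity_index", "index_copy"),
            loglike=0.0, n=len(frame), n_iter=1,
            params=np.array([-2.5, 0.12, 0.12]),
            term_order=["intercept", "severity_index", "index_copy"])
        om, _ = omega_statistic(model, frame, ["severity_index"],
                                ["index_copy"], n_boot=0)
        assert om == pytest.approx(1.0, rel=1e-12)

    def test_reciprocal_identity(self):
        frame = _omega_frame()
        model = fit_logistic(frame, ["severity_index"])
        demo = [t for t in model.terms
                if t not in ("intercept", "severity_index")]
        o_ab, _ = omega_statistic(model, frame, ["severity_index"], demo,
                                  n_boot=0)
        o_ba, _ = omega_statistic(model, frame, demo, ["severity_index"],
                                  n_boot=0)
        assert o_ab * o_ba == pytest.approx(1.0, rel=1e-12)

    def test_zero_variance_reference_group_is_error(self):
        frame = _omega_frame()
        frame["flat"] = 1  # constant contribution
        from procsev.derivation import FittedModel, TermEstimate
        model = FittedModel(
            terms={"intercept": TermEstimate(0, 1, 0, 1),
                   "severity_index": TermEstimate(0.1, 0.01, 10, 0.0),
                   "flat": TermEstimate(0.5, 0.1, 5, 0.0)},
            covariates=(), extra_columns=("severity_index", "flat"),
            loglike=0.0, n=len(frame), n_iter=1,
            params=np.array([0.0, 0.1, 0.5]),
            term_order=["intercept", "severity_index", "flat"])
        with pytest.raises(ZeroMarginError):
            omega_statistic(model, frame, ["severity_index"], ["flat"],
                            n_boot=0)

    def test_overlapping_groups_rejected(self):
        frame = _omega_frame()
        model = fit_logistic(frame, ["severity_index"])
        with pytest.raises(ConfigError):
            omega_statistic(model, frame, ["severity_index"],
                            ["severity_index"], n_boot=0)

    def test_bootstrap_ci_brackets_estimate_and_is_seeded(self):
        frame = _omega_frame(n=3000)
        model = fit_logistic(frame, ["severity_index"])
        demo = [t for t in model.terms
                if t not in ("intercept", "severity_index")]
        om1, ci1 = omega_statistic(model, frame, ["severity_index"], demo,
                                   n_boot=25, seed=7)
        om2, ci2 = omega_statistic(model, frame, ["severity_index"], demo,
                                   n_boot=25, seed=7)
        assert ci1 == ci2
        assert ci1[0] < om1 < ci1[1]


class TestHosmerLemeshow:
    def test_expected_totals_conserve_sum_of_p(self):
        rng = np.random.default_rng(5)
        p = rng.random(10_000)
        y = rng.random(10_000) < p
        table = hosmer_lemeshow(p, y)
        assert table["expected"].sum() == pytest.approx(p.sum(), abs=1e-9)
        assert table["n"].sum() == 10_000

    def test_well_calibrated_simulation_tracks_observed(self):
        rng = np.random.default_rng(6)
        n = 100_000
        p = rng.beta(1, 8, n)
        y = rng.random(n) < p
        table = hosmer_lemeshow(p, y)
        assert len(table) == 10
        assert (np.abs(table["observed"] - table["expected"]) / n
                < 0.01).all()

    def test_single_group_is_overall_total(self):
        p = np.array([0.1, 0.2, 0.3])
        y = np.array([0, 1, 0])
        table = hosmer_lemeshow(p, y, g=1)
        assert len(table) == 1
        assert table.loc[0, "observed"] == 1
        assert table.loc[0, "expected"] == pytest.approx(0.6)

    def test_ties_stay_in_lower_group(self):
        p = np.array([0.1] * 6 + [0.9] * 4)
        table = hosmer_lemeshow(p, np.zeros(10), g=2)
        assert table["n"].tolist() == [6, 4]


class TestCalibrationByIndex:
    def test_dense_values_stay_unmerged(self):
        idx = np.repeat([0, 1, 2, 3], 25)
        y = np.zeros(100)
        p = np.full(100, 0.1)
        table = calibration_by_index(idx, y, p)
        assert table["label"].tolist() == ["0", "1", "2", "3"]

    def test_sparse_top_values_merge_into_range_bin(self):
        idx = np.concatenate([np.repeat([0, 1], 400),
                              np.array([10] * 3 + [11] * 3 + [12] * 3)])
        y = np.zeros(len(idx))
        p = np.full(len(idx), 0.1)
        table = calibration_by_index(idx, y, p, min_fraction=0.01)
        assert table["label"].tolist()[-1] == "10 to 12"

    def test_every_bin_holds_min_fraction(self):
        rng = np.random.default_rng(7)
        idx = np.round(rng.normal(3, 6, 20_000)).astype(int)
        p = np.clip(0.02 * (idx + 13), 0.001, 0.99)
        y = rng.random(20_000) < p
        table = calibration_by_index(idx, y, p, min_fraction=0.01)
        assert (table["fraction"] >= 0.01).all()
        assert table["n"].sum() == 20_000
        # bins cover contiguous, ordered, disjoint ranges
        assert (table["index_low"] <= table["index_high"]).all()
        assert (table["index_low"].to_numpy()[1:]
                > table["index_high"].to_numpy()[:-1]).all()


class TestRunValidation:
    def test_battery_on_synthetic_cohort(self, small_scored_frame):
        report = run_validation(small_scored_frame, n_boot=15, seed=1,
                                subgroup_columns=("ambulance",))
        assert set(report.models) == {"model1", "model2", "model3", "model4"}
        for m in report.models.values():
            lo, hi = m["ci95"]
            assert 0 <= lo <= m["c"] <= hi <= 1
        # the index genuinely adds discrimination over demographics alone
        assert report.models["model4"]["c"] > report.models["model3"]["c"]
        assert report.idi["estimate"] > 0
        assert report.omega["estimate"] > 0
        assert len(report.hosmer_lemeshow) == 10
        assert any(k.startswith("diagnosis=") for k in report.subgroups)
        assert any(k.startswith("ambulance=") for k in report.subgroups)

    def test_deterministic_given_seed(self, small_scored_frame):
        frame = small_scored_frame.head(6_000)
        r1 = run_validation(frame, n_boot=8, seed=3, per_diagnosis=False)
        r2 = run_validation(frame, n_boot=8, seed=3, per_diagnosis=False)
        assert r1.to_json() == r2.to_json()

    def test_missing_index_column_rejected(self, default_frame):
        with pytest.raises(ConfigError):
            run_validation(default_frame.head(100))
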