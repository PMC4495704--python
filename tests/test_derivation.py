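import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit
from scipy.stats import kstest

from procsev.derivation import (PointTable, assign_points, fit_logistic,
                                index_range, published_index,
                                reference_coefficient, round_half_away,
                                score_frame, score_index)
from procsev.errors import (ConfigError, NoReferenceError,
                            SingularDesignError)


def _simulated_frame(n, betas, seed, cci1=0.03, cci2=0.182, cci3=0.72):
    """Frame with the four demographic covariates and binary procedure
    columns, death drawn from a known logistic model."""
    rng = np.random.default_rng(seed)
    diag = rng.choice(["acute_myocardial_infarction", "pneumonia",
                       "septicemia"], n, p=[0.3, 0.5, 0.2])
    sex = rng.choice(["male", "female"], n)
    age = rng.choice(["<60", "70-79", ">=90"], n, p=[0.3, 0.5, 0.2])
    cci = rng.choice(["0", "1", "2", ">=3"], n, p=[0.6, 0.13, 0.19, 0.08])
    lp = (-2.8
          + 0.7 * (diag == "septicemia") + 0.04 * (diag == "pneumonia")
          - 0.12 * (sex == "female")
          + 0.68 * (age == "70-79") + 1.60 * (age == ">=90")
          + cci1 * (cci == "1") + cci2 * (cci == "2") + cci3 * (cci == ">=3"))
    frame = pd.DataFrame({"diagnosis": diag, "sex": sex,
                          "age_category": age, "cci_category": cci})
    for name, beta in betas.items():
        x = rng.random(n) < 0.25
        frame[name] = x.astype(int)
        lp = lp + beta * x
    frame["death"] = (rng.random(n) < expit(lp)).astype(int)
    return frame


PROC_BETAS = {"proc_pos": 0.9, "proc_neg": -0.4, "proc_null": 0.0}


class TestFitLogistic:
    def test_recovers_known_coefficients(self):
        frame = _simulated_frame(200_000, PROC_BETAS, seed=5)
        model = fit_logistic(frame, list(PROC_BETAS))
        for term, truth in [("proc_pos", 0.9), ("proc_neg", -0.4),
                            ("proc_null", 0.0), ("age=>=90", 1.60),
                            ("sex=female", -0.12)]:
            est = model[term]
            assert abs(est.beta - truth) < 3 * est.se, term

    def test_wald_machinery_is_consistent(self):
        frame = _simulated_frame(5_000, PROC_BETAS, seed=6)
        model = fit_logistic(frame, list(PROC_BETAS))
        est = model["proc_pos"]
        assert est.odds_ratio == pytest.approx(np.exp(est.beta))
        lo, hi = est.ci95
        assert lo < est.odds_ratio < hi
        assert est.z == pytest.approx(est.beta / est.se)

    def test_null_term_p_values_are_uniform(self):
        """Under no true effect, the Wald P of the procedure term follows
        Uniform(0,1) across replicate simulations."""
        pvals = []
        for rep in range(60):
            frame = _simulated_frame(1_500, {"proc_null": 0.0},
                                     seed=1000 + rep)
            pvals.append(fit_logistic(frame, ["proc_null"])["proc_null"].p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_duplicated_column_raises_singular_design(self):
        frame = _simulated_frame(500, {"proc_pos": 0.5}, seed=7)
        frame["copy"] = frame["proc_pos"]
        with pytest.raises(SingularDesignError):
            fit_logistic(frame, ["proc_pos", "copy"])

    def test_prediction_matches_design_algebra(self):
        frame = _simulated_frame(2_000, PROC_BETAS, seed=8)
        model = fit_logistic(frame, list(PROC_BETAS))
        p = model.predict(frame)
        assert p.shape == (2_000,)
        assert ((p > 0) & (p < 1)).all()
        # mean predicted risk equals observed rate at the MLE (score eq.)
        assert p.mean() == pytest.approx(frame["death"].mean(), abs=1e-8)


class TestReferenceCoefficient:
    def _model_with(self, p1, b2=0.182, p2=1e-6, b1=0.03):
        frame = _simulated_frame(60_000, {}, seed=9)
        model = fit_logistic(frame, [])
        # surgically install the CCI estimates under test
        from procsev.derivation import TermEstimate
        model.terms["cci=1"] = TermEstimate(b1, 0.02, b1 / 0.02, p1)
        model.terms["cci=2"] = TermEstimate(b2, 0.02, b2 / 0.02, p2)
        return model

    def test_nonsignificant_cci1_falls_back_to_half_cci2(self):
        model = self._model_with(p1=0.233)
        assert reference_coefficient(model) == pytest.approx(0.091)

    def test_significant_cci1_is_used_directly(self):
        model = self._model_with(p1=0.001, b1=0.10)
        assert reference_coefficient(model) == pytest.approx(0.10)

    def test_both_nonsignificant_is_an_error(self):
        model = self._model_with(p1=0.233, p2=0.40)
        with pytest.raises(NoReferenceError):
            reference_coefficient(model)


class TestAssignPoints:
    def test_published_intubation_arithmetic(self):
        assert round_half_away(2.05 / 0.091) == 23

    @pytest.mark.parametrize("x,expected", [
        (2.5, 3), (-2.5, -3), (2.49, 2), (-0.4, 0), (0.5, 1), (-0.5, -1),
        (22.527, 23)])
    def test_rounding_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected

    def test_nonsignificant_procedures_get_no_entry(self):
        frame = _simulated_frame(150_000, {"proc_pos": 0.9,
                                           "proc_null": 0.0}, seed=10)
        model = fit_logistic(frame, ["proc_pos", "proc_null"])
        table = assign_points(model, 0.091)
        assert "proc_pos" in table.points
        assert "proc_null" not in table.points
        assert table.points["proc_pos"] == round_half_away(
            model["proc_pos"].beta / 0.091)

    @given(st.floats(0.1, 10))
    def test_invariant_to_joint_rescaling(self, c):
        """Scaling (beta, ref) -> (c*beta, c*ref) leaves points unchanged."""
        betas = [-0.3, -0.18, 0.06, 0.47, 2.05]
        ref = 0.091
        before = [round_half_away(b / ref) for b in betas]
        after = [round_half_away(c * b / (c * ref)) for b in betas]
        assert before == after

    def test_zero_reference_rejected(self):
        frame = _simulated_frame(5_000, {"proc_pos": 0.9}, seed=11)
        model = fit_logistic(frame, ["proc_pos"])
        with pytest.raises(ConfigError):
            assign_points(model, 0.0)


PUBLISHED = published_index()


class TestPublishedIndex:
    def test_has_nineteen_scored_procedures(self):
        assert len(PUBLISHED) == 19

    @pytest.mark.parametrize("name,points", [
        ("intratracheal_intubation", 23),
        ("sputum_suction", 12),
        ("urinary_catheter_insertion", 5),
        ("catecholamines_or_vasopressin", 8),
        ("invasive_arterial_pressure_measurement", -3),
        ("blood_tests_excluding_coagulation", -3),
        ("temporary_urinary_catheterization", -1),
    ])
    def test_published_points(self, name, points):
        assert PUBLISHED[name] == points

    def test_attainable_range(self):
        assert index_range(PUBLISHED) == (-13, 69)

    def test_all_positive_procedures_hit_the_maximum(self):
        fv = {k: int(v > 0) for k, v in PUBLISHED.points.items()}
        assert score_index(fv, PUBLISHED) == 69

    def test_json_round_trip(self):
        again = PointTable.from_json(PUBLISHED.to_json())
        assert again.points == PUBLISHED.points
        assert again.reference_coefficient == 0.091


class TestScoreIndex:
    def test_no_procedures_scores_zero(self):
        fv = dict.fromkeys(PUBLISHED.points, 0)
        assert score_index(fv, PUBLISHED) == 0

    def test_mixed_published_example(self):
        """CT (+3) + pulse oximetry (+3) + blood tests (-3) +
        radiography (-2) = 1."""
        fv = dict.fromkeys(PUBLISHED.points, 0)
        for k in ("computed_tomography_scan", "pulse_oximetry",
                  "blood_tests_excluding_coagulation", "radiography"):
            fv[k] = 1
        assert score_index(fv, PUBLISHED) == 1

    def test_additive_over_disjoint_sets(self):
        a = dict.fromkeys(PUBLISHED.points, 0)
        b = dict.fromkeys(PUBLISHED.points, 0)
        a["sputum_suction"] = 1
        b["radiography"] = b["urinary_catheter_insertion"] = 1
        union = {k: a[k] | b[k] for k in a}
        assert (score_index(union, PUBLISHED)
                == score_index(a, PUBLISHED) + score_index(b, PUBLISHED))

    def test_missing_indicator_warns_and_counts_zero(self):
        with pytest.warns(UserWarning, match="missing"):
            assert score_index({"sputum_suction": 1}, PUBLISHED) == 12

    def test_score_frame_matches_scalar_path(self):
        rng = np.random.default_rng(12)
        frame = pd.DataFrame(
            rng.integers(0, 2, size=(50, 19)), columns=list(PUBLISHED.points))
        vec = score_frame(frame, PUBLISHED)
        scalar = [score_index(row.to_dict(), PUBLISHED)
                  for _, row in frame.iterrows()]
        assert vec.tolist() == scalar

    def test_index_range_definitions(self):
        assert index_range(PointTable({}, 0.1)) == (0, 0)
        assert index_range(PointTable({"a": -2, "b": 5, "c": 7}, 0.1)) \
            == (-2, 12)
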