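"""Analytic density layer: closed-form, symmetry, and quadrature oracles."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from piddm import (
    DDMParameterSet,
    choice_probability,
    full_density,
    log_likelihood,
    predicted_quantiles,
    prob_upper,
    wfpt_density,
)
from piddm.params import CONDITIONS
from piddm.wfpt import _defective_cdf_grid

S = 0.1


def upper_mass(v, a, z, upper=True, s=S):
    """Independent oracle: integrate the defective density numerically."""
    boundary = "upper" if upper else "lower"
    val, _err = integrate.quad(
        lambda t: wfpt_density(t, boundary, v, a, z, s), 1e-6, 60.0, limit=400
    )
    return val


# A grid spanning the scale of the fitted group estimates.
PARAM_GRID = [
    (0.366, 0.176, 0.088),
    (0.230, 0.176, 0.088),
    (0.304, 0.229, 0.1145),
    (0.196, 0.229, 0.1145),
    (-0.25, 0.15, 0.075),
    (0.05, 0.10, 0.03),  # biased start
]


class TestWfptDensity:
    @pytest.mark.parametrize("v,a,z", PARAM_GRID)
    def test_total_mass_is_one(self, v, a, z):
        total = upper_mass(v, a, z, True) + upper_mass(v, a, z, False)
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("v,a,z", PARAM_GRID)
    def test_defective_mass_matches_closed_form(self, v, a, z):
        # absorption probability has an exact closed form; the density does not
        assert upper_mass(v, a, z, True) == pytest.approx(prob_upper(v, a, z), abs=1e-7)

    def test_zero_drift_symmetry(self):
        t = np.linspace(0.05, 2.0, 40)
        up = wfpt_density(t, "upper", 0.0, 0.16, 0.08)
        lo = wfpt_density(t, "lower", 0.0, 0.16, 0.08)
        assert np.allclose(up, lo, rtol=1e-10)

    def test_reflection_symmetry(self):
        # f_upper(t | v, z) == f_lower(t | -v, a - z)
        t = np.linspace(0.05, 3.0, 50)
        a, z, v = 0.18, 0.06, 0.25
        up = wfpt_density(t, "upper", v, a, z)
        lo = wfpt_density(t, "lower", -v, a, a - z)
        assert np.allclose(up, lo, rtol=1e-12, atol=1e-300)

    def test_nonnegative_and_vanishing_tails(self):
        t = np.linspace(1e-4, 30.0, 200)
        d = wfpt_density(t, "lower", 0.3, 0.16, 0.08)
        assert (d >= 0).all()
        assert d[-1] < 1e-12

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            wfpt_density(0.5, "sideways", 0.3, 0.16, 0.08)
        with pytest.raises(ValueError):
            wfpt_density(0.5, "upper", 0.3, 0.16, 0.20)  # z outside (0, a)
        with pytest.raises(ValueError):
            wfpt_density(-0.1, "upper", 0.3, 0.16, 0.08)


class TestProbUpper:
    def test_unbiased_closed_form(self):
        # for z = a/2 the absorption probability is logistic in v*a/s^2
        v, a = 0.366, 0.176
        expected = 1.0 / (1.0 + math.exp(-v * a / (S * S)))
        assert prob_upper(v, a, a / 2) == pytest.approx(expected, rel=1e-12)

    def test_zero_drift_is_start_fraction(self):
        assert prob_upper(0.0, 0.2, 0.05) == pytest.approx(0.25, rel=1e-12)

    def test_complementarity_under_reflection(self):
        v, a, z = 0.3, 0.18, 0.05
        assert prob_upper(v, a, z) + prob_upper(-v, a, a - z) == pytest.approx(1.0, rel=1e-12)

    def test_extreme_drift_stable(self):
        assert prob_upper(3.0, 0.2, 0.1) == pytest.approx(1.0, abs=1e-10)
        assert prob_upper(-3.0, 0.2, 0.1) == pytest.approx(0.0, abs=1e-10)


class TestFullDensity:
    def test_reduces_to_wfpt_without_variabilities(self, young_params):
        p = young_params.replace(eta=0.0, sz=0.0, st=0.0)
        t = np.linspace(0.35, 2.0, 30)
        cell = p.for_condition("positive")
        direct = wfpt_density(t - cell["ter"], "upper", cell["v"], cell["a"], cell["z"])
        assert np.allclose(full_density(t, "correct", p, "positive"), direct, rtol=1e-12)

    def test_eta_matches_numerical_mixture(self, young_params):
        # drift-variability factor is analytic; check it against brute-force
        # integration of the no-variability density over Normal(v, eta) drifts
        p = young_params.replace(sz=0.0, st=0.0, eta=0.12)
        cell = p.for_condition("positive")
        for t in (0.45, 0.7, 1.2):
            td = t - cell["ter"]
            oracle, _ = integrate.quad(
                lambda mu: norm.pdf(mu, cell["v"], cell["eta"])
                * wfpt_density(td, "upper", mu, cell["a"], cell["z"]),
                cell["v"] - 8 * cell["eta"],
                cell["v"] + 8 * cell["eta"],
                limit=200,
            )
            assert full_density(t, "correct", p, "positive") == pytest.approx(oracle, rel=1e-8)

    def test_sz_quadrature_matches_adaptive_oracle(self, young_params):
        p = young_params.replace(eta=0.0, st=0.0, sz=0.05)
        cell = p.for_condition("positive")
        for t in (0.45, 0.8):
            td = t - cell["ter"]
            oracle, _ = integrate.quad(
                lambda z0: wfpt_density(td, "upper", cell["v"], cell["a"], z0) / cell["sz"],
                cell["z"] - cell["sz"] / 2,
                cell["z"] + cell["sz"] / 2,
                limit=200,
            )
            assert full_density(t, "correct", p, "positive") == pytest.approx(oracle, rel=1e-6)

    def test_st_quadrature_matches_adaptive_oracle(self, young_params):
        p = young_params.replace(eta=0.0, sz=0.0, st=0.16)
        cell = p.for_condition("positive")
        for t in (0.45, 0.8):
            oracle, _ = integrate.quad(
                lambda t0: wfpt_density(t - t0, "upper", cell["v"], cell["a"], cell["z"])
                / cell["st"],
                cell["ter"] - cell["st"] / 2,
                cell["ter"] + cell["st"] / 2,
                limit=200,
            )
            assert full_density(t, "correct", p, "positive") == pytest.approx(oracle, rel=1e-6)

    def test_full_variability_mass_is_one(self, young_params):
        total = 0.0
        for response in ("correct", "error"):
            val, _ = integrate.quad(
                lambda t: full_density(t, response, young_params, "recent_negative"),
                0.0,
                30.0,
                limit=400,
            )
            total += val
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_stimulus_coding_negative_trials(self, young_params):
        # stimulus coding on a negative trial: correct response is the lower
        # boundary with drift -v toward it; for an unbiased start this equals
        # the accuracy-coded density
        t = np.linspace(0.4, 1.5, 20)
        acc = full_density(t, "correct", young_params, "recent_negative", coding="accuracy")
        stim = full_density(t, "correct", young_params, "recent_negative", coding="stimulus")
        assert np.allclose(acc, stim, rtol=1e-10)

    def test_correct_mass_matches_choice_probability(self, young_params):
        mass, _ = integrate.quad(
            lambda t: full_density(t, "correct", young_params, "positive"),
            0.0,
            30.0,
            limit=400,
        )
        assert mass == pytest.approx(
            choice_probability(young_params, "positive"), abs=1e-6
        )


class TestChoiceProbability:
    def test_zero_drift_unbiased_is_half(self):
        p = DDMParameterSet(v=0.0, eta=0.0, a=0.16, sz=0.0, ter=0.3, st=0.0)
        assert choice_probability(p, "positive") == pytest.approx(0.5, rel=1e-10)

    def test_monotone_in_drift(self):
        probs = [
            choice_probability(
                DDMParameterSet(v=v, eta=0.1, a=0.16, sz=0.02, ter=0.3, st=0.1), "positive"
            )
            for v in (0.1, 0.2, 0.3, 0.4)
        ]
        assert np.all(np.diff(probs) > 0)

    def test_correct_and_error_sum_to_one(self, older_params):
        for cond in CONDITIONS:
            summary = predicted_quantiles(older_params, cond)
            total = sum(summary.proportion[(cond, r)] for r in ("correct", "error"))
            assert total == pytest.approx(1.0, abs=1e-9)


class TestPredictedQuantiles:
    def test_quantiles_nondecreasing(self, young_params):
        for cond in CONDITIONS:
            s = predicted_quantiles(young_params, cond)
            for key, q in s.quantiles.items():
                if key in s.unreliable:
                    continue
                assert np.all(np.diff(q) >= -1e-10)

    def test_median_inverts_cdf(self, young_params):
        s = predicted_quantiles(young_params, "positive")
        med = s.quantiles[("positive", "correct")][2]
        t, cdf = _defective_cdf_grid(young_params, "positive", "correct", "accuracy")
        # CDF at the reported median equals half the correct-response mass
        assert np.interp(med, t, cdf) == pytest.approx(0.5 * cdf[-1], rel=1e-3)

    def test_ter_shift_translates_quantiles(self, young_params):
        base = predicted_quantiles(young_params, "positive")
        shifted = predicted_quantiles(young_params.replace(ter=0.404), "positive")
        dq = (
            shifted.quantiles[("positive", "correct")]
            - base.quantiles[("positive", "correct")]
        )
        assert np.allclose(dq, 0.1, atol=1e-3)

    def test_tiny_error_mass_flagged_unreliable(self):
        p = DDMParameterSet(v=1.2, eta=0.0, a=0.2, sz=0.0, ter=0.3, st=0.0)
        s = predicted_quantiles(p, "positive")
        assert ("positive", "error") in s.unreliable
        assert np.isnan(s.quantiles[("positive", "error")]).all()


class TestLogLikelihood:
    def test_matches_sum_of_log_densities(self, young_dataset, young_params):
        sub = young_dataset.head(50)
        ll = log_likelihood(sub, young_params)
        manual = 0.0
        for _, row in sub.iterrows():
            resp = "correct" if row["accuracy"] == 1 else "error"
            d = full_density(row["rt_s"], resp, young_params, row["condition"])
            manual += math.log(max(d, 1e-10))
        assert ll == pytest.approx(manual, rel=1e-9)

    def test_additive_under_duplication(self, young_dataset, young_params):
        import pandas as pd

        sub = young_dataset.head(40)
        twice = pd.concat([sub, sub], ignore_index=True)
        assert log_likelihood(twice, young_params) == pytest.approx(
            2 * log_likelihood(sub, young_params), rel=1e-12
        )

    def test_floor_keeps_outliers_finite(self, young_params):
        import pandas as pd

        # an RT far below the nondecision support has zero density
        df = pd.DataFrame(
            {"condition": ["positive"], "rt_s": [0.205], "accuracy": [1]}
        )
        ll = log_likelihood(df, young_params.replace(st=0.0, ter=0.304))
        assert ll == pytest.approx(math.log(1e-10))

    def test_empty_data_raises(self, young_params):
        import pandas as pd

        with pytest.raises(ValueError, match="empty"):
            log_likelihood(pd.DataFrame({"condition": [], "rt_s": [], "accuracy": []}), young_params)

    def test_true_parameters_beat_perturbed(self, young_dataset, young_params):
        ll_true = log_likelihood(young_dataset, young_params)
        worse = young_params.replace(ter=0.45, v={c: v * 0.5 for c, v in young_params.v.items()})
        assert ll_true > log_likelihood(young_dataset, worse)
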