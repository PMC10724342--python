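"""ABC rejection: distance, acceptance rule, summaries, family fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from glioimmune import (AbcRejection, ParameterSet, fit_distribution,
                        posterior_summaries, relative_error)
from glioimmune.abcfit import (DEFAULT_THRESHOLDS, FAMILIES, AbcResults,
                               PriorSpec, _frozen, _moment_start,
                               _w1_to_sample)


class TestRelativeError:
    def test_identity_is_zero(self):
        assert relative_error([3.0, 5.0, 7.0], [3.0, 5.0, 7.0]) == 0.0

    def test_hand_computed_case(self):
        assert relative_error([100, 200], [110, 180]) == pytest.approx(0.1)

    def test_zero_simulation_gives_one(self):
        assert relative_error([4.0, 9.0, 2.0], [0, 0, 0]) == 1.0

    def test_nonpositive_data_rejected(self):
        with pytest.raises(ValueError):
            relative_error([1.0, 0.0], [1.0, 1.0])

    @given(st.lists(st.floats(1e-3, 1e6), min_size=1, max_size=20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_nonnegative_and_scale_invariant(self, d):
        d = np.asarray(d)
        x = d * 1.3
        e = relative_error(d, x)
        assert e >= 0
        assert e == pytest.approx(0.3, rel=1e-9)
        # error is invariant under joint rescaling of data and simulation
        assert relative_error(10 * d, 10 * x) == pytest.approx(e, rel=1e-9)


class TestPriorSpec:
    def test_default_bounds_are_valid(self):
        PriorSpec()

    def test_rejects_inverted_bounds(self):
        bad = dict(PriorSpec().bounds)
        bad["lambda_C"] = (0.5, 0.1)
        with pytest.raises(ValueError):
            PriorSpec(bad)

    def test_only_mdsc_recruitment_may_start_at_zero(self):
        bad = dict(PriorSpec().bounds)
        bad["eta"] = (0.0, 1e-6)
        with pytest.raises(ValueError):
            PriorSpec(bad)

    def test_sampling_is_deterministic_and_in_bounds(self):
        spec = PriorSpec()
        a = spec.sample(50, seed=4)
        b = spec.sample(50, seed=4)
        np.testing.assert_array_equal(a, b)
        for j, name in enumerate(spec.bounds):
            lo, hi = spec.bounds[name]
            assert np.all((a[:, j] >= lo) & (a[:, j] <= hi))


class TestAcceptanceRule:
    def _result(self, synth_data, errors):
        model = AbcRejection(synth_data)
        n = len(errors)
        draws = model.priors.sample(n, seed=0)
        return AbcResults(model, draws, np.asarray(errors, float),
                          DEFAULT_THRESHOLDS, seed=0)

    def test_error_equal_to_threshold_is_accepted(self, synth_data):
        rc, rt, rm = DEFAULT_THRESHOLDS
        res = self._result(synth_data, [[rc, rt, rm]])
        assert res.accepted_mask[0]

    def test_tiny_exceedance_is_rejected(self, synth_data):
        rc, rt, rm = DEFAULT_THRESHOLDS
        res = self._result(synth_data, [[0.0, rt + 1e-6, 0.0]])
        assert not res.accepted_mask[0]

    def test_total_error_additivity(self, synth_data):
        rng = np.random.default_rng(0)
        errors = rng.uniform(0, 2, size=(100, 3))
        res = self._result(synth_data, errors)
        np.testing.assert_array_equal(res.e_total, errors.sum(axis=1))

    def test_posterior_size_uses_ceiling(self, synth_data):
        errors = np.tile([[0.1, 0.1, 0.1]], (10, 1))
        errors[:, 0] += np.arange(10) * 1e-3
        res = self._result(synth_data, errors)
        assert res.n_accepted == 10
        assert len(res.posterior) == math.ceil(0.25 * 10)

    def test_acceptance_monotone_in_thresholds(self, abc_run):
        errors = abc_run.errors
        base = abc_run.n_accepted
        for j in range(3):
            wider = list(abc_run.thresholds)
            wider[j] += 0.2
            n = int(((errors[:, 0] <= wider[0]) & (errors[:, 1] <= wider[1])
                     & (errors[:, 2] <= wider[2])).sum())
            assert n >= base

    def test_failed_solves_scored_infinite(self, synth_data):
        model = AbcRejection(synth_data)
        # A pathological stiff draw: enormous stimulation, no inhibition.
        bad = ParameterSet.from_dict({
            "lambda_C": 0.5, "C_max": 4.5e7, "eta": 1e-8, "a_T": 6e6,
            "s_T": 1e7, "rho": 1e-300, "eps_C": 1.0, "r": 1e-7,
            "d_T": 0.01, "s_M": 0.1, "alpha": 5e8, "q": 1e9, "d_M": 0.01})
        errs = model.errors_for(bad)
        assert np.all(errs >= 0)  # finite or +inf, never NaN/negative


class TestSummaries:
    def test_constant_sample(self):
        mean, med, mode, sd = posterior_summaries(np.full(20, 3.5))
        assert mean == med == mode == 3.5
        assert sd == 0.0

    def test_small_integer_sample(self):
        mean, med, _, sd = posterior_summaries(np.array([1, 2, 3, 4, 5] * 2))
        assert mean == 3.0 and med == 3.0
        assert sd == pytest.approx(np.std([1, 2, 3, 4, 5] * 2, ddof=1))

    def test_gamma_mode_matches_analytic(self):
        rng = np.random.default_rng(12)
        s = rng.gamma(5.4, 0.05, size=100_000)
        _, _, mode, _ = posterior_summaries(s)
        assert mode == pytest.approx((5.4 - 1) * 0.05, rel=0.05)

    def test_requires_ten_samples(self):
        with pytest.raises(ValueError):
            posterior_summaries(np.arange(9))


class TestFamilyFitting:
    def test_uniform_recovery(self):
        rng = np.random.default_rng(0)
        fit = fit_distribution(rng.uniform(0, 1, 100_000),
                               ("uniform", "normal", "exponential"))
        assert fit.family == "uniform"
        assert fit.parameters["lo"] == pytest.approx(0.0, abs=0.01)
        assert fit.parameters["hi"] == pytest.approx(1.0, abs=0.01)

    def test_exponential_recovery(self):
        rng = np.random.default_rng(1)
        fit = fit_distribution(rng.exponential(0.223, 100_000))
        assert fit.family == "exponential"
        assert fit.parameters["mean"] == pytest.approx(0.223, rel=0.03)

    def test_gamma_recovery(self):
        rng = np.random.default_rng(2)
        fit = fit_distribution(rng.gamma(5.4, 0.05, 100_000))
        assert fit.family == "gamma"
        assert fit.parameters["shape"] == pytest.approx(5.4, rel=0.1)

    def test_self_quantiles_have_near_zero_distance(self):
        frozen = stats.gamma(5.4, scale=0.05)
        levels = (np.arange(10_000) + 0.5) / 10_000
        sample = frozen.ppf(levels)
        fit = fit_distribution(sample, ("gamma",))
        assert fit.w1_distance < 1e-3 * sample.std()

    def test_winner_is_optimal_up_to_quantile_noise(self):
        rng = np.random.default_rng(3)
        s = np.sort(rng.gamma(2.0, 1.5, 5_000))
        fit = fit_distribution(s)
        levels = (np.arange(2048) + 0.5) / 2048
        emp_q = np.quantile(s, levels)
        noise = s.std(ddof=1) / math.sqrt(len(s))
        for fam in FAMILIES:
            w1_start = _w1_to_sample(fam, _moment_start(fam, s), emp_q, levels)
            assert fit.w1_distance <= w1_start + noise

    def test_degenerate_sample_returns_point_mass(self):
        fit = fit_distribution(np.full(200, 2.0))
        assert fit.family == "point_mass"
        assert fit.w1_distance == 0.0

    def test_frozen_distributions_resample_consistently(self):
        fit = fit_distribution(np.random.default_rng(4).normal(10, 2, 10_000))
        frozen = fit.frozen()
        assert frozen.mean() == pytest.approx(10, rel=0.05)


class TestRobustness:
    def test_posterior_stable_across_subset_fractions(self, abc_run):
        """Medians of the smallest 10/25/50% of accepted draws agree to
        within 25% plus the Monte-Carlo error of a median at this scale."""
        acc = abc_run.accepted.sort_values("E_total", kind="stable")
        for name in ("lambda_C", "d_M", "s_M"):
            meds, sems = [], []
            for f in (0.10, 0.25, 0.50):
                sub = acc.head(max(1, math.ceil(f * len(acc))))[name]
                meds.append(sub.median())
                sems.append(1.25 * sub.std(ddof=1) / math.sqrt(len(sub)))
            ref = meds[1]
            for m, s in zip(meds, sems):
                assert abs(m - ref) <= 0.25 * ref + 2 * (s + sems[1])
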