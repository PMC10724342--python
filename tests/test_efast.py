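"""eFAST search curves, design construction, and index estimation."""

import numpy as np
import pytest
from scipy.stats import kstest

from glioimmune.efast import (build_design, run_efast, run_efast_on_model,
                              search_curve_exponential, search_curve_uniform)


class TestSearchCurves:
    def test_uniform_curve_landmarks(self):
        # arcsin(sin(pi/2)) = pi/2 -> x = 1; angle 0 -> x = 1/2.
        assert search_curve_uniform(np.pi / 2, 1.0, 0.0) == pytest.approx(1.0)
        assert search_curve_uniform(0.0, 1.0, 0.0) == pytest.approx(0.5)

    def test_uniform_curve_fills_unit_interval_uniformly(self):
        s = np.linspace(-np.pi, np.pi, 100_001)[:-1]
        x = search_curve_uniform(s, 11, 0.7)
        assert kstest(x, "uniform").statistic < 0.01

    def test_exponential_curve_landmarks(self):
        # sin = 1 -> n * (1/n) = 1; sin = -1 -> n^2; sin = 0 -> nominal.
        assert search_curve_exponential(np.pi / 2, 1.0, 0.0, 0.1) == pytest.approx(1.0)
        assert search_curve_exponential(-np.pi / 2, 1.0, 0.0, 0.1) == pytest.approx(0.01)
        assert search_curve_exponential(0.0, 1.0, 0.0, 0.1) == pytest.approx(0.1)

    def test_exponential_nominal_validated(self):
        with pytest.raises(ValueError):
            search_curve_exponential(0.0, 1.0, 0.0, 1.5)


class TestDesign:
    def test_nyquist_frequency_for_default_size(self):
        design = build_design(d=13, NS=2049, NR=5, M=4)
        assert design.omega_max == 256  # (NS - 1) / (2 M)

    def test_block_sample_count(self):
        design = build_design(d=13, NS=2049, NR=5, M=4)
        assert design.samples_per_block == 10_245

    def test_all_uniform_samples_stay_in_unit_box(self):
        design = build_design(d=4, NS=129, NR=2, M=4, seed=1)
        for block in range(4):
            for r in range(2):
                X = design.samples(block, r)
                assert np.all((X >= 0) & (X <= 1))

    def test_frequency_separation(self):
        design = build_design(d=13, NS=513, NR=1, M=4)
        freqs = design.frequencies(block=5)
        others = np.delete(freqs, 5)
        assert freqs[5] == design.omega_max
        assert np.all(freqs[5] > design.M * others)

    def test_even_or_tiny_ns_rejected(self):
        with pytest.raises(ValueError):
            build_design(d=3, NS=128)
        with pytest.raises(ValueError):
            build_design(d=3, NS=7, M=4)


class TestIndices:
    def test_constant_output_gives_zero_indices_with_warning(self):
        design = build_design(d=3, NS=129, NR=2, M=4, seed=2)
        idx = run_efast(lambda X: np.full(len(X), 3.0), design)
        assert np.all(idx.S == 0) and np.all(idx.ST == 0)
        assert any("constant output" in w for w in idx.warnings)

    def test_linear_additive_model_matches_analytic_sobol(self):
        a = np.array([1.0, 2.0, 0.0])
        V = (a**2).sum() / 12
        true_S = (a**2 / 12) / V
        design = build_design(d=3, NS=513, NR=5, M=4, seed=7)
        idx = run_efast(lambda X: X @ a, design)
        np.testing.assert_allclose(idx.S.ravel(), true_S, atol=0.05)
        assert idx.S[1, 0] / idx.S[0, 0] == pytest.approx(4.0, rel=0.1)
        # additive model: total indices equal first-order ones
        np.testing.assert_allclose(idx.ST.ravel(), true_S, atol=0.05)

    def test_ishigami_matches_closed_form(self):
        A, B = 7.0, 0.1
        ranges = np.array([[-np.pi, np.pi]] * 3)
        design = build_design(d=3, NS=1025, NR=5, M=4, seed=11, ranges=ranges)

        def ishigami(X):
            return (np.sin(X[:, 0]) + A * np.sin(X[:, 1]) ** 2
                    + B * X[:, 2] ** 4 * np.sin(X[:, 0]))

        idx = run_efast(ishigami, design)
        V = A**2 / 8 + B * np.pi**4 / 5 + B**2 * np.pi**8 / 18 + 0.5
        S1 = 0.5 * (1 + B * np.pi**4 / 5) ** 2 / V
        S2 = (A**2 / 8) / V
        V13 = B**2 * np.pi**8 * (1 / 18 - 1 / 50)
        np.testing.assert_allclose(idx.S.ravel(), [S1, S2, 0.0], atol=0.05)
        np.testing.assert_allclose(idx.ST.ravel(),
                                   [S1 + V13 / V, S2, V13 / V], atol=0.05)
        # interaction detected: total index of x3 exceeds its first-order one
        assert idx.ST[2, 0] > idx.S[2, 0] + 0.1

    def test_first_order_below_total_order(self):
        design = build_design(d=3, NS=513, NR=5, M=4, seed=3)
        idx = run_efast(lambda X: X[:, 0] * X[:, 1] + X[:, 2], design)
        assert np.all(idx.S <= idx.ST + 0.02)
        assert idx.S.sum() <= 1.05

    def test_estimates_converge_with_sample_size(self):
        """Raising NS past the aliasing threshold must shrink the error.

        On the Ishigami function the index error is dominated by frequency
        interference when NS is small and collapses once the spectrum is
        resolved; beyond that it plateaus at the harmonic-truncation bias,
        so the halving check is applied across the resolution threshold.
        """
        A, B = 7.0, 0.1
        V = A**2 / 8 + B * np.pi**4 / 5 + B**2 * np.pi**8 / 18 + 0.5
        true_S = np.array([0.5 * (1 + B * np.pi**4 / 5) ** 2 / V,
                           (A**2 / 8) / V, 0.0])
        ranges = np.array([[-np.pi, np.pi]] * 3)

        def ishigami(X):
            return (np.sin(X[:, 0]) + A * np.sin(X[:, 1]) ** 2
                    + B * X[:, 2] ** 4 * np.sin(X[:, 0]))

        devs = []
        for NS in (129, 257):
            design = build_design(d=3, NS=NS, NR=5, M=4, seed=21, ranges=ranges)
            idx = run_efast(ishigami, design)
            devs.append(np.abs(idx.S.ravel() - true_S).sum())
        assert devs[1] <= devs[0] / 2 * 1.5

    def test_resampling_spread_shrinks(self):
        a = np.array([1.0, 2.0, 0.5])
        sems = []
        for NR in (5, 20):
            design = build_design(d=3, NS=257, NR=NR, M=4, seed=13)
            idx = run_efast(lambda X: X @ a, design)
            sems.append(idx.sem_S.mean())
        # SEM should shrink roughly like 1/sqrt(NR): factor 2 within [1.3, 3].
        assert 1.3 <= sems[0] / sems[1] <= 3.0

    def test_failed_solve_imputation(self):
        design = build_design(d=3, NS=129, NR=2, M=4, seed=4)

        def flaky(X):
            y = X @ np.array([1.0, 2.0, 0.0])
            y[::50] = np.nan  # ~2% failures
            return y

        idx = run_efast(flaky, design)
        assert any("imputed" in w for w in idx.warnings)

        def broken(X):
            y = X @ np.array([1.0, 2.0, 0.0])
            y[::5] = np.nan  # 20% failures
            return y

        with pytest.raises(RuntimeError):
            run_efast(broken, design)


class TestModelEfast:
    def test_shape_contract_and_index_sanity(self):
        res = run_efast_on_model(end_times=(40,), NS=65, NR=2, seed=5)
        frame = res[40].to_frame()
        assert len(frame) == 3 * 13
        assert set(frame.output) == {"C", "T", "M"}
        assert np.all(frame.S_i >= 0) and np.all(frame.S_Ti <= 1.05)
        assert np.all(frame.S_i <= frame.S_Ti + 0.05)

    def test_uniform_variant_flag(self):
        res = run_efast_on_model(end_times=(40,), NS=65, NR=1,
                                 curves="uniform", seed=5)
        assert len(res[40].to_frame()) == 39
        with pytest.raises(ValueError):
            run_efast_on_model(curves="sobol")
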