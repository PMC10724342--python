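"""Extended Fourier Amplitude Sensitivity Test (eFAST), from scratch.

Variance-based global sensitivity analysis: each parameter oscillates along
a periodic space-filling search curve x_i(s) = G_i(sin(omega_i*s + phi_i))
as the scalar phase s sweeps (-pi, pi).  The parameter of interest is
assigned a high frequency omega_max and the complementary parameters low
frequencies; the Fourier spectrum of the model output then separates the
variance driven by the parameter of interest (first-order index S_i, the
spectrum at omega_max and its harmonics) from everything else (total-order
index S_Ti = 1 - V_complementary/V, the spectrum below omega_max/2).

Two transformation functions G are provided:

* uniform (arcsine) curve: x = 1/2 + (1/pi) * arcsin(sin(omega*s + phi)),
  which samples the unit interval uniformly;
* exponential curve: x = n * exp(v * sin(omega*s + phi)) with v = ln(1/n),
  anchored at a nominal value n in (0, 1) and spanning [n^2, 1] -- used for
  parameters with right-skewed posteriors, with n the posterior mode.

Estimates are averaged over NR resamplings with independent random phase
shifts; the spread (SEM) across resamplings is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DEFAULT_INIT, simulate_at_days
from .params import (DEFAULT_PRIOR_BOUNDS, PARAM_NAMES, POSTERIOR_SUMMARY,
                     RIGHT_SKEWED_PARAMS)

__all__ = [
    "search_curve_uniform", "search_curve_exponential",
    "EfastDesign", "build_design", "efast_indices", "run_efast",
    "run_efast_on_model", "SensitivityIndices",
    "DEFAULT_END_TIMES",
]

DEFAULT_NS = 2049
DEFAULT_NR = 5
DEFAULT_M = 4
DEFAULT_END_TIMES = (5, 10, 20, 40, 60, 80, 100)


def search_curve_uniform(s, omega, phi):
    """Saltelli's arcsine curve: uniform samples of (0, 1)."""
    return 0.5 + np.arcsin(np.sin(omega * np.asarray(s) + phi)) / np.pi


def search_curve_exponential(s, omega, phi, n_i):
    """Cukier's exponential curve anchored at nominal n_i in (0, 1)."""
    n_i = float(n_i)
    if not 0.0 < n_i < 1.0:
        raise ValueError(f"nominal must lie in (0, 1), got {n_i}")
    v_i = math.log(1.0 / n_i)
    return n_i * np.exp(v_i * np.sin(omega * np.asarray(s) + phi))


@dataclass
class EfastDesign:
    """Frequencies, phases, and the s-grid for a full eFAST experiment.

    One *block* per parameter of interest: within block ``i`` parameter
    ``i`` carries the high frequency ``omega_max`` and the remaining
    parameters the low complementary frequencies.
    """

    curve_kinds: tuple        # per parameter: "uniform" | "exponential"
    nominals: np.ndarray      # normalized nominal per parameter (exponential only)
    ranges: np.ndarray        # (d, 2) target (lo, hi) per parameter
    NS: int
    NR: int
    M: int
    omega_max: int
    comp_freqs: np.ndarray    # (d - 1,) complementary frequencies
    phases: np.ndarray        # (d, NR, d) random phases per block/resampling
    s: np.ndarray             # (NS,) phase grid over (-pi, pi)
    names: tuple = PARAM_NAMES

    @property
    def d(self) -> int:
        return len(self.curve_kinds)

    @property
    def samples_per_block(self) -> int:
        return self.NS * self.NR

    def frequencies(self, block: int) -> np.ndarray:
        """Frequency assigned to each parameter within ``block``."""
        freqs = np.empty(self.d, dtype=int)
        others = [j for j in range(self.d) if j != block]
        freqs[block] = self.omega_max
        for k, j in enumerate(others):
            freqs[j] = self.comp_freqs[k % len(self.comp_freqs)]
        return freqs

    def unit_samples(self, block: int, resampling: int) -> np.ndarray:
        """(NS, d) samples in the unit hypercube for one block/resampling."""
        freqs = self.frequencies(block)
        X = np.empty((self.NS, self.d))
        for j in range(self.d):
            phi = self.phases[block, resampling, j]
            if self.curve_kinds[j] == "exponential":
                X[:, j] = search_curve_exponential(self.s, freqs[j], phi,
                                                  self.nominals[j])
            else:
                X[:, j] = search_curve_uniform(self.s, freqs[j], phi)
        return X

    def samples(self, block: int, resampling: int) -> np.ndarray:
        """(NS, d) samples mapped affinely onto the target ranges."""
        X = self.unit_samples(block, resampling)
        lo, hi = self.ranges[:, 0], self.ranges[:, 1]
        return lo + X * (hi - lo)


def build_design(
    curve_kinds=None,
    nominals=None,
    ranges=None,
    NS: int = DEFAULT_NS,
    NR: int = DEFAULT_NR,
    M: int = DEFAULT_M,
    seed: int = 0,
    d: int | None = None,
) -> EfastDesign:
    """Assemble an eFAST design.

    The frequency of interest is omega_max = (NS - 1) / (2 M) -- the largest
    integer satisfying the Nyquist condition NS >= 2*M*omega_max + 1 -- and
    the complementary frequencies are integers evenly spread over
    [1, omega_max / (2 M)], so that M harmonics of any complementary
    frequency stay below omega_max / 2.
    """
    if curve_kinds is None:
        if d is None:
            d = len(PARAM_NAMES)
        curve_kinds = ("uniform",) * d
    curve_kinds = tuple(curve_kinds)
    d = len(curve_kinds)
    if nominals is None:
        nominals = np.full(d, 0.5)
    nominals = np.asarray(nominals, dtype=float)
    if ranges is None:
        ranges = np.column_stack([np.zeros(d), np.ones(d)])
    ranges = np.asarray(ranges, dtype=float)
    if NS % 2 == 0 or NS < 2 * M * 1 + 1:
        raise ValueError(f"NS must be odd and >= {2 * M + 1}, got {NS}")

    omega_max = (NS - 1) // (2 * M)
    if NS < 2 * M * omega_max + 1:
        raise ValueError("aliasing: NS < 2*M*omega_max + 1")
    w_c_max = max(1, omega_max // (2 * M))
    n_comp = max(1, d - 1)
    comp_freqs = np.unique(
        np.round(np.linspace(1, w_c_max, n_comp)).astype(int)
    ) if w_c_max > 1 else np.array([1])
    # Repeat to cover all complementary slots if fewer distinct values exist.
    comp = np.resize(comp_freqs, n_comp)

    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(d, NR, d))
    k = np.arange(NS)
    s = -np.pi + np.pi * (2 * k + 1) / NS
    return EfastDesign(curve_kinds=curve_kinds, nominals=nominals,
                       ranges=ranges, NS=NS, NR=NR, M=M,
                       omega_max=omega_max, comp_freqs=comp, phases=phases,
                       s=s, names=tuple(f"x{j}" for j in range(d))
                       if d != len(PARAM_NAMES) else PARAM_NAMES)


@dataclass
class SensitivityIndices:
    """First-order (S_i) and total-order (S_Ti) indices with resampling SEM."""

    names: tuple
    outputs: tuple
    S: np.ndarray        # (d, n_outputs)
    ST: np.ndarray
    sem_S: np.ndarray
    sem_ST: np.ndarray
    warnings: list

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for oi, out in enumerate(self.outputs):
            for pi, name in enumerate(self.names):
                rows.append((out, name, self.S[pi, oi], self.ST[pi, oi],
                             self.sem_S[pi, oi], self.sem_ST[pi, oi]))
        return pd.DataFrame(rows, columns=["output", "parameter", "S_i",
                                           "S_Ti", "sem_Si", "sem_STi"])


def _spectrum(y: np.ndarray) -> np.ndarray:
    """One-sided power spectrum: component j >= 1 carries variance share."""
    NS = len(y)
    c = np.fft.rfft(y) / NS
    power = 2.0 * np.abs(c) ** 2
    power[0] = 0.0
    return power


def _indices_single(y: np.ndarray, omega_max: int, M: int) -> tuple[float, float, bool]:
    """(S_i, S_Ti, constant_flag) from one output series."""
    power = _spectrum(y)
    V = power.sum()
    scale = max(abs(float(np.mean(y))), 1.0)
    if V < 1e-12 * scale**2:
        return 0.0, 0.0, True
    harmonics = [h * omega_max for h in range(1, M + 1) if h * omega_max < len(power)]
    V_i = power[harmonics].sum()
    V_c = power[1:omega_max // 2 + 1].sum()
    return float(V_i / V), float(1.0 - V_c / V), False


def efast_indices(design: EfastDesign, model_outputs: np.ndarray) -> SensitivityIndices:
    """Compute indices from precomputed model outputs.

    Parameters
    ----------
    model_outputs : ndarray, shape (d, NR, NS, n_outputs)
        Output value per block, resampling, sample, and model output.
        NaN entries (failed solves) are imputed with the per-curve median;
        more than 5% failures in any curve aborts.
    """
    d, NR, NS, n_out = model_outputs.shape
    if d != design.d or NR != design.NR or NS != design.NS:
        raise ValueError("model_outputs shape does not match the design")
    S = np.empty((d, n_out))
    ST = np.empty((d, n_out))
    sem_S = np.empty((d, n_out))
    sem_ST = np.empty((d, n_out))
    warnings: list[str] = []
    for block in range(d):
        for oi in range(n_out):
            s_vals, st_vals = [], []
            for rrun in range(NR):
                y = model_outputs[block, rrun, :, oi].astype(float).copy()
                bad = ~np.isfinite(y)
                if bad.any():
                    frac = bad.mean()
                    if frac > 0.05:
                        raise RuntimeError(
                            f"block {block} resampling {rrun}: "
                            f"{100 * frac:.1f}% failed solves (> 5%)")
                    y[bad] = np.median(y[~bad])
                    warnings.append(
                        f"block {block} resampling {rrun}: imputed "
                        f"{int(bad.sum())} failed solves with curve median")
                si, sti, const = _indices_single(y, design.omega_max, design.M)
                if const:
                    warnings.append(
                        f"block {block} resampling {rrun} output {oi}: "
                        "constant output, indices set to 0")
                s_vals.append(si)
                st_vals.append(sti)
            s_vals = np.array(s_vals)
            st_vals = np.array(st_vals)
            S[block, oi] = s_vals.mean()
            ST[block, oi] = st_vals.mean()
            denom = math.sqrt(NR) if NR > 1 else 1.0
            sem_S[block, oi] = s_vals.std(ddof=1) / denom if NR > 1 else 0.0
            sem_ST[block, oi] = st_vals.std(ddof=1) / denom if NR > 1 else 0.0
    return SensitivityIndices(names=design.names,
                              outputs=tuple(f"y{j}" for j in range(n_out)),
                              S=S, ST=ST, sem_S=sem_S, sem_ST=sem_ST,
                              warnings=warnings)


def run_efast(func, design: EfastDesign, n_outputs: int = 1) -> SensitivityIndices:
    """Evaluate ``func`` over the design and compute indices.

    ``func`` maps an (NS, d) parameter matrix to an (NS,) or
    (NS, n_outputs) array.
    """
    out = np.empty((design.d, design.NR, design.NS, n_outputs))
    for block in range(design.d):
        for rrun in range(design.NR):
            X = design.samples(block, rrun)
            y = np.asarray(func(X), dtype=float)
            if y.ndim == 1:
                y = y[:, None]
            out[block, rrun] = y
    return efast_indices(design, out)


def run_efast_on_model(
    modes: dict | None = None,
    prior_bounds: dict | None = None,
    end_times=DEFAULT_END_TIMES,
    NS: int = DEFAULT_NS,
    NR: int = DEFAULT_NR,
    M: int = DEFAULT_M,
    curves: str = "mixed",
    init=DEFAULT_INIT,
    seed: int = 0,
) -> dict[int, SensitivityIndices]:
    """eFAST of the GBM-immune model outputs C, T, M at several end times.

    With ``curves='mixed'`` the six right-skewed parameters (lambda_C,
    C_max, eta, rho, eps_C, r) use the exponential curve anchored at their
    posterior modes (normalized into (0,1) over the sampling range) and the
    other seven the uniform curve; ``curves='uniform'`` samples everything
    uniformly.  Returns one :class:`SensitivityIndices` per end time, with
    outputs labelled C/T/M.
    """
    if curves not in ("mixed", "uniform"):
        raise ValueError("curves must be 'mixed' or 'uniform'")
    if modes is None:
        modes = {k: v[2] for k, v in POSTERIOR_SUMMARY.items()}
    bounds_map = dict(DEFAULT_PRIOR_BOUNDS)
    if prior_bounds:
        bounds_map.update(prior_bounds)
    ranges = np.array([bounds_map[p] for p in PARAM_NAMES])

    kinds = []
    nominals = np.empty(len(PARAM_NAMES))
    eps = 1e-6
    for j, name in enumerate(PARAM_NAMES):
        if curves == "mixed" and name in RIGHT_SKEWED_PARAMS:
            kinds.append("exponential")
            lo, hi = ranges[j]
            n_i = (modes[name] - lo) / (hi - lo)
            if not eps < n_i < 1 - eps:
                n_i = min(max(n_i, eps), 1 - eps)
            nominals[j] = n_i
        else:
            kinds.append("uniform")
            nominals[j] = 0.5
    design = build_design(curve_kinds=tuple(kinds), nominals=nominals,
                          ranges=ranges, NS=NS, NR=NR, M=M, seed=seed)
    design.names = PARAM_NAMES

    days = np.asarray(sorted(end_times), dtype=float)
    n_out = 3 * len(days)
    out = np.empty((design.d, design.NR, design.NS, n_out))
    for block in range(design.d):
        for rrun in range(design.NR):
            X = design.samples(block, rrun)
            for i in range(design.NS):
                sim = simulate_at_days(X[i], days, init=init)
                out[block, rrun, i] = (np.full(n_out, np.nan) if sim is None
                                       else sim.ravel())
    idx_all = efast_indices(design, out)
    results: dict[int, SensitivityIndices] = {}
    for ti, t in enumerate(days):
        cols = [ti * 3 + j for j in range(3)]
        results[int(t)] = SensitivityIndices(
            names=design.names, outputs=("C", "T", "M"),
            S=idx_all.S[:, cols], ST=idx_all.ST[:, cols],
            sem_S=idx_all.sem_S[:, cols], sem_ST=idx_all.sem_ST[:, cols],
            warnings=idx_all.warnings,
        )
    return results
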