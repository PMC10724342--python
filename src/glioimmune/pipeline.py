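"""Pipeline stages on top of the fitted model: posterior-predictive
envelopes, best-fit error evaluation, and the end-to-end run.

The posterior-predictive envelope simulates many parameter sets sampled
either from the fitted posterior families (default) or by resampling
accepted posterior draws, records the hourly mean and standard deviation of
each population, and counts how many observed data points fall within
sigma/4, sigma/2, 3*sigma/4, and sigma of the mean at their day.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .abcfit import AbcResults, relative_error
from .data import ObservedData
from .model import DEFAULT_INIT, simulate, simulate_at_days
from .params import PARAM_NAMES, POSTERIOR_FAMILIES, ParameterSet

__all__ = [
    "ErrorTriple", "EnvelopeReport", "posterior_predictive_envelope",
    "sample_parameters_from_families", "best_fit_error", "write_manifest",
]

BANDS = (0.25, 0.5, 0.75, 1.0)

_POP_INDEX = {"C": 0, "T": 1, "M": 2}


@dataclass(frozen=True)
class ErrorTriple:
    """Per-population relative errors and their sum."""

    E_C: float
    E_T: float
    E_M: float

    @property
    def E_total(self) -> float:
        return self.E_C + self.E_T + self.E_M


@dataclass
class EnvelopeReport:
    """Hourly mean/SD across posterior-predictive draws plus data coverage."""

    hours: np.ndarray              # time grid in days (hourly spacing)
    mean: np.ndarray               # (n_hours, 3)
    sd: np.ndarray                 # (n_hours, 3)
    coverage: dict                 # band multiple -> points within band
    n_points: int
    n_draws: int
    n_failed: int

    def coverage_fraction(self, band: float) -> float:
        return self.coverage[band] / self.n_points if self.n_points else float("nan")


def sample_parameters_from_families(
    n: int, rng: np.random.Generator, families: dict | None = None,
) -> np.ndarray:
    """(n, 13) parameter draws from fitted marginal families.

    Families with unbounded support (logistic, normal) can produce
    non-physical values (negative rates, C_max or q below 1 cell); such
    values are rejected and redrawn per parameter, which truncates each
    marginal to its physical domain.
    """
    if families is None:
        families = POSTERIOR_FAMILIES
    out = np.empty((n, len(PARAM_NAMES)))
    for j, name in enumerate(PARAM_NAMES):
        fam = families[name]
        frozen = fam.frozen() if hasattr(fam, "frozen") else _frozen_from_tuple(fam)
        lo_phys = 1.0 if name in ("C_max", "q") else (0.0 if name == "s_M" else 1e-300)
        col = frozen.rvs(size=n, random_state=rng)
        bad = ~(col > lo_phys) if name != "s_M" else ~(col >= lo_phys)
        tries = 0
        while bad.any():
            col[bad] = frozen.rvs(size=int(bad.sum()), random_state=rng)
            bad = ~(col > lo_phys) if name != "s_M" else ~(col >= lo_phys)
            tries += 1
            if tries > 1000:
                raise RuntimeError(f"cannot draw physical values for {name}")
        out[:, j] = col
    return out


def _frozen_from_tuple(fam):
    from .abcfit import _frozen

    family, pars = fam
    return _frozen(family, pars)


def posterior_predictive_envelope(
    source,
    data: ObservedData,
    n_draws: int = 10_000,
    t_end: float | None = None,
    seed: int = 0,
    sampling: str = "families",
) -> EnvelopeReport:
    """Simulate ``n_draws`` parameter sets and summarize hourly statistics.

    Parameters
    ----------
    source : AbcResults, dict of fitted families, or (n, 13) ndarray
        Where parameter sets come from.  With ``sampling='families'`` an
        AbcResults source is first reduced to its fitted families; with
        ``sampling='posterior'`` accepted posterior draws are resampled with
        replacement.  A dict or array source is used directly.
    data : ObservedData
        Points to classify by their distance to the hourly mean in units of
        the hourly SD.
    """
    rng = np.random.default_rng(seed)
    if t_end is None:
        t_end = float(data.days.max())
    if isinstance(source, AbcResults):
        if sampling == "families":
            draws = sample_parameters_from_families(
                n_draws, rng, source.fit_families())
        elif sampling == "posterior":
            pool = source.posterior[list(PARAM_NAMES)].to_numpy()
            if len(pool) == 0:
                raise ValueError("posterior is empty")
            draws = pool[rng.integers(0, len(pool), size=n_draws)]
        else:
            raise ValueError("sampling must be 'families' or 'posterior'")
    elif isinstance(source, dict):
        draws = sample_parameters_from_families(n_draws, rng, source)
    else:
        pool = np.asarray(source, dtype=float)
        if pool.ndim != 2 or pool.shape[1] != len(PARAM_NAMES):
            raise ValueError("array source must have shape (n, 13)")
        draws = (pool if len(pool) == n_draws
                 else pool[rng.integers(0, len(pool), size=n_draws)])

    hours = np.arange(0.0, t_end + 1e-9, 1.0 / 24.0)
    acc = np.zeros((len(hours), 3))
    acc2 = np.zeros((len(hours), 3))
    n_ok = 0
    n_failed = 0
    for i in range(n_draws):
        sim = simulate_at_days(draws[i], hours[1:], init=DEFAULT_INIT)
        if sim is None:
            n_failed += 1
            continue
        full = np.vstack([np.asarray(DEFAULT_INIT)[None, :], sim])
        acc += full
        acc2 += full**2
        n_ok += 1
    if n_draws and n_failed / n_draws > 0.05:
        raise RuntimeError(
            f"{n_failed}/{n_draws} posterior-predictive solves failed (> 5%)")
    if n_ok == 0:
        raise RuntimeError("no successful posterior-predictive solves")
    mean = acc / n_ok
    var = np.clip(acc2 / n_ok - mean**2, 0.0, None)
    # kill catastrophic-cancellation residue (identical draws -> SD 0)
    var[var < 1e-12 * (mean**2 + 1.0)] = 0.0
    sd = np.sqrt(var) * math.sqrt(n_ok / max(n_ok - 1, 1))

    coverage = {b: 0 for b in BANDS}
    n_points = len(data.records)
    for _, row in data.records.iterrows():
        h = int(round(row["day"] * 24))
        j = _POP_INDEX[row["population"]]
        mu, sig = mean[h, j], sd[h, j]
        if sig == 0:
            # degenerate envelope: on-trajectory points (up to solver
            # resolution) count in every band, everything else in none
            z = 0.0 if abs(row["count"] - mu) <= 1e-4 * max(abs(mu), 1.0) else np.inf
        else:
            z = abs(row["count"] - mu) / sig
        for b in BANDS:
            if z <= b:
                coverage[b] += 1
    return EnvelopeReport(hours=hours, mean=mean, sd=sd, coverage=coverage,
                          n_points=n_points, n_draws=n_draws, n_failed=n_failed)


def best_fit_error(params: ParameterSet, data: ObservedData,
                   stat: str = "mean") -> ErrorTriple:
    """Relative errors of one parameter set against per-day data summaries."""
    table = data.summaries(stat)
    days = np.asarray(table.index, dtype=float)
    traj = simulate(params, init=DEFAULT_INIT, t_end=float(days.max()),
                    grid=np.concatenate([[0.0], days]))
    if not traj.success:
        return ErrorTriple(float("inf"), float("inf"), float("inf"))
    sim = traj.at_times(days)
    errs = []
    for j, pop in enumerate(("C", "T", "M")):
        col = table[pop].to_numpy(dtype=float)
        mask = np.isfinite(col)
        errs.append(relative_error(col[mask], sim[mask, j]))
    return ErrorTriple(*errs)


def write_manifest(path, config: dict, seed: int) -> None:
    """Reproducibility manifest: config hash, seed, package versions."""
    import sys

    import numpy
    import pandas
    import scipy

    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {
            "glioimmune": __version__,
            "python": sys.version.split()[0],
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
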