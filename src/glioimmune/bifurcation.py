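"""One-parameter bifurcation sweeps.

For each value on a grid of one parameter, the system is integrated for a
long horizon and the post-transient minimum and maximum of each population
is recorded.  Parameters whose sweep drives the long-run tumor maximum to
zero are candidate therapeutic targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DEFAULT_INIT, simulate
from .params import PARAM_NAMES, ParameterSet

__all__ = ["BifurcationResult", "sweep", "default_grid"]

DEFAULT_T_END = 2000.0
DEFAULT_TRANSIENT_FRACTION = 0.5


@dataclass
class BifurcationResult:
    """Long-run min/max cell counts along a parameter grid.

    min_counts/max_counts have shape (len(sweep_values), 3) with columns
    (C, T, M); rows are NaN where the solver failed.
    """

    parameter_name: str
    sweep_values: np.ndarray
    min_counts: np.ndarray
    max_counts: np.ndarray
    transient_fraction: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "param_value": self.sweep_values,
            "C_min": self.min_counts[:, 0], "C_max": self.max_counts[:, 0],
            "T_min": self.min_counts[:, 1], "T_max": self.max_counts[:, 1],
            "M_min": self.min_counts[:, 2], "M_max": self.max_counts[:, 2],
        })

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 3, figsize=(12, 3.2), sharex=True)
        for k, pop in enumerate(("C", "T", "M")):
            ax[k].plot(self.sweep_values, self.min_counts[:, k], "b-", label="min")
            ax[k].plot(self.sweep_values, self.max_counts[:, k], "r--", label="max")
            ax[k].set_xscale("log")
            ax[k].set_yscale("symlog")
            ax[k].set_title(pop)
            ax[k].set_xlabel(self.parameter_name)
        ax[0].legend()
        return ax


def default_grid(params: ParameterSet, name: str, n_points: int = 100,
                 span: float = 100.0) -> np.ndarray:
    """Log-spaced grid centered on the current value (factor ``span`` each way)."""
    v = getattr(params, name)
    return np.geomspace(v / span, v * span, n_points)


def sweep(
    params: ParameterSet,
    name: str,
    grid=None,
    init=DEFAULT_INIT,
    t_end: float = DEFAULT_T_END,
    transient_fraction: float = DEFAULT_TRANSIENT_FRACTION,
    grid_step_days: float = 0.25,
) -> BifurcationResult:
    """Sweep one parameter and record post-transient min/max populations.

    Solver failures at a grid value leave NaN markers; the sweep continues.
    """
    if name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {name!r}")
    if grid is None:
        grid = default_grid(params, name)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("grid values must be positive")

    mins = np.full((len(grid), 3), np.nan)
    maxs = np.full((len(grid), 3), np.nan)
    for i, value in enumerate(grid):
        p = params.replace(**{name: float(value)})
        traj = simulate(p, init=init, t_end=t_end, grid=grid_step_days,
                        rtol=1e-8, atol=1e-6)
        if not traj.success:
            continue
        start = int(np.searchsorted(traj.times, transient_fraction * t_end))
        window = traj.states()[start:]
        mins[i] = window.min(axis=0)
        maxs[i] = window.max(axis=0)
    return BifurcationResult(parameter_name=name, sweep_values=grid,
                             min_counts=mins, max_counts=maxs,
                             transient_fraction=transient_fraction)
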