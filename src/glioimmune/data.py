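"""Observed-data container, CSV round-trip, and synthetic data generation.

The experimental design emulated here: mice are implanted with 35,000
glioma cells; at days 7, 13, 20, 24, 27, and 34 post-implantation, 1-4 mice
are euthanized and tumor cells (C), CD3+ T cells (T), and MDSCs (M) are
counted.  The generator simulates a ground-truth trajectory and perturbs it
with multiplicative lognormal noise (counts are positive and right-skewed;
the real within-day noise structure is unknown, so the coefficient of
variation is a free knob, not an estimate).

CSV layout: ``day,mouse_id,population,count`` with population in {C, T, M}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import DEFAULT_INIT, simulate
from .params import ParameterSet, default_parameters

__all__ = [
    "ObservedData", "GeneratorSpec", "generate",
    "read_observed", "write_observed", "convert_spreadsheet",
    "DEFAULT_DAYS",
]

DEFAULT_DAYS = (7, 13, 20, 24, 27, 34)
POPULATIONS = ("C", "T", "M")
_COLUMNS = ["day", "mouse_id", "population", "count"]


@dataclass
class ObservedData:
    """Per-mouse, per-day cell counts for the three populations."""

    records: pd.DataFrame  # columns: day, mouse_id, population, count

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        bad = set(df["population"]) - set(POPULATIONS)
        if bad:
            raise ValueError(f"unknown population codes: {sorted(bad)}")
        if len(df) and (df["count"] < 0).any():
            raise ValueError("counts must be >= 0")
        self.records = df[_COLUMNS].reset_index(drop=True)

    @property
    def days(self) -> np.ndarray:
        return np.sort(self.records["day"].unique())

    def summaries(self, stat: str = "mean") -> pd.DataFrame:
        """Per-day, per-population summary (recomputed from records).

        Returns a DataFrame indexed by day with columns C, T, M holding the
        requested statistic ('mean', 'min', or 'max') over mice.
        """
        if stat not in ("mean", "min", "max"):
            raise ValueError(f"stat must be mean/min/max, got {stat!r}")
        table = self.records.pivot_table(
            index="day", columns="population", values="count", aggfunc=stat
        )
        return table.reindex(columns=list(POPULATIONS))

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneratorSpec:
    """Recipe for a synthetic dataset with the murine study's structure."""

    true_params: ParameterSet = field(default_factory=default_parameters)
    init: tuple = DEFAULT_INIT
    days: Sequence[int] = DEFAULT_DAYS
    mice_per_day: Sequence[int] | None = None  # None: drawn 1-4 from seed
    noise_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.mice_per_day is not None:
            if len(self.mice_per_day) != len(self.days):
                raise ValueError("mice_per_day must match days in length")
            if any(m < 1 for m in self.mice_per_day):
                raise ValueError("mice_per_day entries must be >= 1")
            # The murine design uses 1-4 mice per day; larger cohorts are
            # allowed for calibration studies but are not the default draw.


def generate(spec: GeneratorSpec) -> ObservedData:
    """Simulate the ground truth and emit noisy per-mouse counts.

    Each count is truth * LogNormal(mu, sigma) with sigma chosen so the
    multiplier has unit mean and coefficient of variation ``noise_cv``.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    days = np.asarray(spec.days, dtype=float)
    traj = simulate(spec.true_params, init=spec.init, t_end=float(days.max()),
                    grid=np.concatenate([[0.0], days]))
    if not traj.success:
        raise RuntimeError(
            f"ground-truth simulation failed ({traj.message}) for params "
            f"{spec.true_params.to_dict()}"
        )
    truth = traj.at_times(days)  # (n_days, 3)

    if spec.mice_per_day is None:
        mice_per_day = rng.integers(1, 5, size=len(days))
    else:
        mice_per_day = np.asarray(spec.mice_per_day, dtype=int)

    if spec.noise_cv > 0:
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        mu = -0.5 * sigma**2  # unit-mean multiplier
    rows = []
    for i, day in enumerate(spec.days):
        for m in range(int(mice_per_day[i])):
            mouse = f"d{int(day)}_m{m + 1}"
            for j, pop in enumerate(POPULATIONS):
                value = truth[i, j]
                if spec.noise_cv > 0:
                    value *= np.exp(rng.normal(mu, sigma))
                rows.append((int(day), mouse, pop, float(value)))
    return ObservedData(pd.DataFrame(rows, columns=_COLUMNS))


def read_observed(path) -> ObservedData:
    """Read an observed-data CSV, validating rows."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["population"] not in POPULATIONS:
            raise ValueError(
                f"{path}:{line}: unknown population {row['population']!r}")
        if not np.isfinite(row["count"]) or row["count"] < 0:
            raise ValueError(f"{path}:{line}: invalid count {row['count']!r}")
    return ObservedData(df)


def write_observed(data: ObservedData, path) -> None:
    data.records.to_csv(path, index=False)


def convert_spreadsheet(path, counts_sheet: str | int = -1) -> ObservedData:
    """Best-effort converter from a supplementary-style spreadsheet.

    Expects a sheet with a day column and per-population count columns
    (long or wide); the supplementary layout is not formally specified, so
    this converter is tolerant: it looks for columns whose names start with
    day/mouse/population/count (long form) or day plus C/T/M-like names
    (wide form).
    """
    df = pd.read_excel(path, sheet_name=counts_sheet)
    cols = {str(c).strip().lower(): c for c in df.columns}

    def find(prefixes):
        for key, orig in cols.items():
            if any(key.startswith(p) for p in prefixes):
                return orig
        return None

    day_col = find(["day", "time"])
    if day_col is None:
        raise ValueError("could not locate a day/time column")
    pop_col = find(["population", "pop", "cell type", "celltype"])
    if pop_col is not None:  # long form
        count_col = find(["count", "cells", "value"])
        mouse_col = find(["mouse", "id", "animal"])
        out = pd.DataFrame({
            "day": df[day_col].astype(int),
            "mouse_id": df[mouse_col].astype(str) if mouse_col is not None
            else [f"row{i}" for i in range(len(df))],
            "population": df[pop_col].astype(str).str.strip().str.upper().str[0],
            "count": df[count_col].astype(float),
        })
        return ObservedData(out)
    # wide form: one row per mouse, columns per population
    pop_cols = {}
    for pop, prefixes in (("C", ["c", "tumor", "glioma"]),
                          ("T", ["t", "cd3"]),
                          ("M", ["m", "mdsc"])):
        col = find(prefixes)
        if col is not None and col != day_col:
            pop_cols[pop] = col
    if not pop_cols:
        raise ValueError("could not identify population columns")
    mouse_col = find(["mouse", "id", "animal"])
    rows = []
    per_day_counter: dict[int, int] = {}
    for _, row in df.iterrows():
        day = int(row[day_col])
        if mouse_col is not None:
            mouse = str(row[mouse_col])
        else:
            per_day_counter[day] = per_day_counter.get(day, 0) + 1
            mouse = f"d{day}_m{per_day_counter[day]}"
        for pop, col in pop_cols.items():
            v = row[col]
            if pd.notna(v):
                rows.append((day, mouse, pop, float(v)))
    return ObservedData(pd.DataFrame(rows, columns=_COLUMNS))
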