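"""Model parameters for the glioblastoma (GBM)-immune dynamics system.

The model tracks three interacting populations in the glioma
microenvironment -- tumor cells C, activated (CD3+) T cells T, and
myeloid-derived suppressor cells (MDSCs) M -- governed by 13 rate
parameters.  This module defines the :class:`ParameterSet` atom passed to
every analysis stage, the literature ranges used as default priors, and the
posterior summary values (modes, fitted distribution families) used as
nominal values throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ParameterSet",
    "PARAM_NAMES",
    "PARAM_UNITS",
    "LITERATURE_RANGES",
    "DEFAULT_PRIOR_BOUNDS",
    "POSTERIOR_SUMMARY",
    "POSTERIOR_FAMILIES",
    "default_parameters",
    "RIGHT_SKEWED_PARAMS",
]

#: Canonical parameter order used by every array interface in the package.
PARAM_NAMES = (
    "lambda_C", "C_max", "eta", "a_T", "s_T", "rho", "eps_C",
    "r", "d_T", "s_M", "alpha", "q", "d_M",
)

PARAM_UNITS = {
    "lambda_C": "1/day",
    "C_max": "cells",
    "eta": "1/(day*cell)",
    "a_T": "cells/day",
    "s_T": "1/(day*cell)",
    "rho": "1/cell^2",
    "eps_C": "dimensionless",
    "r": "1/(day*cell)",
    "d_T": "1/day",
    "s_M": "1/day",
    "alpha": "cells/day",
    "q": "cells",
    "d_M": "1/day",
}


@dataclass(frozen=True)
class ParameterSet:
    """The 13 rate parameters of the GBM-immune ODE system.

    Parameters
    ----------
    lambda_C : float
        Tumor cell growth rate (1/day).
    C_max : float
        Tumor carrying capacity (cells).
    eta : float
        Kill rate of tumor cells by T cells (1/(day*cell)).
    a_T : float
        Constant T-cell activation rate (cells/day).
    s_T : float
        Tumor-mediated T-cell stimulation rate (1/(day*cell)).
    rho : float
        Strength of T-cell inhibition by the PD-L1-PD-1 complex (1/cell^2).
    eps_C : float
        Relative PD-L1 expression of tumor cells vs. T cells (dimensionless).
    r : float
        Suppression rate of T cells by MDSCs (1/(day*cell)).
    d_T : float
        T-cell death rate (1/day).
    s_M : float
        MDSC recruitment rate via the chemokines CCL2/CCL7 (1/day).
    alpha : float
        MDSC expansion coefficient (cells/day).
    q : float
        Steepness coefficient of the MDSC expansion curve (cells).
    d_M : float
        MDSC death rate (1/day).
    """

    lambda_C: float
    C_max: float
    eta: float
    a_T: float
    s_T: float
    rho: float
    eps_C: float
    r: float
    d_T: float
    s_M: float
    alpha: float
    q: float
    d_M: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if v <= 0:
                raise ValueError(f"parameter {f.name} must be strictly positive, got {v!r}")
        if self.C_max < 1:
            raise ValueError(f"C_max must be >= 1 cell, got {self.C_max!r}")
        if self.q < 1:
            raise ValueError(f"q must be >= 1 cell, got {self.q!r}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "ParameterSet":
        values = list(values)
        if len(values) != len(PARAM_NAMES):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {len(values)}")
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ParameterSet":
        return cls(**{n: float(mapping[n]) for n in PARAM_NAMES})

    def replace(self, **changes: float) -> "ParameterSet":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES}


#: Literature ranges for each parameter (lower, upper).  Point estimates from
#: the literature are recorded as degenerate ranges.
LITERATURE_RANGES = {
    "lambda_C": (0.014, 0.45),
    "C_max": (4.057e6, 4.14e7),
    "eta": (1.1e-7, 1.1e-7),
    "a_T": (5.25e2, 1.18e6),
    "s_T": (1e5, 1e7),
    "rho": (4.17e-13, 3.09e-5),
    "eps_C": (1.0, 50.0),
    "r": (1e-7, 5e-5),
    "d_T": (0.010, 0.303),
    "s_M": (0.0123, 0.0144),
    "alpha": (1.6e7, 1.2e8),
    "q": (1e10, 1e10),
    "d_M": (0.19, 0.19),
}

# Default uniform prior bounds for ABC rejection.  Three of the uniforms
# (s_T, s_M, q) are the posterior uniforms reported verbatim; the remaining
# bounds are the literature ranges widened so that the reported posterior
# supports are covered.  All overridable through PriorSpec.
DEFAULT_PRIOR_BOUNDS = {
    "lambda_C": (0.01, 0.5),
    "C_max": (4.0e6, 4.5e7),
    "eta": (1e-8, 1e-6),
    "a_T": (5.25e2, 6e6),
    "s_T": (1e2, 1e7),
    "rho": (1e-6, 1.0),
    "eps_C": (1.0, 100.0),
    "r": (1e-7, 1e-4),
    "d_T": (0.01, 1.0),
    "s_M": (0.0, 0.1),
    "alpha": (1e7, 5e8),
    "q": (1e9, 1e11),
    "d_M": (0.01, 0.7),
}

#: Posterior summary statistics (mean, median, mode, sd) per parameter from
#: the ABC rejection analysis of the murine dataset.
POSTERIOR_SUMMARY = {
    #            mean       median     mode       sd
    "lambda_C": (0.272,     0.250,     0.174,     0.114),
    "C_max":    (1.87e7,    1.45e7,    4.19e6,    1.48e7),
    "eta":      (1.84e-7,   1.27e-7,   4.03e-8,   1.86e-7),
    "a_T":      (2.48e6,    2.45e6,    1.98e6,    1.45e6),
    "s_T":      (5.73e6,    5.91e6,    8.79e6,    2.63e6),
    "rho":      (0.223,     0.207,     0.0768,    0.142),
    "eps_C":    (37.5,      31.1,      7.00,      29.3),
    "r":        (2.85e-5,   1.83e-5,   3.60e-6,   2.76e-5),
    "d_T":      (0.402,     0.415,     0.656,     0.213),
    "s_M":      (0.0492,    0.0480,    0.0249,    0.0278),
    "alpha":    (2.52e8,    2.53e8,    8.27e7,    1.42e8),
    "q":        (5.09e10,   5.03e10,   3.89e10,   2.83e10),
    "d_M":      (0.258,     0.263,     0.419,     0.143),
}

#: Fitted distribution family per parameter (family name, named parameters).
#: Conventions: gamma(shape, scale); logistic(loc, scale);
#: weibull(scale, shape); exponential(mean); uniform(lo, hi);
#: normal(mean, sd).  Families are named explicitly to avoid positional
#: ambiguity.
POSTERIOR_FAMILIES = {
    "lambda_C": ("gamma", {"shape": 5.40, "scale": 0.050}),
    "C_max": ("logistic", {"loc": 1.74e7, "scale": 8.89e6}),
    "eta": ("weibull", {"scale": 1.84e-7, "shape": 0.999}),
    "a_T": ("logistic", {"loc": 2.48e6, "scale": 8.80e5}),
    "s_T": ("uniform", {"lo": 1e2, "hi": 1e7}),
    "rho": ("exponential", {"mean": 0.223}),
    "eps_C": ("exponential", {"mean": 37.5}),
    "r": ("gamma", {"shape": 0.801, "scale": 3.56e-5}),
    "d_T": ("weibull", {"scale": 0.447, "shape": 1.81}),
    "s_M": ("uniform", {"lo": 0.0, "hi": 0.1}),
    "alpha": ("logistic", {"loc": 2.52e8, "scale": 7.82e7}),
    "q": ("uniform", {"lo": 1e9, "hi": 1e11}),
    "d_M": ("normal", {"mean": 0.258, "sd": 0.143}),
}

#: Parameters whose posterior marginals are right-skewed; these use the
#: exponential (mode-anchored) search curve in eFAST by default.
RIGHT_SKEWED_PARAMS = ("lambda_C", "C_max", "eta", "rho", "eps_C", "r")


def default_parameters() -> ParameterSet:
    """Posterior modes: the nominal parameter set used in examples and eFAST."""
    return ParameterSet.from_dict({k: v[2] for k, v in POSTERIOR_SUMMARY.items()})
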