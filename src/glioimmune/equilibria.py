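"""Equilibria and stability of the GBM-immune system.

The system has a unique tumor-free equilibrium (0, T0*, 0), where T0* is the
single positive root of the cubic

    f(T) = d_T * rho * T^3 + d_T * T - a_T.

The Jacobian there is lower-triangular in the relevant entries, so its
eigenvalues are available in closed form; the equilibrium is locally
asymptotically stable iff lambda_C < eta * T0* and a saddle otherwise.  A
sufficient condition for *global* stability follows from bounding the T-cell
equation from below: with gamma = a_T / (1 + rho*T_hat*(T_hat + eps_C*C_hat))
and beta = gamma / (r*M_hat + d_T), the tumor-free state attracts all
positive trajectories whenever lambda_C < eta * beta.

Tumorous equilibria (C* > 0) are located numerically by reducing the
fixed-point system to one scalar equation in C* via the C- and M-nullclines
and bracketing sign changes on a log-spaced grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import BoundSet, DEFAULT_INIT, bounds, jacobian, _rhs_raw
from .params import ParameterSet

__all__ = [
    "TumorFreeEquilibrium",
    "GlobalStabilityReport",
    "TumorousEquilibriumReport",
    "tumor_free_equilibrium",
    "classify_tumor_free",
    "global_stability_condition",
    "tumorous_equilibria",
]


@dataclass(frozen=True)
class TumorFreeEquilibrium:
    """The unique tumor-free steady state (0, T0*, 0) and its linearization."""

    T0_star: float
    residual: float
    eigenvalues: tuple[float, float, float]
    classification: str  # "stable" | "saddle" | "marginal"
    lambda1_sign_condition: bool  # lambda_C < eta * T0*


@dataclass(frozen=True)
class GlobalStabilityReport:
    """Sufficient condition lambda_C < eta*beta for global tumor clearance."""

    gamma: float
    beta: float
    condition_holds: bool
    bounds_used: BoundSet


@dataclass(frozen=True)
class TumorousFixedPoint:
    C: float
    T: float
    M: float
    eigenvalues: tuple[complex, complex, complex]
    classification: str  # "stable" | "saddle" | "unstable"
    residual: float


@dataclass(frozen=True)
class TumorousEquilibriumReport:
    points: tuple[TumorousFixedPoint, ...]
    existence_screen: bool  # C_max * eps_C * eta / lambda_C < 1


def _cubic_root_closed_form(a_T: float, d_T: float, rho: float) -> float:
    """Positive root of d_T*rho*T^3 + d_T*T - a_T via a stable Cardano form.

    With u = a_T/(2*d_T*rho) and p = 1/(3*rho), the root is
    cbrt(u + w) + cbrt(u - w), w = sqrt(u^2 + p^3).  Since u - w =
    -p^3/(u + w), the second radical is rewritten to avoid the catastrophic
    cancellation that occurs when u >> p^(3/2).
    """
    u = a_T / (2.0 * d_T * rho)
    p = 1.0 / (3.0 * rho)
    w = np.sqrt(u * u + p**3)
    A = np.cbrt(u + w)
    return float(A - p / A)


def _cubic_f(T: float, a_T: float, d_T: float, rho: float) -> float:
    return d_T * rho * T**3 + d_T * T - a_T


def tumor_free_T(params: ParameterSet, polish: bool = True) -> float:
    """T0*: the unique positive root of the tumor-free cubic."""
    a_T, d_T, rho = params.a_T, params.d_T, params.rho
    T0 = _cubic_root_closed_form(a_T, d_T, rho)
    if polish:
        # One or two Newton steps restore full precision after the radicals.
        for _ in range(3):
            f = _cubic_f(T0, a_T, d_T, rho)
            fp = 3.0 * d_T * rho * T0**2 + d_T
            step = f / fp
            T0 -= step
            if abs(step) <= 1e-16 * abs(T0):
                break
    return float(T0)


def tumor_free_equilibrium(params: ParameterSet) -> TumorFreeEquilibrium:
    """Locate (0, T0*, 0), verify it, and classify its local stability."""
    a_T, d_T, rho = params.a_T, params.d_T, params.rho
    T0 = tumor_free_T(params)
    # Bracketed verification: the root must also be found independently.
    hi = a_T / d_T + 1.0
    T0_brack = brentq(_cubic_f, 0.0, hi, args=(a_T, d_T, rho),
                      xtol=1e-300, rtol=8.9e-16, maxiter=200)
    if abs(T0 - T0_brack) > 1e-6 * max(abs(T0), 1e-300):
        raise ArithmeticError(
            f"closed-form T0*={T0} and bracketed root {T0_brack} disagree"
        )
    residual = abs(_cubic_f(T0, a_T, d_T, rho))

    lam1 = params.lambda_C - params.eta * T0
    lam2 = -2.0 * a_T * rho * T0 / (1.0 + rho * T0**2) ** 2 - d_T
    lam3 = -params.d_M
    cond = params.lambda_C < params.eta * T0
    if abs(lam1) < 1e-12 * params.lambda_C:
        classification = "marginal"
    elif cond:
        classification = "stable"
    else:
        classification = "saddle"
    return TumorFreeEquilibrium(
        T0_star=T0, residual=residual,
        eigenvalues=(float(lam1), float(lam2), float(lam3)),
        classification=classification, lambda1_sign_condition=bool(cond),
    )


def classify_tumor_free(params: ParameterSet) -> str:
    """'stable', 'saddle', or 'marginal' per the sign of lambda_C - eta*T0*."""
    return tumor_free_equilibrium(params).classification


def global_stability_condition(params: ParameterSet, init=DEFAULT_INIT) -> GlobalStabilityReport:
    """Check the sufficient global-stability condition lambda_C < eta*beta."""
    b = bounds(params, init)
    gamma = params.a_T / (1.0 + params.rho * b.T_hat * (b.T_hat + params.eps_C * b.C_hat))
    beta = gamma / (params.r * b.M_hat + params.d_T)
    return GlobalStabilityReport(
        gamma=float(gamma), beta=float(beta),
        condition_holds=bool(params.lambda_C < params.eta * beta),
        bounds_used=b,
    )


def _classify_eigs(eigs: np.ndarray) -> str:
    re = eigs.real
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def tumorous_equilibria(
    params: ParameterSet,
    n_grid: int = 2000,
    c_min: float = 1e-3,
) -> TumorousEquilibriumReport:
    """Find fixed points with C* > 0 numerically.

    The C-nullcline with C > 0 gives T* = lambda_C*(1 - C*/C_max)/eta and
    the M-nullcline gives M* = (s_M*C* + alpha*C*/(q + C*))/d_M; what
    remains is one scalar equation (the T-nullcline residual) in C*,
    scanned on a log-spaced grid over (0, C_max] with sign-change
    bracketing.  Each root is classified by the analytic Jacobian.

    The report also carries the existence screen
    ``C_max * eps_C * eta / lambda_C < 1`` as a diagnostic flag; it is never
    used to skip the numeric search.
    """
    p = params

    def T_of_C(C):
        return p.lambda_C * (1.0 - C / p.C_max) / p.eta

    def M_of_C(C):
        return (p.s_M * C + p.alpha * C / (p.q + C)) / p.d_M

    def resid(C):
        T = T_of_C(C)
        M = M_of_C(C)
        return ((p.a_T + p.s_T * T * C) / (1.0 + p.rho * T * (T + p.eps_C * C))
                - p.r * T * M - p.d_T * T)

    grid = np.geomspace(c_min, p.C_max, n_grid)
    vals = np.array([resid(c) for c in grid])
    points = []
    sign = np.sign(vals)
    for i in range(len(grid) - 1):
        if sign[i] == 0:
            roots = [grid[i]]
        elif sign[i] * sign[i + 1] < 0:
            roots = [brentq(resid, grid[i], grid[i + 1], xtol=1e-12, rtol=8.9e-16)]
        else:
            continue
        for C_star in roots:
            T_star = T_of_C(C_star)
            M_star = M_of_C(C_star)
            if T_star < 0 or M_star < 0:
                continue
            y = np.array([C_star, T_star, M_star])
            res = float(np.linalg.norm(_rhs_raw(0.0, y, p.to_array())))
            eigs = np.linalg.eigvals(jacobian(y, p))
            points.append(TumorousFixedPoint(
                C=float(C_star), T=float(T_star), M=float(M_star),
                eigenvalues=tuple(complex(e) for e in eigs),
                classification=_classify_eigs(eigs), residual=res,
            ))
    screen = bool(p.C_max * p.eps_C * p.eta / p.lambda_C < 1.0)
    return TumorousEquilibriumReport(points=tuple(points), existence_screen=screen)
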