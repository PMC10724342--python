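"""Core dynamics: right-hand side, solver wrapper, and analytic bounds.

The GBM-immune system is

    dC/dt = lambda_C * C * (1 - C/C_max) - eta*T*C
    dT/dt = (a_T + s_T*T*C) / (1 + rho*T*(T + eps_C*C)) - r*T*M - d_T*T
    dM/dt = s_M*C + alpha*C/(q + C) - d_M*M

Tumor cells grow logistically and are killed by T cells.  T cells are
activated at a constant rate, stimulated by tumor contact, inhibited by the
PD-L1-PD-1 complex (represented by T*(T + eps_C*C), since only T cells carry
PD-1), suppressed by MDSCs, and die.  MDSCs are recruited by tumor-secreted
chemokines (CCL2/CCL7), expand saturably with tumor load, and die.

Trajectories started positive remain positive and bounded; the solver
wrapper enforces a small negativity guard consistent with that theory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import ParameterSet

__all__ = ["State", "Trajectory", "BoundSet", "rhs", "simulate", "simulate_at_days", "bounds"]

#: Default initial condition: 35,000 implanted glioma cells, no activated
#: T cells, no tumor-infiltrating MDSCs.
DEFAULT_INIT = (35_000.0, 0.0, 0.0)

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-6  # cells


@dataclass(frozen=True)
class State:
    """Population sizes (cells): tumor C, activated T cells T, MDSCs M."""

    C: float
    T: float
    M: float

    def to_array(self) -> np.ndarray:
        return np.array([self.C, self.T, self.M], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "State":
        return cls(float(y[0]), float(y[1]), float(y[2]))


@dataclass
class Trajectory:
    """One ODE solve: time grid (days) and the three population series."""

    times: np.ndarray
    C: np.ndarray
    T: np.ndarray
    M: np.ndarray
    params: ParameterSet
    success: bool = True
    message: str = ""
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL

    def states(self) -> np.ndarray:
        """(n, 3) array of [C, T, M] rows."""
        return np.column_stack([self.C, self.T, self.M])

    def at_times(self, t: Sequence[float]) -> np.ndarray:
        """Linear interpolation of the solution at times ``t`` (days)."""
        t = np.asarray(t, dtype=float)
        return np.column_stack(
            [np.interp(t, self.times, y) for y in (self.C, self.T, self.M)]
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_days": self.times, "C": self.C, "T": self.T, "M": self.M}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class BoundSet:
    """Analytic upper bounds on the three populations.

    C_hat = max{C(0), C_max}.  T_hat comes from maximizing
    g(T) = (a_T + s_T*T*C_hat)/(1 + rho*T^2) at T_m and balancing against
    T-cell death; M_hat from the bounded MDSC source term.
    """

    C_hat: float
    T_hat: float
    M_hat: float
    T_m: float


def _validate_state(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (3,):
        raise ValueError(f"state must have 3 components, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite state: {y}")
    if np.any(y < 0):
        raise ValueError(f"state components must be >= 0, got {y}")
    return y


def rhs(state, params: ParameterSet) -> np.ndarray:
    """Time derivative (dC/dt, dT/dt, dM/dt) in cells/day.

    ``state`` may be a :class:`State` or a length-3 array-like (C, T, M).
    """
    if isinstance(state, State):
        y = state.to_array()
    else:
        y = np.asarray(state, dtype=float)
    y = _validate_state(y)
    return _rhs_raw(0.0, y, params.to_array())


def _rhs_raw(t: float, y: np.ndarray, p: np.ndarray) -> np.ndarray:
    # p follows PARAM_NAMES order; written out for speed in tight loops.
    # Populations are clipped at 0 when evaluating the field: a solver
    # undershoot below zero would otherwise be amplified by the logistic
    # term (C < 0 gives dC < 0), turning a rounding error into a runaway.
    lam, cmax, eta, a_t, s_t, rho, eps_c, r, d_t, s_m, alpha, q, d_m = p
    C = y[0] if y[0] > 0.0 else 0.0
    T = y[1] if y[1] > 0.0 else 0.0
    M = y[2] if y[2] > 0.0 else 0.0
    dC = lam * C * (1.0 - C / cmax) - eta * T * C
    dT = (a_t + s_t * T * C) / (1.0 + rho * T * (T + eps_c * C)) - r * T * M - d_t * T
    dM = s_m * C + alpha * C / (q + C) - d_m * M
    return np.array([dC, dT, dM])


def jacobian(state, params: ParameterSet) -> np.ndarray:
    """Analytic Jacobian of the right-hand side at ``state``."""
    if isinstance(state, State):
        y = state.to_array()
    else:
        y = np.asarray(state, dtype=float)
    lam, cmax, eta, a_t, s_t, rho, eps_c, r, d_t, s_m, alpha, q, d_m = params.to_array()
    C, T, M = y
    N = a_t + s_t * T * C
    D = 1.0 + rho * T * (T + eps_c * C)
    J = np.zeros((3, 3))
    J[0, 0] = lam * (1.0 - 2.0 * C / cmax) - eta * T
    J[0, 1] = -eta * C
    J[1, 0] = s_t * T / D - N * rho * T * eps_c / D**2
    J[1, 1] = s_t * C / D - N * rho * (2.0 * T + eps_c * C) / D**2 - r * M - d_t
    J[1, 2] = -r * T
    J[2, 0] = s_m + alpha * q / (q + C) ** 2
    J[2, 2] = -d_m
    return J


def _jac_wrapped(t, y, p: np.ndarray):
    lam, cmax, eta, a_t, s_t, rho, eps_c, r, d_t, s_m, alpha, q, d_m = p
    C = y[0] if y[0] > 0.0 else 0.0
    T = y[1] if y[1] > 0.0 else 0.0
    M = y[2] if y[2] > 0.0 else 0.0
    N = a_t + s_t * T * C
    D = 1.0 + rho * T * (T + eps_c * C)
    return np.array([
        [lam * (1.0 - 2.0 * C / cmax) - eta * T, -eta * C, 0.0],
        [s_t * T / D - N * rho * T * eps_c / D**2,
         s_t * C / D - N * rho * (2.0 * T + eps_c * C) / D**2 - r * M - d_t,
         -r * T],
        [s_m + alpha * q / (q + C) ** 2, 0.0, -d_m],
    ])


def simulate(
    params: ParameterSet,
    init=DEFAULT_INIT,
    t_end: float = 40.0,
    grid: np.ndarray | float | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Solve the system from ``init`` up to ``t_end`` days.

    Parameters
    ----------
    grid : array, float, or None
        Output grid.  None means an hourly grid (step 1/24 day); a float is
        interpreted as the grid step in days; an array is used verbatim.

    Uses an adaptive solver with automatic stiffness handling (LSODA).
    Components that dip into ``(-atol, 0)`` are clamped to 0; anything more
    negative marks the trajectory as failed (callers treat failed solves as
    infinite fitting error).
    """
    if isinstance(init, State):
        y0 = init.to_array()
    else:
        y0 = np.asarray(init, dtype=float)
    y0 = _validate_state(y0)
    if not (t_end > 0):
        raise ValueError(f"t_end must be positive, got {t_end}")

    if grid is None:
        t_eval = np.arange(0.0, t_end + 1e-12, 1.0 / 24.0)
    elif np.isscalar(grid):
        t_eval = np.arange(0.0, t_end + 1e-12, float(grid))
    else:
        t_eval = np.asarray(grid, dtype=float)
    if t_eval[-1] < t_end - 1e-9:
        t_eval = np.append(t_eval, t_end)

    p = params.to_array()
    # stiffness fallback chain: LSODA first, then fully implicit Radau,
    # then relaxed tolerances
    attempts = [(method, rtol, atol)]
    if method == "LSODA":
        attempts += [("Radau", rtol, atol), ("Radau", max(rtol, 1e-6), max(atol, 1e-3))]
    sol = None
    for meth, rt, at in attempts:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = solve_ivp(
                _rhs_raw, (0.0, float(t_end)), y0, t_eval=t_eval, args=(p,),
                method=meth, rtol=rt, atol=at,
                jac=_jac_wrapped if meth in ("LSODA", "BDF", "Radau") else None,
            )
        if sol.success and sol.y.shape[1] == len(t_eval) and np.all(np.isfinite(sol.y)):
            break
    if not sol.success or sol.y.shape[1] != len(t_eval) or not np.all(np.isfinite(sol.y)):
        return Trajectory(
            times=t_eval, C=np.full_like(t_eval, np.nan),
            T=np.full_like(t_eval, np.nan), M=np.full_like(t_eval, np.nan),
            params=params, success=False, message=str(sol.message),
            rtol=rtol, atol=atol,
        )
    y = sol.y
    # Negativity guard: undershoots up to the solver's resolution on the
    # trajectory scale are numerical (fast-decaying components overshoot by
    # O(rtol * scale)); anything larger is a solver failure (the exact
    # system preserves positivity).
    guard = max(atol, 1e-6 * float(np.nanmax(np.abs(y))))
    if np.any(y < -guard):
        return Trajectory(
            times=t_eval, C=y[0], T=y[1], M=y[2], params=params,
            success=False, message="negative populations beyond tolerance",
            rtol=rtol, atol=atol,
        )
    y = np.clip(y, 0.0, None)
    return Trajectory(times=t_eval, C=y[0], T=y[1], M=y[2], params=params,
                      success=True, message="", rtol=rtol, atol=atol)


def simulate_at_days(
    p: np.ndarray,
    days: np.ndarray,
    init=DEFAULT_INIT,
    rtol: float = 1e-6,
    atol: float = 1e-3,
) -> np.ndarray | None:
    """Fast path used by ABC/eFAST loops: solution at ``days`` only.

    ``p`` is a raw parameter array in canonical order.  Returns an
    (len(days), 3) array, or None on solver failure.  Tolerances are looser
    than :func:`simulate`'s defaults because rejection sampling compares
    against noisy data at a handful of days.
    """
    import warnings

    from scipy.integrate import odeint

    y0 = np.asarray(init, dtype=float)
    t = np.concatenate([[0.0], np.asarray(days, dtype=float)])
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y, info = odeint(
            _rhs_raw, y0, t, args=(p,), Dfun=_jac_wrapped, tfirst=True,
            rtol=rtol, atol=atol, mxstep=10_000, full_output=True,
            printmessg=False,
        )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(y)):
        return None
    guard = max(atol, 1e-6 * float(np.max(np.abs(y))))
    if np.any(y < -guard):
        return None
    return np.clip(y[1:], 0.0, None)


def bounds(params: ParameterSet, init=DEFAULT_INIT) -> BoundSet:
    """Analytic upper bounds C_hat, T_hat, M_hat for a trajectory from ``init``."""
    if isinstance(init, State):
        y0 = init.to_array()
    else:
        y0 = np.asarray(init, dtype=float)
    y0 = _validate_state(y0)
    C0, T0, M0 = y0
    p = params
    C_hat = max(C0, p.C_max)
    # T_m maximizes g(T) = (a_T + s_T*T*C_hat)/(1 + rho*T^2) over T >= 0.
    sc = p.s_T * C_hat
    T_m = np.sqrt(p.rho * (p.rho * p.a_T**2 + sc**2)) / (p.rho * sc) - p.a_T / sc
    g_Tm = (p.a_T + sc * T_m) / (1.0 + p.rho * T_m**2)
    T_hat = max(T0, g_Tm / p.d_T)
    M_hat = max(M0, (p.s_M * C_hat + p.alpha) / p.d_M)
    return BoundSet(C_hat=float(C_hat), T_hat=float(T_hat),
                    M_hat=float(M_hat), T_m=float(T_m))
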