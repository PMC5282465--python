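"""Noise-free SIRS skeleton: right-hand side, equilibria, and ODE reference.

The deterministic system is

    S' = (1-q) Lambda - beta f(S) g(I) - (dS + p) S + eps R
    I' = beta f(S) g(I) - (dI + gamma) I
    R' = q Lambda + p S + gamma I - (dR + eps) R

Its disease-free equilibrium is (S0, 0, Lambda(q dS + p)/(dS(dR+eps)+p dR)),
and for R0 > 1 there is a unique endemic equilibrium found here by reducing
the stationarity system to a one-dimensional root problem in I: eliminating R
from the third equation and adding the first two yields the exact linear
relation S = S0 - S1 I, so the infective balance beta f(S0 - S1 I) g(I) =
(dI + gamma) I is solved by bracketed root-finding on (0, S0/S1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model_core import IncidencePair, ModelParams
from .thresholds import compute_R0_det, compute_S0, compute_S1

__all__ = [
    "EquilibriumResult",
    "OdeTrajectory",
    "rhs",
    "disease_free_equilibrium",
    "endemic_equilibrium",
    "integrate_ode",
]


@dataclass(frozen=True)
class EquilibriumResult:
    kind: str  # "disease-free" | "endemic"
    state: tuple[float, float, float]
    residual: float
    converged: bool


@dataclass(frozen=True)
class OdeTrajectory:
    t: np.ndarray
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray


def rhs(state, params: ModelParams, inc: IncidencePair) -> tuple[float, float, float]:
    """Deterministic derivatives (dS/dt, dI/dt, dR/dt).

    Their sum is Lambda - dS*S - dI*I - dR*R (mass balance).
    """
    S, I, R = state
    if not (np.isfinite(S) and np.isfinite(I) and np.isfinite(R)):
        raise ValueError(f"non-finite state {state}")
    incidence = params.beta * (inc.f(S) * inc.g(I))
    dS = (1 - params.q) * params.Lambda - incidence - (params.dS + params.p) * S + params.epsilon * R
    dI = incidence - (params.dI + params.gamma) * I
    dR = params.q * params.Lambda + params.p * S + params.gamma * I - (params.dR + params.epsilon) * R
    return dS, dI, dR


def disease_free_equilibrium(params: ModelParams, inc: IncidencePair | None = None) -> EquilibriumResult:
    """Closed-form disease-free equilibrium E0 = (S0, 0, R_limit)."""
    den = params.dS * (params.dR + params.epsilon) + params.p * params.dR
    S0 = compute_S0(params)
    R0comp = params.Lambda * (params.q * params.dS + params.p) / den
    state = (S0, 0.0, R0comp)
    if inc is not None:
        res = max(abs(v) for v in rhs(state, params, inc))
    else:
        # residual is independent of the incidence pair since g(0) = 0
        from .model_core import make_builtin_incidence

        res = max(abs(v) for v in rhs(state, params, make_builtin_incidence()))
    return EquilibriumResult("disease-free", state, res, res <= 1e-10)


def endemic_equilibrium(
    params: ModelParams, inc: IncidencePair, residual_tol: float = 1e-10
) -> EquilibriumResult:
    """Unique endemic equilibrium for R0 > 1 via 1-D bracketed root-finding.

    Returns a disease-free fallback (converged=False) when R0 <= 1.
    Raises if the bracket shows no sign change despite R0 > 1.
    """
    R0 = compute_R0_det(params, inc)
    if R0 <= 1:
        dfe = disease_free_equilibrium(params, inc)
        return EquilibriumResult("disease-free", dfe.state, dfe.residual, False)

    S0 = compute_S0(params)
    S1 = compute_S1(params)
    removal = params.dI + params.gamma

    def balance(I: float) -> float:
        return params.beta * inc.f(S0 - S1 * I) * inc.g(I) - removal * I

    upper = min(S0 / S1, params.Lambda / params.mu)
    lo, hi = 1e-12, upper * (1 - 1e-12)
    flo, fhi = balance(lo), balance(hi)
    if flo * fhi > 0:
        raise RuntimeError(
            f"no sign change in endemic bracket despite R0={R0:.4g} > 1: "
            f"balance({lo})={flo:.3g}, balance({hi})={fhi:.3g}"
        )
    Istar = brentq(balance, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    Sstar = S0 - S1 * Istar
    Rstar = (params.q * params.Lambda + params.p * Sstar + params.gamma * Istar) / (
        params.dR + params.epsilon
    )
    state = (Sstar, Istar, Rstar)
    res = max(abs(v) for v in rhs(state, params, inc))
    return EquilibriumResult("endemic", state, res, res < residual_tol)


def integrate_ode(
    state0,
    params: ModelParams,
    inc: IncidencePair,
    T: float,
    dt_max: float = np.inf,
    n_record: int = 1000,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> OdeTrajectory:
    """High-order adaptive integration of the noise-free system."""
    if T <= 0:
        raise ValueError(f"horizon T must be > 0, got {T}")
    t_eval = np.linspace(0.0, T, n_record + 1)
    sol = solve_ivp(
        lambda t, y: rhs(y, params, inc),
        (0.0, T),
        np.asarray(state0, dtype=float),
        method="RK45",
        t_eval=t_eval,
        max_step=dt_max,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return OdeTrajectory(t=sol.t, S=sol.y[0], I=sol.y[1], R=sol.y[2])
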