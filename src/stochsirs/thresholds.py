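"""Closed-form threshold quantities and theorem-condition checkers.

Notation (all rates per unit time):

* ``S0``   -- susceptible level at the disease-free equilibrium,
  ``S0 = Lambda[(1-q)dR + eps] / (dS(dR+eps) + p dR)``;
* ``S1``   -- slope of the long-run linear relation <S> = S0 - S1 <I>,
  ``S1 = [dI(dR+eps) + dR gamma] / (dS(dR+eps) + p dR)``;
* ``Sbar`` -- long-run population bound Lambda/mu, mu = min(dS, dI, dR);
* ``R0``   -- deterministic basic reproduction number
  ``beta f(S0) g'(0) / (dI + gamma)``;
* ``Rtilde0`` -- noise-corrected threshold governing almost-sure exponential
  extinction vs persistence in the mean:

  ``Rtilde0 = [f(S0) g'(0) (beta + sum_j s0j s2j)
               - f(S0)^2 g'(0)^2 sigma_0^2 / 2 - sigma_2^2 / 2] / (dI + gamma)``;

* ``Rbar0`` -- secondary (permanence) threshold, identical except that the
  quadratic penalty is evaluated at the population bound: f(S0) -> f(Sbar)
  in the squared term.  Since f is nondecreasing and Sbar >= S0,
  Rbar0 <= Rtilde0 always, and both collapse to R0 when the noise vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .model_core import IncidencePair, InvalidParameterError, ModelParams

__all__ = [
    "ThresholdReport",
    "ExtinctionConditions",
    "MeanBound",
    "compute_S0",
    "compute_S1",
    "compute_Sbar",
    "compute_R0_det",
    "compute_Rtilde0",
    "compute_Rbar0",
    "check_extinction_thm9",
    "persistence_bound_thm12",
    "permanence_bound_thm14",
    "permanence_bound_thm15",
    "compute_threshold_report",
]


def _denom(params: ModelParams) -> float:
    d = params.dS * (params.dR + params.epsilon) + params.p * params.dR
    if d <= 0:
        raise InvalidParameterError("dS(dR+eps) + p*dR must be positive")
    return d


def compute_S0(params: ModelParams) -> float:
    """Disease-free susceptible level S0."""
    return params.Lambda * ((1 - params.q) * params.dR + params.epsilon) / _denom(params)


def compute_S1(params: ModelParams) -> float:
    """Slope S1 of the long-run identity <S> = S0 - S1 <I>."""
    return (params.dI * (params.dR + params.epsilon) + params.dR * params.gamma) / _denom(params)


def compute_Sbar(params: ModelParams) -> float:
    """Long-run upper bound Lambda/mu on the total population."""
    return params.Lambda / params.mu


def _removal(params: ModelParams) -> float:
    r = params.dI + params.gamma
    if r <= 0:
        raise InvalidParameterError("dI + gamma must be positive")
    return r


def compute_R0_det(params: ModelParams, inc: IncidencePair) -> float:
    """Deterministic basic reproduction number beta f(S0) g'(0)/(dI+gamma)."""
    return inc.f(compute_S0(params)) * inc.gprime0 * params.beta / _removal(params)


def compute_Rtilde0(params: ModelParams, inc: IncidencePair) -> float:
    """Noise-corrected extinction/persistence threshold."""
    r = _removal(params)
    fS0 = inc.f(compute_S0(params))
    drive = fS0 * inc.gprime0 * (params.beta + params.sigma_cross)
    penalty = 0.5 * (fS0 * inc.gprime0) ** 2 * params.sigma_i_sq(0) + 0.5 * params.sigma_i_sq(2)
    return (drive - penalty) / r


def compute_Rbar0(params: ModelParams, inc: IncidencePair) -> float:
    """Secondary (permanence) threshold; the quadratic incidence-noise penalty
    uses f(Sbar) instead of f(S0), so Rbar0 <= Rtilde0."""
    r = _removal(params)
    fS0 = inc.f(compute_S0(params))
    fSbar = inc.f(compute_Sbar(params))
    drive = fS0 * inc.gprime0 * (params.beta + params.sigma_cross)
    penalty = 0.5 * (fSbar * inc.gprime0) ** 2 * params.sigma_i_sq(0) + 0.5 * params.sigma_i_sq(2)
    return (drive - penalty) / r


@dataclass(frozen=True)
class ExtinctionConditions:
    """Raw values and verdicts for the two sufficient extinction conditions.

    Condition (a): Rtilde0 < 1 together with
    ``sigma_0^2 f(S0) g'(0) <= beta + sum_j s0j s2j`` (condA_gap <= 0).
    Condition (b): sigma_0 > 0 and
    ``(beta + sum_j s0j s2j)^2/(2 sigma_0^2) - (dI + gamma + sigma_2^2/2) < 0``.
    ``condB_value`` is None when sigma_0 = 0 (condition not applicable).
    When either holds the infective compartment dies out exponentially a.s.,
    S converges to S0 and R to ``Lambda(q dS + p)/(dS(dR+eps) + p dR)``.
    """

    condA_gap: float
    condA_holds: bool
    condB_value: Optional[float]
    condB_holds: bool
    extinct_predicted: bool
    Rtilde0: float
    S_limit: float
    R_limit: float


def check_extinction_thm9(params: ModelParams, inc: IncidencePair) -> ExtinctionConditions:
    """Evaluate both sufficient conditions for a.s. exponential extinction."""
    s0sq = params.sigma_i_sq(0)
    s2sq = params.sigma_i_sq(2)
    fS0 = inc.f(compute_S0(params))
    bplus = params.beta + params.sigma_cross
    rt = compute_Rtilde0(params, inc)

    condA_gap = s0sq * fS0 * inc.gprime0 - bplus
    condA = rt < 1 and condA_gap <= 0

    if s0sq > 0:
        condB_value = bplus**2 / (2 * s0sq) - (_removal(params) + 0.5 * s2sq)
        condB = condB_value < 0
    else:
        condB_value = None
        condB = False

    return ExtinctionConditions(
        condA_gap=condA_gap,
        condA_holds=condA,
        condB_value=condB_value,
        condB_holds=condB,
        extinct_predicted=condA or condB,
        Rtilde0=rt,
        S_limit=compute_S0(params),
        R_limit=params.Lambda * (params.q * params.dS + params.p) / _denom(params),
    )


@dataclass(frozen=True)
class MeanBound:
    """Lower bound on the long-run mean of I, with applicability flag."""

    value: float
    applicable: bool
    threshold: float
    reason: str = ""


def _sup_Gprime(inc: IncidencePair, upper: float, n_grid: int = 4001) -> float:
    """sup of G'(I) = d(I/g(I))/dI over (0, upper], evaluated analytically
    from g and g' on a grid including the endpoint."""
    grid = np.linspace(upper / n_grid, upper, n_grid)
    return max(inc.Gprime(float(x)) for x in grid)


def _sup_G(inc: IncidencePair, upper: float, n_grid: int = 4001) -> float:
    grid = np.linspace(upper / n_grid, upper, n_grid)
    return max(1.0 / inc.gprime0, max(inc.G(float(x)) for x in grid))


def persistence_bound_thm12(
    params: ModelParams, inc: IncidencePair, M0_bound: float
) -> MeanBound:
    """Persistence-in-the-mean lower bound for the case f(S) = S, incidence
    noise off (sigma row 0 = 0).  ``M0_bound`` is the caller-supplied solution
    bound (S+I+R <= M0); the result is solution-dependent through it."""
    if M0_bound <= 0:
        raise InvalidParameterError(f"M0_bound must be > 0, got {M0_bound}")
    p0 = params.with_zero_rows([0])
    rt = compute_Rtilde0(p0, inc)
    if rt <= 1:
        return MeanBound(0.0, False, rt, "Rtilde0 <= 1: persistence theorem not applicable")
    r = _removal(params)
    S1 = compute_S1(params)
    M = _sup_G(inc, M0_bound)
    supGp = _sup_Gprime(inc, M0_bound)
    denom = (
        params.beta * S1
        + (r + 0.5 * params.sigma_i_sq(2)) * (M * inc.gprime0 + 1.0) * supGp
    ) * inc.gprime0
    return MeanBound(r * (rt - 1.0) / denom, True, rt)


def permanence_bound_thm14(params: ModelParams, inc: IncidencePair) -> MeanBound:
    """Permanence-in-the-mean lower bound for the case f(S) = S with noise only
    on the transmission coefficient (sigma rows 1-3 = 0)."""
    p0 = params.with_zero_rows([1, 2, 3])
    rb = compute_Rbar0(p0, inc)
    if rb <= 1:
        return MeanBound(0.0, False, rb, "Rbar0 <= 1: permanence theorem not applicable")
    r = _removal(params)
    Sbar = compute_Sbar(params)
    denom = (params.beta * compute_S1(params) + r * _sup_Gprime(inc, Sbar)) * inc.gprime0
    return MeanBound(r * (rb - 1.0) / denom, True, rb)


def permanence_bound_thm15(
    params: ModelParams, inc: IncidencePair, tol: float = 1e-12
) -> tuple[MeanBound, float]:
    """Permanence lower bound for the equal-removal special case dS = dR,
    dI = dS + alpha (alpha >= 0), with noise only on transmission.

    Returns the bound and the explicit solution-bound constant M0 replacing
    the trajectory-dependent constant of the general persistence result.
    """
    dS, dR, dI = params.dS, params.dR, params.dI
    if abs(dS - dR) > tol or dI < dS - tol:
        return (
            MeanBound(0.0, False, float("nan"), "requires dS = dR and dI >= dS"),
            float("nan"),
        )
    alpha = max(dI - dS, 0.0)
    e, p, g, L = params.epsilon, params.p, params.gamma, params.Lambda
    M0 = (
        6.0
        * (
            1.0
            + alpha**2 / dS**2
            + g**2 / (dS + e) ** 2
            + p**2 / (dS + e + p) ** 2
            + p * alpha**2 / (dS**2 * (dS + e + p) ** 2)
            + p * g**2 / ((dS + e) ** 2 * (dS + e + p) ** 2)
        )
        * L
        / dS
    )
    p0 = params.with_zero_rows([1, 2, 3])
    rt = compute_Rtilde0(p0, inc)
    if rt <= 1:
        return MeanBound(0.0, False, rt, "Rtilde0 <= 1: theorem not applicable"), M0
    r = _removal(params)
    Sbar = compute_Sbar(params)
    denom = (params.beta * compute_S1(params) + r * _sup_Gprime(inc, Sbar) + M0) * inc.gprime0
    return MeanBound((dS + alpha + params.gamma) * (rt - 1.0) / denom, True, rt), M0


@dataclass(frozen=True)
class ThresholdReport:
    """Every closed-form threshold and theorem-condition value in one bundle."""

    S0: float
    S1: float
    Sbar: float
    mu: float
    R0_det: float
    Rtilde0: float
    Rbar0: float
    condA_gap: float
    condB_value: Optional[float]
    verdicts: dict

    def as_dict(self) -> dict:
        return asdict(self)


def compute_threshold_report(params: ModelParams, inc: IncidencePair) -> ThresholdReport:
    ext = check_extinction_thm9(params, inc)
    rt = ext.Rtilde0
    rb = compute_Rbar0(params, inc)
    return ThresholdReport(
        S0=compute_S0(params),
        S1=compute_S1(params),
        Sbar=compute_Sbar(params),
        mu=params.mu,
        R0_det=compute_R0_det(params, inc),
        Rtilde0=rt,
        Rbar0=rb,
        condA_gap=ext.condA_gap,
        condB_value=ext.condB_value,
        verdicts={
            "thm9_condA": ext.condA_holds,
            "thm9_condB": ext.condB_holds,
            "extinction_predicted": ext.extinct_predicted,
            "Rtilde0_lt_1": rt < 1,
            "Rtilde0_gt_1": rt > 1,
            "Rbar0_gt_1": rb > 1,
        },
    )
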