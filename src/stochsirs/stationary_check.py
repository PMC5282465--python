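"""Sufficient condition for a unique stationary distribution (Lyapunov route).

For f(S) = S the diffusion of the system has row entries

    h1j = -f(S) g(I) s0j - f(S) s1j
    h2j =  f(S) g(I) s0j - I s2j
    h3j = -R s3j

with diagonal a_ii = sum_j h_ij^2.  The checker evaluates, at the endemic
equilibrium (S*, I*, R*), the quadratic-form inequality

    min{ [ (dS+p) k3 + dS - C1 ] S*^2,
         [ (dI+gamma) k3 + dI - C2 ] I*^2,
         [ k1 (dR+eps) + dR - C3 ] R*^2 }
      >  K I* s2^2 / (eps beta g(I*) (gamma-p)) + C1 S*^2 + C2 I*^2 + C3 R*^2

where k3 = [gamma(dS+dR) - p(dI+dR)] / ((gamma-p) eps), k1 = (dI-dS)/(gamma-p),
K = (dS+dI)(gamma-p) eps + (dS+p+dI+gamma)[gamma(dS+dR) - p(dI+dR)], and

    C1 = 2 K I* g'(0)^2 s0^2 / (eps beta g(I*) (gamma-p)) + 2 k3 s1^2 + s^2
    C2 = 2 k3 s2^2 + s^2
    C3 = k1 s3^2 + s^2.

Together with gamma > p, dI > dS, gamma(dS+dR) > p(dI+dR), R0 > 1, and uniform
ellipticity of the diffusion, the inequality guarantees a unique stationary
distribution.  Global ellipticity (a_ii > rho on all of the open positive
octant) cannot literally hold since a_ii -> 0 as the state approaches the
origin; the probe here evaluates the infimum on a bounded box around the
endemic equilibrium and the report notes the distinction.  The condition is
sufficient only: failure does not imply non-existence, and it always holds
for small enough noise when the rate preconditions and R0 > 1 are met.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .deterministic import endemic_equilibrium
from .model_core import IncidencePair, ModelParams
from .thresholds import compute_R0_det

__all__ = [
    "StationaryReport",
    "PreconditionGaps",
    "diffusion_diagonal",
    "precondition_gaps",
    "check_theorem16",
]


def diffusion_diagonal(state, params: ModelParams, inc: IncidencePair) -> tuple[float, float, float]:
    """Diagonal (a11, a22, a33) of the diffusion matrix at ``state``."""
    S, I, R = (float(v) for v in state)
    fS = inc.f(S)
    gI = inc.g(I)
    h1 = -fS * gI * params.sigma[0] - fS * params.sigma[1]
    h2 = fS * gI * params.sigma[0] - I * params.sigma[2]
    h3 = -R * params.sigma[3]
    return float(np.sum(h1**2)), float(np.sum(h2**2)), float(np.sum(h3**2))


@dataclass(frozen=True)
class PreconditionGaps:
    gamma_minus_p: float
    dI_minus_dS: float
    gamma_dSdR_minus_p_dIdR: float

    @property
    def all_positive(self) -> bool:
        return (
            self.gamma_minus_p > 0
            and self.dI_minus_dS > 0
            and self.gamma_dSdR_minus_p_dIdR > 0
        )


def precondition_gaps(params: ModelParams) -> PreconditionGaps:
    """Raw signed gaps of the three rate preconditions."""
    return PreconditionGaps(
        gamma_minus_p=params.gamma - params.p,
        dI_minus_dS=params.dI - params.dS,
        gamma_dSdR_minus_p_dIdR=params.gamma * (params.dS + params.dR)
        - params.p * (params.dI + params.dR),
    )


@dataclass(frozen=True)
class StationaryReport:
    applicable: bool  # f identity and R0 > 1
    preconds: dict
    C1: Optional[float]
    C2: Optional[float]
    C3: Optional[float]
    lhs: Optional[float]
    rhs: Optional[float]
    margin: Optional[float]
    ellipticity_inf: Optional[float]
    equilibrium: Optional[tuple[float, float, float]]
    satisfied: bool
    notes: str = ""


def _f_is_identity(inc: IncidencePair, probes=(0.37, 1.0, 2.5, 7.0)) -> bool:
    return all(abs(inc.f(x) - x) < 1e-12 for x in probes)


def check_theorem16(
    params: ModelParams,
    inc: IncidencePair,
    probe_region: Optional[tuple] = None,
    n_probe: int = 12,
) -> StationaryReport:
    """Full stationary-distribution sufficient-condition check.

    ``probe_region`` is ((S_lo, S_hi), (I_lo, I_hi), (R_lo, R_hi)) for the
    ellipticity probe; default is the box [0.1 x*, 3 x*] per component around
    the endemic equilibrium.  When f is not the identity or R0 <= 1 the
    report carries applicable=False, but the precondition gaps (and, when an
    endemic equilibrium exists, the aggregate inequality evaluated with the
    supplied f) are still reported for diagnostic purposes.
    """
    gaps = precondition_gaps(params)
    R0 = compute_R0_det(params, inc)
    identity_f = _f_is_identity(inc)
    preconds = {
        "gamma_gt_p": gaps.gamma_minus_p > 0,
        "dI_gt_dS": gaps.dI_minus_dS > 0,
        "gamma_dSdR_gt_p_dIdR": gaps.gamma_dSdR_minus_p_dIdR > 0,
        "R0_gt_1": R0 > 1,
        "f_identity": identity_f,
    }
    applicable = identity_f and R0 > 1
    notes = []
    if not identity_f:
        notes.append("f(S) is not the identity; the sufficient condition assumes f(S)=S")
    if R0 <= 1:
        return StationaryReport(
            applicable=False,
            preconds=preconds,
            C1=None,
            C2=None,
            C3=None,
            lhs=None,
            rhs=None,
            margin=None,
            ellipticity_inf=None,
            equilibrium=None,
            satisfied=False,
            notes="; ".join(notes + ["R0 <= 1: no endemic equilibrium"]),
        )

    eq = endemic_equilibrium(params, inc)
    Sst, Ist, Rst = eq.state
    dS, dI, dR = params.dS, params.dI, params.dR
    g_, p, eps, beta = params.gamma, params.p, params.epsilon, params.beta
    s0sq = params.sigma_i_sq(0)
    s1sq = params.sigma_i_sq(1)
    s2sq = params.sigma_i_sq(2)
    s3sq = params.sigma_i_sq(3)
    ssq = params.sigma_sq_total
    gp0 = inc.gprime0
    gIst = inc.g(Ist)

    gp_gap = g_ - p
    if gp_gap == 0 or eps == 0 or beta == 0 or gIst == 0:
        return StationaryReport(
            applicable=applicable,
            preconds=preconds,
            C1=None,
            C2=None,
            C3=None,
            lhs=None,
            rhs=None,
            margin=None,
            ellipticity_inf=None,
            equilibrium=eq.state,
            satisfied=False,
            notes="; ".join(notes + ["degenerate constants (gamma=p, eps=0, or beta=0)"]),
        )

    k3 = gaps.gamma_dSdR_minus_p_dIdR / (gp_gap * eps)
    k1 = gaps.dI_minus_dS / gp_gap
    K = (dS + dI) * gp_gap * eps + (dS + p + dI + g_) * gaps.gamma_dSdR_minus_p_dIdR

    C1 = 2 * K * Ist * gp0**2 * s0sq / (eps * beta * gIst * gp_gap) + 2 * k3 * s1sq + ssq
    C2 = 2 * k3 * s2sq + ssq
    C3 = k1 * s3sq + ssq

    lhs = min(
        ((dS + p) * k3 + dS - C1) * Sst**2,
        ((dI + g_) * k3 + dI - C2) * Ist**2,
        (k1 * (dR + eps) + dR - C3) * Rst**2,
    )
    rhs = K * Ist * s2sq / (eps * beta * gIst * gp_gap) + C1 * Sst**2 + C2 * Ist**2 + C3 * Rst**2
    margin = lhs - rhs

    # ellipticity probe on a bounded box (global infimum over R+^3 is always 0)
    if probe_region is None:
        probe_region = tuple((0.1 * x, 3.0 * x) for x in eq.state)
    axes = [np.linspace(lo, hi, n_probe) for lo, hi in probe_region]
    ell = np.inf
    for S in axes[0]:
        for I in axes[1]:
            for R in axes[2]:
                ell = min(ell, min(diffusion_diagonal((S, I, R), params, inc)))
    notes.append("ellipticity probed on a bounded box; it cannot hold on all of R+^3")

    satisfied = applicable and gaps.all_positive and margin > 0 and ell > 0
    return StationaryReport(
        applicable=applicable,
        preconds=preconds,
        C1=C1,
        C2=C2,
        C3=C3,
        lhs=lhs,
        rhs=rhs,
        margin=margin,
        ellipticity_inf=float(ell),
        equilibrium=eq.state,
        satisfied=satisfied,
        notes="; ".join(notes),
    )
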