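"""Parameterization and incidence-function contract for the stochastic SIRS model.

The model tracks susceptible (S), infectious (I), and recovered (R) individuals
with recruitment ``Lambda``, newborn vaccination fraction ``q``, susceptible
vaccination rate ``p``, immunity-loss rate ``epsilon``, recovery rate ``gamma``,
compartment-specific removal rates ``dS, dI, dR``, and incidence rate
``beta * f(S) * g(I)``.  Environmental noise enters through ``l`` shared Brownian
channels: row ``i`` of the noise matrix ``sigma`` perturbs, respectively, the
transmission coefficient (row 0) and the three removal rates (rows 1-3).

The structural assumptions on the incidence pair are:

* (H1) ``g`` twice continuously differentiable, ``g(0) = 0``, ``g'(0) > 0``, and
  the chain ``g'(I) <= g(I)/I <= g'(0)`` holds for ``I > 0``;
* (H2) ``f`` twice continuously differentiable, ``f(0) = 0``, ``f' >= 0``,
  ``f'' <= 0``.

Assumptions are verified numerically on a finite grid (user-supplied callables
cannot be inspected symbolically).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "IncidencePair",
    "AssumptionReport",
    "InvalidParameterError",
    "make_builtin_incidence",
    "validate_assumptions",
    "params_to_dict",
    "params_from_dict",
    "load_params_json",
    "dump_params_json",
]


class InvalidParameterError(ValueError):
    """Raised when a parameter set violates the model's structural constraints."""


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the stochastic SIRS model.

    ``sigma`` is a 4 x l matrix of non-negative noise intensities: row 0
    multiplies the incidence term, rows 1-3 multiply S, I, R respectively.
    All four rows couple to the same ``l`` Brownian channels.
    """

    Lambda: float
    q: float
    p: float
    epsilon: float
    gamma: float
    beta: float
    dS: float
    dI: float
    dR: float
    sigma: np.ndarray = field(default_factory=lambda: np.zeros((4, 1)))

    def __post_init__(self) -> None:
        sig = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        if sig.shape[0] != 4 or sig.shape[1] < 1:
            raise InvalidParameterError(
                f"sigma must be a 4 x l matrix with l >= 1, got shape {sig.shape}"
            )
        object.__setattr__(self, "sigma", sig)
        if not np.all(np.isfinite(sig)) or np.any(sig < 0):
            raise InvalidParameterError("all noise intensities sigma_ij must be finite and >= 0")
        if not self.Lambda > 0:
            raise InvalidParameterError(f"recruitment rate Lambda must be > 0, got {self.Lambda}")
        if self.beta < 0:
            raise InvalidParameterError(f"transmission coefficient beta must be >= 0, got {self.beta}")
        for name in ("p", "epsilon", "gamma", "dS", "dI", "dR"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"rate {name} must be >= 0, got {getattr(self, name)}")
        if not 0 <= self.q < 1:
            raise InvalidParameterError(f"newborn vaccination fraction q must be in [0, 1), got {self.q}")
        if not self.mu > 0:
            raise InvalidParameterError("min removal rate mu = min(dS, dI, dR) must be > 0")
        if not self.dS * (self.dR + self.epsilon) + self.p * self.dR > 0:
            raise InvalidParameterError("denominator dS(dR+eps) + p*dR must be > 0")

    # -- derived scalars -------------------------------------------------

    @property
    def n_channels(self) -> int:
        """Number of Brownian channels l."""
        return self.sigma.shape[1]

    @property
    def mu(self) -> float:
        """Minimum removal rate, min(dS, dI, dR)."""
        return min(self.dS, self.dI, self.dR)

    def sigma_i_sq(self, i: int) -> float:
        """Row intensity sigma_i^2 = sum_j sigma_ij^2."""
        return float(np.sum(self.sigma[i] ** 2))

    @property
    def sigma_sq_total(self) -> float:
        """sigma^2 = sum_{i=0..3} sigma_i^2."""
        return float(np.sum(self.sigma**2))

    @property
    def sigma_cross(self) -> float:
        """Incidence/removal noise correlation sum_j sigma_0j * sigma_2j."""
        return float(np.sum(self.sigma[0] * self.sigma[2]))

    def with_sigma(self, sigma: np.ndarray) -> "ModelParams":
        """Copy of these parameters with a replacement noise matrix."""
        return replace(self, sigma=np.asarray(sigma, dtype=float))

    def with_zero_rows(self, rows: Sequence[int]) -> "ModelParams":
        """Copy with the given sigma rows zeroed (e.g. Theorem special cases)."""
        sig = self.sigma.copy()
        sig[list(rows)] = 0.0
        return self.with_sigma(sig)


@dataclass(frozen=True)
class IncidencePair:
    """Incidence functions f(S), g(I) with analytic first derivatives.

    ``gprime0`` is g'(0), which enters every threshold formula; it must be
    supplied exactly (no automatic differentiation is attempted).
    """

    f: Callable[[float], float]
    fprime: Callable[[float], float]
    g: Callable[[float], float]
    gprime: Callable[[float], float]
    gprime0: float  # must be > 0 for the thresholds; validate_assumptions reports violations

    def G(self, I: float) -> float:
        """G(I) = I/g(I) extended continuously by G(0) = 1/g'(0)."""
        if I == 0:
            return 1.0 / self.gprime0
        return I / self.g(I)

    def Gprime(self, I: float) -> float:
        """G'(I) = (g(I) - I g'(I)) / g(I)^2 for I > 0 (0 at the origin)."""
        if I == 0:
            return 0.0
        gI = self.g(I)
        return (gI - I * self.gprime(I)) / gI**2


def make_builtin_incidence(a: float = 0.0, omega: float = 0.0) -> IncidencePair:
    """Saturating incidence pair f(S) = S/(1+aS), g(I) = I/(1+omega*I^2).

    ``a = omega = 0`` gives the bilinear incidence beta*S*I.  The quadratic
    denominator in g captures inhibition at high prevalence (media/behaviour
    effects); g(I)/I = 1/(1+omega*I^2) is non-increasing with g'(0) = 1.
    """
    if a < 0 or omega < 0:
        raise InvalidParameterError(f"saturation constants must be >= 0, got a={a}, omega={omega}")

    def f(S: float) -> float:
        return S / (1.0 + a * S)

    def fprime(S: float) -> float:
        return 1.0 / (1.0 + a * S) ** 2

    def g(I: float) -> float:
        return I / (1.0 + omega * I * I)

    def gprime(I: float) -> float:
        w = 1.0 + omega * I * I
        return (1.0 - omega * I * I) / (w * w)

    return IncidencePair(f=f, fprime=fprime, g=g, gprime=gprime, gprime0=1.0)


@dataclass(frozen=True)
class AssumptionReport:
    """Outcome of the numerical (H1)/(H2) check, clause by clause.

    ``g_ratio_nonincreasing`` records the observed direction of g(I)/I; the
    inequality chain g'(I) <= g(I)/I <= g'(0) actually used downstream holds
    when the ratio is non-increasing, so a *nondecreasing* ratio (other than
    the constant bilinear case) is flagged in ``notes``.
    """

    f_zero_at_origin: bool
    f_nondecreasing: bool
    f_concave: bool
    g_zero_at_origin: bool
    gprime0_positive: bool
    g_ratio_chain: bool
    g_ratio_nonincreasing: bool
    worst_violation: float
    all_pass: bool
    notes: str = ""


def validate_assumptions(
    inc: IncidencePair,
    grid_max: float,
    n_grid: int = 201,
    tol: float = 1e-9,
) -> AssumptionReport:
    """Check (H1)/(H2) on a uniform grid of ``n_grid`` points in (0, grid_max].

    Raises on non-finite function values; sign checks use tolerance ``tol``.
    """
    if not grid_max > 0:
        raise InvalidParameterError(f"grid_max must be > 0, got {grid_max}")
    if n_grid < 3:
        raise InvalidParameterError(f"n_grid must be >= 3, got {n_grid}")

    grid = np.linspace(grid_max / n_grid, grid_max, n_grid)
    fv = np.array([inc.f(x) for x in grid])
    fp = np.array([inc.fprime(x) for x in grid])
    gv = np.array([inc.g(x) for x in grid])
    for name, vals in (("f", fv), ("f'", fp), ("g", gv)):
        if not np.all(np.isfinite(vals)):
            bad = grid[~np.isfinite(vals)][0]
            raise InvalidParameterError(f"{name} is non-finite at grid point {bad}")

    f0 = abs(inc.f(0.0))
    g0 = abs(inc.g(0.0))
    # second derivative of f by central differences on the grid
    h = grid[1] - grid[0]
    fsecond = (fv[2:] - 2 * fv[1:-1] + fv[:-2]) / h**2
    ratio = gv / grid

    viol = {
        "f(0)=0": f0,
        "f'>=0": float(np.max(-fp, initial=0.0)),
        "f''<=0": float(np.max(fsecond, initial=0.0)),
        "g(0)=0": g0,
        "g'(0)>0": max(0.0, -inc.gprime0) if inc.gprime0 <= 0 else 0.0,
        "g(I)/I<=g'(0)": float(np.max(ratio - inc.gprime0, initial=0.0)),
    }
    gp = np.array([inc.gprime(x) for x in grid])
    viol["g'(I)<=g(I)/I"] = float(np.max(gp - ratio, initial=0.0))

    ratio_steps = np.diff(ratio)
    nonincreasing = bool(np.all(ratio_steps <= tol))
    notes = ""
    if not nonincreasing and np.any(ratio_steps > tol):
        notes = (
            "g(I)/I increases on part of the grid; the inequality chain "
            "g'(I) <= g(I)/I <= g'(0) used by the threshold analysis may fail"
        )

    report = AssumptionReport(
        f_zero_at_origin=f0 <= tol,
        f_nondecreasing=viol["f'>=0"] <= tol,
        f_concave=viol["f''<=0"] <= tol,
        g_zero_at_origin=g0 <= tol,
        gprime0_positive=inc.gprime0 > 0,
        g_ratio_chain=viol["g(I)/I<=g'(0)"] <= tol and viol["g'(I)<=g(I)/I"] <= tol,
        g_ratio_nonincreasing=nonincreasing,
        worst_violation=max(viol.values()),
        all_pass=all(v <= tol for v in viol.values()) and inc.gprime0 > 0,
        notes=notes,
    )
    return report


# -- configuration I/O ---------------------------------------------------

_SCALAR_FIELDS = ("Lambda", "q", "p", "epsilon", "gamma", "beta", "dS", "dI", "dR")


def params_to_dict(params: ModelParams) -> dict:
    """JSON-ready dict with keys matching the field names; sigma as a 4 x l list."""
    out = {k: getattr(params, k) for k in _SCALAR_FIELDS}
    out["sigma"] = params.sigma.tolist()
    return out


def params_from_dict(doc: dict) -> ModelParams:
    missing = [k for k in _SCALAR_FIELDS + ("sigma",) if k not in doc]
    if missing:
        raise InvalidParameterError(f"missing parameter keys: {missing}")
    return ModelParams(
        **{k: float(doc[k]) for k in _SCALAR_FIELDS},
        sigma=np.asarray(doc["sigma"], dtype=float),
    )


def load_params_json(path) -> ModelParams:
    with open(path) as fh:
        return params_from_dict(json.load(fh))


def dump_params_json(params: ModelParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params_to_dict(params), fh, indent=2)
        fh.write("\n")
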