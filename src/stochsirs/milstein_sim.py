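"""Milstein-type discretization of the stochastic SIRS system.

One step of the scheme updates each compartment with its deterministic drift
plus, for each of the ``l`` shared Brownian channels, the increment

    sigma_ij * xi_j * sqrt(dt) + (1/2) * sigma_ij^2 * (xi_j^2 - 1) * dt

multiplied by the compartment's diffusion factor (f(S)g(I) for the incidence
channel, S, I, or R for the removal channels).  The same standard-normal draw
``xi_j`` is used across the three equations within a step, reflecting the
shared Brownian channels B_j.

The scheme can produce negative excursions the exact process never has; by
default each component is floored at zero after the step and the number of
clamp events is recorded (set ``clamp=False`` for scheme-fidelity studies).
Replicate r of an ensemble draws its normals from
``numpy.random.default_rng(SeedSequence(master_seed, spawn_key=(r,)))``, so
ensembles are reproducible across machines given (seed, config, parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model_core import IncidencePair, ModelParams

__all__ = [
    "SimConfig",
    "Trajectory",
    "EnsembleSummary",
    "StepOverflowError",
    "milstein_step",
    "simulate",
    "simulate_ensemble",
]

_MAX_RECORDED = 100_000


class StepOverflowError(RuntimeError):
    """Raised when an integration step produces a non-finite state."""

    def __init__(self, step: int, state) -> None:
        super().__init__(f"non-finite state {state} at step {step}")
        self.step = step
        self.state = state


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.01
    T: float = 100.0
    n_reps: int = 1
    seed: int = 0
    clamp: bool = True
    record_stride: Optional[int] = None  # None: auto, at most ~1e5 recorded points

    def __post_init__(self) -> None:
        if not 0 < self.dt <= self.T:
            raise ValueError(f"need 0 < dt <= T, got dt={self.dt}, T={self.T}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if self.record_stride is not None and self.record_stride < 1:
            raise ValueError(f"record_stride must be >= 1, got {self.record_stride}")

    @property
    def n_steps(self) -> int:
        return math.ceil(self.T / self.dt)

    @property
    def stride(self) -> int:
        if self.record_stride is not None:
            return self.record_stride
        return max(1, math.ceil(self.n_steps / _MAX_RECORDED))


@dataclass(frozen=True)
class Trajectory:
    """Recorded (t, S, I, R) path with seed provenance and clamp diagnostics."""

    t: np.ndarray
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    seed: Optional[int]
    dt: float
    clamp_events: int = 0
    n_steps: int = 0

    @property
    def any_clamped(self) -> bool:
        return self.clamp_events > 0

    @property
    def clamp_fraction(self) -> float:
        return self.clamp_events / self.n_steps if self.n_steps else 0.0

    @property
    def terminal(self) -> tuple[float, float, float]:
        return float(self.S[-1]), float(self.I[-1]), float(self.R[-1])


def milstein_step(
    state,
    params: ModelParams,
    inc: IncidencePair,
    dt: float,
    xi,
    clamp: bool = True,
):
    """Single step of the discretization; ``xi`` is an l-vector of N(0,1) draws."""
    S, I, R = (float(v) for v in state)
    xi = np.asarray(xi, dtype=float)
    if xi.shape != (params.n_channels,):
        raise ValueError(f"xi must have length l={params.n_channels}, got shape {xi.shape}")
    sqdt = math.sqrt(dt)
    sig = params.sigma
    # channel increment sigma_ij xi_j sqrt(dt) + 0.5 sigma_ij^2 (xi_j^2-1) dt, summed over j
    w = xi * sqdt
    c = 0.5 * (xi * xi - 1.0) * dt
    n0, n1, n2, n3 = (float(np.sum(sig[i] * w + sig[i] ** 2 * c)) for i in range(4))

    fg = inc.f(S) * inc.g(I)
    Sn = (
        S
        + ((1 - params.q) * params.Lambda - params.beta * fg - (params.dS + params.p) * S + params.epsilon * R) * dt
        - fg * n0
        - S * n1
    )
    In = I + (params.beta * fg - (params.dI + params.gamma) * I) * dt + fg * n0 - I * n2
    Rn = (
        R
        + (params.q * params.Lambda + params.p * S + params.gamma * I - (params.dR + params.epsilon) * R) * dt
        - R * n3
    )
    if not (math.isfinite(Sn) and math.isfinite(In) and math.isfinite(Rn)):
        raise StepOverflowError(-1, (Sn, In, Rn))
    if clamp:
        Sn, In, Rn = max(Sn, 0.0), max(In, 0.0), max(Rn, 0.0)
    return Sn, In, Rn


def simulate(
    state0,
    params: ModelParams,
    inc: IncidencePair,
    cfg: SimConfig,
    normals: Optional[np.ndarray] = None,
) -> Trajectory:
    """Iterate the scheme for ceil(T/dt) steps from a non-negative start.

    ``normals`` (shape (n_steps, l)) overrides the seeded stream; this is
    used by path-refinement convergence studies that share Brownian paths.
    """
    S, I, R = (float(v) for v in state0)
    if min(S, I, R) < 0:
        raise ValueError(f"initial state must be componentwise >= 0, got {state0}")
    n_steps = cfg.n_steps
    l = params.n_channels
    if normals is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        normals = rng.standard_normal((n_steps, l))
        seed: Optional[int] = cfg.seed
    else:
        normals = np.asarray(normals, dtype=float)
        if normals.shape != (n_steps, l):
            raise ValueError(f"normals must have shape {(n_steps, l)}, got {normals.shape}")
        seed = None

    dt = cfg.dt
    sqdt = math.sqrt(dt)
    stride = cfg.stride
    n_rec = n_steps // stride + 1
    tg = np.empty(n_rec)
    Sg = np.empty(n_rec)
    Ig = np.empty(n_rec)
    Rg = np.empty(n_rec)
    tg[0], Sg[0], Ig[0], Rg[0] = 0.0, S, I, R

    # flatten model constants for the inner loop
    L1q = (1 - params.q) * params.Lambda
    Lq = params.q * params.Lambda
    beta, eps, p, gam = params.beta, params.epsilon, params.p, params.gamma
    aS, aI, aR = params.dS + params.p, params.dI + params.gamma, params.dR + params.epsilon
    s0 = [float(v) for v in params.sigma[0]]
    s1 = [float(v) for v in params.sigma[1]]
    s2 = [float(v) for v in params.sigma[2]]
    s3 = [float(v) for v in params.sigma[3]]
    s0q = [0.5 * v * v * dt for v in s0]
    s1q = [0.5 * v * v * dt for v in s1]
    s2q = [0.5 * v * v * dt for v in s2]
    s3q = [0.5 * v * v * dt for v in s3]
    f, g = inc.f, inc.g
    clamp = cfg.clamp
    clamp_events = 0
    rec = 0

    for k in range(n_steps):
        row = normals[k]
        n0 = n1 = n2 = n3 = 0.0
        for j in range(l):
            x = row[j]
            w = x * sqdt
            cterm = x * x - 1.0
            n0 += s0[j] * w + s0q[j] * cterm
            n1 += s1[j] * w + s1q[j] * cterm
            n2 += s2[j] * w + s2q[j] * cterm
            n3 += s3[j] * w + s3q[j] * cterm
        fg = f(S) * g(I)
        Sn = S + (L1q - beta * fg - aS * S + eps * R) * dt - fg * n0 - S * n1
        In = I + (beta * fg - aI * I) * dt + fg * n0 - I * n2
        Rn = R + (Lq + p * S + gam * I - aR * R) * dt - R * n3
        if not (math.isfinite(Sn) and math.isfinite(In) and math.isfinite(Rn)):
            raise StepOverflowError(k, (Sn, In, Rn))
        if clamp and (Sn < 0.0 or In < 0.0 or Rn < 0.0):
            clamp_events += 1
            Sn, In, Rn = max(Sn, 0.0), max(In, 0.0), max(Rn, 0.0)
        S, I, R = Sn, In, Rn
        if (k + 1) % stride == 0:
            rec += 1
            tg[rec] = (k + 1) * dt
            Sg[rec], Ig[rec], Rg[rec] = S, I, R

    return Trajectory(
        t=tg[: rec + 1],
        S=Sg[: rec + 1],
        I=Ig[: rec + 1],
        R=Rg[: rec + 1],
        seed=seed,
        dt=dt,
        clamp_events=clamp_events,
        n_steps=n_steps,
    )


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-time-point mean and quantile bands across replicates."""

    t: np.ndarray
    mean: dict = field(default_factory=dict)  # compartment -> array
    q10: dict = field(default_factory=dict)
    q90: dict = field(default_factory=dict)
    running_mean_I: np.ndarray | None = None  # ensemble mean of (1/t) int_0^t I


def summarize_ensemble(trajectories: list[Trajectory]) -> EnsembleSummary:
    t = trajectories[0].t
    out_mean, out_lo, out_hi = {}, {}, {}
    for name in ("S", "I", "R"):
        stack = np.stack([getattr(tr, name) for tr in trajectories])
        out_mean[name] = stack.mean(axis=0)
        out_lo[name] = np.quantile(stack, 0.1, axis=0)
        out_hi[name] = np.quantile(stack, 0.9, axis=0)
    # running time-average of I per replicate (left-Riemann), then ensemble mean
    run = []
    for tr in trajectories:
        dt = np.diff(tr.t)
        csum = np.concatenate([[0.0], np.cumsum(tr.I[:-1] * dt)])
        with np.errstate(invalid="ignore", divide="ignore"):
            ra = np.where(tr.t > 0, csum / np.where(tr.t > 0, tr.t, 1.0), tr.I[0])
        run.append(ra)
    return EnsembleSummary(
        t=t, mean=out_mean, q10=out_lo, q90=out_hi, running_mean_I=np.mean(run, axis=0)
    )


def simulate_ensemble(
    state0,
    params: ModelParams,
    inc: IncidencePair,
    cfg: SimConfig,
) -> tuple[list[Trajectory], EnsembleSummary]:
    """Run ``cfg.n_reps`` independent replicates with documented seed derivation."""
    trajectories = []
    for r in range(cfg.n_reps):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(r,)))
        normals = rng.standard_normal((cfg.n_steps, params.n_channels))
        tr = simulate(state0, params, inc, replace(cfg, n_reps=1), normals=normals)
        tr = replace(tr, seed=cfg.seed)
        trajectories.append(tr)
    return trajectories, summarize_ensemble(trajectories)
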