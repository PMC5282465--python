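"""Time-average functionals, regime classification, and empirical marginals.

The theory's statements are asymptotic: extinction means limsup ln I(t)/t < 0
almost surely, persistence in the mean means liminf <I(t)> > 0 with
<h(t)> = (1/t) int_0^t h(s) ds.  At finite horizon these are operationalised
as (extinct) a negative fitted slope of ln I on the post-burn-in window
together with a small terminal value, and (persistent) a post-burn-in mean
above a level threshold without evidence of decay.  Both tolerances are
exposed because the theory fixes no finite-time cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import IncidencePair, ModelParams
from .milstein_sim import Trajectory
from .thresholds import compute_S0, compute_S1

__all__ = [
    "RegimeReport",
    "MarginalReport",
    "time_average",
    "classify_regime",
    "empirical_marginals",
]

_LOG_FLOOR = 1e-300


def time_average(series, t_grid, burn_in: float = 0.0) -> float:
    """Left-Riemann time average of ``series`` over t >= burn_in.

    Matches <h(t)> = (1/t) int_0^t h(s) ds for burn_in = 0 up to the
    discretization of the integral; a single retained point returns its value.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if y.shape != t.shape:
        raise ValueError(f"series and t_grid shapes differ: {y.shape} vs {t.shape}")
    keep = t >= burn_in
    if not np.any(keep):
        raise ValueError(f"empty averaging window: burn_in={burn_in} >= T={t[-1]}")
    y, t = y[keep], t[keep]
    if len(t) == 1:
        return float(y[0])
    dt = np.diff(t)
    return float(np.sum(y[:-1] * dt) / (t[-1] - t[0]))


@dataclass(frozen=True)
class RegimeReport:
    mean_S: float
    mean_I: float
    mean_R: float
    log_slope_I: float
    terminal_I: float
    classification: str  # "extinct" | "persistent" | "indeterminate"
    lemma3_residual: float
    log_floored: bool
    clamp_fraction: float


def classify_regime(
    traj: Trajectory,
    params: ModelParams,
    inc: IncidencePair,
    burn_in_frac: float = 0.25,
    slope_tol: float = 1e-3,
    level_tol: float = 1e-2,
) -> RegimeReport:
    """Label a trajectory extinct / persistent / indeterminate.

    Extinction requires BOTH a fitted ln-I slope below -slope_tol on the
    post-burn-in window AND a terminal I below level_tol, guarding against
    slow transients mislabelled by either criterion alone.  Runs where the
    positivity clamp fired in more than 1% of steps are indeterminate (the
    log-slope is meaningless there).  The long-run diagnostic
    ``lemma3_residual`` = \\|<S> - (S0 - S1 <I>)\\| uses full-horizon averages,
    for which the model predicts convergence to zero for any positive solution.
    """
    T = float(traj.t[-1])
    burn_in = burn_in_frac * T
    keep = traj.t >= burn_in
    if int(np.sum(keep)) < 100:
        raise ValueError("trajectory must retain at least 100 points after burn-in")

    mean_S = time_average(traj.S, traj.t, burn_in)
    mean_I = time_average(traj.I, traj.t, burn_in)
    mean_R = time_average(traj.R, traj.t, burn_in)
    terminal_I = float(traj.I[-1])

    Iw = traj.I[keep]
    pos = Iw > 0
    floored = bool(np.any(~pos))
    # fit the decay rate on the strictly positive part only: once the clamp
    # pins I at exactly 0 a floored log would flatten the slope of a run
    # that has in fact died out
    if int(np.count_nonzero(pos)) >= 2:
        slope = float(np.polyfit(traj.t[keep][pos], np.log(Iw[pos]), 1)[0])
    else:
        slope = -np.inf
    zero_frac = float(np.mean(~pos))

    S0 = compute_S0(params)
    S1 = compute_S1(params)
    lemma3 = abs(
        time_average(traj.S, traj.t, 0.0) - (S0 - S1 * time_average(traj.I, traj.t, 0.0))
    )

    if traj.clamp_fraction > 0.01:
        label = "indeterminate"
    elif (slope < -slope_tol or zero_frac > 0.5) and terminal_I < level_tol:
        label = "extinct"
    elif mean_I > level_tol and terminal_I > level_tol:
        label = "persistent"
    else:
        label = "indeterminate"

    return RegimeReport(
        mean_S=mean_S,
        mean_I=mean_I,
        mean_R=mean_R,
        log_slope_I=slope,
        terminal_I=terminal_I,
        classification=label,
        lemma3_residual=lemma3,
        log_floored=floored,
        clamp_fraction=traj.clamp_fraction,
    )


@dataclass(frozen=True)
class MarginalReport:
    """Histogram (normalized frequencies) and moments per compartment."""

    bin_edges: dict
    freqs: dict
    mean: dict
    mode: dict
    n_samples: int


def empirical_marginals(
    trajectories: list[Trajectory],
    burn_in_frac: float = 0.25,
    n_bins: int = 50,
) -> MarginalReport:
    """Pool post-burn-in samples across replicates into per-compartment histograms."""
    pooled = {"S": [], "I": [], "R": []}
    for tr in trajectories:
        keep = tr.t >= burn_in_frac * tr.t[-1]
        for name in pooled:
            pooled[name].append(getattr(tr, name)[keep])
    pooled = {k: np.concatenate(v) for k, v in pooled.items()}
    n = len(pooled["S"])
    if n < 1000:
        raise ValueError(f"need >= 1000 pooled post-burn-in samples, got {n}")

    edges, freqs, means, modes = {}, {}, {}, {}
    for name, x in pooled.items():
        counts, e = np.histogram(x, bins=n_bins)
        edges[name] = e
        freqs[name] = counts / counts.sum()
        means[name] = float(np.mean(x))
        centers = 0.5 * (e[:-1] + e[1:])
        modes[name] = float(centers[np.argmax(counts)])
    return MarginalReport(bin_edges=edges, freqs=freqs, mean=means, mode=modes, n_samples=n)
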