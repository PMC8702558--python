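"""Quenched-slow-variable analysis of the fast subsystem.

With the slow variables y frozen, the feedback tanh(r) is a constant vector
and the fast population becomes an autonomous dynamical system

    tau_x dx_i/dt = tanh(beta_x (sum_{j != i} JX_ij x_j + drive_i)) - x_i,

whose attractors can be enumerated.  Sampling y every few time units along
a recall trajectory and repeating the enumeration yields a bifurcation
diagram of x with y as the (slowly moving) bifurcation parameter.  The
mechanism behind robust sequential recall is visible in that diagram: for a
well-trained network the fixed points of the current and the next target
coexist over a window of y before the current one loses stability, so the
state falls onto the next target rather than anywhere else.  Mistimed
learning destroys the window (too-fast plasticity skips targets; too-slow
plasticity leaves only the most recently learned target stable).

Fixed points are located empirically: trajectories are integrated from a
few starts near each target (0.9 xi + 0.1 uniform noise) plus random
starts, endpoints that satisfy a sustained residual tolerance are clustered
with a max-norm merge radius, and a basin is called "large" when at least
one random start reaches it and "small" when only near-target starts do.
Non-convergent (oscillatory) runs are counted and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import _kernels
from .model import (
    ConfigError,
    Connectivity,
    ModelParams,
    Trajectory,
    as_generator,
    overlap,
)

__all__ = [
    "QuenchedSample",
    "FixedPoint",
    "FixedPointSet",
    "PCBasis",
    "sample_slow_states",
    "find_fixed_points",
    "coexistence_windows",
    "pca_fit",
    "project",
    "bifurcation_table",
]


@dataclass
class QuenchedSample:
    """A frozen slow state taken from a trajectory, with the input in force."""

    t: float
    y: np.ndarray
    eta: np.ndarray


@dataclass
class FixedPoint:
    """One attractor of the quenched fast subsystem."""

    x: np.ndarray
    symbol: str  # matched target label, or "other"
    basin: str  # "large" | "small"
    n_random_hits: int
    n_near_hits: int

    @property
    def n_hits(self) -> int:
        return self.n_random_hits + self.n_near_hits


@dataclass
class FixedPointSet:
    """All attractors found for one quenched sample."""

    t: float
    fixed_points: list[FixedPoint] = field(default_factory=list)
    n_random_starts: int = 0
    n_nonconverged: int = 0

    def symbols(self, basin: str | None = None) -> set[str]:
        return {
            fp.symbol
            for fp in self.fixed_points
            if basin is None or fp.basin == basin
        }


def sample_slow_states(
    traj: Trajectory,
    t_start: float = 200.0,
    t_end: float = 500.0,
    interval: float = 5.0,
) -> list[QuenchedSample]:
    """Snapshot y (and the applied input) every ``interval`` units.

    Default window [200, 500] with 5-unit spacing gives 61 samples.
    """
    if t_start < traj.times[0] or t_end > traj.times[-1]:
        raise ConfigError("sampling window outside trajectory")
    if traj.schedule is None:
        raise ConfigError("trajectory carries no input schedule")
    ts = np.arange(t_start, t_end + interval / 2, interval)
    ts = ts[ts <= t_end]
    return [
        QuenchedSample(float(t), traj.state_at(t).y, traj.schedule.eta_at(t))
        for t in ts
    ]


def _cluster(points: list[np.ndarray], merge_radius: float) -> list[int]:
    """Greedy max-norm clustering; returns the cluster index per point."""
    centers: list[np.ndarray] = []
    assign = []
    for p in points:
        for k, c in enumerate(centers):
            if np.max(np.abs(p - c)) < merge_radius:
                assign.append(k)
                break
        else:
            centers.append(p)
            assign.append(len(centers) - 1)
    return assign


def find_fixed_points(
    conn: Connectivity,
    params: ModelParams,
    sample: QuenchedSample,
    targets: Mapping[str, np.ndarray],
    n_random: int = 12,
    n_near: int = 3,
    dt: float = 0.05,
    transient: float = 200.0,
    hold_time: float = 10.0,
    extra_time: float = 300.0,
    tol: float = 1e-6,
    match_overlap: float = 0.7,
    merge_radius: float = 0.05,
    rng=None,
) -> FixedPointSet:
    """Enumerate attractors of the fast subsystem at one frozen y.

    Integrates ``n_near`` starts in the vicinity of each target
    (0.9 xi + 0.1 uniform[-1,1]) plus ``n_random`` uniform random starts
    (3 per target + 12 random = 15 trajectories for a three-target task),
    requires ``max_i |dx_i/dt| < tol`` sustained for ``hold_time`` after the
    transient, clusters endpoints within ``merge_radius`` (max-norm), labels
    each cluster by the target it overlaps beyond ``match_overlap``, and
    classifies its basin as large iff at least one random start reached it.

    ``match_overlap`` defaults to the 0.7 symbolization threshold so that
    "this fixed point is target X" and "the recall trajectory is at target
    X" mean the same thing; attractors pinned to a target typically overlap
    it by 0.75-0.95, not 1.
    """
    rng = as_generator(rng)
    N = params.N
    drive = np.tanh(conn.JXY @ np.tanh(sample.y)) + sample.eta
    labels = list(targets)
    starts = []
    origins = []  # "near" | "random"
    for lab in labels:
        xi = np.asarray(targets[lab], dtype=np.float64)
        for _ in range(n_near):
            starts.append(0.9 * xi + 0.1 * rng.uniform(-1, 1, N))
            origins.append("near")
    for _ in range(n_random):
        starts.append(rng.uniform(-1, 1, N))
        origins.append("random")
    X = np.ascontiguousarray(starts)
    JXT = np.ascontiguousarray(conn.JX.T)
    done = _kernels.relax_fast_batch(
        JXT,
        drive,
        X,
        dt,
        params.tau_x,
        params.beta_x,
        int(round(transient / dt)),
        int(round(extra_time / dt)),
        int(round(hold_time / dt)),
        tol,
    )
    fps = FixedPointSet(sample.t, n_random_starts=n_random)
    converged = [i for i in range(len(starts)) if done[i]]
    fps.n_nonconverged = len(starts) - len(converged)
    if not converged:
        return fps
    assign = _cluster([X[i] for i in converged], merge_radius)
    for k in range(max(assign) + 1):
        members = [converged[i] for i, a in enumerate(assign) if a == k]
        xstar = X[members[0]]
        n_rand = sum(origins[i] == "random" for i in members)
        n_nearh = len(members) - n_rand
        symbol = "other"
        best = 0.0
        for lab in labels:
            m = overlap(xstar, targets[lab])
            if m > match_overlap and m > best:
                symbol, best = lab, m
        fps.fixed_points.append(
            FixedPoint(
                x=xstar.copy(),
                symbol=symbol,
                basin="large" if n_rand >= 1 else "small",
                n_random_hits=n_rand,
                n_near_hits=n_nearh,
            )
        )
    return fps


def coexistence_windows(
    fixed_point_sets: Sequence[FixedPointSet],
    expected_order: Sequence[str],
) -> dict[tuple[str, str], tuple[float, float] | None]:
    """Sample windows where consecutive targets coexist as fixed points.

    For every consecutive pair (mu, mu+1) of the expected recall order
    (cyclically closed), returns the (first, last) sample time at which
    both targets are attractors of the quenched fast subsystem, or None if
    they never coexist — the failure signature of mistimed learning.
    """
    order = list(expected_order)
    pairs = [(order[i], order[(i + 1) % len(order)]) for i in range(len(order))]
    out: dict[tuple[str, str], tuple[float, float] | None] = {}
    for pair in pairs:
        times = [
            fps.t
            for fps in fixed_point_sets
            if pair[0] in fps.symbols() and pair[1] in fps.symbols()
        ]
        out[pair] = (min(times), max(times)) if times else None
    return out


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------


@dataclass
class PCBasis:
    """Orthonormal components fitted on the fast-trajectory sample matrix."""

    components: np.ndarray  # (k, N)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def pca_fit(traj_or_X, n_components: int | None = None) -> PCBasis:
    """Fit principal components on the sampled fast states.

    The basis is fitted on x only; slow states are projected in the same
    basis.  A rank-deficient trajectory yields fewer components.
    """
    X = traj_or_X.X if isinstance(traj_or_X, Trajectory) else np.asarray(traj_or_X)
    if X.shape[0] < 2:
        raise ConfigError("PCA requires at least 2 samples")
    k = min(X.shape) if n_components is None else n_components
    pca = PCA(n_components=k).fit(X)
    keep = pca.explained_variance_ > 1e-12
    return PCBasis(
        components=pca.components_[keep],
        explained_variance_ratio=pca.explained_variance_ratio_[keep],
        mean=pca.mean_,
    )


def project(vectors: np.ndarray, basis: PCBasis) -> np.ndarray:
    """Coordinates of (rows of) ``vectors`` in the fitted PC basis."""
    V = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    return (V - basis.mean) @ basis.components.T


def bifurcation_table(
    fixed_point_sets: Sequence[FixedPointSet], basis: PCBasis
) -> pd.DataFrame:
    """Flat diagram table: sample time, fixed point id, PC1, basin, symbol."""
    rows = []
    for fps in fixed_point_sets:
        for j, fp in enumerate(fps.fixed_points):
            rows.append(
                {
                    "t": fps.t,
                    "fp": j,
                    "pc1": float(project(fp.x, basis)[0, 0]),
                    "basin": fp.basin,
                    "symbol": fp.symbol,
                    "n_random_hits": fp.n_random_hits,
                    "n_near_hits": fp.n_near_hits,
                }
            )
    return pd.DataFrame(rows)
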