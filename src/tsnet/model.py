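"""Core slow-fast rate network: state, connectivity, and coupled dynamics.

The model is two N-unit rate populations.  The fast population X (time
constant ``tau_x``) is driven by its own plastic recurrent connectivity
``JX``, by an external binary input pattern ``eta``, and by a nonlinear
feedback ``tanh(r)`` from the slow population Y (time constant
``tau_y >> tau_x``), which low-pass filters X and thereby stores the recent
history of activity:

    tau_x dx_i/dt = tanh(beta_x I_i) - x_i,
    tau_y dy_i/dt = tanh(beta_y x_i) - y_i,
    I_i = u_i + tanh(r_i) + eta_i,

with recurrent drive ``u_i = sum_{j != i} JX_ij x_j`` and slow feedback
``r_i = sum_j JXY_ij tanh(y_j)`` through a fixed sparse random matrix
``JXY``.  Integration is explicit Euler with a configurable step
(``dt = 0.05 = tau_x/20`` by default); halving the step changes sampled
states at O(dt^2), which the test suite asserts.

Randomness policy: one master seed is split into independent named streams
(:func:`seed_streams`) for connectivity, patterns, initial states, switch
perturbations and dynamics noise, so each ingredient of an experiment can be
replayed in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np

from . import _kernels

__all__ = [
    "ConfigError",
    "ModelParams",
    "Connectivity",
    "NetworkState",
    "LocalField",
    "NoiseConfig",
    "InputSchedule",
    "Trajectory",
    "seed_streams",
    "as_generator",
    "init_connectivity",
    "compute_local_field",
    "step",
    "simulate",
    "overlap",
    "overlap_xy",
    "save_connectivity",
    "load_connectivity",
    "save_trajectory",
    "load_trajectory",
]


class ConfigError(ValueError):
    """Invalid model or experiment configuration."""


#: Named RNG streams spawned from one master seed.
STREAM_NAMES = ("connectivity", "patterns", "init", "switch", "noise")


def as_generator(rng) -> np.random.Generator:
    """Coerce ``rng`` (None, int seed, SeedSequence or Generator) to a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def seed_streams(master_seed: int) -> dict[str, np.random.Generator]:
    """Split one master seed into independent named streams.

    Streams are spawned from a single :class:`numpy.random.SeedSequence` so
    that, e.g., regenerating the patterns does not disturb the connectivity
    draw of the same experiment.
    """
    children = np.random.SeedSequence(master_seed).spawn(len(STREAM_NAMES))
    return {
        name: np.random.default_rng(ss) for name, ss in zip(STREAM_NAMES, children)
    }


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParams:
    """Scalar constants of the slow-fast network.

    Parameters
    ----------
    N : int
        Units per population.
    beta_x, beta_y : float
        Gains of the fast and slow activation functions.  The large slow
        gain (default 20) makes y a near-binary copy of the recent x.
    tau_x, tau_y : float
        Fast and slow time constants (time units).  Their ratio (default
        1:100) is what lets y act as a quasi-static bifurcation parameter
        for x.
    tau_syn : float
        Learning time constant of the plasticity rule; sequence memory is
        best when ``tau_syn ~ tau_y``.
    rho : float
        Connection probability (per sign) of the slow-to-fast matrix JXY.
    c : float
        Amplitude factor of nonzero JXY entries, ``+-c / sqrt(N)``.
    """

    N: int = 100
    beta_x: float = 2.0
    beta_y: float = 20.0
    tau_x: float = 1.0
    tau_y: float = 100.0
    tau_syn: float = 100.0
    rho: float = 0.05
    c: float = 7.0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ConfigError(f"N must be >= 2, got {self.N}")
        for name in ("tau_x", "tau_y", "tau_syn"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.rho <= 0.5:
            raise ConfigError(f"rho must lie in [0, 0.5], got {self.rho}")

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "beta_x": self.beta_x,
            "beta_y": self.beta_y,
            "tau_x": self.tau_x,
            "tau_y": self.tau_y,
            "tau_syn": self.tau_syn,
            "rho": self.rho,
            "c": self.c,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParams":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass
class Connectivity:
    """Plastic fast recurrent matrix ``JX`` and fixed sparse ``JXY``.

    ``JX[i, j]`` connects fast unit j to fast unit i and its diagonal is
    pinned at zero.  ``JXY`` is immutable after construction.
    """

    JX: np.ndarray
    JXY: np.ndarray

    def __post_init__(self) -> None:
        self.JX = np.ascontiguousarray(self.JX, dtype=np.float64)
        self.JXY = np.ascontiguousarray(self.JXY, dtype=np.float64)
        if self.JX.shape != self.JXY.shape or self.JX.ndim != 2:
            raise ConfigError("JX and JXY must be equal-shape square matrices")
        if self.JX.shape[0] != self.JX.shape[1]:
            raise ConfigError("connectivity matrices must be square")
        self.JXY.setflags(write=False)

    @property
    def N(self) -> int:
        return self.JX.shape[0]

    def copy(self) -> "Connectivity":
        return Connectivity(self.JX.copy(), self.JXY.copy())


@dataclass
class NetworkState:
    """Fast vector x, slow vector y and the current time."""

    x: np.ndarray
    y: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ConfigError("x and y must be equal-length vectors")

    @property
    def N(self) -> int:
        return self.x.shape[0]

    def copy(self) -> "NetworkState":
        return NetworkState(self.x.copy(), self.y.copy(), self.t)


@dataclass
class LocalField:
    """Decomposition of the total input: I = u + tanh(r) + eta."""

    I: np.ndarray
    u: np.ndarray
    r: np.ndarray


@dataclass
class NoiseConfig:
    """Additive Gaussian white noise on the fast dynamics.

    The discretized increment is ``s * sqrt(dt) * N(0, 1)`` per component
    per step, applied to x only.  ``s = 0`` (or ``enabled = False``)
    reproduces the deterministic path bit for bit.
    """

    s: float = 0.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ConfigError("noise strength s must be >= 0")

    @property
    def sigma(self) -> float:
        return self.s if self.enabled else 0.0


class InputSchedule:
    """Piecewise-constant external input eta(t).

    Holds segments ``(t_start, t_end, eta)`` with contiguous, increasing
    intervals.  A zero vector encodes "no input" (spontaneous runs).
    """

    def __init__(self, segments: Sequence[tuple[float, float, np.ndarray]]):
        if not segments:
            raise ConfigError("input schedule must contain at least one segment")
        self.segments = [
            (float(t0), float(t1), np.asarray(eta, dtype=np.float64))
            for t0, t1, eta in segments
        ]
        for (a0, a1, _), (b0, _, _) in zip(self.segments, self.segments[1:]):
            if not (a0 < a1 and abs(a1 - b0) < 1e-9):
                raise ConfigError("schedule segments must be contiguous and increasing")

    @classmethod
    def constant(cls, eta: np.ndarray, duration: float = np.inf) -> "InputSchedule":
        return cls([(0.0, duration, eta)])

    @classmethod
    def zero(cls, N: int, duration: float = np.inf) -> "InputSchedule":
        return cls.constant(np.zeros(N), duration)

    @classmethod
    def blocks(
        cls, etas: Iterable[np.ndarray], block_duration: float = 100.0
    ) -> "InputSchedule":
        """Timed presentation: each input applied for ``block_duration`` units."""
        segs = []
        t = 0.0
        for eta in etas:
            segs.append((t, t + block_duration, np.asarray(eta, dtype=np.float64)))
            t += block_duration
        return cls(segs)

    def eta_at(self, t: float) -> np.ndarray:
        for t0, t1, eta in self.segments:
            if t0 <= t < t1:
                return eta
        return self.segments[-1][2]

    def as_arrays(self, duration: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """Segment end indices (in Euler steps) and the stacked eta matrix."""
        n_steps = int(round(duration / dt))
        ends = []
        etas = []
        for t0, t1, eta in self.segments:
            ends.append(min(n_steps, int(round(t1 / dt))) if np.isfinite(t1) else n_steps)
            etas.append(eta)
        ends[-1] = max(ends[-1], n_steps)
        return np.asarray(ends, dtype=np.int64), np.ascontiguousarray(etas)


@dataclass
class Trajectory:
    """Time-sampled (x, y) on a uniform grid, default 20 samples per unit."""

    times: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    sample_rate: float
    dt: float
    schedule: InputSchedule | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.shape != self.Y.shape or len(self.times) != self.X.shape[0]:
            raise ConfigError("times, X and Y must have matching row counts")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ConfigError("times must be strictly increasing")

    @property
    def N(self) -> int:
        return self.X.shape[1]

    def overlaps(self, patterns: np.ndarray) -> np.ndarray:
        """Overlap time series ``m[t, k] = (1/N) sum_i X[t, i] P[k, i]``."""
        P = np.atleast_2d(np.asarray(patterns, dtype=np.float64))
        return self.X @ P.T / self.N

    def state_at(self, t: float) -> NetworkState:
        """Linear interpolation of (x, y) at time ``t``."""
        if not (self.times[0] <= t <= self.times[-1]):
            raise ConfigError(f"t={t} outside trajectory window")
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        if idx >= len(self.times) - 1:
            return NetworkState(self.X[-1].copy(), self.Y[-1].copy(), float(t))
        t0, t1 = self.times[idx], self.times[idx + 1]
        w = (t - t0) / (t1 - t0)
        x = (1 - w) * self.X[idx] + w * self.X[idx + 1]
        y = (1 - w) * self.Y[idx] + w * self.Y[idx + 1]
        return NetworkState(x, y, float(t))

    def window(self, t0: float, t1: float) -> "Trajectory":
        """Sub-trajectory restricted to ``t0 <= t <= t1``."""
        mask = (self.times >= t0) & (self.times <= t1)
        return Trajectory(
            self.times[mask],
            self.X[mask],
            self.Y[mask],
            self.sample_rate,
            self.dt,
            self.schedule,
            dict(self.meta),
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def init_connectivity(params: ModelParams, rng=None) -> Connectivity:
    """Draw the initial connectivity.

    JX entries are iid ``+-(N-1)^(-1/2)`` with probability 1/2 each,
    diagonal zeroed.  JXY entries are ``+-c N^(-1/2)`` with probability
    ``rho`` each and 0 otherwise, fixed thereafter.
    """
    rng = as_generator(rng)
    N = params.N
    JX = (2.0 * rng.integers(0, 2, size=(N, N)) - 1.0) / np.sqrt(N - 1)
    np.fill_diagonal(JX, 0.0)
    draws = rng.random((N, N))
    amp = params.c / np.sqrt(N)
    JXY = np.where(draws < params.rho, amp, np.where(draws >= 1.0 - params.rho, -amp, 0.0))
    return Connectivity(JX, JXY)


def _check_len(v: np.ndarray, N: int, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    if v.shape != (N,):
        raise ConfigError(f"{name} must have length {N}, got shape {v.shape}")
    return v


def compute_local_field(
    state: NetworkState, conn: Connectivity, eta: np.ndarray
) -> LocalField:
    """Total input decomposition I = u + tanh(r) + eta.

    Self-coupling is excluded through the zero diagonal of JX.
    """
    eta = _check_len(eta, conn.N, "eta")
    if state.N != conn.N:
        raise ConfigError("state and connectivity dimensions differ")
    u = conn.JX @ state.x
    r = conn.JXY @ np.tanh(state.y)
    return LocalField(I=u + np.tanh(r) + eta, u=u, r=r)


def step(
    state: NetworkState,
    conn: Connectivity,
    params: ModelParams,
    eta: np.ndarray,
    dt: float = 0.05,
    noise: NoiseConfig | None = None,
    rng=None,
) -> NetworkState:
    """One explicit Euler step of the coupled dynamics (pure reference path).

    The compiled kernels in :mod:`tsnet._kernels` implement the same update
    for long runs; this function is the readable single-step form used for
    construction of tests and small analyses.
    """
    if dt <= 0:
        raise ConfigError("dt must be positive")
    if dt > params.tau_x / 10:
        raise ConfigError(f"dt={dt} too coarse; require dt <= tau_x/10")
    lf = compute_local_field(state, conn, eta)
    x = state.x + dt / params.tau_x * (np.tanh(params.beta_x * lf.I) - state.x)
    y = state.y + dt / params.tau_y * (np.tanh(params.beta_y * state.x) - state.y)
    if noise is not None and noise.sigma > 0:
        x = x + noise.sigma * np.sqrt(dt) * as_generator(rng).standard_normal(state.N)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise FloatingPointError("non-finite state after Euler step")
    return NetworkState(x, y, state.t + dt)


def simulate(
    state: NetworkState,
    conn: Connectivity,
    params: ModelParams,
    schedule: InputSchedule,
    duration: float,
    dt: float = 0.05,
    noise: NoiseConfig | None = None,
    rng=None,
    sample_rate: float = 20.0,
) -> Trajectory:
    """Integrate frozen-connectivity dynamics under a piecewise-constant input.

    Samples are stored at ``sample_rate`` per time unit (default 20) while
    integration proceeds at the finer ``dt``; both rates are recorded in the
    trajectory metadata.  Deterministic for zero noise; with noise, the
    increments are pre-drawn from ``rng`` so the run is reproducible.
    """
    if dt <= 0 or dt > params.tau_x / 10:
        raise ConfigError("dt must satisfy 0 < dt <= tau_x/10")
    n_steps = int(round(duration / dt))
    sample_every = max(1, int(round(1.0 / (dt * sample_rate))))
    seg_ends, etas = schedule.as_arrays(duration, dt)
    n_samples = n_steps // sample_every + 1
    X = np.empty((n_samples, state.N))
    Y = np.empty((n_samples, state.N))
    x = state.x.copy()
    y = state.y.copy()
    X[0] = x
    Y[0] = y
    sigma = noise.sigma if noise is not None else 0.0
    if sigma > 0:
        noise_arr = sigma * np.sqrt(dt) * as_generator(rng).standard_normal(
            (n_steps, state.N)
        )
    else:
        noise_arr = np.empty((0, 0))
    _kernels.run_piecewise(
        conn.JX,
        conn.JXY,
        seg_ends,
        etas,
        x,
        y,
        dt,
        params.tau_x,
        params.tau_y,
        params.beta_x,
        params.beta_y,
        n_steps,
        sample_every,
        noise_arr,
        X,
        Y,
    )
    times = state.t + np.arange(n_samples) * (dt * sample_every)
    meta = {"dt": dt, "sample_rate": 1.0 / (dt * sample_every), "noise_s": sigma}
    return Trajectory(times, X, Y, meta["sample_rate"], dt, schedule, meta)


def overlap(v: np.ndarray, pattern: np.ndarray) -> float:
    """Normalized overlap ``m = (1/N) sum_i v_i xi_i`` in [-1, 1]."""
    v = np.asarray(v, dtype=np.float64)
    pattern = np.asarray(pattern, dtype=np.float64)
    if v.shape != pattern.shape:
        raise ConfigError("overlap arguments must have equal length")
    return float(v @ pattern / v.shape[0])


def overlap_xy(x: np.ndarray, y: np.ndarray) -> float:
    """Overlap between the fast and slow states, ``(1/N) sum_i x_i y_i``."""
    return overlap(x, y)


# ---------------------------------------------------------------------------
# array container I/O
# ---------------------------------------------------------------------------


def save_connectivity(
    path, conn: Connectivity, params: ModelParams | None = None, **attrs
) -> None:
    """Write connectivity (and optional params/seed metadata) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("JX", data=conn.JX)
        f.create_dataset("JXY", data=conn.JXY)
        if params is not None:
            f.attrs["params"] = json.dumps(params.to_dict())
        for k, v in attrs.items():
            f.attrs[k] = v


def load_connectivity(path) -> tuple[Connectivity, ModelParams | None]:
    with h5py.File(path, "r") as f:
        conn = Connectivity(f["JX"][()], f["JXY"][()])
        params = None
        if "params" in f.attrs:
            params = ModelParams.from_dict(json.loads(f.attrs["params"]))
    return conn, params


def save_trajectory(path, traj: Trajectory, **attrs) -> None:
    """Write a sampled trajectory (with dt/sample-rate metadata) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("X", data=traj.X)
        f.create_dataset("Y", data=traj.Y)
        f.attrs["dt"] = traj.dt
        f.attrs["sample_rate"] = traj.sample_rate
        f.attrs["meta"] = json.dumps(traj.meta)
        for k, v in attrs.items():
            f.attrs[k] = v


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        return Trajectory(
            f["times"][()],
            f["X"][()],
            f["Y"][()],
            float(f.attrs["sample_rate"]),
            float(f.attrs["dt"]),
            meta=json.loads(f.attrs["meta"]),
        )
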