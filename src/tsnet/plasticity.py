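"""Local learning rule and the sequence-learning procedure.

Only the fast recurrent matrix changes.  The rule combines a Hebbian term
between the target and the presynaptic activity with an anti-Hebbian
normalizing decay:

    tau_syn dJX_ij/dt = (1/N) (xi_i - x_i) (x_j - u_i JX_ij),   i != j,

so plasticity freezes exactly when x reaches the target.  Patterns of a
sequence are trained one at a time: a learning step presents (xi, eta) until
the fast state matches the target (overlap > 0.85) AND the slow state has
caught up with the fast one (x.y/N > 0.5).  The second, intermediate-valued
criterion is what writes history into y — waiting for full x/y agreement
would store only the present pattern, while no wait at all would store
nothing.  At every pattern change each fast variable is multiplied by an
independent U[0,1] draw (the switch perturbation).  One pass over a
sequence is an epoch; the default schedule repeats 20 epochs.  For tasks
whose input changes within a sequence (the inference task) each pair is
instead presented for a fixed 100 time units.

With K > 1 the sequences are trained in blocks within each epoch (sequence
1 fully, then sequence 2, ...).  The slow state observed at the start of
each sequence's block in the final epoch is stored: it is the initial slow
state from which recall of that sequence starts at its first pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from . import _kernels
from .model import (
    ConfigError,
    Connectivity,
    ModelParams,
    NetworkState,
    as_generator,
    compute_local_field,
)
from .tasks import TaskSpec

__all__ = [
    "LearningCriteria",
    "StepRecord",
    "LearningLog",
    "TrainedNetwork",
    "plasticity_update",
    "apply_switch_perturbation",
    "train_pattern",
    "train_sequences",
    "train_timed",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class LearningCriteria:
    """Termination criteria of one criterion-based learning step.

    ``max_step_time`` caps a step that never meets the criteria (the
    original procedure states no cap; 1000 time units ~ 10 tau_y is far
    beyond observed convergence times).  Non-convergence is recorded, not
    fatal.
    """

    target_overlap: float = 0.85
    xy_overlap: float = 0.5
    max_step_time: float = 1000.0

    def __post_init__(self) -> None:
        if not (0 < self.target_overlap < 1 and 0 < self.xy_overlap < 1):
            raise ConfigError("overlap thresholds must lie strictly in (0, 1)")
        if self.max_step_time <= 0:
            raise ConfigError("max_step_time must be positive")


@dataclass
class StepRecord:
    """Outcome of one learning step (one target presentation)."""

    epoch: int
    seq: int
    mu: int
    label: str
    time_to_criterion: float
    final_mx: float
    final_mxy: float
    converged: bool


@dataclass
class LearningLog:
    """Per-step records accumulated over the whole learning process."""

    records: list[StepRecord] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    @property
    def n_unconverged(self) -> int:
        return sum(not r.converged for r in self.records)

    @property
    def total_time(self) -> float:
        return float(sum(r.time_to_criterion for r in self.records))

    def to_csv(self, path) -> None:
        """One row per learning step."""
        self.to_dataframe().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "n_steps": len(self.records),
            "n_unconverged": self.n_unconverged,
            "total_time": self.total_time,
            "epochs": max((r.epoch for r in self.records), default=-1) + 1,
        }


@dataclass
class TrainedNetwork:
    """A trained connectivity plus everything recall needs.

    ``y_seq_init[alpha]`` is the slow state from which recall of sequence
    ``alpha`` starts at its first pattern (see module docstring); for the
    first sequence it is the very final slow state of learning.
    """

    params: ModelParams
    conn: Connectivity
    task: TaskSpec
    y_final: np.ndarray
    x_final: np.ndarray
    y_seq_init: np.ndarray | None
    log: LearningLog = field(default_factory=LearningLog)


def plasticity_update(
    conn: Connectivity,
    state: NetworkState,
    target: np.ndarray,
    params: ModelParams,
    dt: float,
) -> Connectivity:
    """One Euler step of the learning rule (pure reference path, in place).

    ``JX_ij += (dt / tau_syn) (1/N) (xi_i - x_i)(x_j - u_i JX_ij)`` with the
    diagonal forced back to zero.  The compiled training kernel applies the
    identical update; tests cross-check the two.
    """
    target = np.asarray(target, dtype=np.float64)
    u = compute_local_field(state, conn, np.zeros(conn.N)).u
    e = (target - state.x) * dt / (params.tau_syn * conn.N)
    conn.JX += np.outer(e, state.x) - (e * u)[:, None] * conn.JX
    np.fill_diagonal(conn.JX, 0.0)
    return conn


def apply_switch_perturbation(x: np.ndarray, rng=None) -> np.ndarray:
    """Multiply each fast variable by an independent U[0, 1] draw."""
    rng = as_generator(rng)
    return x * rng.random(x.shape[0])


def train_pattern(
    conn: Connectivity,
    state: NetworkState,
    target: np.ndarray,
    eta: np.ndarray,
    params: ModelParams,
    criteria: LearningCriteria | None = None,
    dt: float = 0.05,
    *,
    epoch: int = 0,
    seq: int = 0,
    mu: int = 0,
    label: str = "",
    present_time: float | None = None,
) -> StepRecord:
    """Run one learning step in place on ``conn``/``state``.

    Criterion mode (default): integrate dynamics plus plasticity until both
    learning criteria hold or ``criteria.max_step_time`` elapses.  Timed
    mode (``present_time`` given): integrate for exactly that long.
    """
    criteria = criteria or LearningCriteria()
    target = np.asarray(target, dtype=np.float64)
    eta = np.asarray(eta, dtype=np.float64)
    timed = present_time is not None
    cap = present_time if timed else criteria.max_step_time
    max_steps = int(round(cap / dt))
    steps, mx, mxy, conv = _kernels.present_pattern(
        conn.JX,
        conn.JXY,
        eta,
        target,
        state.x,
        state.y,
        dt,
        params.tau_x,
        params.tau_y,
        params.tau_syn,
        params.beta_x,
        params.beta_y,
        criteria.target_overlap,
        criteria.xy_overlap,
        max_steps,
        timed,
        True,
    )
    state.t += steps * dt
    return StepRecord(epoch, seq, mu, label, steps * dt, mx, mxy, bool(conv))


def _presentation_order(task: TaskSpec, sequence_order: str):
    """(alpha, mu) presentation order of one epoch."""
    if sequence_order == "blocked":
        return [
            (alpha, mu)
            for alpha, seq in enumerate(task.sequences)
            for mu in range(seq.M)
        ]
    if sequence_order == "alternating":
        max_M = max(seq.M for seq in task.sequences)
        return [
            (alpha, mu)
            for mu in range(max_M)
            for alpha, seq in enumerate(task.sequences)
            if mu < seq.M
        ]
    raise ConfigError(f"unknown sequence order {sequence_order!r}")


def _train(
    conn: Connectivity,
    task: TaskSpec,
    params: ModelParams,
    criteria: LearningCriteria,
    epochs: int,
    dt: float,
    rng,
    x0: np.ndarray | None,
    y0: np.ndarray | None,
    present_time: float | None,
    sequence_order: str = "blocked",
) -> TrainedNetwork:
    rng = as_generator(rng)
    N = params.N
    if conn.N != N or task.N != N:
        raise ConfigError("params, connectivity and task dimensions disagree")
    x = x0.copy() if x0 is not None else rng.uniform(-1, 1, N)
    y = y0.copy() if y0 is not None else np.zeros(N)
    state = NetworkState(x, y)
    log = LearningLog()
    y_seq_init = np.zeros((task.K, N))
    order = _presentation_order(task, sequence_order)
    fresh = x0 is None
    for epoch in range(epochs):
        for alpha, mu in order:
            seq = task.sequences[alpha]
            if epoch == epochs - 1 and mu == 0:
                y_seq_init[alpha] = state.y
            if not fresh:
                state.x = apply_switch_perturbation(state.x, rng)
            fresh = False
            rec = train_pattern(
                conn,
                state,
                task.patterns[seq.labels[mu]],
                task.input_patterns[seq.input_labels[mu]],
                params,
                criteria,
                dt,
                epoch=epoch,
                seq=alpha,
                mu=mu,
                label=seq.labels[mu],
                present_time=present_time,
            )
            log.records.append(rec)
    if epochs > 0:
        y_seq_init[0] = state.y
    return TrainedNetwork(
        params, conn, task, state.y.copy(), state.x.copy(), y_seq_init, log
    )


def train_sequences(
    conn: Connectivity,
    task: TaskSpec,
    params: ModelParams,
    criteria: LearningCriteria | None = None,
    epochs: int = 20,
    dt: float = 0.05,
    rng=None,
    x0: np.ndarray | None = None,
    y0: np.ndarray | None = None,
    sequence_order: str = "blocked",
) -> TrainedNetwork:
    """Train all sequences of a task with the two-criteria procedure.

    Each epoch presents every sequence in block order by default
    (``sequence_order="alternating"`` interleaves the sequences at pattern
    granularity instead); each pattern step terminates on the learning
    criteria (or the cap).  The very first learning step starts from y = 0
    (no stored history) unless ``y0`` is given.  ``rng`` drives the initial
    state and the switch perturbations.
    """
    return _train(
        conn,
        task,
        params,
        criteria or LearningCriteria(),
        epochs,
        dt,
        rng,
        x0,
        y0,
        None,
        sequence_order,
    )


def train_timed(
    conn: Connectivity,
    task: TaskSpec,
    params: ModelParams,
    present_time: float = 100.0,
    epochs: int = 20,
    dt: float = 0.05,
    rng=None,
    x0: np.ndarray | None = None,
    y0: np.ndarray | None = None,
) -> TrainedNetwork:
    """Train with fixed-duration presentations (the inference-task variant).

    Every (target, input) pair is presented for exactly ``present_time``
    units with plasticity on, regardless of the overlap criteria.  Pass the
    final ``x0``/``y0`` of a previous phase to continue training the same
    connectivity on a new curriculum.
    """
    if present_time < 0:
        raise ConfigError("present_time must be >= 0")
    if present_time == 0 or epochs == 0:
        state = NetworkState(
            x0.copy() if x0 is not None else np.zeros(params.N),
            y0.copy() if y0 is not None else np.zeros(params.N),
        )
        return TrainedNetwork(
            params, conn, task, state.y.copy(), state.x.copy(), None
        )
    return _train(
        conn,
        task,
        params,
        LearningCriteria(),
        epochs,
        dt,
        rng,
        x0,
        y0,
        present_time,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_network(path, net: TrainedNetwork, **attrs) -> None:
    """Write a trained network (connectivity, recall states, task) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("JX", data=net.conn.JX)
        f.create_dataset("JXY", data=net.conn.JXY)
        f.create_dataset("y_final", data=net.y_final)
        f.create_dataset("x_final", data=net.x_final)
        if net.y_seq_init is not None:
            f.create_dataset("y_seq_init", data=net.y_seq_init)
        f.attrs["params"] = json.dumps(net.params.to_dict())
        f.attrs["task"] = net.task.to_json()
        for k, v in attrs.items():
            f.attrs[k] = v


def load_network(path) -> TrainedNetwork:
    with h5py.File(path, "r") as f:
        conn = Connectivity(f["JX"][()], f["JXY"][()])
        params = ModelParams.from_dict(json.loads(f.attrs["params"]))
        task = TaskSpec.from_json(f.attrs["task"])
        y_seq_init = f["y_seq_init"][()] if "y_seq_init" in f else None
        return TrainedNetwork(
            params, conn, task, f["y_final"][()], f["x_final"][()], y_seq_init
        )
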