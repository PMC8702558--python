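"""Plasticity-frozen recall, symbolization and success-rate statistics.

During recall the connectivity is fixed.  The fast state starts from a
uniform[-1, 1] draw; the slow state starts from its stored final-learning
value (so the recalled sequence starts at the first target) unless a random
slow start is requested.  Transitions through the sequence then occur
spontaneously, driven by the drift of y.

Continuous trajectories are reduced to symbol sequences by thresholding the
target overlaps at 0.7: the pattern whose overlap is highest and above
threshold is the current symbol, a symbol is emitted once it persists for a
minimum dwell time (1 time unit by default, to suppress transition
flicker), and consecutive duplicates are collapsed.  A recall is successful
when the expected ordered symbol string occurs contiguously in the emitted
string for every sequence of the task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    ConfigError,
    InputSchedule,
    ModelParams,
    NetworkState,
    NoiseConfig,
    Trajectory,
    as_generator,
    init_connectivity,
    simulate,
)
from .plasticity import LearningCriteria, TrainedNetwork, train_sequences
from .tasks import InferenceTask, TaskSpec

__all__ = [
    "RecallConfig",
    "SymbolizeConfig",
    "SuccessRateResult",
    "recall",
    "recall_probe",
    "symbolize",
    "dwell_times",
    "recall_success",
    "success_rate",
    "subsequence_success_rate",
    "paired_signed_rank_test",
    "noise_sweep",
]


@dataclass
class RecallConfig:
    """How a recall run is initialized and integrated."""

    duration: float = 1000.0
    dt: float = 0.05
    x0_policy: str = "uniform"  # "uniform" | "given"
    y0_policy: str = "final"  # "final" | "random"
    noise: NoiseConfig | None = None
    sample_rate: float = 20.0
    block_duration: float = 100.0  # timed probes: input change interval

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("recall duration must be positive")
        if self.y0_policy not in ("final", "random"):
            raise ConfigError(f"unknown y0 policy {self.y0_policy!r}")


@dataclass
class SymbolizeConfig:
    """Overlap threshold (0.7) and the dwell filter for symbol emission."""

    threshold: float = 0.7
    min_dwell: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ConfigError("threshold must lie in (0, 1)")


@dataclass
class RealizationRecord:
    seed: int
    symbols: list[tuple[str, ...]]
    success: bool


@dataclass
class SuccessRateResult:
    """Binomial success proportion over independent realizations."""

    n_realizations: int
    n_success: int
    records: list[RealizationRecord] = field(default_factory=list)
    task_name: str = ""

    @property
    def rate(self) -> float:
        return self.n_success / self.n_realizations

    def ci(self, confidence: float = 0.95) -> tuple[float, float]:
        """Exact (Clopper-Pearson) binomial confidence interval."""
        res = stats.binomtest(self.n_success, self.n_realizations)
        lo, hi = res.proportion_ci(confidence_level=confidence, method="exact")
        return float(lo), float(hi)


def _as_seedseq(rng) -> np.random.SeedSequence:
    if isinstance(rng, np.random.SeedSequence):
        return rng
    if isinstance(rng, np.random.Generator):
        return np.random.SeedSequence(int(rng.integers(2**31)))
    return np.random.SeedSequence(rng)


def _initial_state(net: TrainedNetwork, seq: int, config: RecallConfig, rng):
    rng = as_generator(rng)
    x0 = rng.uniform(-1, 1, net.params.N)
    if config.y0_policy == "random":
        y0 = rng.uniform(-1, 1, net.params.N)
    else:
        if net.y_seq_init is None:
            raise ConfigError(
                "y0_policy='final' requires a network trained with stored slow states"
            )
        y0 = net.y_seq_init[seq].copy()
    return NetworkState(x0, y0)


def recall(
    net: TrainedNetwork,
    seq: int = 0,
    config: RecallConfig | None = None,
    rng=None,
) -> Trajectory:
    """Recall one sequence of the trained task with frozen connectivity.

    The sequence's constant input is held for the whole run (for timed
    tasks use :func:`recall_probe` instead).
    """
    config = config or RecallConfig()
    rng = as_generator(rng)
    state = _initial_state(net, seq, config, rng)
    schedule = InputSchedule.constant(net.task.constant_input(seq))
    return simulate(
        state,
        net.conn,
        net.params,
        schedule,
        config.duration,
        config.dt,
        config.noise,
        rng,
        config.sample_rate,
    )


def recall_probe(
    net: TrainedNetwork,
    input_labels: Sequence[str],
    config: RecallConfig | None = None,
    rng=None,
    extra_inputs: Mapping[str, np.ndarray] | None = None,
) -> Trajectory:
    """Timed recall: the input changes every ``block_duration`` units.

    ``input_labels`` name entries of the task's input dictionary;
    ``extra_inputs`` supplies vectors for labels outside it (the untrained
    probe pattern v).  The slow state starts from the final learning state.
    """
    config = config or RecallConfig()
    rng = as_generator(rng)
    inputs = dict(net.task.input_patterns)
    if extra_inputs:
        inputs.update(extra_inputs)
    try:
        etas = [inputs[l] for l in input_labels]
    except KeyError as e:
        raise ConfigError(f"no input pattern for label {e.args[0]!r}") from None
    schedule = InputSchedule.blocks(etas, config.block_duration)
    duration = config.block_duration * len(etas)
    x0 = rng.uniform(-1, 1, net.params.N)
    y0 = (
        rng.uniform(-1, 1, net.params.N)
        if config.y0_policy == "random"
        else net.y_final.copy()
    )
    return simulate(
        NetworkState(x0, y0),
        net.conn,
        net.params,
        schedule,
        duration,
        config.dt,
        config.noise,
        rng,
        config.sample_rate,
    )


# ---------------------------------------------------------------------------
# symbolization
# ---------------------------------------------------------------------------


def _runs(traj: Trajectory, patterns: Mapping[str, np.ndarray], cfg: SymbolizeConfig):
    """Maximal runs of the per-sample winning symbol: (label, n_samples)."""
    labels = list(patterns)
    m = traj.overlaps(np.array([patterns[l] for l in labels]))
    best = np.argmax(m, axis=1)
    vals = m[np.arange(len(best)), best]
    cur = None
    runs: list[list] = []
    for b, v in zip(best, vals):
        lab = labels[b] if v > cfg.threshold else None
        if runs and lab == cur:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
            cur = lab
    return runs


def symbolize(
    traj: Trajectory,
    patterns: Mapping[str, np.ndarray],
    cfg: SymbolizeConfig | None = None,
) -> list[str]:
    """Reduce a trajectory to its sequence of visited target symbols.

    A symbol is emitted when its overlap is the largest one above the
    threshold for at least ``min_dwell`` time units; consecutive duplicates
    are collapsed.  Returns a list of labels (possibly empty).
    """
    cfg = cfg or SymbolizeConfig()
    dwell_samples = max(1, int(round(cfg.min_dwell * traj.sample_rate)))
    out: list[str] = []
    for lab, n in _runs(traj, patterns, cfg):
        if lab is None or n < dwell_samples:
            continue
        if not out or out[-1] != lab:
            out.append(lab)
    return out


def dwell_times(
    traj: Trajectory,
    patterns: Mapping[str, np.ndarray],
    cfg: SymbolizeConfig | None = None,
) -> list[float]:
    """Durations (time units) of the emitted symbols' above-threshold runs."""
    cfg = cfg or SymbolizeConfig()
    dwell_samples = max(1, int(round(cfg.min_dwell * traj.sample_rate)))
    return [
        n / traj.sample_rate
        for lab, n in _runs(traj, patterns, cfg)
        if lab is not None and n >= dwell_samples
    ]


def recall_success(symbols: Sequence[str], expected: Sequence[str]) -> bool:
    """True iff ``expected`` occurs contiguously and in order in ``symbols``."""
    sym = list(symbols)
    exp = list(expected)
    if not exp:
        return True
    return any(sym[i : i + len(exp)] == exp for i in range(len(sym) - len(exp) + 1))


# ---------------------------------------------------------------------------
# success-rate statistics
# ---------------------------------------------------------------------------


def success_rate(
    task_factory: Callable[[np.random.Generator], TaskSpec],
    params: ModelParams,
    n_realizations: int,
    epochs: int = 20,
    criteria: LearningCriteria | None = None,
    recall_config: RecallConfig | None = None,
    symbolize_config: SymbolizeConfig | None = None,
    dt: float = 0.05,
    rng=None,
    sequence_order: str = "blocked",
) -> SuccessRateResult:
    """Train-and-recall success proportion over independent realizations.

    Each realization draws a fresh connectivity and a fresh task from
    ``task_factory``; it succeeds iff every sequence of the task is
    recalled in correct order under its input.
    """
    if n_realizations < 1:
        raise ConfigError("n_realizations must be >= 1")
    root = _as_seedseq(rng)
    recall_config = recall_config or RecallConfig()
    symbolize_config = symbolize_config or SymbolizeConfig()
    result = SuccessRateResult(n_realizations, 0)
    for i, child in enumerate(root.spawn(n_realizations)):
        r = np.random.default_rng(child)
        task = task_factory(r)
        conn = init_connectivity(params, r)
        net = train_sequences(
            conn, task, params, criteria, epochs, dt, r, sequence_order=sequence_order
        )
        symbols = []
        ok = True
        for alpha in range(task.K):
            traj = recall(net, alpha, recall_config, r)
            sym = symbolize(traj, task.patterns, symbolize_config)
            symbols.append(tuple(sym))
            ok &= recall_success(sym, task.expected(alpha))
        result.n_success += ok
        result.records.append(RealizationRecord(i, symbols, ok))
        result.task_name = task.name
    return result


def subsequence_success_rate(
    net: TrainedNetwork,
    task: InferenceTask,
    n_initial_states: int = 20,
    config: RecallConfig | None = None,
    symbolize_config: SymbolizeConfig | None = None,
    rng=None,
) -> dict[str, float]:
    """Fraction of probe runs that generate the (B, C) sub-sequence under b.

    For each probe input sequence, ``n_initial_states`` recalls are run from
    fresh fast initial states; a run counts as a success when the symbol
    string restricted to the window where input b is applied contains the
    scored sub-sequence.  The probe pattern v is redrawn for every run.
    """
    config = config or RecallConfig()
    symbolize_config = symbolize_config or SymbolizeConfig()
    rng = as_generator(rng)
    rates: dict[str, float] = {}
    for name, labels in task.probes.items():
        b_blocks = [i for i, l in enumerate(labels) if l == "b"]
        n_ok = 0
        for _ in range(n_initial_states):
            extra = {}
            if "v" in labels:
                extra["v"] = 2.0 * rng.integers(0, 2, size=task.N) - 1.0
            traj = recall_probe(net, labels, config, rng, extra)
            t0 = b_blocks[0] * config.block_duration
            t1 = (b_blocks[-1] + 1) * config.block_duration
            sym = symbolize(traj.window(t0, t1), task.patterns, symbolize_config)
            n_ok += recall_success(sym, task.subsequence)
        rates[name] = n_ok / n_initial_states
    return rates


def paired_signed_rank_test(rates_a, rates_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired success rates.

    One pair per network realization.  When every pair is tied the test is
    degenerate (no evidence of a difference); p = 1 is returned with a
    warning.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigError("paired samples must have equal length")
    if np.all(a == b):
        warnings.warn("all paired differences are zero; signed-rank test degenerate")
        return 1.0
    return float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)


def noise_sweep(
    net: TrainedNetwork,
    strengths: Sequence[float],
    n_trials: int = 20,
    seq: int = 0,
    config: RecallConfig | None = None,
    symbolize_config: SymbolizeConfig | None = None,
    rng=None,
) -> pd.DataFrame:
    """Recall performance and mean dwell time versus noise strength.

    Runs ``n_trials`` recalls of one trained sequence at each additive
    noise strength s; identical initial-state seeds are used across
    strengths so s = 0 reproduces the noiseless baseline exactly.
    """
    config = config or RecallConfig()
    symbolize_config = symbolize_config or SymbolizeConfig()
    root = _as_seedseq(rng)
    trial_seeds = root.spawn(n_trials)
    expected = list(net.task.expected(seq))
    rows = []
    for s in strengths:
        n_ok = 0
        dwells: list[float] = []
        for child in trial_seeds:
            r = np.random.default_rng(child)
            cfg = RecallConfig(
                duration=config.duration,
                dt=config.dt,
                y0_policy=config.y0_policy,
                noise=NoiseConfig(s=float(s)),
                sample_rate=config.sample_rate,
            )
            traj = recall(net, seq, cfg, r)
            sym = symbolize(traj, net.task.patterns, symbolize_config)
            n_ok += recall_success(sym, expected)
            dwells.extend(dwell_times(traj, net.task.patterns, symbolize_config))
        rows.append(
            {
                "s": float(s),
                "n_trials": n_trials,
                "n_success": n_ok,
                "rate": n_ok / n_trials,
                "mean_dwell": float(np.mean(dwells)) if dwells else np.nan,
            }
        )
    return pd.DataFrame(rows)
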