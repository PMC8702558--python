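"""Configuration-driven experiment families.

Each ``run_*`` function reproduces one experiment family end to end —
generate tasks, train networks, recall, score — from an
:class:`ExperimentConfig` alone, and optionally writes ``config.json``,
``results.csv`` and ``summary.json`` into an output directory.  Every run
is reproducible from the config plus its master seed; per-realization
seeds are spawned deterministically from the master, so any single row can
be replayed in isolation.

Realization counts default to 50 (as in the success-rate figures); the
``quick`` flag scales them to desk size and binomial confidence intervals
are always reported so scaled runs stay interpretable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bifurcation import (
    bifurcation_table,
    coexistence_windows,
    find_fixed_points,
    pca_fit,
    sample_slow_states,
)
from .model import ConfigError, ModelParams, init_connectivity
from .plasticity import TrainedNetwork, train_sequences, train_timed
from .recall import (
    RecallConfig,
    SymbolizeConfig,
    paired_signed_rank_test,
    recall,
    subsequence_success_rate,
    success_rate,
    symbolize,
)
from .tasks import (
    make_bidirectional_task,
    make_history_task,
    make_inference_task,
    make_simple_task,
)

__all__ = [
    "ExperimentConfig",
    "run_capacity",
    "run_history",
    "run_inference",
    "run_timescale_sweep",
    "run_bifurcation_report",
]


@dataclass
class ExperimentConfig:
    """Fully serializable description of one experiment run."""

    name: str = "experiment"
    seed: int = 0
    outdir: str | None = None
    quick: bool = False
    params: dict = field(default_factory=dict)  # ModelParams overrides
    task: dict = field(default_factory=dict)  # family, K, M, variant
    n_realizations: int = 50
    epochs: int = 20
    dt: float = 0.05
    recall: dict = field(default_factory=dict)  # RecallConfig overrides
    symbolize: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)  # grids: M, K, tau_y, tau_syn, s, ...

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    @property
    def n(self) -> int:
        return min(self.n_realizations, 10) if self.quick else self.n_realizations

    def model_params(self, **extra) -> ModelParams:
        return ModelParams.from_dict({**self.params, **extra})

    def recall_config(self) -> RecallConfig:
        return RecallConfig(**self.recall)

    def symbolize_config(self) -> SymbolizeConfig:
        return SymbolizeConfig(**self.symbolize)


def _write(cfg: ExperimentConfig, df: pd.DataFrame, summary: dict) -> None:
    if cfg.outdir is None:
        return
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(cfg.to_json())
    df.to_csv(out / "results.csv", index=False)
    summary = {"config_hash": cfg.config_hash, "seed": cfg.seed, **summary}
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))


def _rate_row(res, **keys) -> dict:
    lo, hi = res.ci()
    return {
        **keys,
        "n": res.n_realizations,
        "n_success": res.n_success,
        "rate": res.rate,
        "ci_lo": lo,
        "ci_hi": hi,
    }


def run_capacity(cfg: ExperimentConfig) -> pd.DataFrame:
    """Success rate over a (K, M) grid of simple sequence tasks."""
    params = cfg.model_params()
    Ks = cfg.sweep.get("K", [1])
    Ms = cfg.sweep.get("M", [3])
    root = np.random.SeedSequence(cfg.seed)
    rows = []
    for K in Ks:
        for M in Ms:
            res = success_rate(
                lambda r, K=K, M=M: make_simple_task(params.N, K, M, r),
                params,
                cfg.n,
                cfg.epochs,
                recall_config=cfg.recall_config(),
                symbolize_config=cfg.symbolize_config(),
                dt=cfg.dt,
                rng=root.spawn(1)[0],
            )
            rows.append(_rate_row(res, K=K, M=M))
    df = pd.DataFrame(rows)
    _write(cfg, df, {"experiment": "capacity"})
    return df


def run_history(cfg: ExperimentConfig) -> pd.DataFrame:
    """Success rates of the history-dependent task families.

    Covers repeat-middle (rate vs. number of preceding patterns stored,
    M/2 - 1), alternating-return (rate vs. number of slow states to
    discriminate, M/2) and the bidirectional forward/reverse pair.
    """
    params = cfg.model_params()
    grids = {
        "repeat-middle": cfg.sweep.get("repeat_middle_M", [6, 8, 10]),
        "alternating-return": cfg.sweep.get("alternating_M", [6, 8, 10]),
        "bidirectional": cfg.sweep.get("bidirectional_M", [3, 4]),
    }
    root = np.random.SeedSequence(cfg.seed)
    rows = []
    for family, Ms in grids.items():
        for M in Ms:
            if family == "bidirectional":
                factory = lambda r, M=M: make_bidirectional_task(params.N, M, r)
                depth = M
            else:
                factory = lambda r, M=M, f=family: make_history_task(params.N, f, M, r)
                depth = M // 2 - 1 if family == "repeat-middle" else M // 2
            res = success_rate(
                factory,
                params,
                cfg.n,
                cfg.epochs,
                recall_config=cfg.recall_config(),
                symbolize_config=cfg.symbolize_config(),
                dt=cfg.dt,
                rng=root.spawn(1)[0],
            )
            rows.append(_rate_row(res, family=family, M=M, history_depth=depth))
    df = pd.DataFrame(rows)
    _write(cfg, df, {"experiment": "history"})
    return df


def train_inference_phase1(
    params: ModelParams, rng, epochs: int = 20, dt: float = 0.05
):
    """Fresh network + inference task, trained on the phase-1 curriculum."""
    task = make_inference_task(params.N, rng)
    conn = init_connectivity(params, rng)
    net = train_timed(conn, task.phase1, params, 100.0, epochs, dt, rng)
    return net, task


def run_inference(cfg: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-phase inference experiment with the sub-sequence statistic.

    For each network realization: train phase 1 (20 timed epochs), then
    train the phase-2 sequence one epoch at a time, probing the (B, C)
    generation rate under the three probe input families after each epoch.
    Returns the per-(net, epoch, probe) rates and the per-epoch paired
    signed-rank p-values (a' probe vs. v probe across networks).
    """
    params = cfg.model_params()
    n_nets = cfg.n
    phase2_epochs = cfg.sweep.get("phase2_epochs", 3 if cfg.quick else 10)
    n_init = cfg.sweep.get("n_initial_states", 20)
    root = np.random.SeedSequence(cfg.seed)
    rows = []
    for i, child in enumerate(root.spawn(n_nets)):
        r = np.random.default_rng(child)
        net, task = train_inference_phase1(params, r, cfg.epochs, cfg.dt)
        for epoch in range(phase2_epochs + 1):
            if epoch > 0:
                net = train_timed(
                    net.conn,
                    task.phase2,
                    params,
                    100.0,
                    1,
                    cfg.dt,
                    r,
                    x0=net.x_final,
                    y0=net.y_final,
                )
            rates = subsequence_success_rate(
                net, task, n_init, cfg.recall_config(), cfg.symbolize_config(), r
            )
            for probe, rate in rates.items():
                rows.append({"net": i, "epoch": epoch, "probe": probe, "rate": rate})
    df = pd.DataFrame(rows)
    pv_rows = []
    for epoch, g in df.groupby("epoch"):
        wide = g.pivot(index="net", columns="probe", values="rate")
        pv_rows.append(
            {
                "epoch": epoch,
                "p_aprime_vs_v": paired_signed_rank_test(wide["aprime"], wide["v"]),
                "p_a_vs_v": paired_signed_rank_test(wide["a"], wide["v"]),
            }
        )
    pvals = pd.DataFrame(pv_rows)
    _write(cfg, df, {"experiment": "inference", "pvalues": pv_rows})
    return df, pvals


def run_timescale_sweep(cfg: ExperimentConfig) -> pd.DataFrame:
    """Success rate over a (tau_y, tau_syn) grid at K=1, M=7.

    Curves for different tau_y overlay when plotted against tau_syn/tau_y
    (except for tau_y close to tau_x), with the optimum near
    tau_syn/tau_y = 1.
    """
    params0 = cfg.model_params()
    tau_ys = cfg.sweep.get("tau_y", [10.0, 100.0])
    ratios = cfg.sweep.get("ratio", [0.1, 0.3, 1.0, 3.0, 10.0])
    K = cfg.task.get("K", 1)
    M = cfg.task.get("M", 7)
    root = np.random.SeedSequence(cfg.seed)
    rows = []
    for tau_y in tau_ys:
        for ratio in ratios:
            params = cfg.model_params(tau_y=tau_y, tau_syn=ratio * tau_y)
            res = success_rate(
                lambda r: make_simple_task(params0.N, K, M, r),
                params,
                cfg.n,
                cfg.epochs,
                recall_config=cfg.recall_config(),
                symbolize_config=cfg.symbolize_config(),
                dt=cfg.dt,
                rng=root.spawn(1)[0],
            )
            rows.append(
                _rate_row(
                    res,
                    tau_y=tau_y,
                    tau_syn=ratio * tau_y,
                    ratio=ratio,
                    K=K,
                    M=M,
                )
            )
    df = pd.DataFrame(rows)
    _write(cfg, df, {"experiment": "timescale_sweep"})
    return df


def run_bifurcation_report(
    cfg: ExperimentConfig, net: TrainedNetwork | None = None
) -> tuple[pd.DataFrame, dict, TrainedNetwork]:
    """Quenched-y bifurcation diagram of a (freshly trained) network.

    Trains a K=1, M=3 network unless one is supplied, recalls it, samples
    the slow variables along the recall trajectory, enumerates the fast
    fixed points at each sample and reports the coexistence windows of
    consecutive targets.  A network whose recall failed still produces a
    diagram (that is the interesting case for the failure modes).
    """
    params = cfg.model_params()
    root = np.random.SeedSequence(cfg.seed)
    r = np.random.default_rng(root)
    K = cfg.task.get("K", 1)
    M = cfg.task.get("M", 3)
    if net is None:
        task = make_simple_task(params.N, K, M, r)
        conn = init_connectivity(params, r)
        net = train_sequences(conn, task, params, epochs=cfg.epochs, dt=cfg.dt, rng=r)
    rc = cfg.recall_config()
    traj = recall(net, 0, rc, r)
    sym = symbolize(traj, net.task.patterns, cfg.symbolize_config())
    samples = sample_slow_states(
        traj,
        cfg.sweep.get("t_start", 200.0),
        cfg.sweep.get("t_end", 500.0),
        cfg.sweep.get("interval", 5.0),
    )
    targets = {l: net.task.patterns[l] for l in net.task.expected(0)}
    fps_list = [
        find_fixed_points(net.conn, params, s, targets, rng=r) for s in samples
    ]
    windows = coexistence_windows(fps_list, net.task.expected(0))
    basis = pca_fit(traj)
    table = bifurcation_table(fps_list, basis)
    summary = {
        "experiment": "bifurcation",
        "recall_symbols": sym,
        "windows": {"->".join(k): v for k, v in windows.items()},
    }
    _write(cfg, table, summary)
    return table, windows, net
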