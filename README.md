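# tsnet — slow–fast recurrent network for history-dependent sequence memory

`tsnet` is a simulator and analysis toolkit for a two-population rate
network that learns and spontaneously recalls sequences of random binary
activity patterns — including *non-Markov* sequences, in which the correct
successor of a pattern depends on patterns further back than its immediate
predecessor, and sequence *concatenation* (inferring an unseen continuation
from previously learned pieces).  It is aimed at computational
neuroscientists studying metastable sequential dynamics, multiple-timescale
interactions between cortical areas, and biologically plausible (local)
learning rules.

## Model

Two populations of N = 100 rate units are coupled:

```
τ_x dx_i/dt = tanh(β_x I_i) − x_i            (fast population X)
τ_y dy_i/dt = tanh(β_y x_i) − y_i            (slow population Y)
I_i = Σ_{j≠i} J^X_ij x_j + tanh(r_i) + η_i,  r_i = Σ_j J^XY_ij tanh(y_j)
```

with τ_x = 1, τ_y = 100, β_x = 2, β_y = 20.  X receives a binary input
pattern η and recurrent drive through the plastic matrix J^X; Y low-pass
filters X (storing the recent history) and feeds it back through a fixed
sparse random matrix J^XY (connection probability ρ = 0.05 per sign,
amplitude ±c/√N with c = 7).  Only J^X learns, by a local
Hebbian/anti-Hebbian rule with learning timescale τ_syn = 100:

```
τ_syn dJ^X_ij/dt = (1/N) (ξ_i − x_i)(x_j − u_i J^X_ij)
```

where ξ is the current ±1 target pattern and u_i the recurrent input.
Training presents the targets of a sequence one at a time, each until the
fast state matches the target (overlap m = x·ξ/N > 0.85) *and* the slow
state has caught up (x·y/N > 0.5) — the intermediate second criterion is
what writes usable history into Y — with a random U[0,1] shrink of every
x_i at each pattern switch; 20 passes (epochs) over the task complete
learning.  During recall the connectivity is frozen and the transitions
between the stored patterns occur autonomously: the slowly drifting y acts
as a bifurcation parameter that stabilizes the next target before the
current one loses stability.  The package exposes this mechanism directly
(`tsnet.bifurcation`): freeze y at samples along the recall trajectory,
enumerate the attractors of the fast subsystem, and report the
coexistence windows of consecutive targets.

## Worked example

```python
import numpy as np, tsnet

params = tsnet.ModelParams()                      # N=100, τ_x=1, τ_y=100, ...
rng    = np.random.default_rng(3)
task   = tsnet.make_simple_task(params.N, K=1, M=3, rng=rng)
conn   = tsnet.init_connectivity(params, rng)
net    = tsnet.train_sequences(conn, task, params, rng=rng)

traj = tsnet.recall(net, 0, tsnet.RecallConfig(duration=1000.0), rng)
print("".join(tsnet.symbolize(traj, task.patterns)))
print(tsnet.recall_success(tsnet.symbolize(traj, task.patterns), task.expected(0)))
```

prints

```
ABCABCABCABCAB
True
```

— the three learned patterns are visited cyclically, in order, with no
external switching (each symbol is emitted when the overlap of x with that
target exceeds 0.7 for at least one time unit).  Success-rate sweeps over
task families are one call each, e.g.

```python
res = tsnet.success_rate(lambda r: tsnet.make_simple_task(100, 1, 3, r),
                         params, n_realizations=10, rng=0)
print(res.rate, res.ci())        # 1.0 (0.6915028921812371, 1.0)
```

A command-line layer wraps the experiment families:

```
tsnet capacity  --seed 0 --out runs/capacity --quick
tsnet history   --seed 0 --out runs/history --quick
tsnet inference --seed 0 --out runs/inference --quick
tsnet sweep     --seed 0 --out runs/sweep --quick
tsnet bifurcate --seed 0 --out runs/bifurcation
tsnet train --k 1 --m 3 --seed 0 --out net.h5 && tsnet recall --net net.h5
```

Every run writes `config.json`, `results.csv` and `summary.json` and is
fully reproducible from the config plus its master seed.

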