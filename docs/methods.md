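# Methods

This note documents the model, the procedures, the measurement protocols
and the numerical choices behind `tsnet`, including the places where the
design was genuinely open and what the package decided.

## Model and assumptions

The network consists of two N-unit rate populations.  The fast population
X (time constant `tau_x = 1`) is the pattern-generating substrate; the
slow population Y (`tau_y = 100`) is a leaky copy of X that stores the
recent activity history and feeds it back through a fixed sparse random
matrix `JXY` (each entry is ±c/√N with probability ρ per sign, zero
otherwise; ρ = 0.05, c = 7).  The feedback passes through two tanh
nonlinearities — once per slow unit, once at the aggregated branch —
modeling nonlinear dendritic integration of top-down input; the external
input η enters X additively.  The fast recurrent matrix `JX` starts from
iid binary values ±(N−1)^(−1/2) with zero diagonal, and is the only
plastic structure.

Intuition for the division of labor: with the slow feedback frozen, the
fast subsystem is an autonomous attractor network whose fixed points are
set jointly by `JX`, the input, and the frozen feedback.  Because y moves
two orders of magnitude more slowly than x, it acts as a quasi-static
bifurcation parameter: learning shapes `JX` so that, as y drifts toward
the currently expressed pattern, the attractor of the *next* target
appears while the current one still exists, and only then does the
current one destabilize.  That ordering — stabilize the successor, then
release the present — is what makes the recalled sequence robust, and is
directly observable with the tools in `tsnet.bifurcation`.

## Learning procedure

One learning step presents a (target ξ, input η) pair with the local rule

    tau_syn dJX_ij/dt = (1/N)(ξ_i − x_i)(x_j − u_i JX_ij),  i ≠ j,

until the two criteria hold: overlap(x, ξ) > 0.85 and x·y/N > 0.5.  The
x-criterion says the pattern is expressed; the y-criterion says the slow
population has absorbed enough of it to key the next transition.  The 0.5
value must be intermediate: near 1, y would store only the present
pattern; near 0, nothing.  At each pattern switch every fast variable is
multiplied by an independent U[0,1] draw, which knocks the state off the
old attractor without erasing it.  A sequence is presented in order
(pattern 1 … M), one pass per epoch, for 20 epochs.  With K > 1 the
sequences are trained in blocks within each epoch (sequence 1 fully, then
sequence 2, …); interleaving the sequences at pattern granularity was
implemented as an option and degrades performance badly (a K=2, M=3 task
falls from ≈0.8 to ≈0 success), so blocked order is the default.

Two bookkeeping decisions matter for recall:

* **Initial slow state of recall.**  Recall of sequence α starts from the
  slow state recorded at the start of α's training block in the final
  epoch (for the first sequence, the very final slow state — the two are
  equivalent because training wraps around).  With a single shared final
  slow state, sequences other than the last start mid-history and recall
  of the second sequence fails almost always; the per-sequence state
  restores it (validated: K=2, M=3 goes from 1/10 to 10/10 on the same
  nets).
* **Step cap.**  A criterion step that has not converged after 1000 time
  units (≈10 tau_y; convergence normally takes well under 300) is
  abandoned and logged, never fatal.

For tasks whose input changes within a sequence (the inference task) the
criteria are replaced by fixed 100-time-unit presentations, and recall
likewise switches inputs every 100 units regardless of the state.

## Task generator

All patterns are iid fair-coin ±1 vectors; the generator resamples only
exact duplicates (|overlap| = 1), leaving the natural O(N^(−1/2)) random
correlations intact.  Reused symbols within history-dependent sequences
alias the identical vector.  Families: simple (K sequences × M distinct
targets, one constant input each); repeat-middle history sequences
(A,B,C,D,B,E and longer — an aliased run whose successor is ambiguous
without M/2−1 patterns of history); alternating-return (A,B,A,C,A,D — the
slow state must discriminate M/2 returns to A); bidirectional (same
targets forward under one input, reversed under another); and the
two-phase inference task (S,A,B,C under s,a,b,b plus distractor D under
b; then S,A′,B under s,a′,b) with probe input families (s,a,b,b),
(s,a′,b,b) and (s,v,b,b), v drawn fresh for every probe run and never
trained.

What the generator emulates is exactly the stated study conditions —
random unstructured patterns at N=100.  It does not emulate correlated or
sparse neural representations, so passing results say nothing about
structured pattern ensembles.

## Recall scoring

A trajectory is reduced to symbols by the overlap threshold 0.7: the
pattern with the highest overlap above threshold is the current symbol; a
symbol is emitted after persisting for 1 time unit (the dwell filter —
the threshold is from the original protocol, the dwell filter is this
package's anti-flicker choice; typical dwell times are ~75 units, so the
filter is far from the signal); consecutive duplicates collapse.  A
recall succeeds when the expected ordered string occurs contiguously in
the emitted string for every sequence of the task (cyclic recall makes
repeated traversals common, so any contiguous occurrence counts).
Success rates over independent (network, pattern-set) realizations are
binomial proportions and are always reported with exact Clopper–Pearson
intervals; at desk-scale realization counts those intervals are the
honest statement of precision.

The inference statistic scores, for each probe input family, the fraction
of 20 fresh-initial-state runs whose symbol string *within the b-input
window* (the final two 100-unit blocks) contains the sub-sequence (B, C);
paired comparisons across probe families use the two-sided Wilcoxon
signed-rank test (`scipy.stats.wilcoxon`), one pair per network
realization, with an all-ties degenerate case reported as p = 1 with a
warning.

## Quenched-slow-variable analysis

Along a recall trajectory, y is sampled every 5 units (default window
t ∈ [200, 500], 61 samples).  For each sample the fast subsystem (y
frozen ⇒ the feedback tanh(r) is a constant drive) is integrated from 3
near-target starts per target (0.9·ξ + 0.1·uniform[−1,1]; the "vicinity"
radius is this package's quantification of an unquantified notion) plus
12 uniform random starts.  Endpoints qualify as fixed points when
max|dx/dt| < 1e−6 sustained for 10 units after a 200-unit transient
(runs that keep oscillating are counted and excluded), are clustered with
a 0.05 max-norm merge radius, and a basin is "large" iff at least one
random start reached it (the converging fraction is also reported so
users can re-threshold).  A fixed point is labeled with a target when its
overlap exceeds 0.7 — deliberately the symbolization threshold, so that
"this attractor is target X" and "the trajectory is at target X" mean the
same thing; target-pinned attractors typically overlap their target by
0.75–0.95, and a 0.85 match cut misclassifies a substantial fraction of
them as unmatched.

Coexistence windows are reported per consecutive target pair (cyclically
closed): the span of sample times at which both are attractors.  On
successfully and persistently cycling default networks every pair has a
nonempty window.  Two failure regimes are diagnostic: with learning much
faster than the slow dynamics (τ_syn = 10, τ_y = 100) failing networks
skip targets during recall and the skipped transition has no coexistence
window; with learning much slower (τ_syn = 1000) only the most recently
learned target survives — recall emits at most that target, and the
end-of-learning quenched analysis finds a single large-basin attractor
nearest to it (in this implementation that surviving attractor is weak,
overlapping the latest target by only ≈0.5 rather than standing at it).

PCA for trajectory projection is fitted on the sampled fast states only
(`sklearn.decomposition.PCA`); slow states are projected in the same
basis.

## Numerical choices

* **Integrator:** explicit Euler, default dt = 0.05 = τ_x/20
  (configurable; dt > τ_x/10 is rejected).  The test suite asserts the
  first-order convergence of the scheme (halving dt reduces endpoint
  error monotonically) rather than assuming it.
* **Noise:** additive Gaussian on the fast variables only,
  x += s·√dt·𝒩(0,1) per component per step — the standard Wiener scaling;
  whether the original robustness runs also perturbed y is unknown, so
  the entry point is documented here and kept in one place
  (`NoiseConfig`) for easy switching.
* **Plasticity discretization:** the rule is integrated with the same
  Euler dt as the neural dynamics, synchronously from the pre-step state;
  the JX diagonal is re-zeroed after every update.
* **RNG policy:** a single master seed is split into named
  `SeedSequence` streams (connectivity, patterns, initial states, switch
  perturbations, noise); experiment drivers spawn one child per
  realization, so any row of any results table can be replayed alone.
  Noise increments are pre-drawn outside the compiled kernels, which are
  themselves deterministic.
* **Compiled kernels:** the three inner loops (pattern presentation with
  plasticity, frozen-connectivity simulation, frozen-y relaxation) are
  numba kernels; pure-python reference implementations of the single-step
  dynamics and the plasticity update remain the documented surface and
  are cross-checked against the kernels in the tests.

## Measurement protocols and problem sizes

Success-rate experiments default to 50 realizations (with exact binomial
CIs); the always-on test suite and the acceptance script use desk-scale
counts chosen for CI interpretability: 25–50 realizations for the simple
and alternating families, 40 for K=2, 15 for the bidirectional family, 5
for the inference overlaps, and 5 networks × 20 trials per level for the
noise sweep.

Protocol details worth flagging:

* **Inference learning overlaps** are read from the learning log: for
  each of S, A, B, C, the overlap reached at the end of that target's
  presentation in the final phase-1 epoch, averaged over realizations
  (the reported value is the minimum across the four targets).  They sit
  at 0.94–0.98.  The *autonomous recall* peaks are a different, harsher
  quantity: in roughly a third of realizations the trained distractor
  association (b → D) wins the b-block competition and suppresses the
  (B, C) continuation in that run.
* **Noise robustness** is a property of the typical trained network:
  about 4 in 5 networks recall identically up to s = 0.3 (usually 0.5),
  while a minority train to fragile cycles that degrade earlier; the
  tests assert the majority behavior and the acceptance script reports
  the median over 5 networks.
* **Bidirectional tasks** are the hardest family here: measured success
  is 0–5% at M=3–4, lower than the low-teens one might expect; within
  desk-scale binomial error of that expectation, but plausibly also
  reflecting a residual protocol difference (the blocked interleaving and
  the per-sequence recall initialization are this package's explicit
  choices where no protocol is fixed by the task itself).
* **Inference phase-2 timing:** the (B, C) continuation under a′ probes
  appears after 1–2 phase-2 epochs and the over-stabilization of B (C
  dropping out) sets in around epochs 2–3 — earlier than the ~5 epochs
  one might expect; the qualitative structure (A′ weak throughout, B then
  C evoked, later only B) is the robust content.

## Known limitations

* Rates, not spikes; no conductances, no dendritic biophysics beyond the
  two tanh filters on the feedback path.
* No plasticity on `JXY` or on input weights; no gradient-based training.
* Fixed-point analysis is empirical (integration + clustering), not
  continuation-based; stability is classified by convergence, not by
  Jacobian spectra — adequate for attractors, blind to saddles.
* Capacity statements are for N = 100 fair-coin patterns; no claims about
  scaling in N or about structured pattern ensembles.
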