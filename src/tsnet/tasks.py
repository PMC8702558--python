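"""Task generation: random binary patterns and the sequence-task families.

A task is a set of K ordered sequences of N-dimensional +-1 target patterns
``xi`` together with the +-1 input patterns ``eta`` under which they must be
recalled.  Patterns are fair-coin vectors (``P[+-1] = 1/2``).  Reused
symbols (e.g. the B that occurs twice in a history-dependent sequence) alias
the identical vector, which is what makes those sequences non-Markov: the
correct successor of an aliased pattern depends on targets further back than
the immediate predecessor.

Families
--------
simple
    K independent sequences of M distinct targets, one constant input per
    sequence.
history, variant "repeat-middle"
    (A,B,C,D,B,E)-style sequences of even length M in which a run of
    patterns recurs with a different successor; storing the sequence
    requires M/2 - 1 preceding patterns of history.
history, variant "alternating-return"
    (A,B,A,C,A,D,...)-style sequences that return to A before each new
    pattern; the network must discriminate M/2 slow states.
bidirectional
    The same M targets in forward order under one input and reverse order
    under another.
inference
    The two-phase concatenation task with a distractor, plus its probe
    input sequences.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import ConfigError, as_generator

__all__ = [
    "SequenceSpec",
    "TaskSpec",
    "InferenceTask",
    "make_patterns",
    "make_simple_task",
    "make_history_task",
    "make_bidirectional_task",
    "make_inference_task",
]


@dataclass(frozen=True)
class SequenceSpec:
    """Ordered target labels of one sequence and the input label per step.

    For standard tasks every step carries the same input label; the timed
    inference curriculum changes the input within the sequence.
    """

    labels: tuple[str, ...]
    input_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.input_labels):
            raise ConfigError("labels and input_labels must have equal length")

    @property
    def M(self) -> int:
        return len(self.labels)


@dataclass
class TaskSpec:
    """K sequences over a shared dictionary of labeled +-1 patterns."""

    N: int
    patterns: dict[str, np.ndarray]
    input_patterns: dict[str, np.ndarray]
    sequences: list[SequenceSpec]
    timed: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        for d in (self.patterns, self.input_patterns):
            for k, v in d.items():
                v = np.asarray(v, dtype=np.float64)
                if v.shape != (self.N,):
                    raise ConfigError(f"pattern {k!r} must have length {self.N}")
                d[k] = v
        for seq in self.sequences:
            for lab in seq.labels:
                if lab not in self.patterns:
                    raise ConfigError(f"unknown target label {lab!r}")
            for lab in seq.input_labels:
                if lab not in self.input_patterns:
                    raise ConfigError(f"unknown input label {lab!r}")

    @property
    def K(self) -> int:
        return len(self.sequences)

    def targets(self, alpha: int) -> np.ndarray:
        """(M, N) target matrix of sequence ``alpha``; aliases share vectors."""
        return np.array([self.patterns[l] for l in self.sequences[alpha].labels])

    def inputs(self, alpha: int) -> np.ndarray:
        """(M, N) per-step input matrix of sequence ``alpha``."""
        return np.array(
            [self.input_patterns[l] for l in self.sequences[alpha].input_labels]
        )

    def constant_input(self, alpha: int) -> np.ndarray:
        labs = set(self.sequences[alpha].input_labels)
        if len(labs) != 1:
            raise ConfigError(f"sequence {alpha} does not have a constant input")
        return self.input_patterns[labs.pop()]

    def expected(self, alpha: int) -> tuple[str, ...]:
        """The symbol sequence a correct recall of sequence ``alpha`` must contain."""
        return self.sequences[alpha].labels

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "N": self.N,
                "name": self.name,
                "timed": self.timed,
                "patterns": {k: v.astype(int).tolist() for k, v in self.patterns.items()},
                "input_patterns": {
                    k: v.astype(int).tolist() for k, v in self.input_patterns.items()
                },
                "sequences": [
                    {"labels": list(s.labels), "input_labels": list(s.input_labels)}
                    for s in self.sequences
                ],
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "TaskSpec":
        d = json.loads(s)
        return cls(
            N=d["N"],
            patterns={k: np.asarray(v, float) for k, v in d["patterns"].items()},
            input_patterns={
                k: np.asarray(v, float) for k, v in d["input_patterns"].items()
            },
            sequences=[
                SequenceSpec(tuple(s["labels"]), tuple(s["input_labels"]))
                for s in d["sequences"]
            ],
            timed=d["timed"],
            name=d["name"],
        )


def make_patterns(N: int, count: int, rng=None) -> list[np.ndarray]:
    """Draw ``count`` iid fair-coin +-1 vectors of length N.

    Exact collisions (a pair with |overlap| = 1) are resampled so that
    distinct draws are guaranteed distinct; correlations of random draws
    are otherwise left untouched.
    """
    if count < 1:
        raise ConfigError("count must be >= 1")
    rng = as_generator(rng)
    out: list[np.ndarray] = []
    while len(out) < count:
        v = 2.0 * rng.integers(0, 2, size=N) - 1.0
        if any(abs(float(v @ w)) == N for w in out):
            continue
        out.append(v)
    return out


def _letters(n: int) -> list[str]:
    if n > 26:
        raise ConfigError("at most 26 distinct target symbols supported")
    return list(string.ascii_uppercase[:n])


def make_simple_task(N: int, K: int, M: int, rng=None, name: str = "") -> TaskSpec:
    """K sequences of M distinct random targets, one constant input each."""
    rng = as_generator(rng)
    labels = _letters(K * M)
    pats = dict(zip(labels, make_patterns(N, K * M, rng)))
    input_labels = [f"eta{a + 1}" for a in range(K)]
    inputs = dict(zip(input_labels, make_patterns(N, K, rng)))
    seqs = [
        SequenceSpec(tuple(labels[a * M : (a + 1) * M]), (input_labels[a],) * M)
        for a in range(K)
    ]
    return TaskSpec(N, pats, inputs, seqs, name=name or f"simple-K{K}-M{M}")


def _repeat_middle_labels(M: int) -> tuple[str, ...]:
    # M = 2L: prefix of L+1 new symbols, aliased re-run of symbols 2..L-1,
    # then one fresh symbol whose predecessor run is ambiguous.
    L = M // 2
    letters = _letters(L + 2)
    prefix = letters[: L + 1]
    rerun = letters[1 : L - 1]
    return tuple(prefix + rerun + [letters[L + 1]])


def make_history_task(
    N: int, variant: str, M: int, rng=None, name: str = ""
) -> TaskSpec:
    """History-dependent single-sequence tasks with aliased patterns.

    variant "repeat-middle" (M = 6, 8, 10, ...): e.g. M=6 gives
    (A,B,C,D,B,E), M=8 gives (A,B,C,D,E,B,C,F); recalling the step after
    the aliased run requires M/2 - 1 patterns of history.

    variant "alternating-return" (even M >= 4): (A,B,A,C,A,D,...); the
    network must discriminate the M/2 slow states preceding each return.
    """
    rng = as_generator(rng)
    if variant == "repeat-middle":
        if M < 6 or M % 2:
            raise ConfigError("repeat-middle requires even M >= 6")
        labels = _repeat_middle_labels(M)
    elif variant == "alternating-return":
        if M < 4 or M % 2:
            raise ConfigError("alternating-return requires even M >= 4")
        others = _letters(M // 2 + 1)[1:]
        labels = tuple(x for o in others for x in ("A", o))
    else:
        raise ConfigError(f"unknown history variant {variant!r}")
    uniq = sorted(set(labels))
    pats = dict(zip(uniq, make_patterns(N, len(uniq), rng)))
    (eta,) = make_patterns(N, 1, rng)
    seq = SequenceSpec(labels, ("eta1",) * M)
    return TaskSpec(
        N, pats, {"eta1": eta}, [seq], name=name or f"history-{variant}-M{M}"
    )


def make_bidirectional_task(N: int, M: int, rng=None, name: str = "") -> TaskSpec:
    """The same M targets forward under input 1 and reversed under input 2."""
    if M < 3:
        raise ConfigError("bidirectional task requires M >= 3")
    rng = as_generator(rng)
    labels = _letters(M)
    pats = dict(zip(labels, make_patterns(N, M, rng)))
    inputs = dict(zip(("eta1", "eta2"), make_patterns(N, 2, rng)))
    seqs = [
        SequenceSpec(tuple(labels), ("eta1",) * M),
        SequenceSpec(tuple(reversed(labels)), ("eta2",) * M),
    ]
    return TaskSpec(N, pats, inputs, seqs, name=name or f"bidirectional-M{M}")


@dataclass
class InferenceTask:
    """Two-phase concatenation task with a distractor.

    Phase 1 trains (S,A,B,C) under inputs (s,a,b,b) together with the
    one-pattern distractor sequence (D) under b — the distractor prevents a
    trivial b -> (B,C) association.  Phase 2 trains (S,A',B) under
    (s,a',b).  Probes present timed input blocks (s,a,b,b), (s,a',b,b) and
    (s,v,b,b), where v is a fresh random pattern never used in training,
    regenerated per probe run.
    """

    N: int
    patterns: dict[str, np.ndarray]
    input_patterns: dict[str, np.ndarray]
    phase1: TaskSpec
    phase2: TaskSpec
    probes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "a": ("s", "a", "b", "b"),
            "aprime": ("s", "a'", "b", "b"),
            "v": ("s", "v", "b", "b"),
        }
    )

    #: the sub-sequence whose generation during the b blocks is scored
    subsequence: tuple[str, ...] = ("B", "C")


def make_inference_task(N: int, rng=None) -> InferenceTask:
    """Build the inference task (patterns S, A, A', B, C, D; inputs s, a, a', b)."""
    rng = as_generator(rng)
    tlabels = ["S", "A", "A'", "B", "C", "D"]
    pats = dict(zip(tlabels, make_patterns(N, len(tlabels), rng)))
    ilabels = ["s", "a", "a'", "b"]
    inputs = dict(zip(ilabels, make_patterns(N, len(ilabels), rng)))
    phase1 = TaskSpec(
        N,
        pats,
        inputs,
        [
            SequenceSpec(("S", "A", "B", "C"), ("s", "a", "b", "b")),
            SequenceSpec(("D",), ("b",)),
        ],
        timed=True,
        name="inference-phase1",
    )
    phase2 = TaskSpec(
        N,
        pats,
        inputs,
        [SequenceSpec(("S", "A'", "B"), ("s", "a'", "b"))],
        timed=True,
        name="inference-phase2",
    )
    return InferenceTask(N, pats, inputs, phase1, phase2)
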