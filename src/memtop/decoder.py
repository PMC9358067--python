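"""Grammar-constrained Viterbi decoding of class probabilities.

The topology grammar has three rules: (1) a signal peptide may only start at
the first residue, (2) signal peptides and transmembrane segments are at
least five residues long, and (3) the inside/outside orientation must flip
across every transmembrane segment.

The rules are compiled into a fixed 27-state machine: the two loop states
``i`` and ``o``, a 5-state signal-peptide chain whose last state repeats, and
for each transmembrane kind x direction (B up, B down, H up, H down) a
5-state minimum-duration chain whose last state repeats.  "up" means
in->out (entered from ``i``, exits to ``o``); "down" is the mirror.  The
signal-peptide tail exits to ``o`` (translocated N-terminus).  There is no
direct ``i`` <-> ``o`` arc, so orientation can only change through a
transmembrane chain.  The machine has no trainable parameters: a path scores
the sum of log probabilities of each visited state's emission class, and
transitions themselves contribute nothing.

Ties are broken deterministically by preferring the lowest state index at
every backtracking step (state order: i, o, S, B up, B down, H up, H down,
low sub-state first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from memtop.io_formats import CLASS_INDEX, LabelSequence, Segment, parse_labels

__all__ = [
    "StateMachine",
    "LabelPath",
    "build_state_machine",
    "viterbi_decode",
    "brute_force_decode",
    "labels_to_segments",
    "segments_to_labels",
]

MIN_DURATION = 5


@dataclass(frozen=True)
class StateMachine:
    """Expanded state graph enforcing the topology grammar."""

    n_states: int
    emission: np.ndarray          # state -> class index in (B, H, S, i, o)
    label_char: tuple[str, ...]   # state -> output label character
    successors: tuple[tuple[int, ...], ...]
    predecessors: tuple[tuple[int, ...], ...]
    start_states: tuple[int, ...]
    end_states: tuple[int, ...]


@dataclass(frozen=True)
class LabelPath:
    """A decoded state path with its induced label string and log score."""

    states: tuple[int, ...]
    labels: LabelSequence
    score: float


def build_state_machine() -> StateMachine:
    """Construct the fixed 27-state decoder graph (see module docstring).

    State layout: 0=i, 1=o, 2..6 = S1..S5, then four minimum-duration chains
    of five sub-states each for B up (7..11), B down (12..16), H up (17..21)
    and H down (22..26).
    """
    # (emission class char, label char, entry loop state, exit loop state)
    chains = [
        ("S", "S", None, 1),   # signal peptide: start-only entry, exits to o
        ("B", "B", 0, 1),      # beta strand in->out
        ("B", "b", 1, 0),      # beta strand out->in
        ("H", "H", 0, 1),      # helix in->out
        ("H", "h", 1, 0),      # helix out->in
    ]
    emission = [CLASS_INDEX["i"], CLASS_INDEX["o"]]
    label_char = ["i", "o"]
    arcs: list[tuple[int, int]] = [(0, 0), (1, 1)]
    start_states = [0, 1]
    end_states = [0, 1]

    next_state = 2
    for emis, char, entry, exit_ in chains:
        first = next_state
        last = first + MIN_DURATION - 1
        for s in range(first, last + 1):
            emission.append(CLASS_INDEX[emis])
            label_char.append(char)
            if s < last:
                arcs.append((s, s + 1))
        arcs.append((last, last))     # repeatable tail beyond the minimum
        arcs.append((last, exit_))
        if entry is not None:
            arcs.append((entry, first))
        # every chain may begin at residue 0 (S by rule 1; TM chains so that
        # N-terminally truncated proteins can start inside the membrane) and
        # may run into the C-terminus once past its minimum duration
        start_states.append(first)
        end_states.append(last)
        next_state = last + 1

    n = next_state
    succ: list[list[int]] = [[] for _ in range(n)]
    pred: list[list[int]] = [[] for _ in range(n)]
    for a, b in arcs:
        succ[a].append(b)
        pred[b].append(a)
    return StateMachine(
        n_states=n,
        emission=np.array(emission),
        label_char=tuple(label_char),
        successors=tuple(tuple(sorted(s)) for s in succ),
        predecessors=tuple(tuple(sorted(p)) for p in pred),
        start_states=tuple(sorted(start_states)),
        end_states=tuple(sorted(end_states)),
    )


def _log_emissions(probs: np.ndarray, sm: StateMachine) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 5:
        raise ValueError(f"expected L x 5 probabilities, got {probs.shape}")
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    return logp[:, sm.emission]  # L x n_states


def viterbi_decode(probs: np.ndarray, sm: StateMachine | None = None) -> LabelPath:
    """Maximum-score grammar-valid path through the class probabilities."""
    if sm is None:
        sm = build_state_machine()
    loge = _log_emissions(probs, sm)
    L = loge.shape[0]
    # dense arc matrix: 0 for an allowed transition, -inf otherwise, so the
    # argmax over predecessors picks the lowest allowed state index on ties
    T = np.full((sm.n_states, sm.n_states), -np.inf)
    for a, succ in enumerate(sm.successors):
        T[a, list(succ)] = 0.0
    delta = np.full((L, sm.n_states), -np.inf)
    back = np.zeros((L, sm.n_states), dtype=np.int64)
    for s in sm.start_states:
        delta[0, s] = loge[0, s]
    for t in range(1, L):
        cand = delta[t - 1][:, None] + T
        back[t] = cand.argmax(axis=0)
        delta[t] = cand[back[t], np.arange(sm.n_states)] + loge[t]
    ends = list(sm.end_states)
    end_vals = delta[L - 1, ends]
    best_end = ends[int(np.argmax(end_vals))]
    states = [best_end]
    for t in range(L - 1, 0, -1):
        states.append(int(back[t, states[-1]]))
    states.reverse()
    labels = "".join(sm.label_char[s] for s in states)
    return LabelPath(tuple(states), parse_labels(labels), float(delta[L - 1, best_end]))


def brute_force_decode(probs: np.ndarray, sm: StateMachine | None = None) -> LabelPath:
    """Exhaustive enumeration oracle for tiny inputs (L <= 10).

    Independent of the dynamic program: walks every grammar-valid state path
    and keeps the maximum score, breaking ties by the reverse-lexicographically
    smallest state tuple (which matches the Viterbi backtrack tie-break).
    """
    if sm is None:
        sm = build_state_machine()
    loge = _log_emissions(probs, sm)
    L = loge.shape[0]
    if L > 10:
        raise ValueError(f"brute force enumeration limited to L <= 10, got {L}")
    end_set = set(sm.end_states)
    best: tuple[float, tuple[int, ...]] | None = None

    def visit(path: list[int], score: float) -> None:
        nonlocal best
        t = len(path)
        if t == L:
            if path[-1] not in end_set:
                return
            key = (score, tuple(reversed(path)))
            if best is None or score > best[0] or (score == best[0] and key[1] < tuple(reversed(best[1]))):
                best = (score, tuple(path))
            return
        for s in sm.successors[path[-1]]:
            path.append(s)
            visit(path, score + loge[t, s])
            path.pop()

    for s in sm.start_states:
        visit([s], loge[0, s])
    assert best is not None, "i/o paths are always valid"
    labels = "".join(sm.label_char[s] for s in best[1])
    return LabelPath(best[1], parse_labels(labels), best[0])


# ---------------------------------------------------------------------------
# label <-> segment conversions

_SEG_KIND = {"B": "TMB", "b": "TMB", "H": "TMH", "h": "TMH", "S": "SP"}
_SEG_DIR = {"B": "in_out", "H": "in_out", "b": "out_in", "h": "out_in", "S": None}


def labels_to_segments(labels: LabelSequence | str) -> list[Segment]:
    """Maximal B/b/H/h/S runs as sorted, non-overlapping segments."""
    if isinstance(labels, str):
        labels = parse_labels(labels)
    s = labels.labels
    segments: list[Segment] = []
    start = 0
    for k in range(1, len(s) + 1):
        if k == len(s) or s[k] != s[start]:
            ch = s[start]
            if ch in _SEG_KIND:
                segments.append(Segment(_SEG_KIND[ch], start, k, _SEG_DIR[ch]))
            start = k
    return segments


def segments_to_labels(segments: list[Segment], L: int, n_term_side: str = "i") -> LabelSequence:
    """Inverse of :func:`labels_to_segments`.

    Loop sides are derived by alternating across TM segments starting from
    ``n_term_side``; a signal peptide forces side ``o`` after it.  Segment
    directions inconsistent with the alternation raise.
    """
    if n_term_side not in ("i", "o"):
        raise ValueError("n_term_side must be 'i' or 'o'")
    chars = {"TMB": {"in_out": "B", "out_in": "b"}, "TMH": {"in_out": "H", "out_in": "h"}}
    out: list[str] = []
    side = n_term_side
    pos = 0
    for seg in segments:
        if seg.start < pos or seg.end > L:
            raise ValueError("segments must be sorted, non-overlapping and within [0, L)")
        if seg.kind == "SP":
            if seg.start != 0:
                raise ValueError("signal peptide must start at the N-terminus")
            out.append("S" * len(seg))
            side = "o"
        else:
            out.append(side * (seg.start - pos))
            expected = "in_out" if side == "i" else "out_in"
            if seg.direction != expected:
                raise ValueError(
                    f"{seg.kind} at [{seg.start},{seg.end}) has direction {seg.direction} "
                    f"but the flanking side is {side!r}"
                )
            out.append(chars[seg.kind][seg.direction] * len(seg))
            side = "o" if side == "i" else "i"
        pos = seg.end
    out.append(side * (L - pos))
    return parse_labels("".join(out))
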