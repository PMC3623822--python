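"""Per-prefix lower bounds on edit cost used to prune inexact search.

Two bounds are computed for a read ``W`` against a reference ``X``:

* the *basic* bound: scan ``W`` left to right keeping the longest window
  that is still an exact substring of ``X`` (checked in O(1) amortised per
  character on the FM-index of the reversed reference); every time the
  window breaks, at least one more edit is unavoidable;
* the *pattern* bound: the same fallback recurrence run concurrently with
  an Aho-Corasick scan over substrings previously mined from training reads
  and known to need exactly two edits against the reference.  A completed
  pattern ends a segment worth two edits, which can only tighten the bound.

Both are valid lower bounds under the D-metric, in which substitutions,
insertions, deletions *and gap extensions* all cost 1.  The search metric
charges gap extensions 0, which is the documented source of occasional
missed gapped alignments when pruning with these bounds.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence as TypingSequence

import numpy as np

from .fm_index import DNA_ALPHABET, FMIndex, Sequence

__all__ = [
    "DArray",
    "FrequentPattern",
    "ACAutomaton",
    "edit_distance_to_reference",
    "calculate_d_basic",
    "mine_frequent_patterns",
    "build_ac_automaton",
    "scan_patterns",
    "calculate_d_dcdc",
    "BYTES_PER_AC_STATE",
]

#: Accounting constant converting an automaton byte budget to a state budget.
BYTES_PER_AC_STATE = 32

FULL_EDIT = "full_edit"
SUBSTITUTION_ONLY = "substitution_only"


@dataclass(frozen=True)
class DArray:
    """Non-decreasing lower bounds, ``values[i]`` bounding prefix ``W[0..i]``."""

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b < a for a, b in zip(self.values, self.values[1:])):
            raise ValueError("D-array values must be non-decreasing")

    def __getitem__(self, i: int) -> int:
        return self.values[i]

    def __len__(self) -> int:
        return len(self.values)

    def digits(self) -> str:
        return "".join(str(v) for v in self.values)


@dataclass(frozen=True)
class FrequentPattern:
    """A mined substring with its recorded minimal edit value (always 2)."""

    f: str
    e_value: int = 2
    frequency: int = 0


def _min_edit_full(w: str, x: str) -> int:
    """Min edits (sub/ins/del = 1) from ``w`` to any substring of ``x``.

    Semi-global DP: the first row is all zeros (a match may start anywhere
    in ``x``) and the answer is the minimum of the last row (it may end
    anywhere).  Vectorised per row; the in-row insertion chain
    ``cur[j] <= cur[j-1] + 1`` is resolved with a min-plus prefix scan.
    """
    nx = len(x)
    xa = np.frombuffer(x.encode(), dtype=np.uint8)
    prev = np.zeros(nx + 1, dtype=np.int64)
    ar = np.arange(nx + 1)
    for i, ch in enumerate(w, start=1):
        mism = (xa != ord(ch)).astype(np.int64)
        cur = np.empty(nx + 1, dtype=np.int64)
        cur[0] = i
        cur[1:] = np.minimum(prev[:-1] + mism, prev[1:] + 1)
        cur = np.minimum(cur, np.minimum.accumulate(cur - ar) + ar)
        prev = cur
    return int(prev.min())


def _min_hamming(w: str, x: str) -> int:
    if len(w) > len(x):
        return len(w)  # no equal-length window exists
    wa = np.frombuffer(w.encode(), dtype=np.uint8)
    xa = np.frombuffer(x.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(xa, len(w))
    return int((windows != wa).sum(axis=1).min())


def edit_distance_to_reference(
    w: str | Sequence, x: str | Sequence, model: str = FULL_EDIT
) -> int:
    """Minimal cost ``e(w)`` of aligning ``w`` exactly onto some substring
    of the reference.

    ``model="full_edit"`` charges substitutions, insertions and deletions 1
    each; ``model="substitution_only"`` counts mismatches over equal-length
    windows only.
    """
    wb = w.bases if isinstance(w, Sequence) else w
    xb = x.bases if isinstance(x, Sequence) else x
    if not wb:
        raise ValueError("w must be nonempty")
    if model == FULL_EDIT:
        return _min_edit_full(wb, xb)
    if model == SUBSTITUTION_ONLY:
        return _min_hamming(wb, xb)
    raise ValueError(f"unknown edit model {model!r}")


def calculate_d_basic(w: str | Sequence, rev_ref_index: FMIndex) -> DArray:
    """Single-mismatch-segmentation lower bound.

    Extending the current window on the right by ``W[i]`` corresponds to a
    backward extension on the index of the reversed reference; when the
    window stops being a reference substring the running bound increments
    and the window restarts after position ``i``.
    """
    wb = w.bases if isinstance(w, Sequence) else w
    if not wb:
        raise ValueError("W must be nonempty")
    iv = rev_ref_index.full_interval()
    z = 0
    values = []
    for ch in wb:
        iv = rev_ref_index.backward_extend(iv, ch)
        if iv.is_empty:
            z += 1
            iv = rev_ref_index.full_interval()
        values.append(z)
    return DArray(tuple(values))


# ---------------------------------------------------------------------------
# Frequent-pattern mining
# ---------------------------------------------------------------------------

_TRAINING_SEPARATOR = "#"


def mine_frequent_patterns(
    training_reads: TypingSequence[Sequence | str],
    ref: Sequence | str,
    byte_budget: int,
    model: str = FULL_EDIT,
    min_freq: int = 10,
    max_len: int = 16,
) -> list[FrequentPattern]:
    """Mine substrings of the training reads that need exactly 2 edits
    against the reference.

    Candidates are enumerated by a depth-first traversal of an FM-index
    built over the training reads (reads joined on a separator so no
    candidate spans two reads), restricted to frequency >= ``min_freq`` and
    length <= ``max_len``.  Qualifying patterns are taken in decreasing
    frequency (ties broken lexicographically) until the Aho-Corasick state
    estimate fills ``byte_budget`` at :data:`BYTES_PER_AC_STATE` bytes per
    state.
    """
    if not training_reads:
        raise ValueError("training read set is empty")
    if byte_budget < 1:
        raise ValueError("byte_budget must be >= 1")
    reads = [r.bases if isinstance(r, Sequence) else r for r in training_reads]
    ref_b = ref.bases if isinstance(ref, Sequence) else ref
    text = _TRAINING_SEPARATOR.join(reads)
    fm = FMIndex(text, alphabet=_TRAINING_SEPARATOR + DNA_ALPHABET)

    candidates: list[tuple[str, int]] = []
    stack = [("", fm.full_interval())]
    while stack:
        s, iv = stack.pop()
        if len(s) >= max_len:
            continue
        for c in DNA_ALPHABET:
            child = fm.backward_extend(iv, c)
            if child.width >= min_freq:
                candidates.append((c + s, child.width))
                stack.append((c + s, child))

    qualifying = [
        (s, freq)
        for s, freq in candidates
        if edit_distance_to_reference(s, ref_b, model) == 2
    ]
    qualifying.sort(key=lambda item: (-item[1], item[0]))

    chosen: list[FrequentPattern] = []
    prefixes: set[str] = set()
    n_states = 1  # root
    for s, freq in qualifying:
        new = {s[:i] for i in range(1, len(s) + 1)} - prefixes
        if (n_states + len(new)) * BYTES_PER_AC_STATE > byte_budget:
            break
        prefixes |= new
        n_states += len(new)
        chosen.append(FrequentPattern(f=s, e_value=2, frequency=freq))
    return chosen


# ---------------------------------------------------------------------------
# Aho-Corasick automaton
# ---------------------------------------------------------------------------


class ACAutomaton:
    """Goto/failure automaton over a pattern set, with reset-on-match scans.

    States are trie nodes of the patterns; a state whose string is itself a
    pattern is a *leaf state*.  Transitions are totalised through failure
    links, so stepping is O(1).  ``match(state)`` reports the longest
    pattern that is a suffix of the state's string (via output links),
    which is the pattern a reset-on-match scan acts upon.
    """

    def __init__(self, patterns: Iterable[FrequentPattern | str]) -> None:
        pats: dict[str, FrequentPattern] = {}
        for p in patterns:
            fp = p if isinstance(p, FrequentPattern) else FrequentPattern(f=p)
            pats.setdefault(fp.f, fp)  # duplicates collapse to one leaf
        self.patterns = [pats[f] for f in sorted(pats)]

        # Trie construction.
        self.goto: list[dict[str, int]] = [{}]
        self.fail: list[int] = [0]
        self.leaf: list[Optional[FrequentPattern]] = [None]
        for fp in self.patterns:
            state = 0
            for c in fp.f:
                nxt = self.goto[state].get(c)
                if nxt is None:
                    nxt = len(self.goto)
                    self.goto.append({})
                    self.fail.append(0)
                    self.leaf.append(None)
                    self.goto[state][c] = nxt
                state = nxt
            self.leaf[state] = fp

        # Failure links breadth-first, then totalised transitions and
        # output links (nearest leaf on the failure chain, self included).
        queue = deque(self.goto[0].values())
        while queue:
            state = queue.popleft()
            for c, child in self.goto[state].items():
                queue.append(child)
                f = self.fail[state]
                while f and c not in self.goto[f]:
                    f = self.fail[f]
                self.fail[child] = self.goto[f].get(c, 0)
                if self.fail[child] == child:
                    self.fail[child] = 0

        self.delta: list[dict[str, int]] = [dict() for _ in self.goto]
        self.out: list[Optional[FrequentPattern]] = [None] * len(self.goto)
        order = deque([0])
        seen = {0}
        while order:
            state = order.popleft()
            if self.leaf[state] is not None:
                self.out[state] = self.leaf[state]
            elif state:
                self.out[state] = self.out[self.fail[state]]
            for c in DNA_ALPHABET:
                if c in self.goto[state]:
                    self.delta[state][c] = self.goto[state][c]
                else:
                    self.delta[state][c] = 0 if state == 0 else self.delta[self.fail[state]][c]
            for child in self.goto[state].values():
                if child not in seen:
                    seen.add(child)
                    order.append(child)

    @property
    def n_states(self) -> int:
        return len(self.goto)

    @property
    def root(self) -> int:
        return 0

    def step(self, state: int, c: str) -> int:
        trans = self.delta[state]
        if c in trans:
            return trans[c]
        return 0  # characters outside the alphabet reset progress

    def match(self, state: int) -> Optional[FrequentPattern]:
        """Longest pattern ending at this state, or None."""
        return self.out[state]

    def scan(self, w: str) -> list[tuple[int, FrequentPattern]]:
        """Reset-on-match scan; see :func:`scan_patterns`."""
        state = 0
        hits = []
        for i, c in enumerate(w):
            state = self.step(state, c)
            fp = self.out[state]
            if fp is not None:
                hits.append((i, fp))
                state = 0
        return hits

    # -- serialization (patterns fully determine the automaton) --------

    def to_dict(self) -> dict:
        return {
            "patterns": [
                {"f": p.f, "e_value": p.e_value, "frequency": p.frequency}
                for p in self.patterns
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ACAutomaton":
        return cls(
            FrequentPattern(f=p["f"], e_value=p["e_value"], frequency=p["frequency"])
            for p in d["patterns"]
        )


def build_ac_automaton(patterns: Iterable[FrequentPattern | str]) -> ACAutomaton:
    """Build the goto/failure automaton for a pattern set (possibly empty)."""
    return ACAutomaton(patterns)


def scan_patterns(
    automaton: ACAutomaton, w: str | Sequence
) -> list[tuple[int, FrequentPattern]]:
    """Single left-to-right pass reporting greedy non-overlapping matches.

    On any match the automaton resets to its root and scanning resumes at
    the next character, so each reported match starts after the end of the
    previous one.
    """
    wb = w.bases if isinstance(w, Sequence) else w
    return automaton.scan(wb)


def calculate_d_dcdc(
    w: str | Sequence,
    rev_ref_index: FMIndex,
    automaton: ACAutomaton,
) -> DArray:
    """Tighter lower bound driven by mined frequent patterns.

    The basic fallback recurrence and the automaton run concurrently from
    the current segment start.  While no pattern has completed, positions
    carry the fallback bound.  When a pattern ``f`` completes at ``i``, the
    bound becomes (bound at the pattern-segment start) + ``e(f)``, both
    trackers restart at ``i + 1``, and the automaton resets.  The result is
    finalised as a running maximum, which preserves monotonicity (a bound
    valid for a prefix is valid for every longer prefix).
    """
    wb = w.bases if isinstance(w, Sequence) else w
    if not wb:
        raise ValueError("W must be nonempty")
    full = rev_ref_index.full_interval()
    iv = full
    z = 0  # fallback running bound (window resets on pattern matches)
    base = 0  # bound at the current pattern-segment start
    state = automaton.root
    basic_iv = full  # independent plain recurrence, never reset by patterns
    basic_z = 0
    values: list[int] = []
    for ch in wb:
        iv = rev_ref_index.backward_extend(iv, ch)
        broke = iv.is_empty
        basic_iv = rev_ref_index.backward_extend(basic_iv, ch)
        if basic_iv.is_empty:
            basic_z += 1
            basic_iv = full
        state = automaton.step(state, ch)
        fp = automaton.match(state)
        if fp is not None:
            d_i = base + fp.e_value
            z = base = d_i
            iv = full
            state = automaton.root
        else:
            if broke:
                z += 1
                iv = full
            d_i = z
        # The plain bound and the pattern bound are each valid, so their
        # pointwise maximum is too; the running maximum keeps monotonicity.
        d_i = max(d_i, basic_z)
        values.append(max(d_i, values[-1]) if values else d_i)
    return DArray(tuple(values))
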