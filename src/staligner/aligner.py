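"""Bounded inexact backward search with lower-bound pruning.

The search walks the read from its last character toward the first,
maintaining an SA interval (through the Suffix Tarray when available, raw
FM extension otherwise) and branching on match, substitution, deletion of a
reference base and insertion of a read base.  A gap open costs one
difference; up to ``max_gap_extensions`` consecutive further deletion
columns cost zero, mirroring the search metric of the original tool.  The
D-array charges those extension columns one each, and this asymmetry --
implemented here exactly as documented -- is the known source of
occasionally missed gapped alignments when pruning is enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Optional, Union

from .fm_index import DNA_ALPHABET, FMIndex, SAInterval, Sequence, revcomp
from .pruning import DArray, calculate_d_basic, calculate_d_dcdc
from .suffix_tarray import SuffixTarray

__all__ = [
    "SearchParams",
    "IntervalHit",
    "AlignmentHit",
    "EditOp",
    "inexact_search",
    "align_read",
    "mapping_quality",
    "replay_script",
]


@dataclass(frozen=True)
class SearchParams:
    """Knobs of the inexact search.

    ``z`` caps total charged differences; ``max_gap_extensions`` caps the
    free deletion columns following a gap open; ``seed_length`` (0 = off)
    restricts the last ``seed_length`` read bases to ``seed_max_diff``
    differences; ``use_dcdc`` selects the pattern-tightened D-array.
    """

    z: int = 4
    max_gap_extensions: int = 3
    seed_length: int = 0
    seed_max_diff: int = 2
    use_dcdc: bool = False
    use_sta: bool = True
    max_nodes: Optional[int] = None

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError("z must be >= 0")
        if self.max_gap_extensions < 0:
            raise ValueError("max_gap_extensions must be >= 0")


class EditOp(NamedTuple):
    """One edit transforming the read into the reference window.

    ``op`` is ``"S"`` (window holds ``base`` where the read differs),
    ``"I"`` (read base ``base`` at index ``i`` absent from the window) or
    ``"D"`` (window holds an extra ``base`` between read indices ``i`` and
    ``i + 1``).
    """

    op: str
    i: int
    base: str


class IntervalHit(NamedTuple):
    interval: SAInterval
    diff: int
    script: tuple[EditOp, ...]


@dataclass(frozen=True)
class AlignmentHit:
    """A located mapping, ready for SAM serialization."""

    read_name: str
    seq: str
    qual: Optional[str]
    mapped: bool
    strand: str = "+"
    pos: int = -1  # 0-based on the concatenated reference
    diff_count: int = 0
    script: tuple[EditOp, ...] = ()
    mapq: int = 0
    n_cooptimal: int = 0


def replay_script(read: str, script: tuple[EditOp, ...]) -> str:
    """Apply an edit script to a read, producing the reference window.

    The script is stored in search (right-to-left) order; consecutive
    deletions recorded at the same read index therefore appear right to
    left and are reversed here.
    """
    subs: dict[int, str] = {}
    ins: set[int] = set()
    dels: dict[int, list[str]] = {}
    for op, i, base in script:
        if op == "S":
            subs[i] = base
        elif op == "I":
            ins.add(i)
        elif op == "D":
            dels.setdefault(i, []).append(base)
        else:  # pragma: no cover
            raise ValueError(f"unknown edit op {op!r}")
    out: list[str] = []
    for i, ch in enumerate(read):
        if i in ins:
            pass
        elif i in subs:
            out.append(subs[i])
        else:
            out.append(ch)
        if i in dels:
            out.extend(reversed(dels[i]))
    return "".join(out)


def _stepper(index: Union[SuffixTarray, FMIndex]):
    """Uniform (start_state, step, interval_of) triple over either index."""
    if isinstance(index, SuffixTarray):
        return index.start_state(), index.step, lambda st: st.interval
    if isinstance(index, FMIndex):
        return index.full_interval(), index.backward_extend, lambda st: st
    raise TypeError(f"cannot search over {type(index).__name__}")


def inexact_search(
    w: str | Sequence,
    index: Union[SuffixTarray, FMIndex],
    d_array: Optional[DArray],
    params: SearchParams,
) -> list[IntervalHit]:
    """All SA intervals of windows matching ``w`` with <= ``z`` differences.

    Depth-first from the end of the read; a branch whose next unresolved
    prefix ``w[0..i]`` satisfies ``z - used < D[i]`` is pruned.  Insertions
    and deletions are only opened strictly inside the read, so alignments
    never begin or end on a gap column.  Hits are deduplicated per interval,
    keeping the lowest difference count.
    """
    wb = w.bases if isinstance(w, Sequence) else w
    m = len(wb)
    if m == 0:
        raise ValueError("cannot search an empty read")
    if d_array is not None and len(d_array) != m:
        raise ValueError("D-array length does not match the read")
    z = params.z
    max_ext = params.max_gap_extensions
    seed_start = m - params.seed_length if params.seed_length > 0 else -1

    start, step, iv_of = _stepper(index)
    hits: dict[tuple[int, int], IntervalHit] = {}
    nodes = 0

    def allowed(i_next: int, used: int, seed_used: int) -> bool:
        if used > z:
            return False
        if seed_start >= 0 and seed_used > params.seed_max_diff:
            return False
        if d_array is not None and i_next >= 0 and z - used < d_array[i_next]:
            return False
        return True

    # Frame: (i, state, used, in_del_run, ext_count, seed_used, script-cons)
    stack = [(m - 1, start, 0, False, 0, 0, None)]
    while stack:
        i, state, used, in_del, ext, seed_used, script = stack.pop()
        nodes += 1
        if params.max_nodes is not None and nodes > params.max_nodes:
            break
        if i < 0:
            iv = iv_of(state)
            key = (iv.k, iv.l)
            prev = hits.get(key)
            if prev is None or used < prev.diff:
                ops = []
                cell = script
                while cell is not None:
                    ops.append(cell[0])
                    cell = cell[1]
                ops.reverse()  # store in search (right-to-left) order
                hits[key] = IntervalHit(iv, used, tuple(ops))
            continue

        ch = wb[i]
        in_seed = i >= seed_start >= 0

        # Insertion: read base absent from the window (interior only).
        if 1 <= i <= m - 2:
            u = used + 1
            s = seed_used + (1 if in_seed else 0)
            if allowed(i - 1, u, s):
                stack.append(
                    (i - 1, state, u, False, 0, s, ((EditOp("I", i, ch)), script))
                )

        # Deletion: window gains a reference base between i and i + 1.
        if 0 <= i <= m - 2:
            if in_del and ext < max_ext:
                cost, next_ext = 0, ext + 1
            else:
                cost, next_ext = 1, 0
            u = used + cost
            s = seed_used + (cost if in_seed else 0)
            if allowed(i, u, s):
                for b in DNA_ALPHABET:
                    nstate = step(state, b)
                    if not iv_of(nstate).is_empty:
                        stack.append(
                            (i, nstate, u, True, next_ext, s, ((EditOp("D", i, b)), script))
                        )

        # Substitutions.
        u = used + 1
        s = seed_used + (1 if in_seed else 0)
        if allowed(i - 1, u, s):
            for b in DNA_ALPHABET:
                if b == ch:
                    continue
                nstate = step(state, b)
                if not iv_of(nstate).is_empty:
                    stack.append(
                        (i - 1, nstate, u, False, 0, s, ((EditOp("S", i, b)), script))
                    )

        # Exact match (pushed last: explored first).
        if allowed(i - 1, used, seed_used):
            nstate = step(state, ch)
            if not iv_of(nstate).is_empty:
                stack.append((i - 1, nstate, used, False, 0, seed_used, script))

    return list(hits.values())


#: Placements closer than this (same strand) count as one locus.
_LOCUS_TOLERANCE = 5
#: Runner-up intervals wider than this are not located individually.
_MAX_LOCATED_RUNNERS = 50


def _count_loci(placements: list[tuple[int, str]]) -> int:
    """Number of distinct loci, merging same-strand positions within
    ``_LOCUS_TOLERANCE`` bases."""
    count = 0
    by_strand: dict[str, list[int]] = {}
    for p, s in placements:
        by_strand.setdefault(s, []).append(p)
    for positions in by_strand.values():
        positions.sort()
        count += 1 + sum(
            1 for a, b in zip(positions, positions[1:]) if b - a > _LOCUS_TOLERANCE
        )
    return count


def mapping_quality(n_best: int, n_second: int) -> int:
    """Documented monotone scheme on the hit-stratum summary.

    A unique best hit with an empty runner-up stratum scores 37; multiple
    co-optimal placements score 0; otherwise the quality decreases with the
    size of the runner-up stratum.  Always within [0, 60].
    """
    if n_best != 1:
        return 0
    if n_second == 0:
        return 37
    return max(0, 25 - 3 * min(n_second, 8))


def _d_for(seq: str, bundle, params: SearchParams) -> DArray:
    if params.use_dcdc and getattr(bundle, "automaton", None) is not None:
        return calculate_d_dcdc(seq, bundle.rev_fm, bundle.automaton)
    return calculate_d_basic(seq, bundle.rev_fm)


def align_read(read: Sequence, bundle, params: SearchParams) -> list[AlignmentHit]:
    """Search both orientations, locate the best stratum and pick a primary.

    The search is run with iteratively increasing difference caps
    ``0..z``; the first cap producing hits is the best stratum ``d`` (the
    hit set for stratum ``d`` is identical to the one a single run at ``z``
    would return).  One further run at ``d + 1`` counts the runner-up
    stratum for the mapping quality.  The primary placement is the
    co-optimal hit with the lowest reference coordinate.
    """
    qual = getattr(read, "qual", None)
    if len(read.bases) < 2:
        return [AlignmentHit(read.name, read.bases, qual, mapped=False)]

    fwd = read.bases
    rev = revcomp(read.bases)
    orientations = [("+", fwd), ("-", rev)]
    d_arrays = {s: _d_for(seq, bundle, params) for s, seq in orientations}
    index: Union[SuffixTarray, FMIndex]
    if params.use_sta and getattr(bundle, "sta", None) is not None:
        index = bundle.sta
    else:
        index = bundle.fm

    best_d: Optional[int] = None
    for d in range(params.z + 1):
        trial = replace(params, z=d)
        found = {
            s: inexact_search(seq, index, d_arrays[s], trial)
            for s, seq in orientations
        }
        if any(found.values()):
            best_d = d
            break
    if best_d is None:
        return [AlignmentHit(read.name, fwd, qual, mapped=False)]

    if best_d < params.z:
        wider = replace(params, z=best_d + 1)
        found = {
            s: inexact_search(seq, index, d_arrays[s], wider)
            for s, seq in orientations
        }

    # Within the best difference stratum, hits with fewer gap columns rank
    # first (a substitution is preferred over an equal-difference indel);
    # only the top sub-stratum counts as co-optimal.  Everything else --
    # same-stratum gapped variants and the runner-up stratum -- competes
    # for the mapping quality, but only when it lands at a genuinely
    # different locus (more than ``_LOCUS_TOLERANCE`` bases away), so
    # alternative gap placements of one alignment do not masquerade as
    # competing hits.
    placements: list[tuple[int, str, int, IntervalHit]] = []
    runner_up: list[tuple[int, str]] = []
    runner_width = 0
    for strand, _seq in orientations:
        for h in found[strand]:
            if h.diff == best_d:
                n_gap = sum(1 for op in h.script if op.op != "S")
                for p in bundle.fm.locate(h.interval):
                    placements.append((p, strand, n_gap, h))
            elif h.diff == best_d + 1:
                runner_width += h.interval.width
                if runner_width <= _MAX_LOCATED_RUNNERS:
                    runner_up.extend(
                        (p, strand) for p in bundle.fm.locate(h.interval)
                    )
    min_gap = min(p[2] for p in placements)
    best_placements = [p for p in placements if p[2] == min_gap]
    pos, strand, _gap, hit = min(best_placements, key=lambda t: (t[0], t[1]))

    n_best = _count_loci([(p, s) for p, s, _, _ in best_placements])
    competitors = runner_up + [
        (p, s) for p, s, g, _ in placements if g > min_gap
    ]
    n_second = len(
        {
            (p, s)
            for p, s in competitors
            if s != strand or abs(p - pos) > _LOCUS_TOLERANCE
        }
    )
    if runner_width > _MAX_LOCATED_RUNNERS:
        n_second = max(n_second, runner_width)
    mapq = mapping_quality(n_best, n_second)
    seq = fwd if strand == "+" else rev
    oriented_qual = qual if (strand == "+" or qual is None) else qual[::-1]
    return [
        AlignmentHit(
            read_name=read.name,
            seq=seq,
            qual=oriented_qual,
            mapped=True,
            strand=strand,
            pos=pos,
            diff_count=hit.diff,
            script=hit.script,
            mapq=mapq,
            n_cooptimal=n_best,
        )
    ]
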