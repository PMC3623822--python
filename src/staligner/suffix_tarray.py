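"""Frequency-truncated trie of cached SA intervals layered on an FM-index.

The trie is built over the *reversed* reference: a root-to-node path spells
the characters of a query in backward-search consumption order, i.e. the
reverse of the matched query suffix.  Each node caches the SA interval (on
the index of the forward reference) of that query suffix, so a backward
search can descend the trie without any Occ computation and fall back to
plain FM extension once it leaves the trie.

A node's frequency is the occurrence count in the reversed reference of the
string its path spells, which equals its interval width.  Nodes whose
frequency falls below a threshold ``epsilon`` are discarded; ``epsilon`` is
chosen as the smallest value whose trie fits a node budget (trie size is
non-increasing in ``epsilon``, so a binary search applies).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

from .fm_index import DNA_ALPHABET, FMIndex, SAInterval, Sequence

__all__ = [
    "TrieNode",
    "SuffixTarray",
    "STAState",
    "SizeExceeded",
    "node_frequency",
    "build_truncated_trie",
    "select_epsilon",
    "sta_backward_step",
    "BYTES_PER_TRIE_NODE",
]

#: On-disk/in-memory accounting constant used to convert a byte budget for
#: the trie into a node budget.
BYTES_PER_TRIE_NODE = 36

DEFAULT_MAX_DEPTH = 12


class SizeExceeded(Exception):
    """Raised when a trie under construction outgrows its node budget."""


class TrieNode:
    """One trie node: per-character children plus a cached SA interval."""

    __slots__ = ("children", "k", "l")

    def __init__(self, k: int, l: int) -> None:
        self.children: dict[str, TrieNode] = {}
        self.k = k
        self.l = l

    @property
    def interval(self) -> SAInterval:
        return SAInterval(self.k, self.l)

    @property
    def frequency(self) -> int:
        return self.l - self.k + 1

    def walk(self) -> Iterator["TrieNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children.values())

    def node_count(self, include_root: bool = False) -> int:
        total = sum(1 for _ in self.walk())
        return total if include_root else total - 1


def node_frequency(xbar: Sequence | str, s: Sequence | str) -> int:
    """Occurrence count (overlaps included) of ``s`` in the reversed reference."""
    hay = xbar.bases if isinstance(xbar, Sequence) else xbar
    needle = s.bases if isinstance(s, Sequence) else s
    if not needle:
        raise ValueError("frequency of the empty string is undefined")
    count = 0
    start = hay.find(needle)
    while start != -1:
        count += 1
        start = hay.find(needle, start + 1)
    return count


def build_truncated_trie(
    fm: FMIndex,
    xbar_fm: Optional[FMIndex],
    epsilon: int,
    node_budget: int,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> TrieNode:
    """Build the trie of all strings with frequency >= ``epsilon``.

    ``fm`` indexes the forward reference; node intervals are obtained by
    backward extension on it, so a child along edge ``c`` of the node for
    path ``s`` holds the interval of ``reverse(s + c)``, whose width is the
    frequency of ``s + c`` in the reversed reference.  ``xbar_fm`` is
    accepted for interface symmetry but not needed for construction.

    Raises :class:`SizeExceeded` as soon as the (root-exclusive) node count
    would pass ``node_budget``.
    """
    if epsilon < 1:
        raise ValueError(f"epsilon must be >= 1, got {epsilon}")
    if node_budget < 0:
        raise ValueError(f"node_budget must be >= 0, got {node_budget}")
    full = fm.full_interval()
    root = TrieNode(full.k, full.l)
    count = 0
    stack: list[tuple[TrieNode, int]] = [(root, 0)]
    while stack:
        node, depth = stack.pop()
        if depth >= max_depth:
            continue
        for c in fm.alphabet:
            if c not in DNA_ALPHABET:  # record separators never enter the trie
                continue
            iv = fm.backward_extend(node.interval, c)
            if iv.width < epsilon:
                continue
            count += 1
            if count > node_budget:
                raise SizeExceeded(
                    f"trie exceeds node budget {node_budget} at epsilon={epsilon}"
                )
            child = TrieNode(iv.k, iv.l)
            node.children[c] = child
            stack.append((child, depth + 1))
    return root


def select_epsilon(
    fm: FMIndex,
    xbar_fm: Optional[FMIndex],
    node_budget: int,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> tuple[int, TrieNode]:
    """Smallest ``epsilon`` whose trie fits ``node_budget``, plus that trie.

    Because trie size is non-increasing in ``epsilon``, feasibility is
    monotone and a binary search over ``[1, n]`` is exact.  ``epsilon = n``
    is always feasible for ``node_budget >= 1`` (at most one child can have
    frequency ``n``); a zero budget degenerates to a bare root.
    """
    if node_budget < 1:
        return fm.n + 1, TrieNode(0, fm.n)

    def attempt(eps: int) -> Optional[TrieNode]:
        try:
            return build_truncated_trie(fm, xbar_fm, eps, node_budget, max_depth)
        except SizeExceeded:
            return None

    lo, hi = 1, max(fm.n, 1)
    best: Optional[TrieNode] = attempt(hi)
    if best is None:  # budget cannot even hold the epsilon=n trie
        return fm.n + 1, TrieNode(0, fm.n)
    best_eps = hi
    while lo < hi:
        mid = (lo + hi) // 2
        trie = attempt(mid)
        if trie is not None:
            best, best_eps, hi = trie, mid, mid
        else:
            lo = mid + 1
    return best_eps, best


@dataclass(frozen=True)
class STAState:
    """Backward-search position: a trie node while resolvable, else FM mode."""

    node: Optional[TrieNode]
    interval: SAInterval

    @property
    def in_trie(self) -> bool:
        return self.node is not None


class SuffixTarray:
    """Truncated trie + FM-index bundle driving backward search."""

    def __init__(
        self,
        fm: FMIndex,
        root: TrieNode,
        epsilon: int,
        max_depth: int = DEFAULT_MAX_DEPTH,
    ) -> None:
        self.fm = fm
        self.root = root
        self.epsilon = epsilon
        self.max_depth = max_depth

    @classmethod
    def build(
        cls,
        fm: FMIndex,
        xbar_fm: Optional[FMIndex] = None,
        node_budget: Optional[int] = None,
        trie_bytes: Optional[int] = None,
        epsilon: Optional[int] = None,
        max_depth: int = DEFAULT_MAX_DEPTH,
    ) -> "SuffixTarray":
        """Build with a fixed ``epsilon`` or auto-select it from a budget.

        ``trie_bytes`` is converted to a node budget at
        :data:`BYTES_PER_TRIE_NODE` bytes per node.
        """
        if node_budget is None:
            if trie_bytes is not None:
                node_budget = trie_bytes // BYTES_PER_TRIE_NODE
            else:
                node_budget = 1 << 30
        if epsilon is not None:
            root = build_truncated_trie(fm, xbar_fm, epsilon, node_budget, max_depth)
            return cls(fm, root, epsilon, max_depth)
        eps, root = select_epsilon(fm, xbar_fm, node_budget, max_depth)
        return cls(fm, root, eps, max_depth)

    def start_state(self) -> STAState:
        return STAState(self.root, self.fm.full_interval())

    def step(self, state: STAState, c: str) -> STAState:
        """One backward-search step; see :func:`sta_backward_step`."""
        if state.node is not None:
            child = state.node.children.get(c)
            if child is not None:
                return STAState(child, child.interval)
            # Leave the trie permanently, seeded with the cached interval.
            return STAState(None, self.fm.backward_extend(state.interval, c))
        return STAState(None, self.fm.backward_extend(state.interval, c))

    def node_count(self, include_root: bool = False) -> int:
        return self.root.node_count(include_root=include_root)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        def pack(node: TrieNode) -> dict:
            return {
                "k": node.k,
                "l": node.l,
                "children": {c: pack(ch) for c, ch in sorted(node.children.items())},
            }

        return {
            "epsilon": self.epsilon,
            "max_depth": self.max_depth,
            "root": pack(self.root),
        }

    @classmethod
    def from_dict(cls, d: dict, fm: FMIndex) -> "SuffixTarray":
        def unpack(pd: dict) -> TrieNode:
            node = TrieNode(pd["k"], pd["l"])
            for c, cd in pd["children"].items():
                node.children[c] = unpack(cd)
            return node

        return cls(fm, unpack(d["root"]), d["epsilon"], d["max_depth"])


def sta_backward_step(sta: SuffixTarray, state: STAState, c: str) -> STAState:
    """Descend the trie if the child edge exists (cached interval, no Occ
    work); otherwise transition permanently to FM mode and delegate to
    backward extension."""
    return sta.step(state, c)
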