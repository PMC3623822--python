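"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately naive (sorting, sliding windows, full DP)
and shares no code path with the package.
"""

from __future__ import annotations


def brute_suffix_array(text: str) -> list[int]:
    """Sort sentinel-terminated suffixes lexicographically ('$' < 'A')."""
    full = text + "$"
    return sorted(range(len(full)), key=lambda i: full[i:])


def brute_bwt(text: str) -> str:
    full = text + "$"
    return "".join(full[i - 1] for i in brute_suffix_array(text))


def brute_count(text: str, w: str) -> int:
    """Overlapping occurrence count by sliding window."""
    return sum(1 for i in range(len(text) - len(w) + 1) if text[i : i + len(w)] == w)


def brute_positions(text: str, w: str) -> set[int]:
    return {i for i in range(len(text) - len(w) + 1) if text[i : i + len(w)] == w}


def brute_d_basic(w: str, x: str) -> list[int]:
    """Re-implementation of the window-break recurrence via substring tests."""
    z, j = 0, 0
    out = []
    for i in range(len(w)):
        if w[j : i + 1] not in x:
            z += 1
            j = i + 1
        out.append(z)
    return out


def dp_min_cost_prefix(w: str, x: str) -> list[int]:
    """For every prefix w[0..i], the minimal cost (sub/ins/del/extension all
    1) of aligning it to some substring of x.  Full O(|w||x|) DP."""
    nx = len(x)
    prev = [0] * (nx + 1)
    out = []
    for i in range(1, len(w) + 1):
        cur = [i] * (nx + 1)
        for j in range(1, nx + 1):
            cur[j] = min(
                prev[j - 1] + (w[i - 1] != x[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        out.append(min(cur))
        prev = cur
    return out


def brute_min_edit(w: str, x: str) -> int:
    return dp_min_cost_prefix(w, x)[-1]


def brute_min_hamming(w: str, x: str) -> int:
    if len(w) > len(x):
        return len(w)
    return min(
        sum(a != b for a, b in zip(w, x[i : i + len(w)]))
        for i in range(len(x) - len(w) + 1)
    )


def brute_failure_link(pattern_prefixes: set[str], s: str) -> str:
    """Longest proper suffix of s that is itself a trie state."""
    for start in range(1, len(s) + 1):
        cand = s[start:]
        if cand in pattern_prefixes:
            return cand
    return ""


def brute_greedy_scan(patterns: list[str], w: str) -> list[tuple[int, str]]:
    """Greedy reset-on-match scan: repeatedly take the first position at
    which any pattern ends (starting at or after the current cursor),
    preferring the longest pattern at that position, then resume after it."""
    hits = []
    start = 0
    i = 0
    while i < len(w):
        best = None
        for f in patterns:
            b = i - len(f) + 1
            if b >= start and w[b : i + 1] == f:
                if best is None or len(f) > len(best):
                    best = f
        if best is not None:
            hits.append((i, best))
            start = i + 1
        i += 1
    return hits


def substitution_variants(w: str, max_subs: int):
    """Every string within max_subs substitutions of w (for small inputs)."""
    from itertools import combinations, product

    yield w
    positions = range(len(w))
    for k in range(1, max_subs + 1):
        for idxs in combinations(positions, k):
            alts = [[b for b in "ACGT" if b != w[i]] for i in idxs]
            for repl in product(*alts):
                out = list(w)
                for i, b in zip(idxs, repl):
                    out[i] = b
                yield "".join(out)
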