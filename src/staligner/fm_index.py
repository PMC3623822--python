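"""Sentinel-terminated FM-index over small DNA alphabets.

The index stores the Burrows-Wheeler transform of ``text + sentinel``, the
``C`` array of cumulative character counts, a bucketed table of ``Occ``
checkpoints and a sampled suffix array, and answers interval, counting and
locate queries via backward search.

Conventions
-----------
* The sentinel is a single character lexicographically smaller than every
  alphabet character; it is appended internally and never exposed.
* Rows are 0-based over ``n + 1`` rows; row 0 is always the sentinel suffix.
* The SA interval of the empty string is ``[0, n]`` (every row).  Extending
  it by a character ``c`` with the C/Occ relations yields exactly the rows
  whose suffixes start with ``c``, which would not hold for a convention
  that excludes the sentinel row from the starting interval.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "Sequence",
    "SAInterval",
    "FMIndex",
    "build_suffix_array",
    "build_fm_index",
    "apply_n_policy",
    "revcomp",
    "DNA_ALPHABET",
]

DNA_ALPHABET = "ACGT"
SENTINEL = "$"

#: Seed for the deterministic replacement of N bases in references.
N_POLICY_SEED = 9973

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(bases: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return bases.translate(_COMPLEMENT)[::-1]


def apply_n_policy(bases: str, seed: int = N_POLICY_SEED) -> str:
    """Replace every ``N`` in a reference by a deterministic pseudo-random base.

    The draw depends only on ``seed`` and the position of the ``N`` so the
    substitution is reproducible across runs and platforms.
    """
    if "N" not in bases:
        return bases
    out = list(bases)
    for i, ch in enumerate(out):
        if ch == "N":
            out[i] = DNA_ALPHABET[random.Random(f"{seed}:{i}").randrange(4)]
    return "".join(out)


@dataclass(frozen=True)
class Sequence:
    """A named nucleotide sequence over {A, C, G, T} (plus N in raw reads)."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"sequence {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.bases)


class SAInterval(NamedTuple):
    """Closed interval ``[k, l]`` of suffix-array rows; empty iff ``k > l``."""

    k: int
    l: int

    @property
    def is_empty(self) -> bool:
        return self.k > self.l

    @property
    def width(self) -> int:
        return 0 if self.k > self.l else self.l - self.k + 1


EMPTY_INTERVAL = SAInterval(0, -1)


def _encode(text: str, rank: dict) -> np.ndarray:
    try:
        return np.array([rank[c] for c in text], dtype=np.uint8)
    except KeyError as exc:  # pragma: no cover - guarded by callers
        raise ValueError(f"character {exc.args[0]!r} outside alphabet") from None


def _suffix_array_codes(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling; O(n log n), numpy-vectorised."""
    n = len(codes)
    rank = codes.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        new_rank = np.zeros(n, dtype=np.int64)
        r_ord = rank[order]
        k_ord = key2[order]
        changed = (r_ord[1:] != r_ord[:-1]) | (k_ord[1:] != k_ord[:-1])
        new_rank[order[1:]] = np.cumsum(changed)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


def build_suffix_array(text: str | Sequence) -> list[int]:
    """Suffix array of ``text`` with a sentinel appended internally.

    Returns the start positions of all ``n + 1`` sentinel-terminated
    suffixes in lexicographic order; row 0 is always the sentinel suffix.
    """
    bases = text.bases if isinstance(text, Sequence) else text
    if not bases:
        raise ValueError("cannot build a suffix array of empty text")
    rank = {SENTINEL: 0}
    for i, c in enumerate(sorted(set(bases))):
        rank[c] = i + 1
    codes = _encode(bases + SENTINEL, rank)
    return _suffix_array_codes(codes).tolist()


class FMIndex:
    """FM-index of a single text over a fixed alphabet.

    Parameters
    ----------
    text:
        The text to index (without sentinel).
    bucket_size:
        Number of BWT rows per Occ checkpoint bucket.
    sample_rate:
        Every ``sample_rate``-th suffix-array row is stored for locate.
    alphabet:
        Ordered alphabet (sentinel excluded).  Characters rank in the given
        order, all above the sentinel.
    """

    def __init__(
        self,
        text: str | Sequence,
        bucket_size: int = 128,
        sample_rate: int = 4,
        alphabet: str = DNA_ALPHABET,
    ) -> None:
        bases = text.bases if isinstance(text, Sequence) else text
        if not bases:
            raise ValueError("cannot index empty text")
        if bucket_size < 1:
            raise ValueError(f"bucket_size must be >= 1, got {bucket_size}")
        if sample_rate < 1:
            raise ValueError(f"sample_rate must be >= 1, got {sample_rate}")

        self.text = bases
        self.n = len(bases)
        self.alphabet = alphabet
        self.bucket_size = bucket_size
        self.sample_rate = sample_rate
        self._rank = {SENTINEL: 0}
        for i, c in enumerate(alphabet):
            self._rank[c] = i + 1
        self._sigma = len(alphabet) + 1

        codes = _encode(bases + SENTINEL, self._rank)
        sa = _suffix_array_codes(codes)
        self._bwt_codes = codes[sa - 1]  # sa-1 == -1 wraps to the sentinel
        self.bwt = bytes(self._bwt_codes)

        # C[c] = count of characters strictly smaller than c (sentinel incl.)
        totals = np.bincount(codes, minlength=self._sigma)
        cum = np.concatenate([[0], np.cumsum(totals)[:-1]])
        self._C = cum.tolist()
        self.C = {c: self._C[self._rank[c]] for c in alphabet}

        # Occ checkpoints: _cp[code][b] = #occurrences of code in bwt[: b*bucket_size]
        nrows = self.n + 1
        nbuckets = nrows // bucket_size + 1
        self._cp = []
        for code in range(self._sigma):
            cum_counts = np.concatenate(
                [[0], np.cumsum(self._bwt_codes == code)]
            )
            self._cp.append(cum_counts[:: bucket_size][:nbuckets].tolist())

        # Sampled SA rows (row 0 and the SA==0 row always kept so locate
        # walk-back terminates without wrapping past the text start).
        self.sa_samples: dict[int, int] = {}
        for row in range(0, nrows, sample_rate):
            self.sa_samples[row] = int(sa[row])
        zero_row = int(np.nonzero(sa == 0)[0][0])
        self.sa_samples[zero_row] = 0
        self.sa_samples[0] = self.n

    # -- low level -----------------------------------------------------

    def _occ_code(self, code: int, y: int) -> int:
        if y < 0:
            return 0
        b = (y + 1) // self.bucket_size
        return self._cp[code][b] + self.bwt.count(code, b * self.bucket_size, y + 1)

    def _extend_code(self, k: int, l: int, code: int) -> tuple[int, int]:
        c0 = self._C[code]
        return c0 + self._occ_code(code, k - 1), c0 + self._occ_code(code, l) - 1

    def code(self, c: str) -> int | None:
        """Internal code of an alphabet character, or None if foreign."""
        r = self._rank.get(c)
        return None if r in (None, 0) else r

    # -- public queries ------------------------------------------------

    def occ(self, c: str, y: int) -> int:
        """Number of occurrences of ``c`` in ``bwt[0..y]`` (``y = -1`` -> 0)."""
        if not -1 <= y <= self.n:
            raise ValueError(f"row index {y} outside [-1, {self.n}]")
        code = self._rank.get(c)
        if code is None:
            raise ValueError(f"character {c!r} outside alphabet")
        return self._occ_code(code, y)

    def full_interval(self) -> SAInterval:
        """SA interval of the empty string: all rows ``[0, n]``."""
        return SAInterval(0, self.n)

    def backward_extend(self, interval: SAInterval, c: str) -> SAInterval:
        """Interval of ``c + W`` given the interval of ``W``.

        A character outside the alphabet (e.g. ``N`` in a read) yields an
        empty interval rather than an error: it can never match.
        """
        if interval.k > interval.l:
            return EMPTY_INTERVAL
        code = self._rank.get(c)
        if code is None or code == 0:
            return EMPTY_INTERVAL
        k, l = self._extend_code(interval.k, interval.l, code)
        return SAInterval(k, l) if k <= l else EMPTY_INTERVAL

    def interval(self, w: str) -> SAInterval:
        """SA interval of ``w`` via backward search (empty string -> all rows)."""
        iv = self.full_interval()
        for c in reversed(w):
            iv = self.backward_extend(iv, c)
            if iv.is_empty:
                return EMPTY_INTERVAL
        return iv

    def count_occurrences(self, w: str | Sequence) -> int:
        """Number of occurrences of ``w`` in the text (|w| backward steps)."""
        bases = w.bases if isinstance(w, Sequence) else w
        if not bases:
            raise ValueError("cannot count the empty string")
        return self.interval(bases).width

    def _sa_value(self, row: int) -> int:
        steps = 0
        while row not in self.sa_samples:
            code = self._bwt_codes[row]
            row = self._C[code] + self._occ_code(code, row) - 1
            steps += 1
        return self.sa_samples[row] + steps

    def locate(self, interval: SAInterval) -> list[int]:
        """Sorted text positions for all rows of ``interval``."""
        if interval.is_empty:
            return []
        return sorted(self._sa_value(row) for row in range(interval.k, interval.l + 1))

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "alphabet": self.alphabet,
            "bucket_size": self.bucket_size,
            "sample_rate": self.sample_rate,
            "text": self.text,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FMIndex":
        return cls(
            d["text"],
            bucket_size=d["bucket_size"],
            sample_rate=d["sample_rate"],
            alphabet=d["alphabet"],
        )


def build_fm_index(
    text: str | Sequence,
    bucket_size: int = 128,
    sample_rate: int = 4,
    alphabet: str = DNA_ALPHABET,
) -> FMIndex:
    """Convenience constructor mirroring :class:`FMIndex`."""
    return FMIndex(text, bucket_size=bucket_size, sample_rate=sample_rate, alphabet=alphabet)
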