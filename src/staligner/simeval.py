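"""Synthetic read generation and truth-based scoring.

Reads are sampled uniformly from the reference, each strand with
probability 1/2, with per-base substitution errors and (optionally) short
indels.  The truth is encoded in the read name as
``{contig}_{start1based}_{strand}_{serial}`` so any SAM-emitting aligner
can be scored.  Scoring follows the simulator convention: a read counts as
correctly mapped iff it is mapped at or above the confidence threshold, on
the true strand, within a small positional tolerance of the truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pysam

from .fm_index import DNA_ALPHABET, Sequence, revcomp

__all__ = [
    "SimulatedRead",
    "EvalReport",
    "simulate_reads",
    "evaluate",
    "write_truth",
    "read_truth",
    "DEFAULT_TOLERANCE",
    "DEFAULT_CONFIDENCE",
]

DEFAULT_TOLERANCE = 5
DEFAULT_CONFIDENCE = 10


@dataclass(frozen=True)
class SimulatedRead:
    """A read plus the truth it was generated from (``pos`` is 0-based)."""

    name: str
    bases: str
    qual: str
    ref_name: str
    pos: int
    strand: str
    edits: tuple[tuple[int, str, str], ...] = ()

    def __len__(self) -> int:
        return len(self.bases)

    def to_sequence(self) -> Sequence:
        return Sequence(self.name, self.bases)


@dataclass(frozen=True)
class EvalReport:
    n_input: int
    n_mapped_confident: int
    n_correct: int

    @property
    def tpr(self) -> float:
        return self.n_correct / self.n_input if self.n_input else 0.0

    @property
    def ppv(self) -> float:
        if self.n_mapped_confident == 0:
            return 0.0
        return self.n_correct / self.n_mapped_confident

    @property
    def conf_rate(self) -> float:
        return self.n_mapped_confident / self.n_input if self.n_input else 0.0


def _pick_other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in DNA_ALPHABET if b != base]
    return choices[rng.integers(0, 3)]


def simulate_reads(
    ref: Sequence | TypingSequence[Sequence],
    n_reads: int,
    read_length: int = 100,
    error_rate: float = 0.02,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Generate ``n_reads`` reads with planted errors, reproducibly.

    Substitutions are planted per base at ``error_rate``; single-base
    indels at ``indel_rate`` (off by default).  Records are sampled with
    probability proportional to their usable length.
    """
    records = [ref] if isinstance(ref, Sequence) else list(ref)
    if not 0 <= error_rate < 1 or not 0 <= indel_rate < 1:
        raise ValueError("rates must be in [0, 1)")
    margin = 8 if indel_rate > 0 else 0
    usable = [len(r) - read_length - margin + 1 for r in records]
    if any(u <= 0 for u in usable):
        raise ValueError(
            f"read_length {read_length} too long for reference "
            f"(shortest record {min(len(r) for r in records)} bp)"
        )
    rng = np.random.default_rng(seed)
    weights = np.array(usable, dtype=float)
    weights /= weights.sum()

    reads: list[SimulatedRead] = []
    for serial in range(n_reads):
        rec = records[int(rng.choice(len(records), p=weights))]
        start = int(rng.integers(0, len(rec) - read_length - margin + 1))
        out: list[str] = []
        edits: list[tuple[int, str, str]] = []
        cursor = start
        n_del = 0
        while len(out) < read_length:
            if indel_rate > 0 and 0 < len(out) < read_length - 1 and rng.random() < indel_rate:
                if rng.random() < 0.5 or n_del >= margin:  # insertion into the read
                    b = DNA_ALPHABET[rng.integers(0, 4)]
                    out.append(b)
                    edits.append((len(out) - 1, "I", b))
                    continue
                edits.append((len(out), "D", rec.bases[cursor]))
                cursor += 1  # deletion: skip one reference base
                n_del += 1
                continue
            base = rec.bases[cursor]
            cursor += 1
            if rng.random() < error_rate:
                sub = _pick_other_base(rng, base)
                edits.append((len(out), "S", sub))
                out.append(sub)
            else:
                out.append(base)
        bases = "".join(out)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            bases = revcomp(bases)
        name = f"{rec.name}_{start + 1}_{'F' if strand == '+' else 'R'}_{serial}"
        reads.append(
            SimulatedRead(
                name=name,
                bases=bases,
                qual="I" * read_length,
                ref_name=rec.name,
                pos=start,
                strand=strand,
                edits=tuple(edits),
            )
        )
    return reads


def write_truth(reads: Iterable[SimulatedRead], path) -> None:
    """Tab-separated truth sidecar: name, contig, 1-based pos, strand."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.name}\t{r.ref_name}\t{r.pos + 1}\t{r.strand}\n")


def read_truth(path) -> list[SimulatedRead]:
    out = []
    with open(path) as fh:
        for line in fh:
            name, ref_name, pos1, strand = line.rstrip("\n").split("\t")
            out.append(
                SimulatedRead(
                    name=name,
                    bases="",
                    qual="",
                    ref_name=ref_name,
                    pos=int(pos1) - 1,
                    strand=strand,
                )
            )
    return out


def evaluate(
    sam_path,
    truth: TypingSequence[SimulatedRead],
    tolerance: int = DEFAULT_TOLERANCE,
    confidence_threshold: int = DEFAULT_CONFIDENCE,
) -> EvalReport:
    """Score SAM alignments against the simulation truth.

    A read is *confident* iff mapped with quality >= the threshold, and
    *correct* iff additionally on the true contig and strand within
    ``tolerance`` bases of the true position.  TPR divides correct reads by
    all input reads, PPV by the confident ones.
    """
    by_name = {t.name: t for t in truth}
    n_conf = 0
    n_correct = 0
    seen: set[str] = set()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            t = by_name.get(rec.query_name)
            if t is None:
                raise ValueError(f"read {rec.query_name!r} absent from the truth set")
            seen.add(rec.query_name)
            if rec.is_unmapped or rec.mapping_quality < confidence_threshold:
                continue
            n_conf += 1
            strand = "-" if rec.is_reverse else "+"
            if (
                rec.reference_name == t.ref_name
                and strand == t.strand
                and abs(rec.reference_start - t.pos) <= tolerance
            ):
                n_correct += 1
    missing = set(by_name) - seen
    if missing:
        raise ValueError(
            f"{len(missing)} truth reads missing from the SAM input "
            f"(e.g. {sorted(missing)[0]!r})"
        )
    return EvalReport(
        n_input=len(truth), n_mapped_confident=n_conf, n_correct=n_correct
    )
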