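"""Format readers/writers and the serialized index bundle.

Coordinates are 0-based half-open internally and 1-based inclusive in SAM.
Multi-record references are concatenated with separator characters so that
no match can span two records; the offset table translates concatenated
coordinates back to per-record ones.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence as TypingSequence, TextIO, Union

from Bio import SeqIO

from .aligner import AlignmentHit, EditOp
from .fm_index import DNA_ALPHABET, FMIndex, Sequence, apply_n_policy
from .pruning import ACAutomaton
from .suffix_tarray import SuffixTarray

__all__ = [
    "Read",
    "ParseError",
    "IndexBundle",
    "read_fasta",
    "read_fastq",
    "write_fastq",
    "write_sam",
    "cigar_from_script",
]

#: Record separator in the concatenated reference text.  It ranks between
#: the sentinel and 'A' and is never emitted by any search branch, so no
#: alignment window can contain it.
RECORD_SEPARATOR = "#"

BUNDLE_FORMAT = "staligner-index"
BUNDLE_VERSION = 1


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class Read(Sequence):
    """A sequencing read: a named sequence plus optional qualities."""

    qual: Optional[str] = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.qual is not None and len(self.qual) != len(self.bases):
            raise ParseError(
                f"read {self.name!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.bases)}"
            )


def _check_fasta_head(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(f"{path}:{lineno}: expected FASTA header, got {line[:30]!r}")
            return
    raise ParseError(f"{path}: empty FASTA file")


def read_fasta(path) -> list[Sequence]:
    """All records of a FASTA file, wrapped lines joined, case folded up."""
    _check_fasta_head(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append(Sequence(rec.id, str(rec.seq).upper()))
    return out


def read_fastq(path) -> list[Read]:
    """All records of a 4-line-record FASTQ file, with qualities."""
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append(Read(rec.id, str(rec.seq).upper(), qual))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not out:
        raise ParseError(f"{path}: empty FASTQ file")
    return out


def write_fastq(reads: Iterable, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = getattr(r, "qual", None) or "I" * len(r.bases)
            fh.write(f"@{r.name}\n{r.bases}\n+\n{qual}\n")


def read_sequences(path) -> list:
    """FASTA or FASTQ by sniffing the first byte."""
    with open(path) as fh:
        head = fh.read(1)
    return read_fastq(path) if head == "@" else read_fasta(path)


# ---------------------------------------------------------------------------
# Index bundle
# ---------------------------------------------------------------------------


class IndexBundle:
    """Forward and reverse-reference FM indexes, optional trie and automaton.

    The two FM indexes are built over the same concatenated text: the
    forward one drives the search and locate, the reversed one the D-array
    computation.
    """

    def __init__(
        self,
        records: TypingSequence[Sequence],
        fm: FMIndex,
        rev_fm: FMIndex,
        sta: Optional[SuffixTarray],
        automaton: Optional[ACAutomaton],
        build_params: dict,
    ) -> None:
        self.records = list(records)
        self.fm = fm
        self.rev_fm = rev_fm
        self.sta = sta
        self.automaton = automaton
        self.build_params = dict(build_params)
        self.offsets = []
        off = 0
        for rec in self.records:
            self.offsets.append(off)
            off += len(rec) + 1  # +1 for the separator

    @classmethod
    def build(
        cls,
        records: TypingSequence[Sequence],
        bucket_size: int = 128,
        sample_rate: int = 4,
        with_trie: bool = True,
        trie_bytes: Optional[int] = None,
        epsilon: Optional[int] = None,
        max_depth: int = 12,
        automaton: Optional[ACAutomaton] = None,
    ) -> "IndexBundle":
        if not records:
            raise ValueError("no reference records")
        cleaned = [Sequence(r.name, apply_n_policy(r.bases)) for r in records]
        text = RECORD_SEPARATOR.join(r.bases for r in cleaned)
        alphabet = RECORD_SEPARATOR + DNA_ALPHABET
        fm = FMIndex(text, bucket_size=bucket_size, sample_rate=sample_rate, alphabet=alphabet)
        rev_fm = FMIndex(
            text[::-1], bucket_size=bucket_size, sample_rate=sample_rate, alphabet=alphabet
        )
        sta = None
        if with_trie:
            sta = SuffixTarray.build(
                fm,
                xbar_fm=rev_fm,
                trie_bytes=trie_bytes,
                epsilon=epsilon,
                max_depth=max_depth,
            )
        params = {
            "bucket_size": bucket_size,
            "sample_rate": sample_rate,
            "with_trie": with_trie,
            "trie_bytes": trie_bytes,
            "max_depth": max_depth,
        }
        return cls(cleaned, fm, rev_fm, sta, automaton, params)

    # -- coordinate translation ---------------------------------------

    def translate(self, pos: int, span: int = 1) -> tuple[str, int]:
        """Concatenated 0-based position -> (record name, local position)."""
        idx = bisect.bisect_right(self.offsets, pos) - 1
        rec = self.records[idx]
        local = pos - self.offsets[idx]
        if local + span > len(rec):
            raise RuntimeError(
                f"alignment window [{pos}, {pos + span}) crosses a record boundary"
            )
        return rec.name, local

    # -- serialization -------------------------------------------------

    def save(self, path) -> None:
        doc = {
            "format": BUNDLE_FORMAT,
            "version": BUNDLE_VERSION,
            "records": [{"name": r.name, "bases": r.bases} for r in self.records],
            "fm": self.fm.to_dict(),
            "rev_fm": self.rev_fm.to_dict(),
            "sta": self.sta.to_dict() if self.sta is not None else None,
            "automaton": self.automaton.to_dict() if self.automaton is not None else None,
            "build_params": self.build_params,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path) -> "IndexBundle":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != BUNDLE_FORMAT:
            raise ParseError(f"{path}: not a {BUNDLE_FORMAT} container")
        if doc.get("version") != BUNDLE_VERSION:
            raise ParseError(f"{path}: unsupported index version {doc.get('version')}")
        records = [Sequence(r["name"], r["bases"]) for r in doc["records"]]
        fm = FMIndex.from_dict(doc["fm"])
        rev_fm = FMIndex.from_dict(doc["rev_fm"])
        sta = SuffixTarray.from_dict(doc["sta"], fm) if doc["sta"] is not None else None
        automaton = (
            ACAutomaton.from_dict(doc["automaton"]) if doc["automaton"] is not None else None
        )
        return cls(records, fm, rev_fm, sta, automaton, doc["build_params"])


# ---------------------------------------------------------------------------
# SAM output
# ---------------------------------------------------------------------------


def cigar_from_script(read_length: int, script: tuple[EditOp, ...]) -> str:
    """CIGAR over M/I/D runs; substitutions are M columns."""
    ins = {op.i for op in script if op.op == "I"}
    dels: dict[int, int] = {}
    for op in script:
        if op.op == "D":
            dels[op.i] = dels.get(op.i, 0) + 1
    runs: list[tuple[str, int]] = []

    def emit(kind: str, count: int = 1) -> None:
        if count == 0:
            return
        if runs and runs[-1][0] == kind:
            runs[-1] = (kind, runs[-1][1] + count)
        else:
            runs.append((kind, count))

    for i in range(read_length):
        emit("I" if i in ins else "M")
        emit("D", dels.get(i, 0))
    return "".join(f"{count}{kind}" for kind, count in runs)


def write_sam(
    hits: Iterable[AlignmentHit],
    bundle: IndexBundle,
    out: Union[str, Path, TextIO],
    program_args: str = "",
) -> None:
    """Serialize hits as SAM with @HD/@SQ/@PG header lines.

    POS is 1-based; FLAG is 0/16/4 for forward/reverse/unmapped.  NM counts
    every edited column: charged differences plus free gap-extension
    columns, so it can exceed the search's difference count.
    """
    own = isinstance(out, (str, Path))
    fh: TextIO = open(out, "w") if own else out
    try:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for rec in bundle.records:
            fh.write(f"@SQ\tSN:{rec.name}\tLN:{len(rec)}\n")
        fh.write(f"@PG\tID:staligner\tPN:staligner\tCL:{program_args}\n")
        for hit in hits:
            qual = hit.qual or "*"
            if not hit.mapped:
                fh.write(
                    f"{hit.read_name}\t4\t*\t0\t0\t*\t*\t0\t0\t{hit.seq}\t{qual}\n"
                )
                continue
            n_ins = sum(1 for op in hit.script if op.op == "I")
            n_del = sum(1 for op in hit.script if op.op == "D")
            span = len(hit.seq) - n_ins + n_del
            ref_name, local = bundle.translate(hit.pos, span)
            flag = 16 if hit.strand == "-" else 0
            cigar = cigar_from_script(len(hit.seq), hit.script)
            nm = len(hit.script)
            fh.write(
                f"{hit.read_name}\t{flag}\t{ref_name}\t{local + 1}\t{hit.mapq}\t"
                f"{cigar}\t*\t0\t0\t{hit.seq}\t{qual}\tNM:i:{nm}\n"
            )
    finally:
        if own:
            fh.close()
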