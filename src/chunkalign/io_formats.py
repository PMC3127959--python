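"""Reading FASTA/FASTQ and writing SAM / BED6.

Internal coordinates are 0-based half-open everywhere; conversion to SAM's
1-based convention happens only at emission time. Output order follows the
order alignments are handed to the writers (chunk concatenation order), so
downstream comparisons should be order-insensitive or sort first.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence, Union

from Bio import SeqIO

from .errors import ConsistencyError, FormatError, ParameterError

__all__ = [
    "Read",
    "ReferenceSeq",
    "read_fasta",
    "read_reads",
    "write_fasta",
    "write_fastq",
    "write_sam",
    "write_bed6",
    "revcomp",
    "sam_flag",
]

# Any IUPAC ambiguity code other than A/C/G/T becomes N on input.
_ALLOWED = set("ACGTN")
_NORMALIZE = {c: c if c in _ALLOWED else "N" for c in
              "ABCDEFGHIJKLMNOPQRSTUVWXYZ"}
_NORM_TABLE = str.maketrans(_NORMALIZE)
_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")


def normalize_seq(seq: str) -> str:
    """Uppercase and map every non-ACGT letter to N."""
    return seq.upper().translate(_NORM_TABLE)


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMP_TABLE)[::-1]


@dataclass(frozen=True)
class Read:
    """One sequencing read.

    ``qual`` is the Phred+33 quality string when the read came from FASTQ,
    ``None`` for FASTA input. ``mate_index`` is 0 for unpaired reads,
    1 or 2 for the first/second mate of a pair.
    """

    id: str
    seq: str
    qual: Optional[str] = None
    mate_index: int = 0

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise FormatError(f"read {self.id!r} has an empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReferenceSeq:
    """One reference sequence; ``name`` is the first word of the header."""

    name: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


Source = Union[str, os.PathLike, IO[str]]


def _as_text_handle(source: Source, mode: str = "rt"):
    """Return (handle, needs_close) for a path or an open handle."""
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode), True
    if isinstance(source, (bytes, bytearray)):
        return io.StringIO(source.decode("ascii")), True
    return source, False


def read_fasta(source: Source) -> list[ReferenceSeq]:
    """Parse a (possibly multi-record, line-wrapped) FASTA reference file.

    Sequences are uppercased and ambiguity codes collapse to N. Record order
    is preserved. Raises :class:`FormatError` on an empty file, an empty
    sequence, or duplicate names.
    """
    handle, close = _as_text_handle(source)
    try:
        refs: list[ReferenceSeq] = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            name = rec.id
            seq = normalize_seq(str(rec.seq))
            if not seq:
                raise FormatError(f"FASTA record {name!r} has an empty sequence")
            if name in seen:
                raise FormatError(f"duplicate FASTA record name {name!r}")
            seen.add(name)
            refs.append(ReferenceSeq(name=name, seq=seq))
        if not refs:
            raise FormatError("no FASTA records found")
        return refs
    finally:
        if close:
            handle.close()


def _skip_blank(handle: IO[str]) -> Optional[str]:
    """Advance past leading blank lines; leave the handle at the start of
    the first non-blank line and return that line's first character."""
    while True:
        pos = handle.tell()
        line = handle.readline()
        if not line:
            return None
        stripped = line.strip()
        if stripped:
            handle.seek(pos)
            return stripped[0]


def read_reads(source: Source, format: str = "auto",
               mate_index: int = 0) -> list[Read]:
    """Parse reads from FASTA or FASTQ, preserving input order.

    ``format`` may be ``fasta``, ``fastq`` or ``auto`` (detect from the
    first non-blank character: '>' = FASTA, '@' = FASTQ). FASTQ qualities
    are carried verbatim (Sanger Phred+33 assumed). A malformed FASTQ
    record raises :class:`FormatError` carrying its 1-based record index.
    """
    if format not in ("auto", "fasta", "fastq"):
        raise ParameterError(f"unknown read format {format!r}")
    handle, close = _as_text_handle(source)
    try:
        first = _skip_blank(handle)
        if first is None:
            raise FormatError("no reads found (empty file)")
        if format == "auto":
            if first == ">":
                fmt = "fasta"
            elif first == "@":
                fmt = "fastq"
            else:
                raise FormatError(
                    f"cannot auto-detect read format (first character {first!r})")
        else:
            fmt = format
        reads: list[Read] = []
        parser = SeqIO.parse(handle, fmt)
        index = 0
        while True:
            index += 1
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise FormatError(
                    f"malformed {fmt.upper()} record {index}: {exc}") from exc
            qual = None
            if fmt == "fastq":
                phred = rec.letter_annotations["phred_quality"]
                qual = "".join(chr(q + 33) for q in phred)
            reads.append(Read(id=rec.id, seq=normalize_seq(str(rec.seq)),
                              qual=qual, mate_index=mate_index))
        if not reads:
            raise FormatError("no reads found")
        return reads
    finally:
        if close:
            handle.close()


def write_fasta(reads: Iterable[Read], sink: Source) -> int:
    handle, close = _as_text_handle(sink, "wt")
    try:
        n = 0
        for r in reads:
            handle.write(f">{r.id}\n{r.seq}\n")
            n += 1
        return n
    finally:
        if close:
            handle.close()


def write_fastq(reads: Iterable[Read], sink: Source) -> int:
    """Serialize reads as Sanger FASTQ; reads without qualities get 'I' (Q40)."""
    handle, close = _as_text_handle(sink, "wt")
    try:
        n = 0
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            handle.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
            n += 1
        return n
    finally:
        if close:
            handle.close()


# --- SAM ------------------------------------------------------------------

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80


def sam_flag(*, paired: bool = False, proper: bool = False,
             unmapped: bool = False, mate_unmapped: bool = False,
             reverse: bool = False, mate_reverse: bool = False,
             first: bool = False, second: bool = False) -> int:
    flag = 0
    for bit, on in ((FLAG_PAIRED, paired), (FLAG_PROPER, proper),
                    (FLAG_UNMAPPED, unmapped),
                    (FLAG_MATE_UNMAPPED, mate_unmapped),
                    (FLAG_REVERSE, reverse), (FLAG_MATE_REVERSE, mate_reverse),
                    (FLAG_FIRST, first), (FLAG_SECOND, second)):
        if on:
            flag |= bit
    return flag


@dataclass
class SamEntry:
    """One SAM alignment line (already in SAM conventions: 1-based POS)."""

    qname: str
    flag: int
    rname: str
    pos: int          # 1-based; 0 for unmapped
    mapq: int
    cigar: str
    rnext: str
    pnext: int
    tlen: int
    seq: str
    qual: str
    tags: list[str] = field(default_factory=list)

    def line(self) -> str:
        fields = [self.qname, str(self.flag), self.rname, str(self.pos),
                  str(self.mapq), self.cigar, self.rnext, str(self.pnext),
                  str(self.tlen), self.seq, self.qual]
        fields.extend(self.tags)
        return "\t".join(fields)


def _oriented(read: Read, reverse: bool) -> tuple[str, str]:
    """SEQ/QUAL in SAM orientation: reverse-complemented for '-' hits."""
    seq = revcomp(read.seq) if reverse else read.seq
    qual = read.qual if read.qual is not None else "*"
    if reverse and qual != "*":
        qual = qual[::-1]
    return seq, qual


def sam_entry_single(read: Read, hit) -> SamEntry:
    """SAM line for a single-end hit (hit is an align.AlignmentHit)."""
    reverse = hit.strand == "-"
    seq, qual = _oriented(read, reverse)
    return SamEntry(
        qname=read.id, flag=sam_flag(reverse=reverse), rname=hit.ref_name,
        pos=hit.start + 1, mapq=255, cigar=f"{len(read)}M",
        rnext="*", pnext=0, tlen=0, seq=seq, qual=qual,
        tags=[f"NM:i:{hit.mismatches}"],
    )


def sam_entry_unmapped(read: Read) -> SamEntry:
    qual = read.qual if read.qual is not None else "*"
    return SamEntry(qname=read.id, flag=FLAG_UNMAPPED, rname="*", pos=0,
                    mapq=0, cigar="*", rnext="*", pnext=0, tlen=0,
                    seq=read.seq, qual=qual)


def sam_entries_pair(read1: Read, hit1, read2: Read, hit2) -> list[SamEntry]:
    """Two SAM lines for a concordant pair (proper, FR orientation)."""
    entries = []
    left = min(hit1.start, hit2.start)
    right = max(hit1.start + hit1.read_len, hit2.start + hit2.read_len)
    insert = right - left
    for read, hit, mate_hit, first in ((read1, hit1, hit2, True),
                                       (read2, hit2, hit1, False)):
        reverse = hit.strand == "-"
        seq, qual = _oriented(read, reverse)
        tlen = insert if hit.start <= mate_hit.start else -insert
        entries.append(SamEntry(
            qname=read.id, rname=hit.ref_name, pos=hit.start + 1,
            flag=sam_flag(paired=True, proper=True, reverse=reverse,
                          mate_reverse=mate_hit.strand == "-",
                          first=first, second=not first),
            mapq=255, cigar=f"{len(read)}M", rnext="=",
            pnext=mate_hit.start + 1, tlen=tlen, seq=seq, qual=qual,
            tags=[f"NM:i:{hit.mismatches}"],
        ))
    return entries


def write_sam(entries: Iterable[SamEntry], refs: Sequence[ReferenceSeq],
              sink: Source) -> int:
    """Write a SAM v1.6 file (unsorted) with @HD and one @SQ per reference.

    Raises :class:`ConsistencyError` when an entry references a sequence
    name absent from ``refs``.
    """
    known = {r.name: r.length for r in refs}
    handle, close = _as_text_handle(sink, "wt")
    try:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for r in refs:
            handle.write(f"@SQ\tSN:{r.name}\tLN:{r.length}\n")
        n = 0
        for e in entries:
            if e.rname != "*" and e.rname not in known:
                raise ConsistencyError(
                    f"alignment of {e.qname!r} references unknown sequence "
                    f"{e.rname!r}")
            handle.write(e.line() + "\n")
            n += 1
        return n
    finally:
        if close:
            handle.close()


def write_bed6(records: Iterable[tuple[Read, object]], sink: Source) -> int:
    """Write hits as headerless BED6: chrom, start, end, read id, mismatch
    count in the score column, strand. ``records`` yields (read, hit) pairs.
    """
    handle, close = _as_text_handle(sink, "wt")
    try:
        n = 0
        for read, hit in records:
            end = hit.start + hit.read_len
            handle.write(f"{hit.ref_name}\t{hit.start}\t{end}\t"
                         f"{read.id}\t{hit.mismatches}\t{hit.strand}\n")
            n += 1
        return n
    finally:
        if close:
            handle.close()
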