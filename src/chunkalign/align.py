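"""Ungapped seed-and-extend alignment under a mismatch budget.

Candidate placements come from exact seed lookups (see :mod:`.seeding`);
each candidate is verified by a position-wise Hamming comparison with early
termination once the budget is exceeded. No indels are considered.

Base-comparison rules
---------------------
* A read N or a reference N always counts as a mismatch ("bad base" rule).
* With a quality cutoff set, a read base whose Phred score is below the
  cutoff also counts as a mismatch, whatever the bases are.
* Plain mode: bases must be equal.
* Bisulfite mode (directional library): reads from the original top strand
  are compared forward in C->T space, where a read T over a reference C is a
  match (the unmethylated-C conversion) but a read C over a reference T is
  NOT; reads from the original bottom strand are handled by reverse
  complementing the read, which mirrors the rule into G->A space (read A
  over reference G is a match).

The reverse strand is always handled by reverse complementing the read and
comparing against the forward reference, so the index only ever covers the
forward reference.

Uniqueness is defined at the minimum-mismatch stratum: a read is *unique*
when exactly one placement attains its best (lowest) mismatch count, even if
worse placements exist; *ambiguous* with two or more best placements;
*unmapped* with none within the budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import ParameterError
from .io_formats import Read, ReferenceSeq, revcomp
from .seeding import (IndexCache, SeedPattern, pigeonhole_patterns,
                      rewrite_keyspace, seed_key)

__all__ = [
    "AlignmentHit",
    "MappingResult",
    "PairConstraint",
    "PairResult",
    "ClassCounts",
    "count_mismatches",
    "find_candidates",
    "seed_and_extend",
    "align_pair",
    "classify_run",
]

logger = logging.getLogger(__name__)

MODES = ("plain", "bisulfite")


@dataclass(frozen=True, order=True)
class AlignmentHit:
    """One verified placement: 0-based ``start`` of the leftmost aligned
    base on the forward reference."""

    ref_name: str
    start: int
    strand: str
    read_id: str = field(compare=False)
    mismatches: int = field(compare=False)
    read_len: int = field(compare=False)
    mode: str = field(default="plain", compare=False)

    @property
    def end(self) -> int:
        return self.start + self.read_len

    def placement(self) -> tuple[str, int, str]:
        return (self.ref_name, self.start, self.strand)


@dataclass
class MappingResult:
    """Per-read verdict. ``hits`` holds only the best-stratum placements
    (all share ``best_mismatches``), sorted for deterministic output."""

    read_id: str
    status: str  # unique | ambiguous | unmapped
    best_mismatches: Optional[int]
    hits: list[AlignmentHit]

    @property
    def mapped(self) -> bool:
        return self.status != "unmapped"


def _match_fn(mode: str, strand: str):
    """Return a predicate (read_base, ref_base) -> bool for non-N bases."""
    if mode == "plain":
        return None  # equality; handled inline
    if mode == "bisulfite":
        if strand == "+":
            return lambda r, f: r == f or (f == "C" and r == "T")
        return lambda r, f: r == f or (f == "G" and r == "A")
    raise ParameterError(f"unknown mode {mode!r}")


def count_mismatches(read: Read, ref: ReferenceSeq, start: int, strand: str,
                     mode: str = "plain",
                     bad_qual_cutoff: Optional[int] = None,
                     budget: Optional[int] = None) -> Optional[int]:
    """Mismatch count of placing ``read`` at ``start`` on ``ref``.

    Returns None ("exceeds") as soon as the count passes ``budget``.
    For strand '-' the reverse-complemented read is compared against the
    forward reference (qualities reversed alongside).
    """
    n = len(read.seq)
    if start < 0 or start + n > ref.length:
        raise ParameterError(
            f"placement [{start}, {start + n}) out of range for reference "
            f"{ref.name!r} of length {ref.length}")
    if strand not in ("+", "-"):
        raise ParameterError(f"strand must be '+' or '-', got {strand!r}")
    oriented = read.seq if strand == "+" else revcomp(read.seq)
    qual = read.qual
    if qual is not None and strand == "-":
        qual = qual[::-1]
    window = ref.seq[start:start + n]
    limit = budget if budget is not None else n

    # Fast path: literal equality with no Ns and no quality masking.
    if (mode == "plain" and bad_qual_cutoff is None
            and oriented == window and "N" not in oriented):
        return 0

    match = _match_fn(mode, strand)
    count = 0
    for i in range(n):
        r = oriented[i]
        f = window[i]
        if r == "N" or f == "N":
            bad = True
        elif bad_qual_cutoff is not None and qual is not None \
                and ord(qual[i]) - 33 < bad_qual_cutoff:
            bad = True
        elif match is None:
            bad = r != f
        else:
            bad = not match(r, f)
        if bad:
            count += 1
            if count > limit:
                return None
    return count


def _read_patterns(read_len: int, k: int,
                   user_patterns: Optional[Sequence[SeedPattern]]) \
        -> list[SeedPattern]:
    if user_patterns is None:
        return pigeonhole_patterns(read_len, k)
    usable = []
    for p in user_patterns:
        if p.offset + p.span > read_len:
            logger.warning("seed pattern (offset %d, span %d) does not fit "
                           "read of length %d; skipped", p.offset, p.span,
                           read_len)
            continue
        usable.append(p)
    if not usable:
        raise ParameterError(
            f"no seed pattern fits reads of length {read_len}")
    return usable


def find_candidates(read: Read, cache: IndexCache, k: int,
                    mode: str = "plain",
                    bad_qual_cutoff: Optional[int] = None,
                    patterns: Optional[Sequence[SeedPattern]] = None
                    ) -> list[AlignmentHit]:
    """All verified placements of ``read`` with at most ``k`` mismatches
    reachable through the seed index, on both strands, de-duplicated by
    (reference, start, strand) and sorted deterministically."""
    if mode not in MODES:
        raise ParameterError(f"unknown mode {mode!r}")
    pats = _read_patterns(len(read), k, patterns)
    ref_by_name = {r.name: r for r in cache.refs}

    seen: set[tuple[str, int, str]] = set()
    hits: list[AlignmentHit] = []
    n = len(read)
    for strand in ("+", "-"):
        oriented = read.seq if strand == "+" else revcomp(read.seq)
        if mode == "bisulfite":
            keyspace = "bisulfite_ct" if strand == "+" else "bisulfite_ga"
        else:
            keyspace = "plain"
        rewritten = rewrite_keyspace(oriented, keyspace)
        for pat in pats:
            index = cache.get(pat, keyspace)
            key = seed_key(rewritten, pat, pat.offset)
            if key is None:
                continue
            for ref_name, pos in index.lookup(key):
                start = pos - pat.offset
                ref = ref_by_name[ref_name]
                if start < 0 or start + n > ref.length:
                    continue
                place = (ref_name, start, strand)
                if place in seen:
                    continue
                seen.add(place)
                mm = count_mismatches(read, ref, start, strand, mode=mode,
                                      bad_qual_cutoff=bad_qual_cutoff,
                                      budget=k)
                if mm is not None:
                    hits.append(AlignmentHit(
                        ref_name=ref_name, start=start, strand=strand,
                        read_id=read.id, mismatches=mm, read_len=n,
                        mode=mode))
    hits.sort()
    return hits


def _result_from_hits(read_id: str,
                      hits: Sequence[AlignmentHit]) -> MappingResult:
    if not hits:
        return MappingResult(read_id, "unmapped", None, [])
    best = min(h.mismatches for h in hits)
    best_hits = [h for h in hits if h.mismatches == best]
    status = "unique" if len(best_hits) == 1 else "ambiguous"
    return MappingResult(read_id, status, best, best_hits)


def seed_and_extend(read: Read, cache: IndexCache, k: int,
                    mode: str = "plain",
                    bad_qual_cutoff: Optional[int] = None,
                    patterns: Optional[Sequence[SeedPattern]] = None
                    ) -> MappingResult:
    """Map one read: seed, extend, keep the minimum-mismatch stratum and
    classify as unique / ambiguous / unmapped."""
    hits = find_candidates(read, cache, k, mode=mode,
                           bad_qual_cutoff=bad_qual_cutoff,
                           patterns=patterns)
    return _result_from_hits(read.id, hits)


# --- paired-end -------------------------------------------------------------


@dataclass(frozen=True)
class PairConstraint:
    """Forward-reverse orientation with the outermost-to-outermost insert
    span constrained to [min_insert, max_insert]."""

    min_insert: int = 1
    max_insert: int = 1000

    def __post_init__(self) -> None:
        if not (1 <= self.min_insert <= self.max_insert):
            raise ParameterError(
                f"invalid insert window [{self.min_insert}, "
                f"{self.max_insert}]")


@dataclass
class PairResult:
    pair_id: str
    status: str  # concordant_unique | concordant_ambiguous | discordant | unmapped
    hit1: Optional[AlignmentHit]
    hit2: Optional[AlignmentHit]
    combined_mismatches: Optional[int]

    @property
    def insert(self) -> Optional[int]:
        if self.hit1 is None or self.hit2 is None:
            return None
        left = min(self.hit1.start, self.hit2.start)
        right = max(self.hit1.end, self.hit2.end)
        return right - left


def align_pair(pair_id: str, hits1: Sequence[AlignmentHit],
               hits2: Sequence[AlignmentHit],
               constraint: PairConstraint) -> PairResult:
    """Resolve one mate pair from the mates' candidate hit lists.

    A valid pair has both hits on the same reference, opposite strands with
    the leftmost mate on the forward strand (FR), and an insert within the
    constraint window. Valid pairs are ranked by combined mismatch count,
    ties broken by (reference, leftmost start, strand of mate 1) so output
    is deterministic. Both-mates-mapped but no valid pair => discordant.
    """
    if not hits1 or not hits2:
        return PairResult(pair_id, "unmapped", None, None, None)

    valid: list[tuple[int, str, int, str, AlignmentHit, AlignmentHit]] = []
    for h1 in hits1:
        for h2 in hits2:
            if h1.ref_name != h2.ref_name or h1.strand == h2.strand:
                continue
            fwd, rev = (h1, h2) if h1.strand == "+" else (h2, h1)
            if fwd.start > rev.start:
                continue  # not leftmost-forward
            insert = rev.end - fwd.start
            if not (constraint.min_insert <= insert <= constraint.max_insert):
                continue
            combined = h1.mismatches + h2.mismatches
            left = min(h1.start, h2.start)
            valid.append((combined, h1.ref_name, left, h1.strand, h1, h2))
    if not valid:
        return PairResult(pair_id, "discordant", None, None, None)
    valid.sort(key=lambda t: t[:4])
    best_combined = valid[0][0]
    n_best = sum(1 for t in valid if t[0] == best_combined)
    status = "concordant_unique" if n_best == 1 else "concordant_ambiguous"
    _, _, _, _, h1, h2 = valid[0]
    return PairResult(pair_id, status, h1, h2, best_combined)


# --- run-level summary -------------------------------------------------------


@dataclass(frozen=True)
class ClassCounts:
    unique: int
    ambiguous: int
    unmapped: int
    total: int


def classify_run(results: Iterable[MappingResult]) -> ClassCounts:
    """Tally unique / ambiguous / unmapped; the three always sum to total."""
    unique = ambiguous = unmapped = 0
    for r in results:
        if r.status == "unique":
            unique += 1
        elif r.status == "ambiguous":
            ambiguous += 1
        else:
            unmapped += 1
    return ClassCounts(unique, ambiguous, unmapped,
                       unique + ambiguous + unmapped)
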