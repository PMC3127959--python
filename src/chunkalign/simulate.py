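"""Seedable synthetic references and planted reads with known truth.

All randomness flows through numpy's ``default_rng`` (the PCG64 generator),
so every fixture is reproducible across platforms from a 64-bit seed.

Planting rules that keep truth counts exact rather than stochastic:

* a planted substitution never recreates the original base;
* N-injection sites are disjoint from substitution sites;
* bisulfite conversion only touches read Cs that still match a reference C
  (untouched by substitution or N), so conversions are free under the
  bisulfite match rule and are never part of ``mismatches``.

Hence in plain mode the Hamming distance between an emitted read and its
truth window is exactly ``mismatches + n_count``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import IO, Optional, Sequence

import numpy as np

from .errors import ParameterError
from .io_formats import Read, ReferenceSeq, revcomp

__all__ = [
    "PlantedTruth",
    "gen_reference",
    "plant_reads",
    "bisulfite_convert",
    "plant_pairs",
    "write_truth_tsv",
]

_BASES = np.array(list("ACGT"))
_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one planted read (positions are read coordinates)."""

    read_id: str
    ref_name: str
    start: int            # 0-based start of the truth window on the forward ref
    strand: str
    mismatches: int       # planted substitutions
    n_count: int          # injected Ns
    insert: Optional[int] = None            # pairs only: outermost span
    converted_positions: tuple[int, ...] = ()  # bisulfite only


def gen_reference(length: int, gc: float = 0.5, rng_seed: int = 0,
                  name: str = "ref1") -> ReferenceSeq:
    """i.i.d. random reference with P(G)+P(C) = ``gc`` split evenly."""
    if length < 1:
        raise ParameterError("reference length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ParameterError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(rng_seed)
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return ReferenceSeq(name=name, seq=seq)


def _mutate(seq: str, n_subs: int, n_rate: float, rng: np.random.Generator,
            bisulfite_safe: bool = False) -> tuple[str, int, int, set[int]]:
    """Apply exactly n_subs substitutions plus Bernoulli(n_rate) Ns at
    disjoint positions; returns (new seq, subs, n_count, touched sub sites).

    With ``bisulfite_safe`` a C never substitutes to T (in read space), so
    the substitution stays a mismatch even under the bisulfite match rule.
    """
    bases = list(seq)
    L = len(bases)
    sub_sites = set(rng.choice(L, size=n_subs, replace=False)) if n_subs else set()
    for i in sub_sites:
        choices = _OTHER[bases[i]]
        if bisulfite_safe and bases[i] == "C":
            choices = [c for c in choices if c != "T"]
        bases[i] = choices[rng.integers(len(choices))]
    n_count = 0
    if n_rate > 0:
        for i in range(L):
            if i not in sub_sites and rng.random() < n_rate:
                bases[i] = "N"
                n_count += 1
    return "".join(bases), n_subs, n_count, sub_sites


def plant_reads(ref: ReferenceSeq, n: int, read_len: int,
                mismatches_per_read: int = 0, n_rate: float = 0.0,
                rng_seed: int = 0, id_prefix: str = "r",
                with_quality: bool = False, bisulfite_safe: bool = False
                ) -> tuple[list[Read], list[PlantedTruth]]:
    """Plant ``n`` reads of ``read_len`` at uniform starts and strands, each
    carrying exactly ``mismatches_per_read`` substitutions plus Ns injected
    per base at rate ``n_rate`` (disjoint sites).

    Set ``bisulfite_safe`` for reads destined for
    :func:`bisulfite_convert`: substitutions then avoid C->T so they remain
    countable mismatches under the bisulfite match rule."""
    if read_len > ref.length:
        raise ParameterError("read_len exceeds reference length")
    if read_len < 1 or n < 0:
        raise ParameterError("invalid n / read_len")
    if mismatches_per_read < 0 or mismatches_per_read >= read_len:
        raise ParameterError("mismatches_per_read must be in [0, read_len)")
    if not 0.0 <= n_rate <= 1.0:
        raise ParameterError("n_rate must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    reads, truths = [], []
    for i in range(n):
        start = int(rng.integers(0, ref.length - read_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        window = ref.seq[start:start + read_len]
        true_read = window if strand == "+" else revcomp(window)
        seq, subs, n_count, _ = _mutate(true_read, mismatches_per_read,
                                        n_rate, rng,
                                        bisulfite_safe=bisulfite_safe)
        rid = f"{id_prefix}{i}"
        qual = "I" * read_len if with_quality else None
        reads.append(Read(id=rid, seq=seq, qual=qual))
        truths.append(PlantedTruth(read_id=rid, ref_name=ref.name,
                                   start=start, strand=strand,
                                   mismatches=subs, n_count=n_count))
    return reads, truths


def bisulfite_convert(reads: Sequence[Read], truths: Sequence[PlantedTruth],
                      ref: ReferenceSeq, conversion_rate: float,
                      rng_seed: int = 0
                      ) -> tuple[list[Read], list[PlantedTruth]]:
    """Simulate bisulfite treatment of a directional library: each read C
    that still matches its truth-window base converts to T independently
    with probability ``conversion_rate``.

    Converted positions are recorded in the truth and are NOT counted as
    mismatches — they must be free under the bisulfite match rule. Cs
    created by planted substitutions are left alone so the substitution
    stays a guaranteed mismatch in every mode.
    """
    if not 0.0 <= conversion_rate <= 1.0:
        raise ParameterError("conversion_rate must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    out_reads, out_truths = [], []
    for read, truth in zip(reads, truths):
        window = ref.seq[truth.start:truth.start + len(read.seq)]
        true_read = window if truth.strand == "+" else revcomp(window)
        bases = list(read.seq)
        converted = []
        for i, (b, t) in enumerate(zip(bases, true_read)):
            if b == "C" and t == "C" and rng.random() < conversion_rate:
                bases[i] = "T"
                converted.append(i)
        out_reads.append(Read(id=read.id, seq="".join(bases), qual=read.qual,
                              mate_index=read.mate_index))
        out_truths.append(replace(truth, converted_positions=tuple(converted)))
    return out_reads, out_truths


def plant_pairs(ref: ReferenceSeq, n_pairs: int, read_len: int,
                insert_mean: float, insert_sd: float, mismatches: int = 0,
                rng_seed: int = 0, id_prefix: str = "p"
                ) -> tuple[list[Read], list[Read], list[PlantedTruth]]:
    """Plant FR-oriented mate pairs: mate 1 forward at ``s``, mate 2 the
    reverse complement of the window ending at ``s + insert``, with the
    insert drawn from a rounded normal clamped to [read_len, ref length].
    Reads carry constant high (Q40) qualities.
    """
    if n_pairs < 1:
        raise ParameterError("n_pairs must be >= 1")
    if insert_mean < read_len:
        raise ParameterError("insert_mean must be >= read_len")
    if read_len > ref.length:
        raise ParameterError("read_len exceeds reference length")
    if mismatches < 0 or mismatches >= read_len:
        raise ParameterError("mismatches must be in [0, read_len)")
    rng = np.random.default_rng(rng_seed)
    reads1, reads2, truths = [], [], []
    qual = "I" * read_len
    for i in range(n_pairs):
        insert = int(round(rng.normal(insert_mean, insert_sd)))
        insert = max(read_len, min(insert, ref.length))
        s = int(rng.integers(0, ref.length - insert + 1))
        w1 = ref.seq[s:s + read_len]
        w2 = ref.seq[s + insert - read_len:s + insert]
        seq1, m1, _, _ = _mutate(w1, mismatches, 0.0, rng)
        seq2, m2, _, _ = _mutate(revcomp(w2), mismatches, 0.0, rng)
        pid = f"{id_prefix}{i}"
        reads1.append(Read(id=f"{pid}/1", seq=seq1, qual=qual, mate_index=1))
        reads2.append(Read(id=f"{pid}/2", seq=seq2, qual=qual, mate_index=2))
        truths.append(PlantedTruth(read_id=f"{pid}/1", ref_name=ref.name,
                                   start=s, strand="+", mismatches=m1,
                                   n_count=0, insert=insert))
        truths.append(PlantedTruth(read_id=f"{pid}/2", ref_name=ref.name,
                                   start=s + insert - read_len, strand="-",
                                   mismatches=m2, n_count=0, insert=insert))
    return reads1, reads2, truths


def write_truth_tsv(truths: Sequence[PlantedTruth], sink: IO[str]) -> int:
    """TSV sidecar: read_id, ref, start, strand, mismatches, Ns, insert,
    converted read positions (comma-joined)."""
    sink.write("read_id\tref\tstart\tstrand\tmismatches\tn_count\t"
               "insert\tconverted_positions\n")
    for t in truths:
        conv = ",".join(map(str, t.converted_positions))
        ins = "" if t.insert is None else str(t.insert)
        sink.write(f"{t.read_id}\t{t.ref_name}\t{t.start}\t{t.strand}\t"
                   f"{t.mismatches}\t{t.n_count}\t{ins}\t{conv}\n")
    return len(truths)
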