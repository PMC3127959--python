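# chunkalign

A map-only, chunk-parallel **seed-and-extend short-read aligner** for
ungapped mapping under a mismatch budget, with bisulfite and paired-end
modes, strict bad-base accounting, and SAM / BED6 output.

## Who this is for

Anyone who needs a transparent, fully testable reference implementation of
the classic ungapped mapping stack used by tools such as RMAP and
CloudBurst-era mappers: short reads (FASTA or FASTQ) are placed on a
reference genome allowing up to *k* substitutions, reads are classified as
uniquely mapped / ambiguous / unmapped, and the whole run is partitioned
into independent chunks so that results survive partial failures and runs
parallelise trivially.

## The algorithm

**Seeding (pigeonhole partition).** A read of length *L* aligned with at
most *k* substitutions is split into *k*+1 disjoint contiguous segments of
span ⌊*L*/(*k*+1)⌋. By the pigeonhole principle at least one segment matches
the reference exactly, so candidate placements are found by exact lookup of
each segment in a hash index over all reference windows — full sensitivity,
no heuristics. RMAP-style spaced `1`/`0` seed masks are available as an
opt-in alternative (`--seed-mask`), without the sensitivity guarantee.

**Extension.** Each candidate placement is verified by a position-wise
Hamming comparison with early termination once the budget *k* is exceeded
(strictly ungapped; no indels). A position counts as a mismatch when the
bases differ under the active mode's rule, **or** when either base is N,
**or** when a quality cutoff is set and the read base's Phred score falls
below it (the *bad-base rule*: an uncallable base can never support a
match).

**Modes.**

- *plain* — literal base equality;
- *bisulfite* (directional libraries) — a read T over a reference C is a
  match (unmethylated-C conversion) but a read C over a reference T is not;
  bottom-strand reads are handled by reverse complementing the read, which
  mirrors the rule into G→A space. Seeds are built in the corresponding
  converted keyspace so conversions never break a seed;
- *paired-end* — each mate's full candidate set is combined under an FR
  orientation constraint with the outermost-to-outermost insert confined to
  `[min_insert, max_insert]`; pairs are ranked by combined mismatch count.

**Classification.** A read is *unique* when exactly one placement attains
its minimum mismatch count, *ambiguous* with two or more best placements,
*unmapped* with none within budget. Always:
`unique + ambiguous + unmapped == total`.

**Map-only execution.** The read stream is cut into balanced contiguous
chunks; every chunk is aligned independently against the whole reference and
the merged output is just the concatenation of the succeeded chunks —
no reduce/sort phase exists, so the result multiset is invariant under the
number of splits and workers, and a failed chunk costs only its own reads.
The default split count is `workers − 1`.

## Worked example

Generate a toy dataset with the built-in simulator and map it:

```python
from chunkalign import gen_reference, plant_reads, write_fastq

ref = gen_reference(2000, gc=0.5, rng_seed=7)
with open("ref.fa", "w") as fh:
    fh.write(f">{ref.name}\n{ref.seq}\n")
reads, truths = plant_reads(ref, 50, 36, mismatches_per_read=2,
                            rng_seed=8, with_quality=True)
with open("reads.fq", "w") as fh:
    write_fastq(reads, fh)
```

```
$ chunkalign map --reference ref.fa --reads reads.fq -k 3 --out out.sam
INFO chunkalign: loaded 1 reference sequence(s), 50 read(s)
INFO chunkalign: wrote 50 record(s) to out.sam
chunk_id  state      reads  elapsed_s  message
0         succeeded  50     0.003
summary   mismatch   total=50  unique=50  ambiguous=0  unmapped=0
```

All 50 planted reads map uniquely (each carries 2 substitutions, within the
budget of 3). The SAM output starts:

```
@HD	VN:1.6	SO:unsorted
@SQ	SN:ref1	LN:2000
r0	16	ref1	1414	255	36M	*	0	0	CGGCCACC...	IIII...	NM:i:2
```

Read `r0` maps to the reverse strand (FLAG 16) at 1-based position 1414 with
2 mismatches (`NM:i:2`) — exactly the planted truth. `chunkalign bsmap`
(bisulfite) and `chunkalign pemap` (paired-end, two `--reads` files plus
`--min-insert`/`--max-insert`) work the same way; `--out-format bed` writes
BED6 instead of SAM. Exit status 0 means every chunk succeeded, 3 signals
partial results after chunk failures, 4 total failure.

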