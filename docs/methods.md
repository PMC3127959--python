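# Methods

## Model and assumptions

chunkalign performs ungapped alignment of short reads to a reference under a
hard substitution budget *k*. The model deliberately excludes indels and any
probabilistic scoring: a placement is characterised entirely by its
(reference, start, strand) and its mismatch count, and ranking is by
mismatch count alone. This matches the semantics of classical
mismatch-budget mappers and makes the implementation exactly checkable
against an exhaustive Hamming scan, which the test suite and the acceptance
script exploit.

### Seeding

The default scheme is the pigeonhole partition: for read length *L* and
budget *k*, the read prefix is tiled by *k*+1 contiguous seeds of span
⌊*L*/(*k*+1)⌋. Any placement with ≤ *k* substitutions must contain one exact
seed (provided no N falls under a seed — an N in a read segment disables
that one seed but the other *k* segments still cover all placements with
< *k* substitutions). The scheme is fully sensitive, which lets the test
suite demand **equality**, not approximation, with the brute-force oracle.

Spaced seed masks (`1` = care, `0` = don't-care) are accepted as an
alternative; their sensitivity depends on the mask and is *not* guaranteed,
so they are opt-in and excluded from the oracle-equivalence guarantees.

The index maps every usable reference window (no N under a care position) to
its (sequence, position) list, one index per (window shape, keyspace), built
lazily and cached. Reads of different lengths need different pigeonhole
spans; grouping by length is implicit in the cache. The reverse strand is
handled by reverse complementing the read, not by double-indexing the
reference, halving index memory.

### Extension and the bad-base rule

Extension is a per-position comparison with early exit once the running
count exceeds *k*. The mismatch predicate, in priority order:

1. read base N or reference base N → mismatch (bad bases can never support
   a placement; this is the accounting rule that distinguishes this
   implementation from mappers that ignore uncallable bases);
2. with `--qual-cutoff Q` set and the read carrying qualities, a base with
   Phred < Q → mismatch (disabled by default; Sanger Phred+33 assumed);
3. otherwise the mode rule: literal equality (plain), or the asymmetric
   bisulfite rule below.

### Bisulfite mode

A directional (two-strand) library is assumed: every read is C→T-converted
relative to its strand of origin. Original-top-strand reads are compared
forward against the reference with "read T over reference C" free;
original-bottom-strand reads are reverse complemented, under which the same
biology appears as "read A over reference G" free. The converse events
(read C over reference T; read G over reference A) remain mismatches — the
asymmetry is load-bearing and tested with directed vectors. Seed keys are
formed after rewriting both read and reference into the corresponding
converted keyspace (C→T for forward search, G→A for the reverse search), so
conversions cannot break seeds and the pigeonhole guarantee carries over.
Non-directional (four-strand) protocols are out of scope in this version.

### Paired-end resolution

Both mates are aligned independently and their **full** candidate sets
(every placement within budget, before uniqueness filtering) are crossed:
a valid pair lies on one reference, on opposite strands with the leftmost
mate forward (FR), with the outermost-to-outermost span inside
`[min_insert, max_insert]` (defaults 1 and 1000). Pairs are ranked by
combined mismatch count with ties broken by (reference, leftmost start,
mate-1 strand), making output deterministic. Statuses: concordant_unique /
concordant_ambiguous (≥ 2 best pairings) / discordant (both mates map, no
valid pairing) / unmapped (a mate has no placement).

### Classification

Uniqueness is defined at the minimum-mismatch stratum: exactly one
best-scoring placement ⇒ unique, regardless of worse placements. This makes
the unique-map count a well-defined accuracy metric and is the convention
the summary line reports.

### Map-only engine

`plan_splits` cuts the read list into balanced contiguous ranges (sizes
differ by at most one read, or one pair in paired mode; pairs never straddle
a boundary). Each chunk aligns against the whole reference with a shared
read-only index cache; merging concatenates succeeded chunks in chunk order.
There is deliberately no cross-chunk operation of any kind, which is what
the split-invariance property tests: the result multiset must be identical
for any (num_splits, workers) combination. A chunk failure is caught,
reported in the run report, and costs only that chunk's reads; the CLI then
exits with status 3 (partial) instead of 0. Concurrency uses a thread pool —
the contract is chunk independence, not a particular parallel mechanism.
The default split count is `max(1, workers − 1)`, a rule of thumb that
leaves one slot of headroom so a straggler chunk does not serialize the run.

## Synthetic data generator

All experiments run on generated inputs with exact ground truth. The
generator uses numpy's `default_rng` (PCG64), so every fixture is
reproducible from a 64-bit seed on any platform.

* `gen_reference(length, gc, seed)` — i.i.d. bases, GC split evenly.
* `plant_reads(...)` — uniform start/strand; **exactly** the requested
  substitutions (never recreating the original base) plus Ns at a per-base
  rate at disjoint sites, so planted mismatch counts are exact, not
  stochastic. `bisulfite_safe=True` additionally forbids C→T substitutions
  in read space, keeping planted substitutions countable under the
  bisulfite rule.
* `bisulfite_convert(...)` — converts read Cs that still match a reference
  C to T with the given probability, recording converted positions;
  conversions are never counted as mismatches.
* `plant_pairs(...)` — FR pairs with insert drawn from a rounded normal
  clamped to [read_len, reference length], constant Q40 qualities.

What the generator does **not** emulate: sequencer error profiles
(quality-dependent miscalls, indels), genomic repeat structure, coverage
biases, or incomplete/strand-specific bisulfite conversion at realistic
rates. Passing tests therefore demonstrate algorithmic correctness of the
mapping rules — not mapping accuracy on real libraries, where repeats and
indels dominate the hard cases.

## Problem sizes and tolerances

The validation suite and `scripts/acceptance.py` use desk-scale versions of
realistic regimes, chosen so the whole suite runs in well under a minute of
CPU per component:

* oracle equivalence: 50 random instances, references 5–10 kb, reads
  25–100 nt, k ∈ {0..3}, exact set equality required (both modes);
* bad-base rule: 1,000 reads, increment must be exactly 1;
* pigeonhole sensitivity: 10,000 planted 36 nt reads (0–3 substitutions)
  on a 200 kb reference, zero misses allowed;
* split invariance: 20,000 reads, num_splits ∈ {1, 2, 7, 32} × workers
  ∈ {1, 4}, exact multiset equality; injected single-chunk failure must
  reproduce the union of the surviving chunks' standalone outputs;
* paired-end: 2,000 pairs, insert ~ N(300, 30²), window [210, 390] (±3σ,
  so ≈ 99.7% of planted inserts fall inside; the acceptance bound is
  ≥ 99%); 200 pairs planted at a fixed insert of 500 must all be
  discordant under that window.

Deterministic choices worth noting: candidate placements are de-duplicated
by (reference, start, strand) before extension; hits and pair rankings are
sorted lexicographically so reruns are byte-identical after a stable sort;
MAPQ is emitted as 255 (unavailable) since the model computes no mapping
quality; SAM conversion (+1, reverse-complemented SEQ on '−' hits) happens
only at emission, all internal coordinates being 0-based half-open.

## Known limitations

* Ungapped only: a single indel shifts every downstream base and typically
  unmaps the read.
* Bisulfite mode is single-end and directional-protocol only.
* The quality cutoff treats qualities as Sanger Phred+33; no
  Solexa/Phred+64 detection.
* Spaced-seed sensitivity is the user's responsibility.
* Thread-based workers share one Python interpreter; the engine's value is
  its failure isolation and split semantics, not raw multicore speedup.
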