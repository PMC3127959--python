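import pytest
from hypothesis import given, settings, strategies as st

from chunkalign.align import (AlignmentHit, PairConstraint, align_pair,
                              classify_run, count_mismatches, find_candidates,
                              seed_and_extend)
from chunkalign.errors import ParameterError
from chunkalign.io_formats import Read, ReferenceSeq, revcomp
from chunkalign.seeding import IndexCache
from chunkalign.simulate import gen_reference, plant_reads

from oracle import brute_force_best


def mkread(seq, rid="r", qual=None):
    return Read(id=rid, seq=seq, qual=qual)


def mkhit(ref="c", start=0, strand="+", mm=0, length=76, rid="r"):
    return AlignmentHit(ref_name=ref, start=start, strand=strand,
                        read_id=rid, mismatches=mm, read_len=length)


class TestCountMismatches:
    REF = ReferenceSeq("c", "ACGTACGT")

    def test_identity(self):
        assert count_mismatches(mkread("ACGT"), self.REF, 0, "+") == 0

    def test_read_n_counts_as_mismatch(self):
        assert count_mismatches(mkread("ACNT"), self.REF, 0, "+") == 1

    def test_reference_n_counts_as_mismatch(self):
        ref = ReferenceSeq("c", "ANGT")
        assert count_mismatches(mkread("ACGT"), ref, 0, "+") == 1

    def test_reverse_strand_uses_revcomp(self):
        read = mkread(revcomp("CGTA"))  # "TACG"
        assert count_mismatches(read, self.REF, 1, "-") == 0
        assert count_mismatches(read, self.REF, 1, "+") == 4

    def test_budget_exceeded_returns_none(self):
        assert count_mismatches(mkread("TTTT"), self.REF, 0, "+",
                                budget=2) is None

    def test_quality_cutoff_marks_bad_base(self):
        read = mkread("ACGT", qual="I!II")  # '!' = Phred 0
        assert count_mismatches(read, self.REF, 0, "+",
                                bad_qual_cutoff=20) == 1
        assert count_mismatches(read, self.REF, 0, "+") == 0

    def test_bisulfite_read_t_over_ref_c_matches(self):
        assert count_mismatches(mkread("ATGT"), self.REF, 0, "+",
                                mode="bisulfite") == 0

    def test_bisulfite_read_c_over_ref_t_is_mismatch(self):
        ref = ReferenceSeq("c", "ATGT")
        assert count_mismatches(mkread("ACGT"), ref, 0, "+",
                                mode="bisulfite") == 1

    def test_bisulfite_reverse_strand_ga_space(self):
        # bottom-strand read: revcomp(read) 'A' over reference 'G' is free
        ref = ReferenceSeq("c", "GGTA")
        read = mkread(revcomp("AGTA"))  # oriented A over ref G at pos 0
        assert count_mismatches(read, ref, 0, "-", mode="bisulfite") == 0
        # ...but oriented G over reference A is not
        ref2 = ReferenceSeq("c", "AGTA")
        read2 = mkread(revcomp("GGTA"))
        assert count_mismatches(read2, ref2, 0, "-", mode="bisulfite") == 1

    def test_out_of_range_start(self):
        with pytest.raises(ParameterError):
            count_mismatches(mkread("ACGT"), self.REF, 6, "+")


class TestSeedAndExtend:
    def test_exact_planted_read_is_unique_at_truth(self, small_ref,
                                                   small_cache):
        read = mkread(small_ref.seq[100:125])
        res = seed_and_extend(read, small_cache, k=3)
        assert res.status == "unique"
        assert res.best_mismatches == 0
        assert res.hits[0].placement() == (small_ref.name, 100, "+")

    def test_twice_planted_read_is_ambiguous(self):
        core = gen_reference(400, rng_seed=9).seq
        dup = core[50:75]
        ref = ReferenceSeq("c", core + dup)
        res = seed_and_extend(mkread(dup), IndexCache([ref]), k=2)
        assert res.status == "ambiguous"
        assert len(res.hits) == 2
        assert {h.start for h in res.hits} == {50, 400}

    def test_garbage_read_unmapped(self, small_cache):
        res = seed_and_extend(mkread("A" * 30 + "C" * 30), small_cache, k=1)
        assert res.status == "unmapped" and res.hits == []

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_oracle_equivalence_random_instances(self, k):
        """Best-hit sets equal an exhaustive Hamming scan on both strands."""
        ref = gen_reference(3000, rng_seed=100 + k)
        cache = IndexCache([ref])
        reads, _ = plant_reads(ref, 30, 36, mismatches_per_read=k,
                               rng_seed=200 + k)
        for read in reads:
            res = seed_and_extend(read, cache, k)
            status, best, places = brute_force_best(read, [ref], k)
            assert res.status == status
            assert res.best_mismatches == best
            assert {h.placement() for h in res.hits} == places

    def test_strand_symmetry(self, small_ref, small_cache):
        reads, _ = plant_reads(small_ref, 20, 30, mismatches_per_read=1,
                               rng_seed=77)
        for read in reads:
            fwd = seed_and_extend(read, small_cache, k=2)
            rc = seed_and_extend(mkread(revcomp(read.seq), rid=read.id),
                                 small_cache, k=2)
            flip = {"+": "-", "-": "+"}
            assert {(h.ref_name, h.start, flip[h.strand], h.mismatches)
                    for h in fwd.hits} == \
                   {(h.ref_name, h.start, h.strand, h.mismatches)
                    for h in rc.hits}

    def test_mapped_count_monotone_in_k(self, small_ref, small_cache):
        reads, _ = plant_reads(small_ref, 50, 36, mismatches_per_read=3,
                               rng_seed=5)
        mapped = []
        for k in range(4):
            res = [seed_and_extend(r, small_cache, k) for r in reads]
            c = classify_run(res)
            mapped.append(c.unique + c.ambiguous)
        assert mapped == sorted(mapped)

    def test_single_n_raises_best_mismatches_by_one(self, small_ref,
                                                    small_cache):
        read = mkread(small_ref.seq[500:530])
        res0 = seed_and_extend(read, small_cache, k=2)
        damaged = mkread(read.seq[:7] + "N" + read.seq[8:])
        res1 = seed_and_extend(damaged, small_cache, k=2)
        assert res0.best_mismatches == 0
        assert res1.best_mismatches == 1

    def test_find_candidates_deduplicates_and_sorts(self, small_ref,
                                                    small_cache):
        read = mkread(small_ref.seq[0:40])
        hits = find_candidates(read, small_cache, k=3)
        places = [h.placement() for h in hits]
        assert len(places) == len(set(places))
        assert places == sorted(places)


class TestAlignPair:
    def test_concordant_unique_with_insert_arithmetic(self):
        h1 = [mkhit(start=100, strand="+")]
        h2 = [mkhit(start=300, strand="-")]
        res = align_pair("p", h1, h2, PairConstraint(100, 500))
        assert res.status == "concordant_unique"
        assert res.insert == 300 + 76 - 100 == 276
        assert res.combined_mismatches == 0

    def test_insert_outside_window_is_discordant(self):
        h1 = [mkhit(start=100, strand="+")]
        h2 = [mkhit(start=300, strand="-")]
        res = align_pair("p", h1, h2, PairConstraint(100, 200))
        assert res.status == "discordant"

    def test_wrong_orientation_is_discordant(self):
        # reverse mate leftmost: RF, not FR
        h1 = [mkhit(start=300, strand="+")]
        h2 = [mkhit(start=100, strand="-")]
        assert align_pair("p", h1, h2,
                          PairConstraint(1, 1000)).status == "discordant"

    def test_mate_unmapped(self):
        res = align_pair("p", [mkhit()], [], PairConstraint(1, 1000))
        assert res.status == "unmapped"

    def test_ambiguous_pairing(self):
        h1 = [mkhit(start=100, strand="+"), mkhit(start=600, strand="+")]
        h2 = [mkhit(start=300, strand="-"), mkhit(start=800, strand="-")]
        res = align_pair("p", h1, h2, PairConstraint(100, 500))
        assert res.status == "concordant_ambiguous"
        # deterministic tie-break: leftmost pairing chosen
        assert (res.hit1.start, res.hit2.start) == (100, 300)

    def test_invalid_window(self):
        with pytest.raises(ParameterError):
            PairConstraint(500, 100)


class TestClassifyRun:
    def test_empty(self):
        import dataclasses
        assert dataclasses.astuple(classify_run([])) == (0, 0, 0, 0)

    def test_planted_mixture(self, small_ref, small_cache):
        uniq, _ = plant_reads(small_ref, 10, 30, rng_seed=1, id_prefix="u")
        dup_seq = small_ref.seq[10:40]
        ref2 = ReferenceSeq("c", small_ref.seq + dup_seq)
        cache = IndexCache([ref2])
        garbage = [mkread("ACGT" * 8, rid=f"g{i}") for i in range(3)]
        dups = [mkread(dup_seq, rid=f"d{i}") for i in range(2)]
        results = [seed_and_extend(r, cache, 0)
                   for r in uniq + dups + garbage]
        counts = classify_run(results)
        assert (counts.unique, counts.ambiguous, counts.unmapped,
                counts.total) == (10, 2, 3, 15)
        assert counts.unique + counts.ambiguous + counts.unmapped \
            == counts.total
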