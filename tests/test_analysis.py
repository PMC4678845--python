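"""Reference conversion, alignment, pileup and the methylation/error statistics."""

import math

import numpy as np
import pytest

from bsforge import (
    MethylatedTemplate,
    TreatmentCondition,
    align_bisulfite,
    align_reads,
    build_pileup,
    c_content,
    conversion_rate,
    cpg_methylation,
    error_rates,
    insilico_convert,
    locus_success_summary,
    locus_union_summary,
    make_amplicon_template,
    treat_pool,
)

from conftest import exhaustive_dp_score, make_pileup, mutate_read


class TestInsilicoConvert:
    @pytest.mark.parametrize(
        "seq,converted,cpgs",
        [
            ("ACGTCC", "ATGTTT", (1,)),
            ("ATGTA", "ATGTA", ()),
            ("CGCG", "TGTG", (0, 2)),
        ],
    )
    def test_examples(self, seq, converted, cpgs):
        ref = insilico_convert(seq)
        assert ref.converted == converted
        assert ref.cpg_sites == cpgs

    def test_differences_are_exactly_c_positions(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        ref = insilico_convert(seq)
        diffs = {i for i, (a, b) in enumerate(zip(ref.original, ref.converted)) if a != b}
        assert diffs == {i for i, b in enumerate(seq) if b == "C"}
        assert "C" not in ref.converted

    def test_ambiguity_codes_rejected_with_positions(self):
        with pytest.raises(ValueError, match=r"\(2, 'N'\)"):
            insilico_convert("ACNGT")


class TestAlignment:
    def test_prefix_read_aligns_at_zero(self):
        ref = insilico_convert("ACGTACGTACGTACGT")
        aln = align_bisulfite("ACGTACGT", ref)
        assert aln.offset == 0
        assert aln.score == 8
        assert aln.pairs == [(i, i) for i in range(8)]

    def test_converted_read_has_no_scoring_mismatch(self):
        # T wherever the reference original holds a (non-CpG) C is not a
        # mismatch under the collapsed alphabet
        seq = "ACTCATCGAC"
        ref = insilico_convert(seq)
        read = seq.replace("C", "T")
        aln = align_bisulfite(read, ref)
        assert aln.offset == 0
        assert aln.score == len(read)
        assert aln.collapsed_identity == 1.0

    def test_methylated_c_read_also_matches(self):
        ref = insilico_convert("ACGTACGT")
        aln = align_bisulfite("ACGTACGT", ref)  # unconverted Cs in the read
        assert aln.score == 8

    def test_internal_offset_found(self):
        ref = insilico_convert("GGGGGGGGGGACGTACGTAAGGGGGGG")
        aln = align_bisulfite("ACGTACGTAA", ref)
        assert aln.offset == 10

    def test_empty_read_rejected(self):
        ref = insilico_convert("ACGT")
        with pytest.raises(ValueError, match="empty"):
            align_bisulfite("", ref)

    def test_banded_matches_exhaustive_dp(self, rng):
        # spec-style sweep: reads sampled off a 200 nt reference
        ref_seq = "".join(rng.choice(list("ACGT"), size=200))
        ref = insilico_convert(ref_seq)
        for _ in range(100):
            read = mutate_read(rng, ref_seq, 30)
            aln = align_bisulfite(read, ref)
            assert aln.score == exhaustive_dp_score(read, ref_seq)

    def test_low_identity_reads_filtered_and_counted(self, rng):
        ref = insilico_convert("ACGTACGTACGTACGTACGTACGT")
        junk = "".join(rng.choice(list("GC"), size=24))
        alns, stats = align_reads(["ACGTACGTACGTACGTACGTACGT", junk], ref)
        assert stats["n_aligned"] == 1
        assert stats["n_filtered"] == 1


class TestPileup:
    def test_single_read_depth(self):
        ref = insilico_convert("ACGTACGTAC")
        alns, _ = align_reads(["ATGTA"], ref)
        pile = build_pileup(alns, ref)
        assert list(pile.depth) == [1] * 5 + [0] * 5
        assert pile.depth.sum() == pile.counts.sum()

    def test_overlap_depth_and_merge_invariance(self):
        ref = insilico_convert("ACGTACGTACGT")
        reads = ["ATGTATGT", "ATGTATGTATGT", "ATGT"]
        alns, _ = align_reads(reads, ref)
        whole = build_pileup(alns, ref)
        assert list(whole.depth) == [3, 3, 3, 3, 2, 2, 2, 2, 1, 1, 1, 1]
        # shard + merge and read order leave the pileup unchanged
        a, _ = align_reads(reads[:1], ref)
        b, _ = align_reads(reads[1:][::-1], ref)
        merged = build_pileup(a, ref).merge(build_pileup(b, ref))
        assert np.array_equal(merged.counts, whole.counts)

    def test_majority_base_is_converted_reference(self, rng):
        t = make_amplicon_template(length=200, n_cpg=4, cpg_methylation=0.0, seed=3)
        pool = treat_pool(t, TreatmentCondition("full", 1.0, 1.0), 500, seed=1)
        reads = [s.clean_copy_seq()[:150] for s in pool]
        ref = insilico_convert(t.seq)
        alns, stats = align_reads(reads, ref)
        assert stats["n_aligned"] == 500
        pile = build_pileup(alns, ref)
        covered = pile.depth > 0
        majority = pile.counts.argmax(axis=1)
        expected = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in ref.converted])
        assert np.array_equal(majority[covered], expected[covered])


class TestMethylation:
    def test_all_c_and_all_t_extremes(self):
        pile = make_pileup("ACGT", {1: {"C": 20}})
        rep = cpg_methylation(pile)
        assert rep.table.loc[0, "fraction"] == 1.0
        pile = make_pileup("ACGT", {1: {"T": 20}})
        assert cpg_methylation(pile).table.loc[0, "fraction"] == 0.0

    def test_other_bases_excluded_from_fraction(self):
        pile = make_pileup("ACGT", {1: {"C": 6, "T": 4, "G": 5}})
        row = cpg_methylation(pile).table.loc[0]
        assert row["fraction"] == pytest.approx(0.6)
        assert row["other"] == 5

    def test_low_depth_flagged_not_dropped(self):
        pile = make_pileup("ACGT", {1: {"C": 3}})
        rep = cpg_methylation(pile, min_depth=10)
        assert rep.n_sites == 1 and bool(rep.table.loc[0, "low_depth"])

    def test_binomial_recovery_at_depth_1e4(self):
        # molecules treated at full conversion with 70% CpG methylation
        t = make_amplicon_template(length=160, n_cpg=3, cpg_methylation=0.7, seed=6)
        pool = treat_pool(t, TreatmentCondition("full", 1.0, 1.0), 10_000, seed=2)
        reads = [s.clean_copy_seq() for s in pool]
        ref = insilico_convert(t.seq)
        alns, _ = align_reads(reads, ref)
        rep = cpg_methylation(build_pileup(alns, ref))
        se = math.sqrt(0.7 * 0.3 / 10_000)
        for frac in rep.table["fraction"]:
            assert abs(frac - 0.7) <= 3 * se


class TestConversionAndErrors:
    def test_conversion_arithmetic(self):
        # 98 T + 2 C summed over non-CpG C sites -> 98.0%
        pile = make_pileup("ACTCAT", {1: {"T": 50, "C": 1}, 3: {"T": 48, "C": 1}})
        assert conversion_rate(pile) == pytest.approx(98.0)

    def test_cpg_positions_excluded_from_conversion(self):
        # CpG site fully methylated (all C) but non-CpG sites fully converted
        pile = make_pileup("ACGTCA", {1: {"C": 30}, 4: {"T": 30}})
        assert conversion_rate(pile) == pytest.approx(100.0)

    def test_no_eligible_positions_is_undefined(self):
        pile = make_pileup("ACGT", {1: {"C": 10}})  # only a CpG C
        assert conversion_rate(pile) is None

    def test_error_free_pileup(self):
        pile = make_pileup("AGT", {0: {"A": 10}, 1: {"G": 10}, 2: {"T": 10}})
        rep = error_rates(pile, total_cycles=70)
        assert rep.overall_error_pct == 0.0
        assert rep.per_cycle_rate == 0.0
        assert all(v == 0.0 for v in rep.per_base_error.values())

    def test_cumulative_error_to_per_cycle_rate(self):
        # 1000 observations at original A/G/T with 4 mismatches -> 0.4%,
        # i.e. ~6e-5/cycle over 70 cycles
        pile = make_pileup(
            "AGT",
            {0: {"A": 330, "G": 2}, 1: {"G": 334}, 2: {"T": 332, "C": 2}},
        )
        rep = error_rates(pile, total_cycles=70)
        assert rep.overall_error_pct == pytest.approx(0.4)
        assert rep.per_cycle_rate == pytest.approx(0.4 / 100 / 70)
        assert float(f"{rep.per_cycle_rate:.0e}") == 6e-5
        # the identity per_cycle_rate * total_cycles == cumulative fraction
        assert rep.per_cycle_rate * 70 == pytest.approx(0.004, abs=0)

    def test_c_to_t_events_never_count_as_errors(self):
        base_obs = {
            0: {"A": 100, "G": 1},
            1: {"T": 99, "C": 1},  # original non-CpG C: conversion signal
            2: {"G": 100},
            3: {"T": 100, "A": 1},
        }
        pile = make_pileup("ACAT", base_obs)
        rep = error_rates(pile, total_cycles=70)
        # inject many extra C->T events at the original-C position
        more = {k: dict(v) for k, v in base_obs.items()}
        more[1]["T"] += 500
        pile2 = make_pileup("ACAT", more)
        rep2 = error_rates(pile2, total_cycles=70)
        assert rep2.overall_error_pct == rep.overall_error_pct
        assert rep2.conversion_pct != rep.conversion_pct

    def test_per_base_breakdown_only_g_a_t(self):
        pile = make_pileup(
            "ACGT",
            {0: {"A": 99, "C": 1}, 1: {"T": 100}, 2: {"G": 98, "T": 2}, 3: {"T": 100}},
        )
        rep = error_rates(pile, total_cycles=10)
        assert set(rep.per_base_error) == {"G", "A", "T"}
        assert rep.per_base_error["A"] == pytest.approx(1.0)
        assert rep.per_base_error["G"] == pytest.approx(2.0)
        assert rep.per_base_error["T"] == pytest.approx(0.0)

    def test_zero_cycles_rejected(self):
        pile = make_pileup("AGT", {0: {"A": 1}})
        with pytest.raises(ValueError):
            error_rates(pile, total_cycles=0)


class TestCContentAndLoci:
    @pytest.mark.parametrize(
        "length,n_c,expected",
        [(160, 20, 12.5), (624, 152, 24.4), (348, 101, 29.0), (20, 8, 40.0)],
    )
    def test_c_content_worked_examples(self, length, n_c, expected):
        seq = "C" * n_c + "A" * (length - n_c)
        res = c_content(seq)
        assert res.count == n_c
        assert res.pct_rounded == expected

    def test_c_content_window_and_edge_cases(self):
        assert c_content("AAAA").pct == 0.0
        assert c_content("AACCAA", window=(2, 4)).pct == 100.0
        with pytest.raises(ValueError):
            c_content("")
        with pytest.raises(ValueError):
            c_content("ACGT", window=(2, 2))

    def test_locus_success_percentages(self):
        assert locus_success_summary([True] * 15 + [False] * 9).percent == 62.5
        assert locus_success_summary([True] * 12 + [False] * 12).percent == 50.0
        assert locus_success_summary([False] * 24).percent == 0.0

    def test_union_across_blends(self):
        ten = [True] * 15 + [False] * 9
        five = [True] * 12 + [False] * 3 + [True] * 3 + [False] * 6
        union = locus_union_summary({"10/1": ten, "5/1": five})
        assert union.successes == 18 and union.percent == 75.0
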