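"""pileup_caller: tallies, terminal filter, binomial tail, calling rules."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from cpedit import pileup_caller as pc
from cpedit.mapper import AlignmentRecord
from cpedit.refio import Feature, ReferenceSequence, ReferenceSet


def exact_log10_tail(k: int, n: int, p: Fraction) -> float:
    """Independent oracle: exact rational binomial tail, log10 via big-int
    logarithms (no floating-point underflow)."""
    total = Fraction(0)
    for j in range(k, n + 1):
        total += (
            Fraction(math.comb(n, j)) * p**j * (1 - p) ** (n - j)
        )
    return (math.log(total.numerator) - math.log(total.denominator)) / math.log(10)


@pytest.fixture
def one_gene_refset():
    sense = "ATG" + "TCA" * 20 + "TAA"  # 66 nt CDS, plenty of C at codon pos 2
    from cpedit.refio import revcomp

    cp = "AAAAA" + sense + "TTTTT"
    feats = [Feature("g1", "CDS", "cp", ((6, 5 + len(sense)),), "+")]
    seqs = [
        ReferenceSequence("cp", cp, "chloroplast"),
        ReferenceSequence("g1", sense, "cds"),
    ]
    return ReferenceSet.build(seqs, feats), sense


class TestBuildPileup:
    def test_single_read_columns(self, one_gene_refset):
        refset, sense = one_gene_refset
        aln = AlignmentRecord("r1", "g1", 10, 18, ())
        piles = pc.build_pileup([aln], refset)
        fp = piles.features["g1"]
        depth = fp.counts.sum(axis=0)
        assert depth[9:27].tolist() == [1.0] * 18
        assert depth.sum() == 18
        for i in range(9, 27):
            assert fp.counts[pc._BASE_INDEX[sense[i]], i] == 1.0

    def test_disagreeing_reads_share_column(self, one_gene_refset):
        refset, sense = one_gene_refset
        alns = [
            AlignmentRecord("r1", "g1", 3, 18, ()),
            AlignmentRecord("r2", "g1", 3, 18, ((8, "C", "T"),)),
        ]
        piles = pc.build_pileup(alns, refset, terminal_window=1)
        col = piles.column("g1", 11)  # start 3 + offset 8
        assert col.depth == 2
        assert col.counts["C"] == 1 and col.counts["T"] == 1

    def test_genome_alignment_projects_into_feature(self, one_gene_refset):
        refset, sense = one_gene_refset
        # genome start 6 == feature position 1
        aln = AlignmentRecord("r1", "cp", 6, 18, ())
        piles = pc.build_pileup([aln], refset)
        assert piles.column("g1", 1).depth == 1
        assert piles.column("g1", 18).depth == 1

    def test_genome_and_cds_placements_deduplicated(self, one_gene_refset):
        refset, sense = one_gene_refset
        alns = [
            AlignmentRecord("r1", "g1", 1, 18, (), n_best_loci=2),
            AlignmentRecord("r1", "cp", 6, 18, (), n_best_loci=2),
        ]
        piles = pc.build_pileup(alns, refset)
        assert piles.column("g1", 5).depth == 1.0

    def test_minus_strand_projection_complements(self):
        from cpedit.refio import revcomp

        sense = "ATGCATCACGTTTGGTAA"
        cp = "AAAAA" + revcomp(sense) + "TTTTT"
        feats = [Feature("gR", "CDS", "cp", ((6, 5 + len(sense)),), "-")]
        refset = ReferenceSet.build(
            [
                ReferenceSequence("cp", cp, "chloroplast"),
                ReferenceSequence("gR", sense, "cds"),
            ],
            feats,
        )
        # antisense read observed through the genome forward strand
        aln = AlignmentRecord("r1", "cp", 6, 18, ())
        piles = pc.build_pileup([aln], refset)
        fp = piles.features["gR"]
        # every observed base must be the sense-strand reference base
        for p in range(1, 19):
            col = fp.column(p)
            assert col.counts[sense[p - 1]] == 1.0

    def test_depth_equals_truth_overlap(self, small_sim_mapped):
        """Simulated library: per-site column depth + terminal-excluded
        equals the truth table's overlapping-read count plus non-feature
        context reads (none, by generator design)."""
        sim, reads, partition, retained = small_sim_mapped
        piles = pc.build_pileup(retained, sim.refset)
        for row in reads.site_truth.itertuples(index=False):
            col = piles.column(row.gene, row.cds_pos)
            assert col.depth + col.terminal_excluded == row.n_reads_overlapping

    def test_fractional_multiread_weights(self, one_gene_refset):
        refset, _ = one_gene_refset
        alns = [
            AlignmentRecord("r1", "g1", 1, 18, (), n_best_loci=2),
            AlignmentRecord("r1", "g1", 30, 18, (), n_best_loci=2),
        ]
        piles = pc.build_pileup(alns, refset, multiread="fractional")
        assert piles.column("g1", 5).depth == 0.5
        assert piles.column("g1", 34).depth == 0.5


class TestTerminalFilter:
    def test_terminal_mismatch_excluded(self, one_gene_refset):
        refset, _ = one_gene_refset
        aln = AlignmentRecord("r1", "g1", 1, 18, ((0, "A", "T"),))
        piles = pc.build_pileup([aln], refset, terminal_window=1)
        col = piles.column("g1", 1)
        assert col.depth == 0
        assert col.terminal_excluded == 1

    def test_interior_mismatch_retained(self, one_gene_refset):
        refset, _ = one_gene_refset
        aln = AlignmentRecord("r1", "g1", 1, 18, ((8, "C", "T"),))
        piles = pc.build_pileup([aln], refset, terminal_window=1)
        col = piles.column("g1", 9)
        assert col.counts["T"] == 1
        assert col.terminal_excluded == 0

    def test_matching_terminal_bases_count_toward_depth(self, one_gene_refset):
        refset, sense = one_gene_refset
        aln = AlignmentRecord("r1", "g1", 1, 18, ())
        piles = pc.build_pileup([aln], refset, terminal_window=1)
        assert piles.column("g1", 1).depth == 1

    @settings(
        deadline=None,
        max_examples=40,
        derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(st.data())
    def test_excluded_plus_retained_equals_nm(self, one_gene_refset, data):
        refset, sense = one_gene_refset
        L = 18
        w = data.draw(st.integers(0, 3))
        offsets = data.draw(
            st.lists(st.integers(0, L - 1), unique=True, max_size=4)
        )
        mism = tuple(
            (o, sense[o], "ACGT"[(("ACGT".index(sense[o])) + 1) % 4]) for o in offsets
        )
        aln = AlignmentRecord("r1", "g1", 1, L, mism)
        piles = pc.build_pileup([aln], refset, terminal_window=w)
        fp = piles.features["g1"]
        excluded = fp.terminal_excluded.sum()
        retained = sum(
            fp.counts[pc._BASE_INDEX[qb], o]
            for o, rb, qb in mism
            if not (o < w or o >= L - w)
        )
        assert excluded + retained == len(mism)


class TestVariantTest:
    def test_zero_edited_is_p_one(self):
        assert pc.variant_test(0, 10, 0.001) == 0.0

    @pytest.mark.parametrize(
        "edited,total", [(2, 10), (1, 5), (5, 40), (3, 100)]
    )
    def test_matches_exact_summation(self, edited, total):
        got = pc.variant_test(edited, total, 0.001)
        want = exact_log10_tail(edited, total, Fraction(1, 1000))
        assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_extreme_tail_finite_log(self):
        got = pc.variant_test(500, 1000, 0.001)
        want = exact_log10_tail(500, 1000, Fraction(1, 1000))
        assert got < -300
        assert math.isfinite(got)
        assert got == pytest.approx(want, rel=1e-6)

    def test_zero_coverage_signals(self):
        with pytest.raises(pc.NoCoverageError):
            pc.variant_test(0, 0, 0.001)

    def test_monotone_in_evidence(self):
        ps = [pc.variant_test(k, 50, 0.001) for k in range(1, 20)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestEditingPercentage:
    @pytest.mark.parametrize(
        "edited,total,expected",
        [
            (32, 40, 80.0),
            (47, 47, 100.0),
            (5, 12, 41.7),  # half-up at the third digit
            (0, 7, 0.0),
            (145, 214, 67.8),
        ],
    )
    def test_reported_rounding(self, edited, total, expected):
        assert pc.editing_percentage(edited, total) == expected

    def test_full_precision_mode(self):
        assert pc.editing_percentage(1, 3, decimals=None) == pytest.approx(
            100 / 3
        )

    def test_half_up_not_bankers(self):
        # 0.25 rounds up to 0.3 under half-up (banker's would give 0.2)
        assert pc.editing_percentage(1, 400) == 0.3

    def test_zero_coverage(self):
        with pytest.raises(pc.NoCoverageError):
            pc.editing_percentage(0, 0)


class TestCallSites:
    def _pileset_with_column(self, refset, counts_c, counts_t):
        alns = []
        rid = 0
        for _ in range(counts_c):
            rid += 1
            alns.append(AlignmentRecord(f"c{rid}", "g1", 1, 18, ()))
        for _ in range(counts_t):
            rid += 1
            alns.append(AlignmentRecord(f"t{rid}", "g1", 1, 18, ((4, "C", "T"),)))
        return pc.build_pileup(alns, refset)

    def test_eighty_percent_call(self, one_gene_refset):
        refset, _ = one_gene_refset
        piles = self._pileset_with_column(refset, 8, 32)
        calls = pc.call_sites(piles, "C2T", refset)
        call = next(c for c in calls if c.cds_pos == 5)
        assert call.total_cov == 40
        assert call.edited_cov == 32
        assert call.percent_display == 80.0

    def test_no_edited_reads_no_call(self, one_gene_refset):
        refset, _ = one_gene_refset
        piles = self._pileset_with_column(refset, 12, 0)
        assert pc.call_sites(piles, "C2T", refset) == []

    def test_below_min_coverage_no_call(self, one_gene_refset):
        refset, _ = one_gene_refset
        piles = self._pileset_with_column(refset, 0, 4)
        assert pc.call_sites(piles, "C2T", refset) == []

    def test_calls_annotated_with_codon_effect(self, one_gene_refset):
        refset, sense = one_gene_refset
        piles = self._pileset_with_column(refset, 8, 32)
        call = next(c for c in pc.call_sites(piles, "C2T", refset) if c.cds_pos == 5)
        assert call.codon_change == "TCA-TTA"
        assert call.aa_change == "S-L"
        assert call.aa_pos == 2

    def test_monotone_thresholds(self, one_gene_refset):
        """Raising min_coverage or lowering max_p never adds a call."""
        refset, _ = one_gene_refset
        piles = self._pileset_with_column(refset, 30, 6)
        base = {
            (c.feature, c.cds_pos)
            for c in pc.call_sites(piles, "C2T", refset, min_coverage=5, max_p=1e-2)
        }
        stricter_cov = {
            (c.feature, c.cds_pos)
            for c in pc.call_sites(piles, "C2T", refset, min_coverage=50, max_p=1e-2)
        }
        stricter_p = {
            (c.feature, c.cds_pos)
            for c in pc.call_sites(piles, "C2T", refset, min_coverage=5, max_p=1e-20)
        }
        assert stricter_cov <= base
        assert stricter_p <= base

    def test_adding_edited_observation_never_removes_call(self, one_gene_refset):
        refset, _ = one_gene_refset
        before = {
            (c.feature, c.cds_pos)
            for c in pc.call_sites(
                self._pileset_with_column(refset, 30, 6), "C2T", refset
            )
        }
        after = {
            (c.feature, c.cds_pos)
            for c in pc.call_sites(
                self._pileset_with_column(refset, 30, 7), "C2T", refset
            )
        }
        assert before <= after
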