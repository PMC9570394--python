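"""Best-hit assignment rules, flank extraction, concentration test."""

import numpy as np
import pytest

from sexlinkscan.io_formats import Hit, HitTable, ReferenceGenome
from sexlinkscan.mapping import (
    AssignmentRules,
    annotate_candidate_genes,
    assign_direct,
    assign_indirect,
    concentration_test,
    extract_flanks,
)
from sexlinkscan.search import exact_search


def hit(query="m1", subject="chr1", e=1e-30, s_lo=1000, s_hi=1150, bits=250.0):
    return Hit(query_id=query, subject_id=subject, percent_identity=100.0,
               alignment_length=s_hi - s_lo, q_lo=0, q_hi=s_hi - s_lo,
               s_lo=s_lo, s_hi=s_hi, strand=1, e_value=e, bit_score=bits)


class TestAssignDirect:
    def test_six_orders_gap_assigns(self):
        hits = HitTable([hit(e=1e-30), hit(subject="chr2", e=1e-24)])
        [a] = assign_direct(hits)
        assert a.assigned and a.chromosome == "chr1"

    def test_three_orders_gap_is_ambiguous(self):
        hits = HitTable([hit(e=1e-30), hit(subject="chr2", e=1e-27)])
        [a] = assign_direct(hits)
        assert a.reason == "ambiguous_gap"

    def test_exactly_five_orders_gap_assigns(self):
        hits = HitTable([hit(e=1e-30), hit(subject="chr2", e=1e-25)])
        [a] = assign_direct(hits)
        assert a.assigned

    def test_single_hit_above_cutoff_fails_evalue(self):
        [a] = assign_direct(HitTable([hit(e=1e-19)]))
        assert a.reason == "fails_evalue"

    def test_single_qualifying_hit_assigns_without_gap(self):
        [a] = assign_direct(HitTable([hit(e=1e-21)]))
        assert a.assigned

    def test_zero_evalue_floor_keeps_gap_finite(self):
        hits = HitTable([hit(e=0.0), hit(subject="chr2", e=0.0)])
        [a] = assign_direct(hits)
        assert a.reason == "ambiguous_gap"

    def test_row_order_invariance(self):
        rows = [hit(e=1e-30), hit(subject="chr2", e=1e-24),
                hit(query="m2", subject="chr3", e=1e-50)]
        fwd = assign_direct(HitTable(rows))
        rev = assign_direct(HitTable(rows[::-1]))
        assert [(a.marker_id, a.chromosome, a.reason) for a in fwd] == \
            [(a.marker_id, a.chromosome, a.reason) for a in rev]


class TestExtractFlanks:
    SCAFFOLD = {"sc1": "A" * 20000}

    def test_interior_hit(self):
        frag, left, right = extract_flanks(
            hit(subject="sc1", s_lo=5000, s_hi=5150), self.SCAFFOLD, 2000
        )
        assert len(frag) == 4150 and not left and not right

    def test_left_clip(self):
        frag, left, right = extract_flanks(
            hit(subject="sc1", s_lo=500, s_hi=650), self.SCAFFOLD, 2000
        )
        assert len(frag) == 2650 and left and not right

    def test_zero_flank_is_identity(self):
        frag, *_ = extract_flanks(
            hit(subject="sc1", s_lo=500, s_hi=650), self.SCAFFOLD, 0
        )
        assert len(frag) == 150

    def test_missing_scaffold_errors(self):
        with pytest.raises(KeyError):
            extract_flanks(hit(subject="nope"), self.SCAFFOLD, 10)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestAssignIndirect:
    def _nested_genomes(self, rng, marker_len=150, clip=False):
        """marker inside a bridge scaffold whose region sits on target chr5."""
        marker = _random_seq(rng, marker_len)
        chunk_pos = 10 if clip else 3000
        bridge = _random_seq(rng, chunk_pos) + marker + _random_seq(rng, 3000)
        target_chr5 = _random_seq(rng, 5000) + bridge + _random_seq(rng, 5000)
        return marker, {"scaf1": bridge}, {"chr5": target_chr5,
                                           "chr1": _random_seq(rng, 20000)}

    def test_end_to_end_nested_assignment(self):
        rng = np.random.default_rng(0)
        marker, bridge, target = self._nested_genomes(rng)
        step1 = exact_search({"m1": marker}, bridge)
        out = assign_indirect(
            step1, bridge, None, AssignmentRules(),
            searcher=lambda frags: exact_search(frags, target),
        )
        [a] = out
        assert a.assigned and a.chromosome == "chr5" and a.method == "indirect"

    def test_clipped_fragment_still_assignable(self):
        rng = np.random.default_rng(1)
        marker, bridge, target = self._nested_genomes(rng, clip=True)
        step1 = exact_search({"m1": marker}, bridge)
        [a] = assign_indirect(
            step1, bridge, None,
            searcher=lambda frags: exact_search(frags, target),
        )
        assert a.assigned and a.chromosome == "chr5"

    def test_unmappable_fragment_is_no_hit_at_step2(self):
        rng = np.random.default_rng(2)
        marker, bridge, _ = self._nested_genomes(rng)
        other_target = {"chrZ": _random_seq(rng, 10000)}
        step1 = exact_search({"m1": marker}, bridge)
        [a] = assign_indirect(
            step1, bridge, None,
            searcher=lambda frags: exact_search(frags, other_target),
        )
        assert a.reason == "no_hit"

    def test_no_bridge_hit_is_no_hit_at_step1(self):
        [a] = assign_indirect(
            HitTable([hit(query="m1", e=1e-5)]), {"chr1": "A" * 2000}, None,
            searcher=lambda frags: HitTable([]),
        )
        assert a.reason == "fails_evalue"


class TestDirectOnSyntheticGenome:
    def test_unique_embeddings_assign_perfectly(self, small_study):
        study = small_study
        sp = "sp1"
        queries = {
            r.locus_id: study.catalogs[sp][r.locus_id].consensus
            for r in study.truth.for_species(sp)
        }
        hits = exact_search(queries, study.reference.sequences)
        truth_chrom = {r.locus_id: r.chromosome
                       for r in study.truth.for_species(sp)}
        assignments = assign_direct(hits)
        assert len(assignments) == len(queries)
        for a in assignments:
            assert a.assigned
            assert a.chromosome == truth_chrom[a.marker_id]

    def test_duplicate_embedding_flips_to_ambiguous(self, small_study):
        study = small_study
        rec = study.truth.for_species("sp1")[0]
        consensus = study.catalogs["sp1"][rec.locus_id].consensus
        genomes = dict(study.reference.sequences)
        genomes["chr_dup"] = "T" * 500 + consensus + "T" * 500
        hits = exact_search({rec.locus_id: consensus}, genomes)
        [a] = assign_direct(hits)
        assert a.reason == "ambiguous_gap"


class TestConcentration:
    GENOME = ReferenceGenome(
        lengths={"chr1": 9000, "chr5": 1000}, chromosome_names={"chr1", "chr5"}
    )

    @staticmethod
    def _assignments(chromosomes):
        out = []
        for i, c in enumerate(chromosomes):
            out.append(
                assign_direct(HitTable([hit(query=f"m{i}", subject=c)]))[0]
            )
        return out

    def test_markers_piled_on_small_chromosome_significant(self):
        report = concentration_test(self._assignments(["chr5"] * 50), self.GENOME)
        chr5 = next(c for c in report.per_chromosome if c.chromosome == "chr5")
        assert chr5.adjusted_p_value < 1e-10
        assert report.concentrated_chromosomes == ["chr5"]

    def test_proportional_scatter_not_significant(self):
        rng = np.random.default_rng(0)
        chroms = rng.choice(["chr1", "chr5"], p=[0.9, 0.1], size=40)
        report = concentration_test(self._assignments(chroms), self.GENOME)
        assert report.concentrated_chromosomes == []

    def test_single_marker_cannot_be_significant(self):
        report = concentration_test(self._assignments(["chr1"]), self.GENOME)
        assert all(c.adjusted_p_value > 0.05 for c in report.per_chromosome
                   if c.expected_fraction > 0.05)

    def test_zero_assigned_skips_test(self):
        [a] = assign_direct(HitTable([hit(e=1.0)]))
        report = concentration_test([a], self.GENOME)
        assert not report.tested and report.fraction_unmapped == 1.0

    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(3)
        chroms = rng.choice(["chr1", "chr5"], size=30)
        report = concentration_test(self._assignments(chroms), self.GENOME)
        for c in report.per_chromosome:
            assert c.adjusted_p_value >= c.p_value - 1e-15


class TestAnnotation:
    def test_qualifying_hit_labelled(self):
        hits = HitTable([
            Hit("m1", "NM_CYP19A1", 85.0, 120, 0, 120, 300, 420, 1, 1e-40, 200.0),
        ])
        ann = annotate_candidate_genes(hits, {"NM_CYP19A1": "CYP19A1"})
        assert ann["m1"][0].gene == "CYP19A1"
        assert ann["m1"][0].subject_start == 301

    def test_weak_evalue_not_labelled(self):
        hits = HitTable([
            Hit("m1", "CYP19A1", 85.0, 120, 0, 120, 300, 420, 1, 1e-10, 80.0),
        ])
        assert annotate_candidate_genes(hits) == {}

    def test_low_identity_not_labelled(self):
        hits = HitTable([
            Hit("m1", "AR", 60.0, 120, 0, 120, 300, 420, 1, 1e-40, 200.0),
        ])
        assert annotate_candidate_genes(hits) == {}
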