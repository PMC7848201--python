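import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hiberseq import annotation as ann
from hiberseq import simulate as sim
from hiberseq.config import MergeRules, SymbolRules

TM = ann.TranscriptModel


def tx(tx_id, exons, strand="+", gene=None, source="primary", chrom="chr1"):
    return TM(tx_id, gene or f"g_{tx_id}", chrom, strand, tuple(exons), source)


class TestExonOverlap:
    def test_identical(self):
        a = tx("a", [(100, 200)])
        assert ann.exon_overlap(a, tx("b", [(100, 200)]))

    def test_adjacent_half_open(self):
        assert not ann.exon_overlap(tx("a", [(100, 200)]), tx("b", [(200, 300)]))

    def test_opposite_strands(self):
        assert not ann.exon_overlap(tx("a", [(100, 200)]), tx("b", [(100, 200)], strand="-"))

    def test_intron_only_overlap_is_false(self):
        a = tx("a", [(100, 200), (500, 600)])
        b = tx("b", [(250, 450)])
        assert not ann.exon_overlap(a, b)


class TestReciprocalOverlap:
    def test_identical_single_exon(self):
        a = tx("a", [(100, 200)])
        assert ann.reciprocal_overlap(a, tx("b", [(100, 200)])) == 1.0

    def test_half_shifted(self):
        a = tx("a", [(100, 200)])
        b = tx("b", [(150, 250)])
        assert ann.reciprocal_overlap(a, b) == pytest.approx(0.5)

    def test_disjoint(self):
        assert ann.reciprocal_overlap(tx("a", [(0, 10)]), tx("b", [(20, 30)])) == 0.0

    @given(
        st.lists(st.tuples(st.integers(0, 400), st.integers(1, 60)), min_size=1, max_size=4),
        st.lists(st.tuples(st.integers(0, 400), st.integers(1, 60)), min_size=1, max_size=4),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_per_base_oracle(self, raw_a, raw_b):
        def build(raw, name):
            exons = []
            cursor = 0
            for gap, width in raw:
                start = cursor + gap
                exons.append((start, start + width))
                cursor = start + width
            return tx(name, exons)

        a, b = build(raw_a, "a"), build(raw_b, "b")
        bases_a = set().union(*(range(s, e) for s, e in a.exons))
        bases_b = set().union(*(range(s, e) for s, e in b.exons))
        shared = len(bases_a & bases_b)
        expected = min(shared / len(bases_a), shared / len(bases_b)) if shared else 0.0
        assert ann.reciprocal_overlap(a, b) == pytest.approx(expected)
        assert ann.exon_overlap(a, b) == (shared > 0)


class TestSupplementSecondary:
    def test_no_overlap_kept(self):
        primary = [tx("p", [(0, 1000)])]
        merged, log = ann.supplement_secondary(primary, [tx("s", [(5000, 5500)], source="secondary")])
        assert {t.tx_id for t in merged} == {"p", "s"}

    def test_short_single_exon_high_ro_dropped(self):
        primary = [tx("p", [(1000, 1800)])]
        s = tx("s", [(1040, 1800)], source="secondary")  # ro = 760/800 = 0.95
        merged, log = ann.supplement_secondary(primary, [s])
        assert {t.tx_id for t in merged} == {"p"}
        assert any(e.tx_id == "s" and e.action == "dropped" for e in log)

    def test_short_single_exon_low_ro_kept(self):
        primary = [tx("p", [(1000, 1800)])]
        s = tx("s", [(1400, 2200)], source="secondary")  # ro = 0.5
        merged, _ = ann.supplement_secondary(primary, [s])
        assert "s" in {t.tx_id for t in merged}

    def test_duplicate_ids_error(self):
        primary = [tx("p", [(0, 100)])]
        with pytest.raises(ValueError, match="duplicate"):
            ann.supplement_secondary(primary, [tx("p", [(500, 600)], source="secondary")])

    def test_idempotent_with_empty_incoming(self):
        primary = [tx("p", [(0, 100)]), tx("q", [(500, 700)])]
        merged, log = ann.supplement_secondary(primary, [])
        assert merged == primary
        assert log == []

    def test_monotone_gate(self):
        # raising reciprocal_overlap_max never removes a kept transcript
        primary = [tx("p", [(1000, 1800)])]
        incoming = [
            tx("s1", [(1400, 2200)], source="secondary"),
            tx("s2", [(1100, 1800)], source="secondary"),
        ]
        kept = {}
        for ro_max in (0.5, 0.7, 0.9, 1.0):
            merged, _ = ann.supplement_secondary(
                primary, incoming, MergeRules(reciprocal_overlap_max=ro_max)
            )
            kept[ro_max] = {t.tx_id for t in merged}
        assert kept[0.5] <= kept[0.7] <= kept[0.9] <= kept[1.0]

    def test_provenance_conservation(self):
        primary = [tx("p", [(1000, 1800)])]
        incoming = [
            tx("s1", [(5000, 5100)], source="secondary"),
            tx("s2", [(1040, 1800)], source="secondary"),
            tx("s3", [(1000, 1200), (1500, 1700)], source="secondary"),
        ]
        merged, log = ann.supplement_secondary(primary, incoming)
        assert sorted(e.tx_id for e in log) == ["s1", "s2", "s3"]


class TestIntegrateNovel:
    def test_empty_novel_is_identity(self):
        base = [tx("p", [(0, 100)])]
        merged, _ = ann.integrate_novel(base, [])
        assert merged == base

    def test_multi_exon_overlapping_excluded(self):
        base = [tx("p", [(1000, 1200), (1500, 1700)])]
        novel = [tx("n", [(1100, 1250), (1500, 1600)], source="novel")]
        merged, log = ann.integrate_novel(base, novel)
        assert "n" not in {t.tx_id for t in merged}

    def test_non_overlapping_kept_as_novel(self):
        base = [tx("p", [(0, 100)])]
        novel = [tx("n", [(5000, 5200)], source="novel")]
        merged, _ = ann.integrate_novel(base, novel)
        (kept,) = [t for t in merged if t.tx_id == "n"]
        assert kept.source == "novel"


class TestReassign:
    def _setup(self):
        ref = tx("p", [(1000, 1200), (2500, 2800)], gene="GX")
        novel_linked = tx("n1", [(1900, 2100)], gene="GN1", source="novel")
        novel_intronic = tx("n2", [(1300, 1400)], gene="GN2", source="novel")
        novel_intergenic = tx("n3", [(9000, 9100)], gene="GN3", source="novel")
        return [ref, novel_linked, novel_intronic, novel_intergenic]

    def test_evidence_reassigns_gene(self):
        merged = self._setup()
        ev = [ann.JunctionEvidence("chr1", "+", 2099, 2500, 3)]
        out, log = ann.reassign_by_splice_evidence(merged, ev)
        n1 = next(t for t in out if t.tx_id == "n1")
        assert n1.gene_id == "GX"

    def test_intronic_without_evidence_removed(self):
        out, log = ann.reassign_by_splice_evidence(self._setup(), [])
        assert "n2" not in {t.tx_id for t in out}
        assert any(e.tx_id == "n2" and e.reason == "contained_in_retained_intron" for e in log)

    def test_intergenic_without_evidence_retained(self):
        out, _ = ann.reassign_by_splice_evidence(self._setup(), [])
        n3 = next(t for t in out if t.tx_id == "n3")
        assert n3.gene_id == "GN3"

    def test_two_reference_genes_tiebreak_by_count(self):
        ref1 = tx("p1", [(1000, 1200)], gene="GA")
        ref2 = tx("p2", [(3000, 3200)], gene="GB")
        novel = tx("n", [(1900, 2100)], gene="GN", source="novel")
        ev = [
            ann.JunctionEvidence("chr1", "+", 1100, 1950, 2),  # into GA
            ann.JunctionEvidence("chr1", "+", 2050, 3100, 5),  # into GB
        ]
        out, _ = ann.reassign_by_splice_evidence([ref1, ref2, novel], ev)
        n = next(t for t in out if t.tx_id == "n")
        assert n.gene_id == "GB"

    def test_low_count_evidence_ignored(self):
        # below min_spliced_reads the junction does not count; the intron-
        # contained novel transcript is then removed
        merged = self._setup()
        ev = [ann.JunctionEvidence("chr1", "+", 2099, 2500, 1)]
        out, log = ann.reassign_by_splice_evidence(merged, ev, MergeRules(min_spliced_reads=2))
        assert "n1" not in {t.tx_id for t in out}
        assert any(e.tx_id == "n1" and e.reason == "contained_in_retained_intron" for e in log)


class TestAssignSymbols:
    def _tx(self):
        return [tx("q", [(0, 500)])]

    def test_plain_symbol(self):
        hits = [ann.AlignmentHit("q", "FOS", 1e-30, 98.0, 0.95)]
        out = ann.assign_symbols(self._tx(), hits, [])
        assert out.loc["q", "symbol"] == "FOS"

    def test_like_and_containing(self):
        out = ann.assign_symbols(self._tx(), [ann.AlignmentHit("q", "FOS", 1e-30, 98.0, 0.70)], [])
        assert out.loc["q", "symbol"] == "FOS_like"
        out = ann.assign_symbols(self._tx(), [ann.AlignmentHit("q", "FOS", 1e-30, 98.0, 0.30)], [])
        assert out.loc["q", "symbol"] == "FOS_containing"

    def test_boundaries(self):
        out = ann.assign_symbols(self._tx(), [ann.AlignmentHit("q", "FOS", 1e-30, 98.0, 0.90)], [])
        assert out.loc["q", "symbol"] == "FOS"  # exactly 0.90 -> plain
        out = ann.assign_symbols(self._tx(), [ann.AlignmentHit("q", "FOS", 1e-30, 98.0, 0.50)], [])
        assert out.loc["q", "symbol"] == "FOS_containing"  # exactly 0.50

    def test_evalue_gate(self):
        out = ann.assign_symbols(self._tx(), [ann.AlignmentHit("q", "FOS", 1e-5, 98.0, 0.95)], [])
        assert out.loc["q", "symbol"] is None

    def test_fallback_used_when_primary_fails_gate(self):
        prim = [ann.AlignmentHit("q", "FOS", 1e-5, 98.0, 0.95)]
        fall = [ann.AlignmentHit("q", "Fosl1", 1e-25, 90.0, 0.95)]
        out = ann.assign_symbols(self._tx(), prim, fall)
        assert out.loc["q", "symbol"] == "Fosl1"
        assert out.loc["q", "db"] == "fallback"

    def test_tie_break_coverage_then_identity(self):
        hits = [
            ann.AlignmentHit("q", "B", 1e-30, 90.0, 0.95),
            ann.AlignmentHit("q", "A", 1e-30, 99.0, 0.99),
        ]
        out = ann.assign_symbols(self._tx(), hits, [])
        assert out.loc["q", "symbol"] == "A"

    def test_coverage_bands_partition(self):
        # every coverage in [0,1] lands in exactly one band
        rules = SymbolRules()
        for cov in np.linspace(0, 1, 101):
            bands = [
                cov >= rules.like_cov_high,
                rules.like_cov_low < cov < rules.like_cov_high,
                cov <= rules.like_cov_low,
            ]
            assert sum(bands) == 1


class TestMergeOracle:
    def test_fixture_reproduced_exactly(self):
        primary, secondary, novel, evidence, expected = sim.gen_annotation_fixture(0)
        merged, _ = ann.supplement_secondary(primary, secondary)
        merged, _ = ann.integrate_novel(merged, novel)
        merged, _ = ann.reassign_by_splice_evidence(merged, evidence)
        got = {(t.tx_id, t.gene_id, t.source) for t in merged}
        exp = {(t.tx_id, t.gene_id, t.source) for t in expected}
        assert got == exp


class TestIO:
    def test_gtf_round_trip(self, tmp_path):
        transcripts = [
            tx("t1", [(99, 200), (299, 400)], gene="g1"),
            tx("t2", [(1000, 1500)], strand="-", gene="g2", source="novel"),
        ]
        path = tmp_path / "x.gtf"
        ann.write_gtf(transcripts, path)
        back = ann.read_gtf(path)
        assert {(t.tx_id, t.gene_id, t.chrom, t.strand, t.exons, t.source) for t in back} == {
            (t.tx_id, t.gene_id, t.chrom, t.strand, t.exons, t.source) for t in transcripts
        }

    def test_evidence_round_trip(self, tmp_path):
        ev = [ann.JunctionEvidence("chr1", "+", 10, 300, 4)]
        path = tmp_path / "ev.tsv"
        ann.write_junction_evidence(ev, path)
        assert ann.read_junction_evidence(path) == ev

    def test_hit_parse_error_reports_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q1\tFOS\t1e-30\t99\t0.9\nq2\tbad_row\n")
        with pytest.raises(ValueError, match=":2"):
            ann.read_alignment_hits(path)

    def test_invalid_transcript_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            TM("t", "g", "chr1", "+", ((100, 200), (150, 300)))
        with pytest.raises(ValueError, match="strand"):
            TM("t", "g", "chr1", "*", ((100, 200),))
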