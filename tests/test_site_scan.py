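"""PAM scanning, cut geometry, CDS assignment, dedup and the GC filter."""

import pytest

from crisprpop.genome_io import GeneModel, GenomeSequence, GenomicInterval
from crisprpop.site_scan import (
    TargetSite,
    assign_to_cds,
    builtin_specs,
    dedup,
    gc_filter,
    get_spec,
    matches_motif,
    scan_targets,
)
from tests.conftest import random_genome

CAS9, CAS12A = builtin_specs()


class TestBuiltinSpecs:
    def test_cas9_geometry(self):
        assert CAS9.pam_motif == "NGG" and CAS9.pam_side == "3prime"
        assert CAS9.spacer_length == 20
        assert CAS9.window_length == 23

    def test_cas12a_geometry(self):
        assert CAS12A.pam_motif == "TTTN" and CAS12A.pam_side == "5prime"
        assert CAS12A.spacer_length == 23
        assert CAS12A.window_length == 27

    def test_cas9_cut_three_bp_from_pam(self):
        # window [100, 123) on + strand: spacer 100-119, PAM 120-122,
        # blunt cut between bases 116 and 117 -> bond coordinate 117
        genome = GenomeSequence({"c": "T" * 100 + "A" * 20 + "TGG" + "T" * 20})
        [site] = [t for t in scan_targets(genome, CAS9) if t.window.strand == "+"]
        assert site.window.start == 100
        assert site.cut_positions == (117,)

    def test_cas12a_staggered_cuts(self):
        genome = GenomeSequence({"c": "G" * 50 + "TTTC" + "A" * 23 + "G" * 50})
        [site] = [t for t in scan_targets(genome, CAS12A) if t.window.strand == "+"]
        assert site.window.start == 50
        # PAM ends at 54; nicks 18 and 23 bases into the spacer
        assert site.cut_positions == (72, 77)


class TestScan:
    def test_constructed_cas9_site(self):
        genome = GenomeSequence({"c": "A" * 20 + "TGG"})
        sites = list(scan_targets(genome, CAS9))
        fwd = [t for t in sites if t.window.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].spacer == "A" * 20 and fwd[0].pam == "TGG"

    def test_constructed_cas12a_site(self):
        genome = GenomeSequence({"c": "TTTC" + "A" * 23})
        fwd = [t for t in scan_targets(genome, CAS12A) if t.window.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].pam == "TTTC"

    def test_pam_free_sequence_yields_nothing(self):
        # poly-A carries no NGG on either strand; note its reverse strand IS
        # poly-T, so it does offer Cas12a TTTN PAMs — use a dinucleotide
        # repeat with neither motif for the joint check
        genome = GenomeSequence({"c": "A" * 200})
        assert list(scan_targets(genome, CAS9)) == []
        rev = [t for t in scan_targets(genome, CAS12A) if t.window.strand == "-"]
        assert len(rev) == 200 - 27 + 1  # every reverse window is TTTN-led
        genome = GenomeSequence({"c": "AG" * 100})
        assert list(scan_targets(genome, CAS9)) == []
        assert list(scan_targets(genome, CAS12A)) == []

    def test_windows_containing_n_skipped(self):
        genome = GenomeSequence({"c": "A" * 10 + "N" + "A" * 9 + "TGG"})
        assert list(scan_targets(genome, CAS9)) == []

    @pytest.mark.parametrize("spec", [CAS9, CAS12A], ids=lambda s: s.name)
    def test_matches_sliding_window_oracle(self, spec):
        """Scanner output equals a naive per-offset motif check, both strands."""
        from crisprpop.genome_io import reverse_complement

        genome = random_genome(4000, seed=17)
        seq = genome["chr1"]
        L = spec.window_length
        expected = set()
        for strand in ("+", "-"):
            oriented = seq if strand == "+" else reverse_complement(seq)
            for i in range(len(seq) - L + 1):
                window = oriented[i : i + L]
                pam = window[spec.pam_offset() : spec.pam_offset() + spec.pam_length]
                if "N" in window or not matches_motif(pam, spec.pam_motif):
                    continue
                start = i if strand == "+" else len(seq) - (i + L)
                expected.add((start, strand))
        got = {
            (t.window.start, t.window.strand) for t in scan_targets(genome, spec)
        }
        assert got == expected

    @pytest.mark.parametrize("spec", [CAS9, CAS12A], ids=lambda s: s.name)
    def test_strand_symmetry_under_reverse_complement(self, spec):
        from crisprpop.genome_io import reverse_complement

        genome = random_genome(3000, seed=23)
        L = genome.length("chr1")
        flipped = GenomeSequence({"chr1": reverse_complement(genome["chr1"])})
        orig = {
            (t.window.start, t.window.end, t.window.strand, t.spacer)
            for t in scan_targets(genome, spec)
        }
        mirrored = {
            (L - t.window.end, L - t.window.start,
             "+" if t.window.strand == "-" else "-", t.spacer)
            for t in scan_targets(flipped, spec)
        }
        assert orig == mirrored

    def test_emitted_sites_satisfy_invariants(self):
        genome = random_genome(3000, seed=5)
        for spec in (CAS9, CAS12A):
            for t in scan_targets(genome, spec):
                assert len(t.spacer) == spec.spacer_length
                assert matches_motif(t.pam, spec.pam_motif)
                w = t.window
                assert all(w.start <= c <= w.end for c in t.cut_positions)
                assert genome.fetch(w) == (
                    t.pam + t.spacer if spec.pam_side == "5prime"
                    else t.spacer + t.pam
                )


def _gene(gene_id, contig, spans, strand="+"):
    return GeneModel(
        gene_id,
        {f"{gene_id}.t": [GenomicInterval(contig, s, e, strand) for s, e in spans]},
    )


class TestAssignToCds:
    def test_cut_inside_cds_window_straddling_kept(self):
        # CDS covers the cut bond (117) but not the whole window
        genome = GenomeSequence({"c": "T" * 100 + "A" * 20 + "TGG" + "T" * 20})
        [site] = [t for t in scan_targets(genome, CAS9) if t.window.strand == "+"]
        kept = list(assign_to_cds([site], [_gene("g1", "c", [(110, 120)])]))
        assert kept == [site] and site.gene_ids == {"g1"}

    def test_intergenic_site_dropped(self):
        genome = GenomeSequence({"c": "T" * 100 + "A" * 20 + "TGG" + "T" * 20})
        [site] = [t for t in scan_targets(genome, CAS9) if t.window.strand == "+"]
        kept = list(assign_to_cds([site], [_gene("g1", "c", [(0, 50)])]))
        assert kept == [] and site.filter_flags["cds"] is False

    def test_cas12a_requires_all_cuts_in_cds(self):
        genome = GenomeSequence({"c": "G" * 50 + "TTTC" + "A" * 23 + "G" * 50})
        [site] = [t for t in scan_targets(genome, CAS12A) if t.window.strand == "+"]
        assert site.cut_positions == (72, 77)
        # covers the first cut only -> dropped under the all-cuts rule
        assert list(assign_to_cds([site], [_gene("g", "c", [(60, 75)])])) == []
        site.filter_flags.clear()
        # covers the second cut only -> dropped as well
        assert list(assign_to_cds([site], [_gene("g", "c", [(75, 100)])])) == []
        site.filter_flags.clear()
        # covers both cuts -> kept; any-cut mode accepts partial coverage
        assert list(assign_to_cds([site], [_gene("g", "c", [(60, 100)])])) == [site]
        assert list(
            assign_to_cds([site], [_gene("g", "c", [(60, 75)])], mode="any")
        ) == [site]

    def test_overlapping_genes_both_assigned(self):
        genome = GenomeSequence({"c": "T" * 100 + "A" * 20 + "TGG" + "T" * 20})
        [site] = [t for t in scan_targets(genome, CAS9) if t.window.strand == "+"]
        models = [_gene("g1", "c", [(100, 130)]), _gene("g2", "c", [(110, 125)])]
        kept = list(assign_to_cds([site], models))
        assert kept and site.gene_ids == {"g1", "g2"}

    def test_never_increases_count(self, demo_fixture):
        genome, models, _ = demo_fixture
        sites = list(scan_targets(genome, CAS9))
        kept = list(assign_to_cds(iter(sites), models))
        assert len(kept) <= len(sites)


class TestDedup:
    def test_same_site_from_two_transcripts_merges_genes(self):
        w = GenomicInterval("c", 0, 23, "+")
        a = TargetSite("cas9", w, "A" * 20, "AGG", (17,), gene_ids={"g1"})
        b = TargetSite("cas9", w, "A" * 20, "AGG", (17,), gene_ids={"g2"})
        out = dedup([a, b])
        assert len(out) == 1 and out[0].gene_ids == {"g1", "g2"}

    def test_identical_spacer_at_two_loci_kept_separately(self):
        a = TargetSite("cas9", GenomicInterval("c", 0, 23), "A" * 20, "AGG", (17,))
        b = TargetSite("cas9", GenomicInterval("c", 50, 73), "A" * 20, "AGG", (67,))
        assert len(dedup([a, b])) == 2

    def test_opposite_strands_at_same_start_kept(self):
        a = TargetSite("cas9", GenomicInterval("c", 0, 23, "+"), "A" * 20, "AGG", (17,))
        b = TargetSite("cas9", GenomicInterval("c", 0, 23, "-"), "T" * 20, "AGG", (6,))
        assert len(dedup([a, b])) == 2

    def test_idempotent(self, demo_fixture):
        genome, _, _ = demo_fixture
        once = dedup(scan_targets(genome, CAS9))
        assert dedup(once) == once


class TestGcFilter:
    def _site(self, spacer):
        return TargetSite(
            "cas9", GenomicInterval("c", 0, 23), spacer, "AGG", (17,),
            gc=(spacer.count("G") + spacer.count("C")) / len(spacer),
        )

    @pytest.mark.parametrize(
        "spacer,expected",
        [
            ("ACGTACGTACGTACGTACGT", True),   # 0.50
            ("A" * 20, False),                # 0.00
            ("GC" * 4 + "A" * 12, True),      # exactly 0.40, inclusive
            ("GC" * 8 + "A" * 4, True),       # exactly 0.80, inclusive
            ("GC" * 8 + "GA" + "A" * 2, False),  # 0.85
        ],
    )
    def test_inclusive_bounds(self, spacer, expected):
        assert gc_filter(self._site(spacer)) is expected

    def test_gc_computed_on_spacer_not_pam(self):
        site = self._site("A" * 20)
        assert site.gc == 0.0  # PAM "AGG" contributes nothing
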