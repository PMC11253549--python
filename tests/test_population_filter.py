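"""Allele frequencies, the P_ref product model and nucleotide diversity."""

import math

import numpy as np
import pytest

from crisprpop.genome_io import (
    GenomicInterval,
    PopulationPanel,
    VariantRecord,
)
from crisprpop.population_filter import (
    COMBINED,
    VariantIndex,
    allele_frequencies,
    classify_good,
    compute_pref,
    nucleotide_diversity,
)
from crisprpop.site_scan import TargetSite
from crisprpop.synthetic_data import (
    SyntheticGenomeConfig,
    SyntheticVariantConfig,
    generate_genome,
    generate_variants,
    variant_site,
)


def _target(start=100, nuclease="cas9", strand="+"):
    L = 23 if nuclease == "cas9" else 27
    return TargetSite(
        nuclease,
        GenomicInterval("chr1", start, start + L, strand),
        "A" * (20 if nuclease == "cas9" else 23),
        "AGG" if nuclease == "cas9" else "TTTA",
        (start + 17,) if nuclease == "cas9" else (start + 22, start + 27),
    )


class TestAlleleFrequencies:
    def _panel(self, n=10, pop="p1"):
        return PopulationPanel({f"s{i}": pop for i in range(n)})

    def test_single_het_in_ten_diploids(self):
        rec = [VariantRecord("chr1", 99, "A", ("G",))]
        geno = np.zeros((1, 10, 2), dtype=np.int8)
        geno[0, 0, 1] = 1
        [site] = allele_frequencies(
            rec, geno, [f"s{i}" for i in range(10)], self._panel(),
            include_combined=False,
        )
        assert site.alt_freq("p1") == pytest.approx(1 / 20)
        assert site.called_haplotypes["p1"] == 20

    def test_all_missing_population_skipped(self, caplog):
        rec = [VariantRecord("chr1", 99, "A", ("G",))]
        geno = np.full((1, 4, 2), -1, dtype=np.int8)
        geno[0, :2] = 0  # pA called, pB all missing
        panel = PopulationPanel({"s0": "pA", "s1": "pA", "s2": "pB", "s3": "pB"})
        with caplog.at_level("WARNING"):
            [site] = allele_frequencies(
                rec, geno, ["s0", "s1", "s2", "s3"], panel,
                include_combined=False,
            )
        assert "pA" in site.freqs and "pB" not in site.freqs

    def test_triallelic_alternates_summed(self):
        rec = [VariantRecord("chr1", 99, "A", ("G", "T"))]
        geno = np.zeros((1, 10, 2), dtype=np.int8)
        geno[0, 0] = [1, 2]
        geno[0, 1, 0] = 2
        [site] = allele_frequencies(
            rec, geno, [f"s{i}" for i in range(10)], self._panel(),
            include_combined=False,
        )
        # alt counts 1 and 2 of 20 called alleles
        assert site.alt_freq("p1") == pytest.approx(0.15)

    def test_missing_excluded_from_denominator(self):
        rec = [VariantRecord("chr1", 99, "A", ("G",))]
        geno = np.zeros((1, 10, 2), dtype=np.int8)
        geno[0, 0] = [1, 1]
        geno[0, 5:] = -1  # five samples uncalled
        [site] = allele_frequencies(
            rec, geno, [f"s{i}" for i in range(10)], self._panel(),
            include_combined=False,
        )
        assert site.alt_freq("p1") == pytest.approx(2 / 10)


class TestComputePref:
    def test_no_overlapping_variants_is_good(self):
        res = compute_pref(_target(), [], "p1")
        assert res.pref == 1.0 and res.good and res.n_variants == 0

    def test_boundary_pref_classified_good(self):
        sites = [variant_site("chr1", 110, "A", "G", {"p1": 0.01})]
        res = compute_pref(_target(), sites, "p1")
        assert res.pref == pytest.approx(0.99, abs=1e-15)
        assert res.good

    def test_product_of_reference_frequencies(self):
        sites = [
            variant_site("chr1", 105, "A", "G", {"p1": 0.02}),
            variant_site("chr1", 110, "A", "G", {"p1": 0.03}),
        ]
        res = compute_pref(_target(), sites, "p1")
        assert res.pref == pytest.approx(0.98 * 0.97, abs=1e-15)
        assert not res.good and res.n_variants == 2

    def test_single_variant_pref_is_one_minus_alt_freq(self):
        for q in (0.001, 0.013, 0.2, 0.9):
            sites = [variant_site("chr1", 111, "A", "G", {"p1": q})]
            assert compute_pref(_target(), sites, "p1").pref == pytest.approx(
                1 - q, abs=1e-15
            )

    def test_variants_outside_window_ignored(self):
        sites = [
            variant_site("chr1", 99, "A", "G", {"p1": 0.5}),
            variant_site("chr1", 123, "A", "G", {"p1": 0.5}),
        ]
        assert compute_pref(_target(), sites, "p1").pref == 1.0

    def test_degenerate_pam_position_excluded_by_default(self):
        # cas9 + strand window [100,123): PAM at 120-122, N position at 120
        sites = [variant_site("chr1", 120, "A", "G", {"p1": 0.5})]
        assert compute_pref(_target(), sites, "p1").pref == 1.0
        res = compute_pref(_target(), sites, "p1", include_degenerate_pam=True)
        assert res.pref == pytest.approx(0.5)
        # the GG positions are always scored
        sites = [variant_site("chr1", 121, "A", "G", {"p1": 0.5})]
        assert compute_pref(_target(), sites, "p1").pref == pytest.approx(0.5)

    def test_degenerate_pam_on_reverse_strand(self):
        # reverse-strand cas9 window [100,123): PAM occupies forward 100-102
        # and its degenerate N maps to forward position 102
        t = _target(strand="-")
        hit = variant_site("chr1", 102, "A", "G", {"p1": 0.5})
        assert compute_pref(t, [hit], "p1").pref == 1.0
        scored = variant_site("chr1", 101, "A", "G", {"p1": 0.5})
        assert compute_pref(t, [scored], "p1").pref == pytest.approx(0.5)

    def test_monotone_in_variants_and_frequencies(self):
        base = [variant_site("chr1", 105, "A", "G", {"p1": 0.1})]
        more = base + [variant_site("chr1", 110, "A", "G", {"p1": 0.1})]
        hotter = [variant_site("chr1", 105, "A", "G", {"p1": 0.3})]
        p0 = compute_pref(_target(), base, "p1").pref
        assert compute_pref(_target(), more, "p1").pref <= p0
        assert compute_pref(_target(), hotter, "p1").pref <= p0

    def test_indel_scored_once_on_any_overlap(self):
        site = variant_site("chr1", 98, "AAAA", "A", {"p1": 0.1})
        res = compute_pref(_target(), [site], "p1")
        assert res.pref == pytest.approx(0.9) and res.n_variants == 1

    def test_empirical_haplotype_match_fraction_converges(self):
        """Without linkage, the fraction of haplotypes matching the reference
        across a window approaches the product of per-site ref frequencies."""
        rng = np.random.default_rng(42)
        n_hap = 4000
        qs = [0.03, 0.05, 0.08]
        hap = np.column_stack([rng.random(n_hap) < q for q in qs])
        match = float((~hap.any(axis=1)).mean())
        q_hat = hap.mean(axis=0)
        sites = [
            variant_site("chr1", 105 + i, "A", "G", {"p1": float(q)})
            for i, q in enumerate(q_hat)
        ]
        pref = compute_pref(_target(), sites, "p1").pref
        se = math.sqrt(pref * (1 - pref) / n_hap)
        assert abs(match - pref) <= 3 * se


class TestClassifyGood:
    def _potential(self, t, value=True):
        for k in ("cds", "gc", "offtarget", "efficiency"):
            t.filter_flags[k] = value
        return t

    def test_per_population_flags(self):
        t = self._potential(_target())
        sites = [
            variant_site("chr1", 110, "A", "G", {"pA": 0.005, "pB": 0.03}),
        ]
        classify_good([t], sites, ["pA", "pB"])
        assert t.good["pA"] and not t.good["pB"]
        assert t.pref["pA"] == pytest.approx(0.995)

    def test_good_requires_potential(self):
        t = self._potential(_target())
        t.filter_flags["gc"] = False
        classify_good([t], [], ["pA"])
        assert t.pref["pA"] == 1.0 and not t.good["pA"]

    def test_threshold_one_keeps_only_variant_free(self):
        t1 = self._potential(_target(100))
        t2 = self._potential(_target(200))
        sites = [variant_site("chr1", 210, "A", "G", {"pA": 1e-6})]
        classify_good([t1, t2], sites, ["pA"], threshold=1.0)
        assert t1.good["pA"] and not t2.good["pA"]


class TestNucleotideDiversity:
    def test_single_site_closed_form(self):
        site = variant_site("chr1", 10, "A", "G", {"p1": 0.5}, n_haplotypes=20)
        iv = [GenomicInterval("chr1", 0, 1000)]
        pi = nucleotide_diversity([site], iv, "p1")
        assert pi == pytest.approx((20 / 19) * 0.5 / 1000)

    def test_no_variants_gives_zero(self):
        assert nucleotide_diversity([], [GenomicInterval("chr1", 0, 100)], "p1") == 0.0

    def test_sites_outside_intervals_ignored(self):
        inside = variant_site("chr1", 10, "A", "G", {"p1": 0.5}, 20)
        outside = variant_site("chr1", 500, "A", "G", {"p1": 0.5}, 20)
        iv = [GenomicInterval("chr1", 0, 100)]
        assert nucleotide_diversity([inside, outside], iv, "p1") == pytest.approx(
            nucleotide_diversity([inside], iv, "p1")
        )

    def test_fewer_than_two_haplotypes_rejected(self):
        site = variant_site("chr1", 10, "A", "G", {"p1": 0.5}, n_haplotypes=1)
        with pytest.raises(ValueError):
            nucleotide_diversity([site], [GenomicInterval("chr1", 0, 100)], "p1")

    def test_synthetic_diversity_matches_generator_expectation(self):
        """pi should approach theta * E[(n/(n-1)) * 2 p (1-p)] with p the
        empirical alt frequency under Binomial(n, 1 - ref_af) draws."""
        gcfg = SyntheticGenomeConfig(
            n_contigs=1, contig_length=100_000, n_genes=5, seed=13
        )
        genome, _ = generate_genome(gcfg)
        theta, ref_af, n_samples = 0.01, 0.9, 30
        table = generate_variants(
            SyntheticVariantConfig(theta=theta, ref_af=ref_af,
                                   n_samples=n_samples, seed=13),
            genome,
        )
        sites = table.to_sites(include_combined=False)
        iv = [GenomicInterval("ctg01", 0, 100_000)]
        pi = nucleotide_diversity(sites, iv, "pop1")
        n = 2 * n_samples
        # E[2p(1-p)] for p = X/n, X ~ Binomial(n, q): 2 q (1-q) (n-1)/n,
        # so each segregating site contributes 2 q (1-q) on average
        q = 1 - ref_af
        expected = theta * 2 * q * (1 - q)
        n_sites = len(table.records)
        per_site_sd = 2 * q * (1 - q)  # conservative bound on site spread
        se = theta * per_site_sd / math.sqrt(n_sites)
        assert abs(pi - expected) <= 3 * se + 3 * expected / math.sqrt(n_sites)
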