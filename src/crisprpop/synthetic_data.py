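"""Synthetic genome / annotation / variant generation with known structure.

The generator emulates the shape of the real inputs — a multi-gene reference
with CDS intervals, biallelic SNVs placed with a tunable per-site density
theta, and diploid genotypes for two labelled populations with distinct
theta (the mechanism behind continental diversity contrasts) — while keeping
every statistical expectation analytic:

* variant sites are independent Bernoulli(theta) draws per position;
* genotypes are drawn per haplotype with non-reference probability
  ``1 - ref_af`` (Hardy-Weinberg, no linkage), matching the independence
  assumption under which P_ref is computed;
* :func:`expected_good_fraction` gives the closed-form probability that a
  window of L scored positions is classified good, against which pipeline
  output can be checked.

No coalescent realism, recombination, indels or sequencing error: the goal
is exercising the pipeline and its analytic expectations, not demography.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.stats import binom

from . import genome_io
from .genome_io import (
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    PopulationPanel,
    VariantRecord,
)
from .population_filter import VariantSite

_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    """Layout and composition of a synthetic multi-gene genome.

    Defaults give a 2 x 100 kb genome with 40 three-exon genes at GC 0.5 —
    large enough that scan statistics are stable, small enough to run in
    seconds.
    """

    n_contigs: int = 2
    contig_length: int = 100_000
    gc_fraction: float = 0.5
    n_genes: int = 40
    cds_per_gene: int = 3
    cds_length: int = 300
    intergenic_gap: int = 500
    intron_length: int = 80
    reverse_strand_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ConfigurationError("gc_fraction must be in [0, 1]")
        if not (0.0 <= self.reverse_strand_fraction <= 1.0):
            raise ConfigurationError("reverse_strand_fraction must be in [0, 1]")
        if min(self.n_contigs, self.contig_length, self.n_genes,
               self.cds_per_gene, self.cds_length) < 1:
            raise ConfigurationError("counts and lengths must be positive")
        footprint = self.gene_footprint + self.intergenic_gap
        if self.n_genes * footprint > self.n_contigs * self.contig_length:
            raise ConfigurationError(
                f"{self.n_genes} genes of footprint {footprint} bp do not fit "
                f"in {self.n_contigs} x {self.contig_length} bp"
            )

    @property
    def gene_footprint(self) -> int:
        return (
            self.cds_per_gene * self.cds_length
            + (self.cds_per_gene - 1) * self.intron_length
        )


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def generate_genome(
    cfg: SyntheticGenomeConfig,
) -> Tuple[GenomeSequence, List[GeneModel]]:
    """Deterministic genome + annotation for a config (child seed offset 1)."""
    rng = np.random.default_rng([cfg.seed, 1])
    contig_names = [f"ctg{i + 1:02d}" for i in range(cfg.n_contigs)]
    contigs = {
        name: _random_sequence(rng, cfg.contig_length, cfg.gc_fraction)
        for name in contig_names
    }
    genome = GenomeSequence(contigs)

    models: List[GeneModel] = []
    per_contig = cfg.contig_length // (cfg.gene_footprint + cfg.intergenic_gap)
    gene_no = 0
    for name in contig_names:
        cursor = cfg.intergenic_gap
        placed = 0
        while gene_no < cfg.n_genes and placed < per_contig:
            if cursor + cfg.gene_footprint > cfg.contig_length:
                break
            gene_no += 1
            placed += 1
            strand = (
                "-" if rng.random() < cfg.reverse_strand_fraction else "+"
            )
            gene_id = f"gene{gene_no:04d}"
            tx_id = f"{gene_id}.t1"
            cds = []
            pos = cursor
            for _ in range(cfg.cds_per_gene):
                cds.append(GenomicInterval(name, pos, pos + cfg.cds_length, strand))
                pos += cfg.cds_length + cfg.intron_length
            models.append(GeneModel(gene_id, {tx_id: cds}))
            cursor += cfg.gene_footprint + cfg.intergenic_gap
    if gene_no < cfg.n_genes:
        raise ConfigurationError(
            f"could only place {gene_no} of {cfg.n_genes} genes"
        )
    return genome, models


@dataclass(frozen=True)
class SyntheticVariantConfig:
    """Variant density and genotype model per population.

    ``theta`` is the per-site probability that a position is polymorphic in
    a population; ``ref_af`` the reference-allele frequency from which each
    haplotype draws independently.  Scalars describe a single population
    labelled ``pop1``.
    """

    theta: Union[float, Mapping[str, float]] = 0.01
    ref_af: float = 0.97
    n_samples: Union[int, Mapping[str, int]] = 50
    ploidy: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for pop, th in self.theta_by_pop.items():
            if not (0.0 <= th <= 1.0):
                raise ConfigurationError(f"theta[{pop}] must be in [0, 1]")
        if not (0.0 < self.ref_af <= 1.0):
            raise ConfigurationError("ref_af must be in (0, 1]")
        for pop, n in self.samples_by_pop.items():
            if n < 1:
                raise ConfigurationError(f"n_samples[{pop}] must be >= 1")
        if self.ploidy < 1:
            raise ConfigurationError("ploidy must be >= 1")

    @property
    def theta_by_pop(self) -> Dict[str, float]:
        if isinstance(self.theta, Mapping):
            return dict(self.theta)
        return {"pop1": float(self.theta)}

    @property
    def samples_by_pop(self) -> Dict[str, int]:
        pops = list(self.theta_by_pop)
        if isinstance(self.n_samples, Mapping):
            missing = set(pops) - set(self.n_samples)
            if missing:
                raise ConfigurationError(f"n_samples missing for {missing}")
            return {p: int(self.n_samples[p]) for p in pops}
        return {p: int(self.n_samples) for p in pops}


@dataclass
class VariantTable:
    """Generated variants with genotypes, panel and provenance flags."""

    records: List[VariantRecord]
    genotypes: np.ndarray  # (n_sites, n_samples, ploidy), allele indices
    samples: List[str]
    panel: PopulationPanel
    segregating_in: Dict[str, np.ndarray]  # pop -> bool per record

    def write_vcf(self, path, genome: GenomeSequence) -> None:
        lengths = {c: genome.length(c) for c in genome}
        genome_io.write_vcf(self.records, self.genotypes, self.samples,
                            lengths, path)

    def write_panel(self, path) -> None:
        genome_io.write_panel(self.panel, path)

    def to_sites(self, include_combined: bool = True) -> List[VariantSite]:
        from .population_filter import allele_frequencies

        return allele_frequencies(
            self.records, self.genotypes, self.samples, self.panel,
            include_combined=include_combined,
        )


def generate_variants(
    cfg: SyntheticVariantConfig, genome: GenomeSequence
) -> VariantTable:
    """Place biallelic SNVs and draw diploid genotypes (child seed offset 2).

    Each position is polymorphic in a population independently with that
    population's theta; at a polymorphic site every haplotype of that
    population carries the alternate allele with probability ``1 - ref_af``.
    Populations not segregating at the site are homozygous reference.
    """
    if genome.total_length == 0:
        raise ConfigurationError("genome is empty")
    rng = np.random.default_rng([cfg.seed, 2])
    thetas = cfg.theta_by_pop
    n_by_pop = cfg.samples_by_pop
    pops = list(thetas)
    samples: List[str] = []
    assignments: Dict[str, str] = {}
    sample_slices: Dict[str, slice] = {}
    offset = 0
    for pop in pops:
        n = n_by_pop[pop]
        names = [f"{pop}_s{i + 1:04d}" for i in range(n)]
        samples.extend(names)
        for s in names:
            assignments[s] = pop
        sample_slices[pop] = slice(offset, offset + n)
        offset += n

    records: List[VariantRecord] = []
    rows: List[np.ndarray] = []
    seg_flags: Dict[str, List[bool]] = {pop: [] for pop in pops}
    alt_p = 1.0 - cfg.ref_af
    for contig, seq in genome.contigs.items():
        clen = len(seq)
        selected = {
            pop: rng.random(clen) < thetas[pop] for pop in pops
        }
        any_sel = np.zeros(clen, dtype=bool)
        for pop in pops:
            any_sel |= selected[pop]
        positions = np.nonzero(any_sel)[0]
        for pos in positions.tolist():
            ref = seq[pos]
            if ref == "N":
                continue
            alt = rng.choice([b for b in "ACGT" if b != ref])
            geno = np.zeros((len(samples), cfg.ploidy), dtype=np.int8)
            for pop in pops:
                hit = bool(selected[pop][pos])
                seg_flags[pop].append(hit)
                if hit:
                    sl = sample_slices[pop]
                    n = n_by_pop[pop]
                    draws = rng.random((n, cfg.ploidy)) < alt_p
                    geno[sl] = draws.astype(np.int8)
            records.append(VariantRecord(contig, pos, ref, (str(alt),)))
            rows.append(geno)
    genotypes = (
        np.stack(rows) if rows
        else np.zeros((0, len(samples), cfg.ploidy), dtype=np.int8)
    )
    return VariantTable(
        records=records,
        genotypes=genotypes,
        samples=samples,
        panel=PopulationPanel(assignments),
        segregating_in={p: np.asarray(v, dtype=bool) for p, v in seg_flags.items()},
    )


def plant_sequence(
    genome: GenomeSequence, seq: str, contig: str, position: int
) -> GenomeSequence:
    """Copy of the genome with ``seq`` written at ``position`` (fixture aid)."""
    seq = seq.upper()
    bad = set(seq) - genome_io.VALID_BASES
    if bad:
        raise ValueError(f"invalid bases in planted sequence: {sorted(bad)}")
    return genome.with_replaced(contig, position, seq)


def variant_site(
    contig: str,
    position: int,
    ref: str,
    alt: str,
    alt_freq: Union[float, Mapping[str, float]],
    n_haplotypes: int = 100,
) -> VariantSite:
    """Hand-built variant site with exact per-population alt frequencies."""
    freqs = (
        dict(alt_freq) if isinstance(alt_freq, Mapping)
        else {"pop1": float(alt_freq)}
    )
    site = VariantSite(contig, position, ref, (alt,))
    for pop, q in freqs.items():
        if not (0.0 <= q <= 1.0):
            raise ConfigurationError("alt_freq must be in [0, 1]")
        site.freqs[pop] = np.array([1.0 - q, q])
        site.called_haplotypes[pop] = n_haplotypes
    return site


def expected_good_fraction(
    theta: float,
    ref_af: float,
    window_length: int,
    threshold: float = 0.99,
) -> float:
    """Probability a window of L independently-variable positions is good.

    A window with k variant positions has P_ref = ref_af**k, so it is good
    iff ref_af**k >= threshold; summing the binomial mass over qualifying k:

        sum_{k: ref_af^k >= threshold} C(L, k) theta^k (1 - theta)^(L - k)
    """
    for arg, name in ((theta, "theta"), (ref_af, "ref_af"),
                      (threshold, "threshold")):
        if not (0.0 <= arg <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    L = int(window_length)
    if L < 1:
        raise ValueError("window_length must be >= 1")
    if ref_af == 1.0:
        return 1.0
    k_max = -1
    for k in range(L + 1):
        if ref_af ** k >= threshold:
            k_max = k
        else:
            break
    if k_max < 0:
        return float(binom.pmf(0, L, theta)) if threshold <= 1.0 else 0.0
    return float(binom.cdf(k_max, L, theta))


def write_fixture(
    genome: GenomeSequence,
    models: Sequence[GeneModel],
    table: Optional[VariantTable],
    out_dir,
    manifest_extra: Optional[Dict] = None,
) -> Dict[str, str]:
    """Write genome.fa / genes.gff3 / variants.vcf / panel.tsv + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": str(out / "genome.fa"),
        "gff3": str(out / "genes.gff3"),
    }
    genome_io.write_fasta(genome, paths["genome"])
    genome_io.write_gff3(models, paths["gff3"])
    if table is not None:
        paths["vcf"] = str(out / "variants.vcf")
        paths["panel"] = str(out / "panel.tsv")
        table.write_vcf(paths["vcf"], genome)
        table.write_panel(paths["panel"])
    manifest = {"files": paths}
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
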