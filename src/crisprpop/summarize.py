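"""Result surfaces: filter-cascade ledgers, per-population comparisons,
per-gene good-target histograms and an auditor for user-supplied gRNAs.

The cascade ledger mirrors the usual presentation of guide-design studies:
how many windows were scanned, how many cleave within CDS, and how many
survive each successive filter down to the per-population good counts, with
percentages of the scanned total and marginal pass rates among CDS sites.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .genome_io import GenomeSequence, GenomicInterval, PopulationPanel
from .offtarget import OfftargetIndex, offtarget_filter
from .efficiency import EfficiencyModel, efficiency_filter, get_model, score
from .population_filter import (
    COMBINED,
    VariantIndex,
    VariantSite,
    classify_good,
    compute_pref,
    is_potential,
    nucleotide_diversity,
)
from .site_scan import (
    NucleaseSpec,
    TargetSite,
    assign_to_cds,
    gc_filter,
    get_spec,
    matches_motif,
)

logger = logging.getLogger(__name__)

HISTOGRAM_BINS = [str(i) for i in range(11)] + [">10"]


@dataclass
class StageCounts:
    """Ledger of how many sites survive each filter stage."""

    label: str
    n_scanned: int
    n_cds: int
    n_gc_pass: int
    n_offtarget_pass: int
    n_efficiency_pass: int
    n_potential: int
    n_good: Dict[str, int] = field(default_factory=dict)
    marginal_cds_rates: Dict[str, float] = field(default_factory=dict)

    @property
    def percentages(self) -> Dict[str, float]:
        def pct(x: int) -> float:
            return round(100.0 * x / self.n_scanned, 2) if self.n_scanned else 0.0

        out = {
            "cds": pct(self.n_cds),
            "gc_pass": pct(self.n_gc_pass),
            "offtarget_pass": pct(self.n_offtarget_pass),
            "efficiency_pass": pct(self.n_efficiency_pass),
            "potential": pct(self.n_potential),
        }
        for pop, n in self.n_good.items():
            out[f"good_{pop}"] = pct(n)
        return out


def stage_counts(
    targets: Sequence[TargetSite],
    populations: Sequence[str],
    label: str = "",
) -> StageCounts:
    """Cascade counts in filter order scanned->CDS->GC->off-target->efficiency.

    Counts are nested (each stage among survivors of the previous); marginal
    pass rates of each filter among all CDS sites are reported separately,
    since a filter's headline impact is usually quoted that way.
    """
    n_scanned = len(targets)
    cds = [t for t in targets if t.passed("cds")]
    gc_pass = [t for t in cds if t.passed("gc")]
    ot_pass = [t for t in gc_pass if t.passed("offtarget")]
    eff_pass = [t for t in ot_pass if t.passed("efficiency")]
    potential = [t for t in eff_pass if is_potential(t)]
    n_good = {
        pop: sum(1 for t in potential if t.good.get(pop)) for pop in populations
    }
    marginal = {}
    for name in ("gc", "offtarget", "efficiency"):
        evaluated = [t for t in cds if t.filter_flags.get(name) is not None]
        if evaluated:
            marginal[name] = round(
                100.0 * sum(1 for t in evaluated if t.passed(name)) / len(evaluated),
                2,
            )
    return StageCounts(
        label=label,
        n_scanned=n_scanned,
        n_cds=len(cds),
        n_gc_pass=len(gc_pass),
        n_offtarget_pass=len(ot_pass),
        n_efficiency_pass=len(eff_pass),
        n_potential=len(potential),
        n_good=n_good,
        marginal_cds_rates=marginal,
    )


@dataclass
class GeneTargetCounts:
    gene_id: str
    cas9_good: int = 0
    cas12a_good: int = 0

    @property
    def combined(self) -> int:
        return self.cas9_good + self.cas12a_good


def per_gene_counts(
    targets: Iterable[TargetSite],
    gene_ids: Sequence[str],
    population: str = COMBINED,
) -> List[GeneTargetCounts]:
    """Good targets per annotated gene for each nuclease plus their sum.

    Genes with zero good targets are retained; a target overlapping the CDS
    of several genes counts once per gene (so per-gene sums can exceed the
    genome-wide total).
    """
    counts = {g: GeneTargetCounts(g) for g in gene_ids}
    for t in targets:
        if not t.good.get(population):
            continue
        for g in t.gene_ids:
            if g not in counts:
                continue
            if t.nuclease == "cas9":
                counts[g].cas9_good += 1
            elif t.nuclease == "cas12a":
                counts[g].cas12a_good += 1
    return [counts[g] for g in gene_ids]


def per_gene_histogram(
    targets: Iterable[TargetSite],
    gene_ids: Sequence[str],
    population: str = COMBINED,
) -> Dict[str, Dict[str, int]]:
    """Distribution of genes over good-target count bins 0..10 and >10."""
    rows = per_gene_counts(targets, gene_ids, population)
    series = {"cas9": {}, "cas12a": {}, "combined": {}}
    for name in series:
        series[name] = {b: 0 for b in HISTOGRAM_BINS}
    for row in rows:
        for name, value in (
            ("cas9", row.cas9_good),
            ("cas12a", row.cas12a_good),
            ("combined", row.combined),
        ):
            key = str(value) if value <= 10 else ">10"
            series[name][key] += 1
    return series


def population_comparison(
    targets: Sequence[TargetSite],
    sites: Sequence[VariantSite],
    panel: PopulationPanel,
    cds_intervals: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Per-population good counts alongside CDS nucleotide diversity."""
    pops = panel.populations
    if len(pops) < 2:
        logger.warning(
            "panel has %d population(s); comparison degenerates to a pooled "
            "report", len(pops),
        )
    potential = [t for t in targets if is_potential(t)]
    rows = []
    for pop in pops:
        n_good = sum(1 for t in potential if t.good.get(pop))
        pi = nucleotide_diversity(sites, cds_intervals, pop)
        rows.append(
            {
                "population": pop,
                "n_samples": len(panel.samples(pop)),
                "n_potential": len(potential),
                "n_good": n_good,
                "pct_good_of_potential": round(
                    100.0 * n_good / len(potential), 2
                ) if potential else 0.0,
                "pi_cds": pi,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Guide auditing


@dataclass
class GuideReport:
    """Verdict for one user-supplied spacer sequence against the genome."""

    sequence: str
    nuclease: str
    loci: List[TargetSite] = field(default_factory=list)
    verdict: str = "not_found"  # pass | fail | not_found
    reasons: List[str] = field(default_factory=list)
    pref: Dict[str, float] = field(default_factory=dict)


def _locate_guide(
    genome: GenomeSequence, spacer: str, spec: NucleaseSpec
) -> List[TargetSite]:
    """Exact spacer occurrences adjacent to a valid PAM, both strands."""
    from .site_scan import scan_targets  # local to avoid cycle at import time

    loci = []
    for contig, seq in genome.contigs.items():
        clen = len(seq)
        for strand in ("+", "-"):
            oriented = seq if strand == "+" else _revcomp(seq)
            start = oriented.find(spacer)
            while start != -1:
                w_local = start - spec.spacer_offset()
                if 0 <= w_local and w_local + spec.window_length <= clen:
                    pam = oriented[
                        w_local + spec.pam_offset():
                        w_local + spec.pam_offset() + spec.pam_length
                    ]
                    if matches_motif(pam, spec.pam_motif):
                        g_start = (
                            w_local if strand == "+"
                            else clen - (w_local + spec.window_length)
                        )
                        bonds = spec.local_cut_bonds()
                        if strand == "+":
                            cut = tuple(g_start + b for b in bonds)
                        else:
                            cut = tuple(
                                sorted(g_start + spec.window_length - b
                                       for b in bonds)
                            )
                        loci.append(
                            TargetSite(
                                nuclease=spec.name,
                                window=GenomicInterval(
                                    contig, g_start,
                                    g_start + spec.window_length, strand,
                                ),
                                spacer=spacer,
                                pam=pam,
                                cut_positions=cut,
                                gc=(spacer.count("G") + spacer.count("C"))
                                / spec.spacer_length,
                            )
                        )
                start = oriented.find(spacer, start + 1)
    return loci


def _revcomp(seq: str) -> str:
    from .genome_io import reverse_complement

    return reverse_complement(seq)


def evaluate_guides(
    guides: Sequence[Tuple[str, str]],
    genome: GenomeSequence,
    models,
    variants: "VariantIndex | Sequence[VariantSite]",
    populations: Sequence[str] = (COMBINED,),
    gc_bounds: Tuple[float, float] = (0.40, 0.80),
    max_mm: int = 3,
    require_pam: bool = True,
    efficiency_models: Optional[Mapping[str, str]] = None,
    efficiency_threshold: float = 0.5,
    pref_threshold: float = 0.99,
    include_degenerate_pam: bool = False,
    offtarget_indexes: Optional[Mapping[str, OfftargetIndex]] = None,
    decision_population: str = COMBINED,
) -> List[GuideReport]:
    """Audit published / proposed gRNAs against the full filter chain.

    Each guide is located by exact spacer match with a required adjacent
    PAM; every located occurrence runs through the CDS, GC, off-target,
    efficiency and P_ref filters.  The verdict is ``pass`` when at least
    one locus passes everything, with failed filters and offending values
    listed otherwise.
    """
    if not isinstance(variants, VariantIndex):
        variants = VariantIndex(variants)
    if efficiency_models is None:
        efficiency_models = {}
    reports = []
    for raw_seq, nuclease in guides:
        spacer = raw_seq.strip().upper()
        spec = get_spec(nuclease)
        if len(spacer) != spec.spacer_length:
            raise ValueError(
                f"guide {spacer!r} has length {len(spacer)}; {nuclease} "
                f"expects {spec.spacer_length}"
            )
        report = GuideReport(sequence=spacer, nuclease=nuclease)
        loci = _locate_guide(genome, spacer, spec)
        if not loci:
            reports.append(report)
            continue
        if offtarget_indexes and nuclease in offtarget_indexes:
            ot_index = offtarget_indexes[nuclease]
        else:
            ot_index = OfftargetIndex(genome, spec, max_mm, require_pam)
        model = get_model(
            efficiency_models.get(
                nuclease,
                {"cas9": "surrogate_cas9", "cas12a": "surrogate_cas12a"}.get(
                    nuclease, "uniform"
                ),
            )
        )
        any_pass = False
        all_reasons: List[str] = []
        # drain the generator so CDS flags are set on every locus
        list(assign_to_cds(iter(loci), models))
        for locus in loci:
            reasons = []
            if not locus.passed("cds"):
                reasons.append("cds:cut outside CDS")
            if not gc_filter(locus, *gc_bounds):
                reasons.append(f"gc:{locus.gc:.2f}")
            if not offtarget_filter(locus, index=ot_index):
                reasons.append(
                    f"offtarget:min_mismatches={locus.min_offtarget_mismatches}"
                )
            score(locus, genome, model)
            if not efficiency_filter(locus, efficiency_threshold):
                reasons.append(f"efficiency:{locus.efficiency:.3f}")
            for pop in populations:
                res = compute_pref(
                    locus, variants, pop, pref_threshold, include_degenerate_pam
                )
                locus.pref[pop] = res.pref
                locus.good[pop] = res.good
            decision_pref = locus.pref.get(decision_population, 1.0)
            if decision_pref < pref_threshold:
                reasons.append(f"pref={decision_pref:.4g}")
            report.loci.append(locus)
            if not reasons:
                any_pass = True
            all_reasons.extend(reasons)
        best = max(report.loci, key=lambda l: l.pref.get(decision_population, 0.0))
        report.pref = dict(best.pref)
        report.verdict = "pass" if any_pass else "fail"
        if not any_pass:
            report.reasons = sorted(set(all_reasons))
        reports.append(report)
    return reports


# ---------------------------------------------------------------------------
# Report output


def write_report(
    out_dir,
    stage: Sequence[StageCounts] = (),
    gene_counts: Sequence[GeneTargetCounts] = (),
    comparison: Optional[pd.DataFrame] = None,
    guide_reports: Sequence[GuideReport] = (),
    config: Optional[Mapping] = None,
) -> Dict[str, str]:
    """Write the TSV report files and a versioned summary.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}

    rows = []
    for sc in stage:
        row = {
            "label": sc.label,
            "n_scanned": sc.n_scanned,
            "n_cds": sc.n_cds,
            "n_gc_pass": sc.n_gc_pass,
            "n_offtarget_pass": sc.n_offtarget_pass,
            "n_efficiency_pass": sc.n_efficiency_pass,
            "n_potential": sc.n_potential,
        }
        for pop, n in sc.n_good.items():
            row[f"n_good_{pop}"] = n
        for k, v in sc.percentages.items():
            row[f"pct_{k}"] = v
        rows.append(row)
    paths["stage_counts"] = str(out / "stage_counts.tsv")
    pd.DataFrame(
        rows,
        columns=None if rows else ["label", "n_scanned", "n_cds", "n_gc_pass",
                                   "n_offtarget_pass", "n_efficiency_pass",
                                   "n_potential"],
    ).to_csv(paths["stage_counts"], sep="\t", index=False)

    paths["per_gene_counts"] = str(out / "per_gene_counts.tsv")
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "cas9_good": g.cas9_good,
                "cas12a_good": g.cas12a_good,
                "combined": g.combined,
            }
            for g in gene_counts
        ],
        columns=["gene_id", "cas9_good", "cas12a_good", "combined"],
    ).to_csv(paths["per_gene_counts"], sep="\t", index=False)

    paths["population_comparison"] = str(out / "population_comparison.tsv")
    if comparison is None:
        comparison = pd.DataFrame(
            columns=["population", "n_samples", "n_potential", "n_good",
                     "pct_good_of_potential", "pi_cds"]
        )
    comparison.to_csv(paths["population_comparison"], sep="\t", index=False)

    paths["guide_reports"] = str(out / "guide_reports.tsv")
    pd.DataFrame(
        [
            {
                "sequence": r.sequence,
                "nuclease": r.nuclease,
                "n_loci": len(r.loci),
                "verdict": r.verdict,
                "reasons": ";".join(r.reasons),
                **{f"pref_{p}": v for p, v in sorted(r.pref.items())},
            }
            for r in guide_reports
        ],
        columns=["sequence", "nuclease", "n_loci", "verdict", "reasons"]
        if not guide_reports else None,
    ).to_csv(paths["guide_reports"], sep="\t", index=False)

    paths["summary"] = str(out / "summary.json")
    summary = {
        "schema_version": 1,
        "tool_version": __version__,
        "config": dict(config or {}),
        "stage_counts": [
            {
                "label": sc.label,
                "n_scanned": sc.n_scanned,
                "n_cds": sc.n_cds,
                "n_gc_pass": sc.n_gc_pass,
                "n_offtarget_pass": sc.n_offtarget_pass,
                "n_efficiency_pass": sc.n_efficiency_pass,
                "n_potential": sc.n_potential,
                "n_good": sc.n_good,
                "percentages": sc.percentages,
                "marginal_cds_rates": sc.marginal_cds_rates,
            }
            for sc in stage
        ],
        "n_guides": len(guide_reports),
    }
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return paths


def plot_per_gene_histogram(histogram: Mapping[str, Mapping[str, int]], path) -> None:
    """Bar chart of the per-gene good-target distribution (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    bins = HISTOGRAM_BINS
    width = 0.27
    for i, (name, series) in enumerate(histogram.items()):
        xs = [j + (i - 1) * width for j in range(len(bins))]
        ax.bar(xs, [series[b] for b in bins], width=width, label=name)
    ax.set_xticks(range(len(bins)))
    ax.set_xticklabels(bins)
    ax.set_xlabel("good targets per gene")
    ax.set_ylabel("genes")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
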