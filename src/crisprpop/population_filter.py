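"""Population polymorphism filtering: allele frequencies, P_ref, diversity.

The reference-match probability of a target window, ``P_ref``, is the chance
that a genome sampled from a population matches the reference across the
window.  Treating each variant as independent,

    P_ref = prod over overlapping variant sites of (1 - q)

where ``q`` is the site's summed non-reference allele frequency in that
population.  A *potential* target (one that passed the GC, off-target and
efficiency filters) with ``P_ref >= 0.99`` is classified a *good* target:
at most a 1% chance that the sampled genome carries a variant in the window.

Fully degenerate PAM positions (the N of NGG / TTTN) are excluded from the
scored window by default — no substitution there abolishes recognition.

Nucleotide diversity over a set of intervals uses the unbiased per-site
estimator pi = sum_sites (n/(n-1)) * (1 - sum_i p_i^2) / total_length with
``n`` the called haplotypes at the site and ``p_i`` the allele frequencies;
monomorphic positions contribute only interval length.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .genome_io import (
    GenomicInterval,
    PopulationPanel,
    VariantRecord,
)
from .site_scan import TargetSite, get_spec

logger = logging.getLogger(__name__)

COMBINED = "combined"

POTENTIAL_FILTERS = ("cds", "gc", "offtarget", "efficiency")


@dataclass
class VariantSite:
    """One polymorphic position with per-population allele frequencies.

    ``freqs[pop]`` is the allele-frequency vector (reference first, then the
    ALT alleles in record order) over called haplotypes; populations with no
    called alleles at the site are absent from the maps.
    """

    contig: str
    position: int
    ref: str
    alts: Tuple[str, ...]
    freqs: Dict[str, np.ndarray] = field(default_factory=dict)
    called_haplotypes: Dict[str, int] = field(default_factory=dict)

    def alt_freq(self, population: str) -> float:
        """Summed non-reference allele frequency in ``population``."""
        return float(self.freqs[population][1:].sum())

    @property
    def span(self) -> Tuple[int, int]:
        """Reference footprint ``[position, position + len(ref))``."""
        return self.position, self.position + len(self.ref)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)


def allele_frequencies(
    records: Sequence[VariantRecord],
    genotypes: np.ndarray,
    samples: Sequence[str],
    panel: PopulationPanel,
    include_combined: bool = True,
) -> List[VariantSite]:
    """Per-population allele frequencies from a genotype array.

    ``genotypes`` has shape (n_sites, n_samples, ploidy) with allele indices
    and -1 for missing calls, which are excluded from denominators.  The
    pooled frequency over all panel samples is stored under ``"combined"``
    when requested.
    """
    unknown = [s for s in samples if s not in panel.assignments]
    if unknown:
        raise ValueError(f"samples missing from panel: {unknown[:5]}")
    groups: Dict[str, np.ndarray] = {}
    for pop in panel.populations:
        idx = [i for i, s in enumerate(samples) if panel.assignments[s] == pop]
        if idx:
            groups[pop] = np.asarray(idx)
    if include_combined:
        groups[COMBINED] = np.arange(len(samples))
    sites: List[VariantSite] = []
    for i, rec in enumerate(records):
        n_alleles = 1 + len(rec.alts)
        site = VariantSite(rec.contig, rec.position, rec.ref, rec.alts)
        for pop, idx in groups.items():
            alleles = genotypes[i, idx, :].ravel()
            called = alleles[alleles >= 0]
            if called.size == 0:
                logger.warning(
                    "site %s:%d has no called alleles in %s; skipped",
                    rec.contig, rec.position, pop,
                )
                continue
            counts = np.bincount(called, minlength=n_alleles)
            site.freqs[pop] = counts / called.size
            site.called_haplotypes[pop] = int(called.size)
        sites.append(site)
    return sites


class VariantIndex:
    """Per-contig sorted index for window-overlap queries (indel-aware)."""

    def __init__(self, sites: Iterable[VariantSite]):
        self._by_contig: Dict[str, Tuple[List[int], List[VariantSite]]] = {}
        self._max_ref: Dict[str, int] = {}
        grouped: Dict[str, List[VariantSite]] = {}
        for s in sites:
            grouped.setdefault(s.contig, []).append(s)
        for contig, ss in grouped.items():
            ss.sort(key=lambda s: s.position)
            self._by_contig[contig] = ([s.position for s in ss], ss)
            self._max_ref[contig] = max(len(s.ref) for s in ss)

    def overlapping(self, contig: str, start: int, end: int) -> List[VariantSite]:
        """Sites whose reference footprint intersects ``[start, end)``."""
        entry = self._by_contig.get(contig)
        if entry is None:
            return []
        positions, ss = entry
        lo = bisect.bisect_left(positions, start - self._max_ref[contig] + 1)
        hi = bisect.bisect_left(positions, end)
        out = []
        for s in ss[lo:hi]:
            a, b = s.span
            if a < end and start < b:
                out.append(s)
        return out


@dataclass
class PrefResult:
    """Reference-match probability of one target in one population."""

    target: TargetSite
    population: str
    pref: float
    n_variants: int
    good: bool


def scored_positions_excluded(
    target: TargetSite, include_degenerate_pam: bool = False
) -> frozenset:
    """Genomic positions inside the window excluded from P_ref scoring."""
    if include_degenerate_pam:
        return frozenset()
    spec = get_spec(target.nuclease)
    w = target.window
    excluded = []
    for off in spec.degenerate_pam_window_offsets():
        if w.strand == "+":
            excluded.append(w.start + off)
        else:
            excluded.append(w.end - 1 - off)
    return frozenset(excluded)


def compute_pref(
    target: TargetSite,
    variants: "VariantIndex | Iterable[VariantSite]",
    population: str,
    threshold: float = 0.99,
    include_degenerate_pam: bool = False,
) -> PrefResult:
    """Product of per-site reference-allele frequencies over the window.

    SNVs falling on excluded (degenerate PAM) positions are not scored;
    indels are scored once on any overlap.  No overlapping variants gives
    ``pref = 1``.  The good flag here reflects the threshold only; pipeline
    classification additionally requires the site to be a potential target.
    """
    if not isinstance(variants, VariantIndex):
        variants = VariantIndex(variants)
    w = target.window
    excluded = scored_positions_excluded(target, include_degenerate_pam)
    pref = 1.0
    n = 0
    for site in variants.overlapping(w.contig, w.start, w.end):
        if population not in site.freqs:
            continue
        if site.is_snv and site.position in excluded:
            continue
        q = site.alt_freq(population)
        if q > 0.0:
            pref *= 1.0 - q
            n += 1
        else:
            n += 1
    good = pref >= threshold
    return PrefResult(target, population, pref, n, good)


def is_potential(target: TargetSite) -> bool:
    """True when every evaluated upstream filter passed."""
    return all(
        target.filter_flags.get(name, True) is True
        for name in POTENTIAL_FILTERS
    )


def classify_good(
    targets: Iterable[TargetSite],
    variants: "VariantIndex | Iterable[VariantSite]",
    populations: Sequence[str],
    threshold: float = 0.99,
    include_degenerate_pam: bool = False,
) -> List[TargetSite]:
    """Annotate targets with per-population P_ref and good flags.

    Good is recorded per population and only for potential targets (those
    passing the GC, off-target and efficiency filters within CDS), so the
    good set is contained in the potential set by construction.
    """
    if not isinstance(variants, VariantIndex):
        variants = VariantIndex(variants)
    out = []
    for t in targets:
        potential = is_potential(t)
        for pop in populations:
            res = compute_pref(
                t, variants, pop, threshold, include_degenerate_pam
            )
            t.pref[pop] = res.pref
            t.good[pop] = bool(potential and res.good)
        out.append(t)
    return out


def _merge_spans(intervals: Sequence[GenomicInterval]) -> Dict[str, List[Tuple[int, int]]]:
    by_contig: Dict[str, List[Tuple[int, int]]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    merged: Dict[str, List[Tuple[int, int]]] = {}
    for contig, spans in by_contig.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[contig] = [(s, e) for s, e in out]
    return merged


def nucleotide_diversity(
    variants: Iterable[VariantSite],
    intervals: Sequence[GenomicInterval],
    population: str,
) -> float:
    """Per-site nucleotide diversity (pi) over the union of ``intervals``."""
    if not intervals:
        raise ValueError("no intervals supplied")
    merged = _merge_spans(intervals)
    total = sum(e - s for spans in merged.values() for s, e in spans)
    numerator = 0.0
    for site in variants:
        spans = merged.get(site.contig)
        if spans is None:
            continue
        i = bisect.bisect_right([s for s, _ in spans], site.position) - 1
        if i < 0 or site.position >= spans[i][1]:
            continue
        if population not in site.freqs:
            continue
        n = site.called_haplotypes[population]
        if n < 2:
            raise ValueError(
                f"site {site.contig}:{site.position} has {n} called "
                f"haplotype(s) in {population}; diversity undefined"
            )
        p = site.freqs[population]
        het = 1.0 - float(np.sum(p * p))
        numerator += n / (n - 1) * het
    return numerator / total
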