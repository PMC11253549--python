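"""End-to-end orchestration: scan -> CDS -> dedup -> GC -> off-target ->
efficiency -> P_ref -> summaries, with every stage toggleable.

Disabled filters are recorded as passing so the cascade stays well defined;
filters are evaluated on *all* CDS-cleaving sites rather than short-circuit
survivors only, so marginal per-filter pass rates can be reported and P_ref
is known even for sites that failed an upstream filter (good targets remain
a subset of potential targets by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

from .genome_io import GeneModel, GenomeSequence
from .offtarget import OfftargetIndex, offtarget_filter
from .efficiency import default_model_for, efficiency_filter, get_model, score
from .population_filter import (
    COMBINED,
    VariantIndex,
    VariantSite,
    classify_good,
)
from .site_scan import TargetSite, assign_to_cds, dedup, gc_filter, get_spec, scan_targets
from .summarize import StageCounts, stage_counts

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and toggles of one reproducible pipeline run.

    Defaults encode the standard profile: GC in [0.40, 0.80], no off-target
    within 3 mismatches, efficiency >= 0.5, P_ref >= 0.99.
    """

    nucleases: Tuple[str, ...] = ("cas9", "cas12a")
    cds_enabled: bool = True
    cds_mode: str = "all"
    gc_enabled: bool = True
    gc_lo: float = 0.40
    gc_hi: float = 0.80
    offtarget_enabled: bool = True
    offtarget_max_mm: int = 3
    offtarget_require_pam: bool = True
    efficiency_enabled: bool = True
    efficiency_model: Optional[str] = None  # None -> per-nuclease surrogate
    efficiency_threshold: float = 0.5
    pref_threshold: float = 0.99
    include_degenerate_pam: bool = False
    seed: int = 0

    def to_dict(self) -> Dict:
        return asdict(self)


@dataclass
class PipelineResult:
    """Annotated targets and cascade ledgers for each nuclease."""

    config: RunConfig
    targets: Dict[str, List[TargetSite]]
    stage: Dict[str, StageCounts]
    populations: List[str]

    def good_targets(self, nuclease: str, population: str = COMBINED) -> List[TargetSite]:
        return [t for t in self.targets[nuclease] if t.good.get(population)]

    def potential_targets(self, nuclease: str) -> List[TargetSite]:
        from .population_filter import is_potential

        return [t for t in self.targets[nuclease] if is_potential(t)]


def run_pipeline(
    genome: GenomeSequence,
    models: Sequence[GeneModel],
    sites: Optional[Sequence[VariantSite]] = None,
    config: Optional[RunConfig] = None,
) -> PipelineResult:
    config = config or RunConfig()
    variant_index = VariantIndex(sites) if sites else None
    populations: List[str] = []
    if sites:
        seen: Dict[str, None] = {}
        for s in sites:
            for pop in s.freqs:
                seen.setdefault(pop)
        populations = list(seen)

    all_targets: Dict[str, List[TargetSite]] = {}
    ledgers: Dict[str, StageCounts] = {}
    for nuclease in config.nucleases:
        spec = get_spec(nuclease)
        targets = dedup(scan_targets(genome, spec))
        targets.sort(key=lambda t: t.key)
        logger.info("%s: scanned %d candidate windows", nuclease, len(targets))

        if config.cds_enabled:
            list(assign_to_cds(iter(targets), models, mode=config.cds_mode))
        else:
            for t in targets:
                t.filter_flags["cds"] = True
        cds_targets = [t for t in targets if t.passed("cds")]
        logger.info("%s: %d cleave within CDS", nuclease, len(cds_targets))

        if config.gc_enabled:
            n = sum(gc_filter(t, config.gc_lo, config.gc_hi) for t in cds_targets)
        else:
            for t in cds_targets:
                t.filter_flags["gc"] = True
            n = len(cds_targets)
        logger.info("%s: %d pass GC filter", nuclease, n)

        if config.offtarget_enabled:
            index = OfftargetIndex(
                genome, spec, config.offtarget_max_mm, config.offtarget_require_pam
            )
            n = sum(offtarget_filter(t, index=index) for t in cds_targets)
        else:
            for t in cds_targets:
                t.filter_flags["offtarget"] = True
            n = len(cds_targets)
        logger.info("%s: %d pass off-target filter", nuclease, n)

        if config.efficiency_enabled:
            model = get_model(config.efficiency_model or default_model_for(nuclease))
            for t in cds_targets:
                score(t, genome, model)
            n = sum(
                efficiency_filter(t, config.efficiency_threshold)
                for t in cds_targets
            )
        else:
            for t in cds_targets:
                t.filter_flags["efficiency"] = True
            n = len(cds_targets)
        logger.info("%s: %d pass efficiency filter", nuclease, n)

        if variant_index is not None:
            classify_good(
                cds_targets,
                variant_index,
                populations,
                config.pref_threshold,
                config.include_degenerate_pam,
            )
        ledger = stage_counts(targets, populations, label=nuclease)
        logger.info(
            "%s: %d potential, good per population %s",
            nuclease, ledger.n_potential, ledger.n_good,
        )
        all_targets[nuclease] = targets
        ledgers[nuclease] = ledger
    return PipelineResult(
        config=config,
        targets=all_targets,
        stage=ledgers,
        populations=populations,
    )
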