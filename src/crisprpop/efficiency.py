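"""Pluggable gRNA cleavage-efficiency scoring and the >= 0.5 filter.

Trained on-target activity models (regression or neural predictors) are
deliberately not reproduced here; the pipeline's behaviour is exercised with
deterministic surrogate models — a fixed position x nucleotide weight table,
summed over the spacer and squashed through a logistic to [0, 1] — shipped
as versioned TSV fixtures.  External models can be registered through the
same interface; all scores live on a 0-1 scale and sites pass the filter at
a threshold of 0.5 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Dict, List, Optional

from .genome_io import GenomeSequence, GenomicInterval
from .site_scan import TargetSite


class RegistrationError(ValueError):
    pass


class StateError(RuntimeError):
    pass


@dataclass(frozen=True)
class EfficiencyModel:
    """A named deterministic scoring function on (spacer, context) -> [0, 1].

    ``required_context`` is the number of bases up- and downstream of the
    target window the model wants to see; the scorer is handed whatever is
    available (truncated at contig ends, with a flag on the target).
    """

    name: str
    scorer: Callable[[str, str], float]
    required_context: int = 0
    version: str = "1"

    def score_sequence(self, spacer: str, context: str = "") -> float:
        value = float(self.scorer(spacer, context))
        if not (0.0 <= value <= 1.0):
            raise ValueError(
                f"model {self.name!r} produced out-of-range score {value}"
            )
        return value


def _load_weight_table(resource_name: str) -> Dict[int, Dict[str, float]]:
    text = (
        resources.files("crisprpop.data").joinpath(resource_name).read_text()
    )
    table: Dict[int, Dict[str, float]] = {}
    header: Optional[List[str]] = None
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts[1:]
            continue
        table[int(parts[0])] = {
            base: float(v) for base, v in zip(header, parts[1:])
        }
    return table


def position_weight_model(
    name: str, resource_name: str, version: str = "1"
) -> EfficiencyModel:
    """Surrogate scorer: logistic of the summed per-position weights.

    Positions without a table row (spacer longer than the table) and bases
    absent from the table (e.g. N) contribute weight 0.
    """
    table = _load_weight_table(resource_name)

    def scorer(spacer: str, context: str) -> float:
        total = 0.0
        for i, base in enumerate(spacer):
            total += table.get(i, {}).get(base, 0.0)
        return 1.0 / (1.0 + math.exp(-total))

    return EfficiencyModel(
        name=name, scorer=scorer, required_context=0, version=version
    )


_REGISTRY: Dict[str, EfficiencyModel] = {}


def register_model(model: EfficiencyModel) -> None:
    if model.name in _REGISTRY:
        raise RegistrationError(f"model {model.name!r} already registered")
    _REGISTRY[model.name] = model


def get_model(name: str) -> EfficiencyModel:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"no efficiency model named {name!r}") from None


def list_models() -> List[str]:
    return sorted(_REGISTRY)


def _register_builtins() -> None:
    register_model(EfficiencyModel("uniform", lambda spacer, context: 1.0))
    register_model(position_weight_model("surrogate_cas9", "surrogate_cas9.tsv"))
    register_model(
        position_weight_model("surrogate_cas12a", "surrogate_cas12a.tsv")
    )


_register_builtins()


def default_model_for(nuclease: str) -> str:
    return {"cas9": "surrogate_cas9", "cas12a": "surrogate_cas12a"}.get(
        nuclease, "uniform"
    )


def score(
    target: TargetSite, genome: GenomeSequence, model: EfficiencyModel
) -> float:
    """Score a target in place; deterministic for identical inputs."""
    w = target.window
    ctx_start = max(0, w.start - model.required_context)
    ctx_end = min(genome.length(w.contig), w.end + model.required_context)
    truncated = (
        ctx_start > w.start - model.required_context
        or ctx_end < w.end + model.required_context
    )
    context = genome.fetch(
        GenomicInterval(w.contig, ctx_start, ctx_end, w.strand)
    )
    value = model.score_sequence(target.spacer, context)
    target.efficiency = value
    if truncated and model.required_context:
        target.filter_flags["context_truncated"] = True
    return value


def efficiency_filter(target: TargetSite, threshold: float = 0.5) -> bool:
    """Pass iff the stored efficiency score is at least ``threshold``."""
    if target.efficiency is None:
        raise StateError("target has no efficiency score; call score() first")
    ok = target.efficiency >= threshold
    target.filter_flags["efficiency"] = ok
    return ok
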