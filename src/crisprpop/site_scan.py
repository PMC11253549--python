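"""Candidate target-site enumeration for parametric CRISPR nucleases.

A nuclease is described by its PAM motif (IUPAC), which side of the spacer
the PAM sits on, the spacer length and the cut offsets.  Scanning emits every
window on either strand whose PAM-aligned bases match the motif; reverse
strand sites are reported with spacer/PAM taken from the reverse complement
and the window in forward coordinates.  Windows containing N are skipped —
the protospacer identity cannot be guaranteed through an ambiguous base.

Cut positions are *bond* coordinates: integer genomic offsets where the cut
falls between bases ``c-1`` and ``c``.  Cas9 cleaves bluntly 3 bp 5' of its
NGG PAM; Cas12a nicks the two strands at different distances from its TTTN
PAM, leaving staggered ends, modelled here as two bond coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree

from .genome_io import GenomeSequence, GenomicInterval, GeneModel, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_reverse_complement(motif: str) -> str:
    return motif.translate(_IUPAC_COMP)[::-1]


def matches_motif(seq: str, motif: str) -> bool:
    """True iff ``seq`` matches ``motif`` position-wise under IUPAC codes.

    A genome N never matches (even motif N): recognition cannot be asserted.
    """
    if len(seq) != len(motif):
        return False
    return all(b in IUPAC[m] for b, m in zip(seq, motif))


@dataclass(frozen=True)
class NucleaseSpec:
    """Parametric description of a nuclease's PAM and cut geometry.

    ``cut_offsets`` are distances in bp from the PAM-proximal end of the
    spacer; each produces one bond coordinate inside the target window.
    """

    name: str
    pam_motif: str
    pam_side: str  # "5prime" or "3prime"
    spacer_length: int
    cut_offsets: Tuple[int, ...]

    def __post_init__(self) -> None:
        if self.pam_side not in ("5prime", "3prime"):
            raise ValueError(f"pam_side must be 5prime/3prime, got {self.pam_side!r}")
        for ch in self.pam_motif:
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC code {ch!r} in PAM motif")
        for off in self.cut_offsets:
            if not (0 <= off <= self.spacer_length):
                raise ValueError(f"cut offset {off} outside spacer")

    @property
    def pam_length(self) -> int:
        return len(self.pam_motif)

    @property
    def window_length(self) -> int:
        return self.spacer_length + self.pam_length

    def spacer_offset(self) -> int:
        """Offset of the spacer within a plus-strand window."""
        return self.pam_length if self.pam_side == "5prime" else 0

    def pam_offset(self) -> int:
        """Offset of the PAM within a plus-strand window."""
        return 0 if self.pam_side == "5prime" else self.spacer_length

    def local_cut_bonds(self) -> Tuple[int, ...]:
        """Cut bond coordinates within a plus-strand window (0..window_length)."""
        if self.pam_side == "3prime":
            # PAM-proximal spacer end is the right edge of the spacer.
            return tuple(self.spacer_length - off for off in self.cut_offsets)
        return tuple(self.pam_length + off for off in self.cut_offsets)

    def degenerate_pam_window_offsets(self) -> Tuple[int, ...]:
        """Plus-strand window offsets of fully degenerate (N) PAM positions."""
        base = self.pam_offset()
        return tuple(base + i for i, m in enumerate(self.pam_motif) if m == "N")


def builtin_specs() -> Tuple[NucleaseSpec, NucleaseSpec]:
    """The two nucleases of interest: SpCas9 (NGG) and Cas12a/Cpf1 (TTTN).

    Cas9: 20-nt spacer + 3-nt PAM = 23-bp window; blunt cut 3 bp from the
    PAM.  Cas12a: 4-nt PAM + 23-nt spacer = 27-bp window; staggered cuts
    after spacer positions 18 and 23 (distal from the PAM).
    """
    cas9 = NucleaseSpec(
        name="cas9",
        pam_motif="NGG",
        pam_side="3prime",
        spacer_length=20,
        cut_offsets=(3,),
    )
    cas12a = NucleaseSpec(
        name="cas12a",
        pam_motif="TTTN",
        pam_side="5prime",
        spacer_length=23,
        cut_offsets=(18, 23),
    )
    return cas9, cas12a


def get_spec(name: str) -> NucleaseSpec:
    for spec in builtin_specs():
        if spec.name == name:
            return spec
    raise KeyError(f"unknown nuclease {name!r}")


@dataclass
class TargetSite:
    """One candidate protospacer + PAM window with its filter annotations."""

    nuclease: str
    window: GenomicInterval
    spacer: str
    pam: str
    cut_positions: Tuple[int, ...]
    gene_ids: Set[str] = field(default_factory=set)
    gc: float = 0.0
    filter_flags: Dict[str, Optional[bool]] = field(default_factory=dict)
    min_offtarget_mismatches: Optional[int] = None
    efficiency: Optional[float] = None
    pref: Dict[str, float] = field(default_factory=dict)
    good: Dict[str, bool] = field(default_factory=dict)

    @property
    def key(self) -> Tuple[str, str, int, str]:
        return (self.nuclease, self.window.contig, self.window.start,
                self.window.strand)

    def passed(self, name: str) -> bool:
        return bool(self.filter_flags.get(name))


# ---------------------------------------------------------------------------
# Vectorised scanning

_BASE_ORD = np.zeros(256, dtype=np.int8) - 1
for _i, _b in enumerate("ACGT"):
    _BASE_ORD[ord(_b)] = _i

# boolean lookup per IUPAC code over byte values; genome N matches nothing
_IUPAC_TABLE: Dict[str, np.ndarray] = {}
for _code, _bases in IUPAC.items():
    _tab = np.zeros(256, dtype=bool)
    for _b in _bases:
        _tab[ord(_b)] = True
    _IUPAC_TABLE[_code] = _tab


def encode(seq: str) -> np.ndarray:
    """Byte view of a sequence (uint8 of ASCII codes)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def pam_valid_starts(seq_arr: np.ndarray, spec: NucleaseSpec) -> np.ndarray:
    """Window starts (strand-local coords) whose PAM matches the motif.

    Windows containing N anywhere are NOT excluded here; the scanner applies
    that restriction separately so the off-target search can keep N-containing
    candidates (N counts as a mismatch there).
    """
    L = spec.window_length
    n = seq_arr.size - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    mask = np.ones(n, dtype=bool)
    p0 = spec.pam_offset()
    for i, code in enumerate(spec.pam_motif):
        mask &= _IUPAC_TABLE[code][seq_arr[p0 + i : p0 + i + n]]
    return np.nonzero(mask)[0]


def _window_has_n(seq_arr: np.ndarray, starts: np.ndarray, L: int) -> np.ndarray:
    """Boolean mask over ``starts``: window contains at least one N."""
    is_n = seq_arr == ord("N")
    if not is_n.any():
        return np.zeros(starts.size, dtype=bool)
    cum = np.concatenate(([0], np.cumsum(is_n)))
    return (cum[starts + L] - cum[starts]) > 0


def scan_targets(
    genome: GenomeSequence, spec: NucleaseSpec
) -> Iterator[TargetSite]:
    """Enumerate every PAM-matching window on both strands of every contig."""
    L = spec.window_length
    sp_off = spec.spacer_offset()
    pam_off = spec.pam_offset()
    local_bonds = spec.local_cut_bonds()
    for contig, seq in genome.contigs.items():
        clen = len(seq)
        for strand in ("+", "-"):
            oriented = seq if strand == "+" else reverse_complement(seq)
            arr = encode(oriented)
            starts = pam_valid_starts(arr, spec)
            if starts.size:
                starts = starts[~_window_has_n(arr, starts, L)]
            for s in starts.tolist():
                if strand == "+":
                    g_start = s
                    bonds = tuple(g_start + b for b in local_bonds)
                else:
                    g_start = clen - (s + L)
                    bonds = tuple(sorted(g_start + L - b for b in local_bonds))
                window = GenomicInterval(contig, g_start, g_start + L, strand)
                spacer = oriented[s + sp_off : s + sp_off + spec.spacer_length]
                pam = oriented[s + pam_off : s + pam_off + spec.pam_length]
                gc = (spacer.count("G") + spacer.count("C")) / spec.spacer_length
                yield TargetSite(
                    nuclease=spec.name,
                    window=window,
                    spacer=spacer,
                    pam=pam,
                    cut_positions=bonds,
                    gc=gc,
                )


# ---------------------------------------------------------------------------
# CDS assignment


def build_cds_trees(models: Sequence[GeneModel]) -> Dict[str, IntervalTree]:
    """Interval tree per contig over gene-level CDS unions, data = gene id."""
    trees: Dict[str, IntervalTree] = {}
    for gene in models:
        for iv in gene.cds_union():
            trees.setdefault(iv.contig, IntervalTree()).addi(
                iv.start, iv.end, gene.gene_id
            )
    return trees


def _bond_in_cds(tree: IntervalTree, bond: int) -> Set[str]:
    """Gene ids whose CDS strictly contains the cut bond.

    A bond ``c`` separates bases ``c-1`` and ``c``; the cleavage falls within
    a CDS ``[a, b)`` iff both flanking bases are coding, i.e. ``a < c < b``.
    """
    hits = set()
    for itv in tree[bond - 1]:  # intervals containing base c-1
        if itv.begin < bond < itv.end:
            hits.add(itv.data)
    return hits


def assign_to_cds(
    targets: Iterable[TargetSite],
    models: Sequence[GeneModel],
    mode: str = "all",
) -> Iterator[TargetSite]:
    """Keep targets whose cleavage falls within a CDS; populate gene ids.

    ``mode='all'`` (default) requires every cut position of the site inside
    some CDS of the same gene; ``mode='any'`` accepts a gene containing at
    least one cut.  The window itself may straddle the CDS boundary — only
    cleavage placement matters.
    """
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    trees = build_cds_trees(models)
    for t in targets:
        tree = trees.get(t.window.contig)
        if tree is None:
            t.filter_flags["cds"] = False
            continue
        per_cut = [_bond_in_cds(tree, c) for c in t.cut_positions]
        genes = (
            set.intersection(*per_cut) if mode == "all" else set.union(*per_cut)
        )
        if genes:
            t.gene_ids |= genes
            t.filter_flags["cds"] = True
            yield t
        else:
            t.filter_flags["cds"] = False


def dedup(targets: Iterable[TargetSite]) -> List[TargetSite]:
    """Unique by (nuclease, contig, start, strand); gene ids merged."""
    seen: Dict[Tuple[str, str, int, str], TargetSite] = {}
    for t in targets:
        prev = seen.get(t.key)
        if prev is None:
            seen[t.key] = t
        else:
            prev.gene_ids |= t.gene_ids
    return list(seen.values())


def gc_filter(target: TargetSite, lo: float = 0.40, hi: float = 0.80) -> bool:
    """Spacer GC-content filter with inclusive bounds (PAM excluded)."""
    ok = lo <= target.gc <= hi
    target.filter_flags["gc"] = ok
    return ok
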