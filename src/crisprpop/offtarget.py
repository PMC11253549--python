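"""Genome-wide near-match (off-target) search for candidate guides.

A guide fails the off-target filter when any other genomic locus carries a
valid PAM for its nuclease and a spacer within ``max_mm`` (default 3)
Hamming mismatches — "no off-target sites with fewer than four mismatches".

Two search routes are provided and must agree exactly:

* :func:`brute_force_hits` — exhaustive scan of every PAM-valid window on
  both strands; the reference oracle.
* :func:`indexed_hits` — pigeonhole seed search: the spacer is split into
  ``max_mm + 1`` segments, so any occurrence with at most ``max_mm``
  mismatches matches at least one segment exactly; exact segment hits from a
  k-mer index seed candidate loci which are then verified.

Mismatches are counted on the spacer only, unweighted; genome N bases count
as mismatches; PAM validity follows IUPAC matching (genome N matches
nothing).  The guide's own locus is identified by exact coordinate + strand
and excluded — a perfect duplicate elsewhere is a hit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .genome_io import GenomeSequence, GenomicInterval, reverse_complement
from .site_scan import (
    NucleaseSpec,
    TargetSite,
    _IUPAC_TABLE,
    encode,
    get_spec,
    pam_valid_starts,
)


class StateError(RuntimeError):
    """Index queried against a genome it was not built from."""


@dataclass(frozen=True)
class OfftargetHit:
    locus: GenomicInterval
    mismatches: int
    pam_valid: bool


def genome_digest(genome: GenomeSequence) -> str:
    h = hashlib.sha256()
    for name, seq in genome.contigs.items():
        h.update(name.encode())
        h.update(b"\0")
        h.update(seq.encode())
        h.update(b"\0")
    return h.hexdigest()


def _segment_bounds(length: int, n_segments: int) -> List[Tuple[int, int]]:
    """Contiguous split of [0, length) into n_segments near-equal pieces."""
    bounds = np.linspace(0, length, n_segments + 1).astype(int)
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(n_segments)]


class _StrandView:
    """One contig in one orientation with its candidate machinery."""

    def __init__(self, contig: str, seq: str, strand: str, spec: NucleaseSpec,
                 require_pam: bool):
        self.contig = contig
        self.strand = strand
        self.length = len(seq)
        self.spec = spec
        oriented = seq if strand == "+" else reverse_complement(seq)
        self.arr = encode(oriented)
        L = spec.window_length
        self.n_windows = max(0, self.length - L + 1)
        # PAM validity over every window start (strand-local coordinates)
        self.pam_ok = np.zeros(self.n_windows, dtype=bool)
        if self.n_windows:
            self.pam_ok[pam_valid_starts(self.arr, spec)] = True
        if require_pam:
            self.candidate_starts = np.nonzero(self.pam_ok)[0]
        else:
            self.candidate_starts = np.arange(self.n_windows, dtype=np.int64)
        self._spacer_matrix: Optional[np.ndarray] = None
        self._kmer_index: Dict[int, Dict[int, np.ndarray]] = {}

    def to_forward_start(self, local_start: int) -> int:
        if self.strand == "+":
            return local_start
        return self.length - (local_start + self.spec.window_length)

    def spacer_matrix(self) -> np.ndarray:
        """Bytes of candidate spacers, shape (spacer_length, n_candidates)."""
        if self._spacer_matrix is None:
            sp_off = self.spec.spacer_offset()
            starts = self.candidate_starts + sp_off
            rows = [self.arr[starts + i] for i in range(self.spec.spacer_length)]
            self._spacer_matrix = (
                np.vstack(rows) if rows else
                np.empty((0, 0), dtype=np.uint8)
            )
        return self._spacer_matrix

    def kmer_index(self, k: int) -> Dict[int, np.ndarray]:
        """Map base-4 k-mer hash -> sorted positions in the oriented sequence."""
        if k not in self._kmer_index:
            codes = _BASE_CODES[self.arr].astype(np.int64)
            n = codes.size - k + 1
            index: Dict[int, np.ndarray] = {}
            if n > 0:
                h = np.zeros(n, dtype=np.int64)
                valid = np.ones(n, dtype=bool)
                for i in range(k):
                    c = codes[i : i + n]
                    valid &= c >= 0
                    h = h * 4 + np.where(c >= 0, c, 0)
                pos = np.nonzero(valid)[0]
                if pos.size:
                    hv = h[pos]
                    order = np.argsort(hv, kind="stable")
                    hv, pos = hv[order], pos[order]
                    cuts = np.nonzero(np.diff(hv))[0] + 1
                    for chunk, key_i in zip(
                        np.split(pos, cuts), hv[np.concatenate(([0], cuts))]
                    ):
                        index[int(key_i)] = chunk
            self._kmer_index[k] = index
        return self._kmer_index[k]


_BASE_CODES = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODES[ord(_b)] = _i


def _hash_kmer(kmer: str) -> Optional[int]:
    h = 0
    for ch in kmer:
        c = _BASE_CODES[ord(ch)]
        if c < 0:
            return None
        h = h * 4 + int(c)
    return h


class OfftargetIndex:
    """Reusable per-genome, per-nuclease search structure.

    Shared across queries so genome-wide audits amortise the PAM scan, the
    candidate spacer matrix and the k-mer segment index.
    """

    def __init__(self, genome: GenomeSequence, spec: NucleaseSpec,
                 max_mm: int = 3, require_pam: bool = True):
        self.spec = spec
        self.max_mm = max_mm
        self.require_pam = require_pam
        self.digest = genome_digest(genome)
        self.views = [
            _StrandView(contig, seq, strand, spec, require_pam)
            for contig, seq in genome.contigs.items()
            for strand in ("+", "-")
        ]

    def check_genome(self, genome: Optional[GenomeSequence]) -> None:
        if genome is not None and genome_digest(genome) != self.digest:
            raise StateError("off-target index was built from a different genome")

    def _oriented_spacer(self, target: TargetSite) -> np.ndarray:
        if len(target.spacer) != self.spec.spacer_length:
            raise ValueError(
                f"spacer length {len(target.spacer)} does not match "
                f"{self.spec.name} ({self.spec.spacer_length})"
            )
        return encode(target.spacer)

    def _collect(self, view: _StrandView, local_starts: np.ndarray,
                 mismatches: np.ndarray, target: TargetSite) -> List[OfftargetHit]:
        L = self.spec.window_length
        hits = []
        for s, mm in zip(local_starts.tolist(), mismatches.tolist()):
            fwd = view.to_forward_start(s)
            if (
                view.contig == target.window.contig
                and fwd == target.window.start
                and view.strand == target.window.strand
            ):
                continue  # the on-target locus itself
            locus = GenomicInterval(view.contig, fwd, fwd + L, view.strand)
            pam_valid = bool(view.pam_ok[s]) if view.n_windows else False
            hits.append(OfftargetHit(locus, int(mm), pam_valid))
        return hits

    def brute_force_hits(self, target: TargetSite) -> List[OfftargetHit]:
        """Exhaustive scan: every candidate window, Hamming-checked."""
        spacer = self._oriented_spacer(target)
        hits: List[OfftargetHit] = []
        for view in self.views:
            if view.candidate_starts.size == 0:
                continue
            mm = (view.spacer_matrix() != spacer[:, None]).sum(axis=0)
            keep = np.nonzero(mm <= self.max_mm)[0]
            hits.extend(
                self._collect(view, view.candidate_starts[keep], mm[keep], target)
            )
        hits.sort(key=_hit_key)
        return hits

    def hits(self, target: TargetSite) -> List[OfftargetHit]:
        """Seed-and-verify search; identical result set to the oracle."""
        spacer_str = target.spacer
        spacer = self._oriented_spacer(target)
        sp_off = self.spec.spacer_offset()
        sp_len = self.spec.spacer_length
        segments = _segment_bounds(sp_len, self.max_mm + 1)
        hits: List[OfftargetHit] = []
        for view in self.views:
            if view.n_windows == 0:
                continue
            cand: List[np.ndarray] = []
            for lo, hi in segments:
                key = _hash_kmer(spacer_str[lo:hi])
                if key is None:
                    continue
                pos = view.kmer_index(hi - lo).get(key)
                if pos is not None:
                    cand.append(pos - (sp_off + lo))
            if not cand:
                continue
            starts = np.unique(np.concatenate(cand))
            starts = starts[(starts >= 0) & (starts < view.n_windows)]
            if self.require_pam:
                starts = starts[view.pam_ok[starts]]
            if starts.size == 0:
                continue
            mm = np.zeros(starts.size, dtype=np.int64)
            for i in range(sp_len):
                mm += view.arr[starts + sp_off + i] != spacer[i]
            keep = np.nonzero(mm <= self.max_mm)[0]
            hits.extend(self._collect(view, starts[keep], mm[keep], target))
        hits.sort(key=_hit_key)
        return hits


def _hit_key(h: OfftargetHit):
    return (h.locus.contig, h.locus.start, h.locus.strand)


def brute_force_hits(
    target: TargetSite,
    genome: GenomeSequence,
    max_mm: int = 3,
    spec: Optional[NucleaseSpec] = None,
    require_pam: bool = True,
) -> List[OfftargetHit]:
    spec = spec or get_spec(target.nuclease)
    return OfftargetIndex(genome, spec, max_mm, require_pam).brute_force_hits(target)


def indexed_hits(
    target: TargetSite,
    genome: GenomeSequence,
    max_mm: int = 3,
    spec: Optional[NucleaseSpec] = None,
    require_pam: bool = True,
) -> List[OfftargetHit]:
    spec = spec or get_spec(target.nuclease)
    return OfftargetIndex(genome, spec, max_mm, require_pam).hits(target)


def offtarget_filter(
    target: TargetSite,
    genome: Optional[GenomeSequence] = None,
    index: Optional[OfftargetIndex] = None,
    max_mm: int = 3,
    require_pam: bool = True,
) -> bool:
    """Pass iff no off-target hit within ``max_mm`` mismatches exists.

    Records the smallest mismatch count found on the target (or None).
    """
    if index is None:
        if genome is None:
            raise ValueError("offtarget_filter needs a genome or a prebuilt index")
        index = OfftargetIndex(genome, get_spec(target.nuclease), max_mm, require_pam)
    hits = index.hits(target)
    target.min_offtarget_mismatches = (
        min(h.mismatches for h in hits) if hits else None
    )
    ok = not hits
    target.filter_flags["offtarget"] = ok
    return ok
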