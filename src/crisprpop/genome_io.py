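"""Genome, annotation and variant I/O plus the internal coordinate model.

All internal coordinates are 0-based half-open; the 1-based inclusive
conventions of GFF3 and VCF are converted at the parsing boundary and BED is
emitted natively.  Keeping a single convention internally avoids off-by-one
drift between the scanner, the off-target search and the population filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


class IntervalError(ValueError):
    """Raised when an interval violates contig bounds or ordering."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on a contig with a strand."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise IntervalError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise IntervalError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


class GenomeSequence:
    """Ordered collection of uppercase contig sequences over {A,C,G,T,N}."""

    def __init__(self, contigs: Mapping[str, str]):
        self.contigs: Dict[str, str] = {}
        for name, seq in contigs.items():
            if name in self.contigs:
                raise FormatError(f"duplicate contig id {name!r}")
            seq = seq.upper()
            if not seq:
                raise FormatError(f"empty sequence for contig {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r} contains invalid characters {sorted(bad)}"
                )
            self.contigs[name] = seq

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __iter__(self):
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, iv: GenomicInterval) -> str:
        """Sequence of ``iv`` in strand orientation (reverse-complemented for −)."""
        seq = self.contigs[iv.contig]
        if iv.end > len(seq):
            raise IntervalError(
                f"interval [{iv.start}, {iv.end}) exceeds {iv.contig} length {len(seq)}"
            )
        sub = seq[iv.start : iv.end]
        return reverse_complement(sub) if iv.strand == "-" else sub

    def gc_fraction(self) -> float:
        g = sum(s.count("G") + s.count("C") for s in self.contigs.values())
        return g / self.total_length

    def with_replaced(self, contig: str, position: int, seq: str) -> "GenomeSequence":
        """Copy of the genome with ``seq`` written at ``position`` on ``contig``."""
        old = self.contigs[contig]
        if position < 0 or position + len(seq) > len(old):
            raise IntervalError(
                f"replacement [{position}, {position + len(seq)}) exceeds "
                f"{contig} length {len(old)}"
            )
        new = dict(self.contigs)
        new[contig] = old[:position] + seq.upper() + old[position + len(seq) :]
        return GenomeSequence(new)


@dataclass
class GeneModel:
    """A gene with one or more transcripts, each an ordered list of CDS spans.

    All CDS of a transcript share contig and strand; the gene-level CDS index
    used for target assignment is the union over transcripts.
    """

    gene_id: str
    transcripts: Dict[str, List[GenomicInterval]] = field(default_factory=dict)

    @property
    def contig(self) -> str:
        for ivs in self.transcripts.values():
            if ivs:
                return ivs[0].contig
        raise ValueError(f"gene {self.gene_id} has no CDS")

    @property
    def strand(self) -> str:
        for ivs in self.transcripts.values():
            if ivs:
                return ivs[0].strand
        raise ValueError(f"gene {self.gene_id} has no CDS")

    def cds_union(self) -> List[GenomicInterval]:
        """Merged, sorted union of all transcripts' CDS intervals."""
        ivs = sorted(
            ((iv.start, iv.end) for t in self.transcripts.values() for iv in t)
        )
        if not ivs:
            return []
        merged: List[List[int]] = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        contig, strand = self.contig, self.strand
        return [GenomicInterval(contig, s, e, strand) for s, e in merged]


@dataclass
class PopulationPanel:
    """Mapping of sample id to population label."""

    assignments: Dict[str, str]

    @property
    def populations(self) -> List[str]:
        seen: Dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop)
        return list(seen)

    def samples(self, population: str) -> List[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def __len__(self) -> int:
        return len(self.assignments)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> GenomeSequence:
    """Read a (multi-)FASTA into a :class:`GenomeSequence`.

    Sequences are uppercased; duplicate record ids are rejected.
    """
    contigs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FormatError(f"duplicate FASTA record id {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq)
    if not contigs:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path) -> List[GeneModel]:
    """Parse gene/mRNA/CDS features linked by ID/Parent into gene models.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Non-coding features are ignored; a file with no CDS rows yields models
    with empty transcripts and a logged warning.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: Dict[str, GeneModel] = {}
    tx_to_gene: Dict[str, str] = {}
    for feat in db.features_of_type("gene"):
        genes[feat.id] = GeneModel(gene_id=feat.id)
    for feat in db.features_of_type("mRNA"):
        parents = feat.attributes.get("Parent", [])
        for parent in parents:
            if parent not in genes:
                raise FormatError(f"mRNA {feat.id} has unknown Parent {parent!r}")
            tx_to_gene[feat.id] = parent
            genes[parent].transcripts.setdefault(feat.id, [])
    n_cds = 0
    for feat in db.features_of_type("CDS"):
        if feat.end < feat.start:
            raise FormatError(f"CDS with end < start at line for {feat.id}")
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        parents = feat.attributes.get("Parent", [])
        if not parents:
            raise FormatError(f"CDS {feat.id} has no Parent attribute")
        for parent in parents:
            if parent not in tx_to_gene:
                raise FormatError(f"CDS {feat.id} has unknown Parent {parent!r}")
            genes[tx_to_gene[parent]].transcripts[parent].append(iv)
            n_cds += 1
    if n_cds == 0:
        logger.warning("no CDS features found in %s", path)
    for gene in genes.values():
        for tx in gene.transcripts.values():
            tx.sort(key=lambda iv: iv.start)
    return list(genes.values())


def write_gff3(models: Sequence[GeneModel], path) -> None:
    """Write gene/mRNA/CDS rows (1-based inclusive, phase populated)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in models:
            union = gene.cds_union()
            if not union:
                continue
            contig, strand = gene.contig, gene.strand
            gstart = min(iv.start for iv in union) + 1
            gend = max(iv.end for iv in union)
            fh.write(
                f"{contig}\tcrisprpop\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            for tx_id, ivs in gene.transcripts.items():
                tstart = min(iv.start for iv in ivs) + 1
                tend = max(iv.end for iv in ivs)
                fh.write(
                    f"{contig}\tcrisprpop\tmRNA\t{tstart}\t{tend}\t.\t{strand}\t.\t"
                    f"ID={tx_id};Parent={gene.gene_id}\n"
                )
                # CDS phase: bases to skip to reach the next codon start,
                # accumulated in translation order.
                ordered = ivs if strand == "+" else list(reversed(ivs))
                phase = 0
                rows = []
                for iv in ordered:
                    rows.append((iv, phase))
                    phase = (3 - ((len(iv) - phase) % 3)) % 3
                for iv, ph in sorted(rows, key=lambda r: r[0].start):
                    fh.write(
                        f"{contig}\tcrisprpop\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
                        f"{strand}\t{ph}\tID=cds-{tx_id};Parent={tx_id}\n"
                    )


# ---------------------------------------------------------------------------
# CDS GC content


def merged_cds_intervals(models: Sequence[GeneModel]) -> Dict[str, List[Tuple[int, int]]]:
    """Union of all genes' CDS spans per contig, merged and sorted."""
    by_contig: Dict[str, List[Tuple[int, int]]] = {}
    for gene in models:
        for iv in gene.cds_union():
            by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    merged: Dict[str, List[Tuple[int, int]]] = {}
    for contig, ivs in by_contig.items():
        ivs.sort()
        out: List[List[int]] = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[contig] = [(s, e) for s, e in out]
    return merged


def cds_gc_content(genome: GenomeSequence, models: Sequence[GeneModel]) -> float:
    """G+C fraction over the union of CDS bases.

    Each genomic base counts once even when shared by several transcripts or
    genes.  N bases contribute to the denominator but not the numerator.
    """
    if not models:
        raise ValueError("no gene models supplied")
    gc = 0
    total = 0
    for contig, ivs in merged_cds_intervals(models).items():
        seq = genome[contig]
        for s, e in ivs:
            if e > len(seq):
                raise IntervalError(
                    f"CDS [{s}, {e}) outside contig {contig} (length {len(seq)})"
                )
            sub = seq[s:e]
            gc += sub.count("G") + sub.count("C")
            total += e - s
    if total == 0:
        raise ValueError("gene models contain no CDS bases")
    return gc / total


# ---------------------------------------------------------------------------
# VCF


@dataclass
class VariantRecord:
    """One VCF row: 0-based position, REF and all ALT alleles."""

    contig: str
    position: int
    ref: str
    alts: Tuple[str, ...]


def read_variant_genotypes(path):
    """Read a VCF with GT fields into records plus a genotype array.

    Returns ``(records, genotypes, samples)`` where ``genotypes`` has shape
    ``(n_sites, n_samples, max_ploidy)`` holding allele indices (0 = REF,
    1.. = ALT order) with −1 for missing calls.  Positions are converted to
    0-based; multi-allelic rows are retained with all alternates.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"VCF {path} has no sample genotype columns")
    records: List[VariantRecord] = []
    rows: List[List[List[int]]] = []
    max_ploidy = 1
    for v in vcf:
        if v.genotypes is None:
            raise FormatError(f"VCF record at {v.CHROM}:{v.POS} lacks GT")
        records.append(
            VariantRecord(v.CHROM, v.start, v.REF, tuple(v.ALT))
        )
        site = []
        for g in v.genotypes:
            alleles = [int(a) for a in g[:-1]]  # last entry is phasing flag
            max_ploidy = max(max_ploidy, len(alleles))
            site.append(alleles)
        rows.append(site)
    genotypes = np.full((len(rows), len(samples), max_ploidy), -1, dtype=np.int8)
    for i, site in enumerate(rows):
        for j, alleles in enumerate(site):
            genotypes[i, j, : len(alleles)] = alleles
    return records, genotypes, samples


def write_vcf(
    records: Sequence[VariantRecord],
    genotypes: np.ndarray,
    samples: Sequence[str],
    contig_lengths: Mapping[str, int],
    path,
) -> None:
    """Write VCF 4.2 with GT-only genotype columns."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for i, rec in enumerate(records):
            gts = []
            for j in range(len(samples)):
                alleles = genotypes[i, j]
                gts.append("/".join("." if a < 0 else str(a) for a in alleles))
            fh.write(
                f"{rec.contig}\t{rec.position + 1}\t.\t{rec.ref}\t"
                f"{','.join(rec.alts)}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Panel TSV


def read_panel(path) -> PopulationPanel:
    """Read a two-column sample_id / population TSV (header optional)."""
    assignments: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            sample, pop = parts
            if sample == "sample_id" and lineno == 1:
                continue
            if sample in assignments:
                raise FormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = pop
    return PopulationPanel(assignments)


def write_panel(panel: PopulationPanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for sample, pop in panel.assignments.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# Target output


def write_targets(targets: Iterable, path, format: str = "tsv") -> None:
    """Write annotated target sites as BED6 or a TSV with all filter columns."""
    targets = list(targets)
    if format == "bed":
        with open(path, "w") as fh:
            for t in targets:
                name = f"{t.nuclease}|{';'.join(sorted(t.gene_ids)) or '.'}"
                score = 0 if t.efficiency is None else int(round(t.efficiency * 1000))
                fh.write(
                    f"{t.window.contig}\t{t.window.start}\t{t.window.end}\t"
                    f"{name}\t{score}\t{t.window.strand}\n"
                )
    elif format == "tsv":
        pops = sorted({p for t in targets for p in t.pref})
        cols = [
            "nuclease",
            "contig",
            "start",
            "end",
            "strand",
            "spacer",
            "pam",
            "cut_positions",
            "gene_ids",
            "gc",
            "cds",
            "gc_pass",
            "offtarget_pass",
            "efficiency_pass",
            "min_offtarget_mismatches",
            "efficiency",
        ]
        cols += [f"pref_{p}" for p in pops] + [f"good_{p}" for p in pops]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for t in targets:
                row = [
                    t.nuclease,
                    t.window.contig,
                    str(t.window.start),
                    str(t.window.end),
                    t.window.strand,
                    t.spacer,
                    t.pam,
                    ",".join(str(c) for c in t.cut_positions),
                    ";".join(sorted(t.gene_ids)),
                    f"{t.gc:.4f}",
                    _flag(t.filter_flags.get("cds")),
                    _flag(t.filter_flags.get("gc")),
                    _flag(t.filter_flags.get("offtarget")),
                    _flag(t.filter_flags.get("efficiency")),
                    "" if t.min_offtarget_mismatches is None
                    else str(t.min_offtarget_mismatches),
                    "" if t.efficiency is None else f"{t.efficiency:.6f}",
                ]
                for p in pops:
                    v = t.pref.get(p)
                    row.append("" if v is None else f"{v:.10g}")
                for p in pops:
                    g = t.good.get(p)
                    row.append(_flag(g))
                fh.write("\t".join(row) + "\n")
    else:
        raise ValueError(f"unknown target output format {format!r}")


def _flag(value) -> str:
    if value is None:
        return "NA"
    return "pass" if value else "fail"


def read_bed(path) -> List[GenomicInterval]:
    ivs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            strand = parts[5] if len(parts) > 5 else "+"
            ivs.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return ivs
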