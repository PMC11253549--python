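# Methods

## Scope and model

`crisprpop` treats guide-RNA design as a filter cascade over candidate
target windows followed by a population-genetic classification. The
quantity of interest is, for each candidate site and each population, the
probability `P_ref` that a genome sampled from that population matches the
reference across the site's scored window. Under the assumption that
variants are independent (no linkage between sites within a ~23–27 bp
window), this is the product of per-site reference-allele frequencies:

    P_ref = ∏_i (1 − q_i),

with `q_i` the summed non-reference allele frequency of variant site *i*
overlapping the scored window. Independence is an approximation — variants
a few base pairs apart are typically in strong LD, which would make the
true haplotype-match probability *larger* than the product — so `P_ref` is
conservative (it under-states conservation). A potential target with
`P_ref ≥ 0.99` is a good target.

## Coordinates and cut geometry

All internal coordinates are 0-based half-open; GFF3 and VCF are converted
at the parsing boundary, BED is emitted natively. Cleavage positions are
*bond* coordinates: an integer `c` denotes the bond between bases `c−1` and
`c`, and a cut lies within a CDS `[a, b)` iff `a < c < b` (both flanking
bases coding). Cas9 is modelled as a single blunt cut 3 bp 5′ of the PAM.
Cas12a cleavage is staggered; the two nicks are placed after spacer
positions 18 and 23 (counting from the PAM-proximal end), which follows
standard descriptions of its cut geometry and is configurable on the
`NucleaseSpec` since reported nick positions vary by a base or two between
studies. By default a site is retained only if *all* its cut positions fall
within a CDS of the same gene (`mode="any"` relaxes this); a window may
straddle the CDS boundary as long as cleavage is coding.

## Filters and their defaults

| parameter | default | notes |
|---|---|---|
| GC bounds | 0.40–0.80, inclusive | computed on the spacer only; PAM bases are motif-constrained and would bias by nuclease |
| off-target max mismatches | 3 (`< 4` fails) | Hamming distance on the spacer, unweighted; genome `N` counts as a mismatch |
| off-target PAM requirement | required | a near-match without a functional PAM cannot be cleaved; `require_pam=False` exposes the stricter reading |
| efficiency threshold | 0.5 on a 0–1 scale | model pluggable per nuclease |
| `P_ref` threshold | 0.99 | boundary inclusive |
| degenerate PAM scoring | excluded | no substitution at the N of `NGG`/`TTTN` abolishes recognition, so a Cas9 window has 22 scored positions and a Cas12a window 26; `include_degenerate_pam=True` restores full-window scoring |

IUPAC matching: a motif code matches its base set; genome `N` matches
nothing (a window containing `N` is skipped during scanning, since the
protospacer sequence cannot be asserted). The guide's own locus is
identified by exact coordinate and strand, so a perfect duplicate elsewhere
in the genome is an off-target hit. Multi-allelic variant records
contribute the sum of their alternate frequencies; an indel overlapping the
window in any way is scored once with its allele frequency. Missing
genotypes are excluded from frequency denominators; a population with no
called alleles at a site is skipped for that site.

## Off-target search

Two routes are implemented and must agree exactly. The brute-force oracle
Hamming-checks every PAM-valid window on both strands. The scalable route
splits the spacer into `max_mm + 1` contiguous segments; by pigeonhole any
occurrence with ≤ `max_mm` mismatches matches at least one segment exactly,
so exact segment hits from a per-genome k-mer index seed candidate loci
that are then verified. Both routes share a per-genome, per-nuclease index
(PAM-validity masks and gathered spacer matrices) so genome-wide audits
amortise the scan. Mismatch counts are position-unweighted; CFD/MIT-style
weighted off-target scoring and bulged alignments are out of scope.

## Efficiency surrogate

Published trained efficiency predictors are not reproduced (their weights
are not redistributable in table form); the shipped surrogates are
versioned position × nucleotide weight tables, summed over the spacer and
squashed through a logistic. They are deterministic, bounded in [0, 1],
invariant to flanking context, and mildly GC-favouring so that score and
composition correlate the way practitioners expect. They are stand-ins for
exercising the ≥ 0.5 filter, not predictors of in-vivo activity; real
models can be registered through `efficiency.register_model`.

## Synthetic data

The generator emulates the *shape* of a real study — multi-gene reference,
CDS annotation, biallelic SNVs, two labelled populations of diploid
samples — with analytically tractable structure: each position is
polymorphic in a population independently with probability θ, and each
haplotype carries the alternate allele with probability `1 − ref_af`
(Hardy–Weinberg, no linkage). Defaults: 2 × 100 kb contigs, GC 0.5, 40
three-exon genes (300 bp CDS, 80 bp introns, 500 bp intergenic), a quarter
of genes on the reverse strand; θ = 0.01, `ref_af = 0.97`, 50 diploid
samples per population. The two-population studies use θ = 0.02 vs 0.002
to produce an order-of-magnitude diversity contrast between labelled
populations, mirroring the kind of continental contrast seen in field
samples.

Because the generator satisfies the same independence assumption the
classifier makes, the expected good-target fraction has the closed form

    Σ_{k : ref_af^k ≥ threshold} C(L, k) θ^k (1 − θ)^{L−k},

with L the number of scored positions (22 for Cas9). Passing the
parameter-recovery checks therefore demonstrates internal consistency of
scanner + frequency estimation + classification, *not* realism: real
populations have linkage, site-frequency spectra, indels, structural
variants and sequencing error that the generator deliberately omits, so
absolute counts from synthetic runs say nothing about any particular
genome.

Nucleotide diversity uses the unbiased per-site estimator
`π = Σ_sites (n/(n−1))(1 − Σ_a p_a²) / L_total` over the union of CDS
intervals, with `n` the called haplotypes at each site.

## Numerical and degenerate-input choices

- Filter bounds are inclusive at both ends (GC 0.40 and 0.80 pass;
  efficiency 0.5 passes; `P_ref = 0.99` is good; an off-target at exactly 3
  mismatches fails, at 4 passes).
- The P_ref product is computed in double precision directly; windows hold
  ≤ 27 factors so no log-space accumulation is needed
  (`|P_ref − ∏(1−q)| = 0` to 1e-12 in the checks).
- Filters are evaluated on *all* CDS-cleaving sites rather than only on
  survivors of earlier stages, so marginal per-filter pass rates and P_ref
  are known for every CDS site; good ⊆ potential is enforced at
  classification time.
- Duplicate windows (same nuclease/contig/start/strand, e.g. via shared
  transcripts) are merged with gene-id union; overlapping genes each
  receive the target in per-gene counts while genome-wide totals count it
  once.
- Empty inputs degrade explicitly: header-only report files, a pooled-only
  comparison for single-population panels (with a warning), configuration
  errors for infeasible gene packing or out-of-range frequencies.

## Problem sizes used in the checks

The test-suite and acceptance-script runs use sizes chosen to make their
statistical assertions sharp while remaining desk-scale: 20 × 50 kb random
genomes for the dual-route off-target equivalence (every Cas9 and Cas12a
target, ~23k queries); a 200 kb genome with 500 diploid samples for
parameter recovery (≈ 25k Cas9 windows, 3-SE binomial tolerance); 5 seeded
60 kb two-population runs for the diversity-ordering check; and a 100 kb,
30-gene, 2 × 40-sample study for the headline screen. Determinism: one
master seed per run; the genome and variant generators derive independent
child streams from fixed offsets, so fixtures are byte-identical across
reruns.

## Known limitations

- `P_ref` ignores linkage (conservative) and treats indels as point events.
- Off-target search covers substitutions only, within the same genome.
- The efficiency surrogate is not a trained activity model.
- The generator produces uniform base composition, uniformly placed
  variants and equal-length genes; repeat structure, GC heterogeneity and
  realistic gene architecture are absent.
- Reported sample bookkeeping is the caller's: the panel abstraction keeps
  sample→population assignment explicit rather than validating study
  metadata.
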