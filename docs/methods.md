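# Methods

This note documents the models and procedures implemented in `mitodui`,
the parameters that matter, the numerical choices made where conventions
diverge, and what the synthetic-data generators do and do not emulate.

## Coordinates, genomes and site classes

Circular genomes use 0-based half-open coordinates internally; GenBank's
1-based inclusive convention is converted at the I/O boundary. A feature
that spans the origin is stored unwrapped (`end > length`) and all
consumers index modulo the genome length; on writing, such features are
re-wrapped into `join()` locations. This makes window and codon arithmetic
unambiguous on the circle.

Translation uses NCBI genetic code 5 (invertebrate mitochondrial:
AGA/AGG = Ser, ATA = Met, TGA = Trp), the code of mytilid mitogenomes;
the table id is configurable everywhere a code is taken. Degeneracy of a
codon position is the number of bases at that position conserving the
amino acid, computed from the actual codon observed at each site rather
than from a gene-average.

`classify_sites` assigns exactly one label per genome position:
`codon_pos1`, `codon_pos2`, `codon_pos3_4fold` (4-fold degenerate third
positions), `codon_pos3_2fold` (all other third positions), `rna_gene`,
or `noncoding`. On overlap the priority is protein > RNA gene >
noncoding; protein features overlapping in incompatible frames are an
error rather than a silent choice. "Neutral" positions are defined as
4-fold third positions plus noncoding positions — the standard
operationalisation of sites where substitutions do not change the
protein; the alternative filter used for compositional scans combines
second codon positions (the most constrained class) with noncoding sites.

## Sliding-window compositional indices

AT-skew `(A−T)/(A+T)`, GC-skew `(G−C)/(G+C)` and GC content are computed
in windows anchored at every multiple of the step (`ceil(L/step)` windows
per circle, wrapping the origin; defaults 200 bp windows, 25 bp step,
with 1,000 bp windows for sparse neutral-site tracks). Window centers are
reported at `(start + window/2) mod L`. When a site filter is active only
positions with eligible labels contribute; a window with no eligible
position carries a missing value, not a zero, so long repeat regions do
not drag filtered tracks toward zero. Relative GC content divides
per-window values by the genome-wide GC over the same filter. Skews are
computed on the stored strand (both genomes modelled here encode all
genes on one strand); a flag computes the complementary strand, which
flips the sign.

## Divergence

p-distance is the proportion of differing sites among used columns.
The default deletion mode is complete deletion — columns containing a
gap or ambiguity code in *any* row are removed before comparison —
matching the defaults of the standard distance tools; pairwise deletion
is available. Ambiguity codes are treated as gaps (conservative mismatch
counting). Between-group distances average over all cross-group pairs;
because that statistic is linear in columns, the bootstrap (columns
resampled with replacement, default 10,000 replicates, seeded) reduces to
resampling per-column mean mismatch fractions, which keeps the 10,000
replicates cheap at full-genome scale. Protein genes are compared as
amino-acid sequences, RNA genes as nucleotides, and the overall distance
is the nucleotide p-distance of the concatenated per-gene alignments.
Alignment construction itself is an input, not a stage: any pre-aligned
FASTA (group labels encoded as `>name|F`) is accepted.

## Population genetics

All site-based statistics use complete deletion. With N sequences of
usable length L: S is the number of polymorphic columns; h the number of
distinct haplotypes; haplotype diversity `hd = N/(N−1)·(1 − Σ p_i²)`;
Watterson's `θ_W = S/(a₁·L)` with `a₁ = Σ_{i<N} 1/i`; π the mean pairwise
difference per site over all C(N,2) pairs. θ is emitted both per site and
per sequence because published tables are often ambiguous about the
scaling.

Tajima's D standardises `π·L − S/a₁` by `sqrt(e₁S + e₂S(S−1))` with the
usual sample-size constants. Significance at p < 0.05 uses the
beta-distribution approximation over the attainable range of D
(rescaled to mean 0, variance 1) — deterministic, unlike
coalescent-simulation p-values, and the convention behind starred table
entries in the field. D is reported as missing when S = 0. Note that D
has a small negative expectation under strict neutrality that grows with
the per-sequence θ; at θ·L ≈ 26 it is about −0.10 (verified against an
independent coalescent implementation), which matters when interpreting
small negative values.

Ka/Ks follows the original Nei–Gojobori method: per-codon synonymous site
fractions count only changes that avoid stop codons; differences between
codons average synonymous/nonsynonymous steps over all minimal mutational
pathways, discarding pathways through stops (if every pathway is blocked,
the average over all pathways is used — the comparison is too divergent
for pathway counting to matter). Proportions are Jukes–Cantor corrected,
`d = −(3/4)·ln(1 − (4/3)p)`, undefined (NaN) at saturation `p ≥ 3/4`.
Within-sample mode averages over all pairs; divergence mode over
between-group pairs. Standard errors resample codons (not sites) with
replacement, 1,000 replicates by default, seeded. Stop-containing or
ambiguous codons are masked per sequence.

## qPCR quantification

A standard curve is the OLS fit of Cq on log10(copies) with replicates
pooled across experiments (default series: 3 experiments × 3 replicates
× 7 decades). Efficiency is `10^(−1/slope) − 1` with a 90–110% QC window;
a non-negative slope is an error. Sample copies invert the curve at the
mean replicate Cq; the confidence interval is the replicate-Cq t-interval
propagated through the (monotone) inversion, collapsing to the point for
a single replicate. The detection cutoff defaults to Cq 35; measurements
at or beyond it are flagged below detection.

Ratios of two targets in one sample propagate both Cq t-intervals through
their curves on the log10 scale (delta method,
`var(log10 r) = (se_num/slope_num)² + (se_den/slope_den)²`) with a
Welch–Satterthwaite t quantile. A below-detection numerator turns the
estimate into a one-sided bound (the true ratio lies below it); a
below-detection denominator is undefined and flagged. The CI construction
is a package choice — only replicate-level Cq data exist in typical
supplementary tables — and its ~95% coverage is verified by simulation in
the test suite (93–97% over 1,000 replicates).

The NGS ratio is `(reads_M/len_M)/(reads_F/len_F)` with a parametric
bootstrap of the binomial read split (10,000 draws, percentile interval).
It ignores mappability differences between the genomes; with genome
lengths as different as 18,113 vs 24,347 bp and a repeat-rich M genome
this is a documented assumption, not a fact.

## The sperm copy-number model

Male mantle tissue mixes somatic cells (F-mtDNA) with sperm (M-mtDNA).
Assuming sperm are homoplasmic for M and somatic F content proxies the
somatic fraction, M/nDNA is linear in F/nDNA across samples and the
y-intercept of the OLS line estimates the M-mtDNA content of pure sperm.
The fit is unweighted by default — the plain trend-line convention —
with an optional inverse-variance weighted mode; the intercept is
reported with both a ±1 SE band (the plotted convention) and a t-based
confidence interval. Female-mantle rows are rejected at input (the
mixture argument only holds for sperm-bearing tissue) and below-detection
M points are excluded with a warning. Copies per mitochondrion divide the
intercept by an assumed count of five mitochondria per sperm cell, the
usual number for bivalve sperm; the divisor is a parameter.

## Synthetic data: what it emulates, what it does not

The generators produce inputs with the statistical structure each stage
assumes, with the planted truth returned alongside; identical seeds give
byte-identical outputs.

**Mitogenome pairs.** The default gene table carries 13 proteins, 2 rRNAs
and 23 tRNAs with mytilid-scale lengths, summing (with noncoding regions
computed as filler) to exactly 18,113 bp (F) and 24,347 bp (M). The M
genome carries the structural signatures of a DUI pair as configurable
options: an atp8 extended to 885 bp, the small-subunit rRNA relocated
next to the large rRNA with a 6 kb repeat-rich region between them, and
freshly drawn noncoding regions with no between-genome similarity. Genes
diverge by per-site substitution at the configured target p-distance
(default 0.347 overall), codon-aware for proteins so CDSs remain
stop-free; targets are capped at 0.75 (Jukes–Cantor saturation). Base
composition defaults to uniform unless a per-region skew profile
(AT-skew, GC-skew, GC content) is given. Not emulated: indels (truth
alignments are gap-free), transfer of the atp8 extension into the
alignments (only the shared core is aligned), rate heterogeneity along
genes, and real codon usage.

**Coalescent samples.** A Hudson coalescent (waiting time exponential
with rate k(k−1)/2 while k lineages remain) with mutations Poisson on
branches at θ/2 per site, placed under the infinite-sites model, so
`E[S] = θ·L·a₁` exactly. The generator is written in-package because the
codon mode needs bespoke control: there, an ancestral stop-free codon
sequence evolves along the tree and each attempted substitution is
rejected if it creates a stop and accepted with probability ω when
nonsynonymous, giving Ka/Ks ≈ ω for ω ≤ 1. The nucleotide mode is
cross-checked against an independent coalescent simulator in the test
suite. ω-recovery simulations are run at 1,000 codons: at a few hundred
codons the Ka/Ks point estimate carries a small-sample ratio (Jensen)
bias of order +0.2 that is a property of ratio estimation, not of the
implementation; at 1,000 codons it is below 2%. Not emulated:
recombination, finite-sites homoplasy (available as the codon mode's
side effect only), population structure, and selection beyond the
ω-acceptance rule.

**qPCR panels.** Each of 18 samples (the panel size of the tissue survey
this package models) draws a somatic F/nDNA load log-uniformly from
1–80; the male-mantle M load is `intercept + slope·F` with defaults
15.06 and 0.8, putting the mean male-mantle M load near 29 copies per
nuclear genome. An optional sample-level scatter (`biological_sd`,
default 0 so noiseless round trips are exact) models real trend-line
dispersion; the acceptance script uses 4.4 copies, which reproduces a
trend-line R² near 0.92 at the default F spread. Female mantles carry
only trace M at planted F/M ratios of 300–10,000. Cq values come from
per-target log-linear curves (slope −3.3219, i.e. 100% efficiency) with
Gaussian replicate noise (default 0.1 cycles). Not emulated: plate and
inhibition effects, pipetting covariance between replicates, primer
cross-reactivity.

Because the generators realise exactly the assumptions of the estimators,
passing recovery tests demonstrates correctness of the computations, not
robustness to real-data violations (alignment error, numts, mapping
bias, non-linear qPCR artefacts).

## Problem sizes and determinism

The test suite and acceptance script run at desk scale: 1,000 coalescent
replicates for the Tajima calibration (n = 18, θ_site = 0.02, 250 bp —
i.e. θ = 5 per sequence, where the neutral expectation of D is within
the calibration band), 60–200 replicates for ω recovery, 25 replicate
panels for the qPCR chain, 10⁶ reads for the NGS split. Every random
stage takes an explicit seed; the pipeline derives stage seeds from one
master seed and stamps each output table with the config hash and seed.
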