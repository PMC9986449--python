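# Methods

`rgenekit` analyses NBS-LRR (nucleotide-binding site, leucine-rich repeat)
plant resistance genes, with particular attention to haplotype-resolved
polyploid genomes such as sugarcane's wild progenitor *Saccharum
spontaneum* (tetraploid assembly) and noble progenitor *S. officinarum*
(octoploid assembly). This note records the models, parameter choices and
numerical conventions behind each stage, and what the synthetic-data tests
do and do not demonstrate.

## Identification and classification

A gene is an NBS-LRR candidate iff the union of canonical domain labels
over all its protein products contains both **NB-ARC** and **LRR**. The
N-terminal domain then assigns the subfamily: TIR → TNL, coiled-coil (no
TIR) → CNL, RPW8 (neither) → RNL, none → NL ("truncated CNL" in monocots,
which lack TNLs); genes carrying both TIR and CC are flagged `TNL+CNL`
and counted once in the NBS-LRR total. The rule is a pure, total function
of the domain set.

Raw InterProScan-style signatures map to canonical labels through an
editable TSV shipped with the package (NB-ARC ← PF00931/IPR002182; TIR ←
PF01582/IPR000157; RPW8 ← PF05659/IPR008808; LRR ← PF00560, PF07725,
PF12799, PF13306, PF13855, IPR032675; CC ← COILS predictor hits). The
precise LRR accession list is a configuration choice, not part of the
rule; genes with NB-ARC but no LRR hit are strictly excluded. Unmapped
signatures become `OTHER`.

Species summaries report subfamily counts as percentages of the NBS-LRR
total, rounded to one decimal. Cross-species correlations are Pearson
product-moment with the two-sided t-transform p-value (n − 2 df);
Spearman is available by flag. Zero-variance inputs raise rather than
returning NaN.

## Allele grouping and retention

Allele IDs follow the grammar `<prefix>.<locus>-<digit><letter>` (e.g.
`Sspon.05G0015970-2C`); the digit is the 1-based haplotype slot and the
letter its slot letter. IDs without a suffix are kept as singleton base
genes (conservative inclusion, logged) rather than dropped. Retention
tables report, per base gene, the number of distinct alleles observed;
the CNL vs truncated-CNL allele-loss contrast uses a two-sided
Mann–Whitney U on alleles lost — a rank test because the response is a
small discrete count with heavy ties. Duplicated-pair summaries consume
an external pair list (plain TSV or MCScanX `.collinearity`); pairs whose
members share a base gene are removed first, since a within-gene "pair"
is allele retention, not gene expansion.

## Gene structure

One representative transcript per gene — the longest CDS, ties broken by
transcript ID. GC is computed over the CDS with ambiguity bases excluded
from numerator and denominator (so GC is invariant under reverse
complement). Introns are gaps between consecutive exons in 1-based
inclusive coordinates; per-gene intron size is reported both as total and
mean, since either aggregate is defensible. Cross-species contrasts use
one-way ANOVA; two-group subfamily contrasts default to Welch's t
(unequal variances), with Mann–Whitney behind a flag.

## Conserved genes

"Conserved" means the gene's orthogroup has at least one member in every
species under comparison — the stricter of the two possible readings of a
cross-species orthogroup criterion; `min_species` relaxes it. Because
polyploid gene totals can be quoted with or without allele collapsing,
the conservation summary optionally reports the conserved percentage
against both denominators.

## Ka/Ks (NG86)

Sites: for each codon and position, the synonymous-site fraction is the
number of synonymous one-step changes divided by the number of one-step
changes that do not create a stop codon (positions adjacent to stops thus
contribute full weight to their remaining changes); N + S = 3 per codon
exactly, and site counts are averaged over the two sequences.
Differences: codons differing at k positions are resolved by equal-weight
averaging over the k! substitution orderings; orderings that pass through
a stop codon are excluded. In the rare case where every ordering is
blocked, each differing position is classified by its direct one-step
change in whichever codon's context avoids a stop. Proportions are
corrected with Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is reported
as saturated and the ratio as undefined (`NA`), as is Ks = 0 — never ∞,
never silently dropped.

Codon alignments come from global protein alignment (BLOSUM62, gap open
10, extend 0.5) back-translated to codons; columns containing a gap,
ambiguity base or stop are dropped, and results from fewer than 30
aligned codons are flagged low-confidence. The genetic code defaults to
the standard table and is configurable.

The test suite checks the implementation against a brute-force oracle
that enumerates every substitution pathway recursively with exact
rational arithmetic; agreement is required to 1e-12 on N, S, Nd, Sd over
random short alignments.

## Differential expression

TPM divides counts by feature length in kb and scales each sample to
1e6. TMM normalization follows the trimmed-mean-of-M-values recipe:
reference sample by upper-quartile proximity to the mean upper quartile,
30% two-sided trim on M, 5% on A, precision-weighted mean of M, factors
centred to geometric mean 1.

The exact test conditions on each feature's total count after scaling all
libraries to their geometric-mean size. Under a common NB dispersion φ,
the group-g sum of n_g samples is NB with shape r_g = n_g/φ, and the
conditional law of the group-2 sum given the total reduces to a negative
hypergeometric that depends only on r_1, r_2 (the null mean cancels); at
φ = 0 it is binomial. Two-sided p doubles the smaller tail, capped at 1.
The common dispersion is estimated by a ratio-of-sums method-of-moments
aggregate of Var = μ + φμ² across features and groups (the μ² term
debiased by Var/n), clipped at 0. With no replicates the dispersion must
be supplied; the conventional default is BCV 0.4 (φ = 0.16). A feature is
DE when BH-adjusted FDR < 0.05 and |log2FC| ≥ 1; log2FC uses normalized
group means with a 0.5 pseudo-count. This is a transparent approximation
to the classic exact-test workflow, validated by calibration on synthetic
truth rather than by numerical agreement with any particular R package.

## Origin, ASE and multi-disease response

Allele-level DE calls collapse to base genes (DE iff ≥ 1 allele DE;
direction "mixed" when DE alleles disagree). The wild-parent share among
DE genes is tested one-sided ("greater", matching the directional claim
that wild-derived resistance genes are over-represented) with the exact
binomial tail P(X ≥ k | n, p₀) computed by direct pmf summation; p₀
defaults to 0.2, the upper end of the wild parent's genome contribution
to modern cultivars. A χ² goodness-of-fit and a two-sided option are
provided. ASE calls require two alleles of one base gene each
individually DE in opposite directions within the same comparison.
Multi-disease intersection reports genes DE in ≥ 2 diseases and a strict
subset re-thresholded at |log2FC| ≥ 2 across all requested diseases.

## Synthetic data

The generator plants known truth at the study's own operating point:

* **Annotation** — tetraploid by default, 300 base genes; allele counts
  drawn from retention probabilities (0.25, 0.35, 0.34, 0.06) for 1–4
  alleles, putting 6% of genes at full retention as observed in the wild
  tetraploid; class mix 28% CNL / 32% truncated / 40% non-NBS, giving a
  ~47% CNL share among NBS-LRR genes; wild-parent prefix on 55% of genes
  (the share observed among disease-responsive genes; the 20% null is set
  explicitly in null simulations). Domain rows follow the planted class
  deterministically — no annotation noise — so classification recovery is
  testable for exact equality. CDS GC targets 44% (CNL) vs 46%
  (truncated).
* **Counts** — NB with dispersion 0.1 around a lognormal baseline of mean
  ~100; three samples per group; planted DE genes shift one group by
  2^±3; planted ASE pairs give two alleles of one gene opposite ±3
  effects; a complete truth table labels every feature.
* **Codon pairs** — two lineages from a random sense-codon ancestor;
  mutation proposals arrive Poisson at `t_branch` per nucleotide site
  (split evenly between lineages), uniform target base, stop-creating
  proposals rejected, synonymous changes always fixed, nonsynonymous
  fixed with probability ω. The uniform proposal kernel with symmetric
  acceptance keeps the sense-codon stationary distribution uniform, so
  the realized nonsynonymous/synonymous rate ratio equals ω and NG86
  should recover it at low divergence (default t = 0.4, ω = 0.2).

Each output draws from its own RNG stream derived from the master seed by
a fixed label, so regenerating one artifact never perturbs another, and
identical configurations give byte-identical files.

What the generator does **not** emulate: annotation error, partial or
chimeric gene models, mapping bias between alleles (a real confounder of
ASE), codon-usage and transition/transversion bias, indels, library-
composition artefacts, or correlated expression between alleles. Passing
tests therefore demonstrate correctness of the statistical machinery
under its stated assumptions, not robustness to real-data artefacts.

## Problem sizes and numerical checks

The standard verification runs use: 200 random alignments of ≤ 30 codons
for oracle equivalence; 50 pairs × 3000 codons per ω for parameter
recovery (±0.1 band); ~2000 allele features at 3+3 samples for DE
calibration (type-I error in [0.035, 0.065] at p < 0.05; sensitivity
≥ 0.9 and observed FDR ≤ 0.1 for planted |log2FC| = 3); 400 replicates of
200 genes for the origin test's null size. The 200-gene size was chosen
after computing the exact test's attained size analytically (0.0494 at
n = 200, p₀ = 0.2): exact binomial tests are conservative, and the
attained size of the discrete rejection region — not the nominal 5% —
is what a finite replicate study can observe.

Degenerate inputs are handled explicitly rather than silently: empty
groups, zero-variance fields, all-zero samples, saturation, unmapped
prefixes and mixed-ploidy group sets all raise typed errors; undefined
ratios propagate as `NA`.
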