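# Methods

This note documents the models, the defaults and why they were chosen, the
synthetic-data generator's scope, and the numerical conventions. It is the
package's own account; every empirical claim here is one the test suite or
`scripts/acceptance.py` computes.

## Count model and window exact test

Per-window MeDIP-Seq fragment counts are modelled as negative binomial,
parameterized by mean μ and dispersion φ with var = μ + φμ². φ = 0
degenerates to Poisson; this is the edgeR parameterization, chosen because
the window statistic is an edgeR-style conditional exact test.

Before testing, each sample's counts are scaled to the geometric-mean
library size with half-even rounding (`numpy.rint`). This deterministic
equalization replaces edgeR's quantile-adjusted pseudo-counts: it is
simpler, exactly reproducible, and its adequacy is checked by the type-I
error simulation rather than by claiming equality with edgeR output. The
conditional total *T* for each window is the sum of the equalized group
sums, which makes the rounding self-consistent (no separate re-syncing
step is needed).

Given equalized libraries, the sum of n i.i.d. NB(μ, φ) counts is
NB(nμ, φ/n). Conditional on T, the distribution of the group-A sum is the
normalized product of the two group-sum NB probability masses over all
splits 0..T; because both masses share the NB probability parameter, this
conditional is the negative hypergeometric and does not depend on the
plug-in μ̂ = T/(n_A+n_B). The two-sided p value sums conditional
probabilities of all splits whose probability does not exceed the observed
split's, with a relative tie tolerance of 1e-7 (the same convention
scipy's Fisher test uses) to absorb floating-point round-off. T = 0
returns p = 1 by convention. At φ = 0 the statistic equals the conditional
binomial exact test; the suite verifies agreement to 1e-12 over every
split of every total up to 40.

The conditional distribution depends only on T, so the all-windows driver
caches it per distinct total; testing 10⁴–10⁵ windows takes seconds.

**Dispersion.** A single common φ is shared by all windows (edgeR
"common" mode; tagwise shrinkage is out of scope).

* `grid_cml` (default): maximize the summed conditional NB log-likelihood
  of the within-group counts given each window's group total, over a
  61-point log-spaced grid φ ∈ [1e-4, 10]. Requires replication in at
  least one group. On simulated NB data with φ = 0.2 the estimate falls
  within [0.1, 0.4] (tested).
* `moments`: max(0, Σ_w(v_w − m_w) / Σ_w m_w²) over pooled within-group
  sample moments — fast, and 0 for Poisson-like data.

The grid has ~21% resolution, so φ̂ can sit a step below the truth; the
null simulations bound the practical consequence (type-I error at α = 0.05
within [0.03, 0.07] at φ = 0.1, 6 vs 6 samples, pooled over 10
replicates).

**Log fold change** is log₂ of the prior-damped normalized group-sum
ratio with a prior count of 0.5 per group; **FDR** is Benjamini–Hochberg
(statsmodels), reported per comparison.

## DMR calling

Seeds are windows with p strictly below the seed threshold (default
1e-06; a per-comparison override to 1e-04 exists for sparse comparisons).
Extension absorbs any window with p < 0.1 whose inter-edge gap to the
current DMR interval is ≤ 1000 bp, iterated to a fixed point; DMRs that
then touch or overlap merge. "Within 1000 bp" is read inclusively, so
exactly one non-qualifying 1-kb window can be bridged. Extension never
crosses a chromosome boundary. Because the growing edge is always the
furthest absorbed window's edge, the fixed point equals maximal chains of
sub-0.1 windows with consecutive gaps ≤ 1000 bp that contain a seed; the
implementation computes those chains directly and is tested against a
naive repeated-absorption oracle on 1,000 random landscapes.

Member windows are all windows overlapped by the final span, including
bridged non-significant ones. The DMR's p is the minimum member p; q and
log₂FC are taken from the seed (most significant, leftmost on ties)
window — the labelling had to be fixed by convention since a region has no
single test. CpG density is CpGs per 100 bp of span.

A consequence of the p < 0.1 extension rule worth knowing: flanking null
windows are absorbed at roughly the null rate (~0.1 per flank, plus
bridging), so for narrow regions a non-trivial share of member windows is
expected to lie outside any true signal. The planted-recovery benchmark
therefore plants multi-window domains (8 regions of 25 windows, balanced
hyper/hypo direction, in a 10,000-window genome), where recovery is
measured as ≥ 90% planted-window sensitivity with ≤ 5% of member windows
outside planted regions, pooled over 5 replicates. Single-window
detection power is assessed separately at the window level (≥ 90% of
planted windows at p < 1e-4 for |log₂FC| = 2, μ = 100, φ = 0.05, 6 vs 6).
Balanced effect direction also mirrors real exposure DMR sets and keeps
library-size equalization free of composition bias; strongly unbalanced
planting inflates the affected group's library sizes and shifts every
null window, which is a property of total-count normalization, not of the
test.

## Gene association and set comparison

Genes associate with an interval when the inter-edge gap between interval
and gene body is ≤ 10 kb (0 when overlapping); the gene body, not the
TSS, anchors distance, and strand is ignored — the anchoring convention
had to be fixed, and gene-body distance is the symmetric choice. All
qualifying genes are kept; association equals a brute-force all-pairs
oracle on random instances.

Overlap between DMR sets means ≥ 1 bp genomic intersection (touching
intervals do not intersect); a window-identity mode exists. Venn region
counts are counts of merged loci (connected components of the
intersection graph) per subset pattern. The extended overlap is
asymmetric: the fraction of a stringent-threshold row set intersecting at
least one p < 0.05 window of the column comparison. The chromosomal
cluster scan is this package's own procedure (there is no canonical
definition of a DMR cluster): 2-Mb windows stepped by 500 kb
scored by DMR midpoints against Poisson(genome-wide density × window),
upper-tail p BH-corrected at α = 0.05, significant windows merged. Its
defaults are labelled as invented in output metadata.

## Methylation modules (WGCNA-lite)

Windows are ranked by mean RPKM across samples (ties to the lower genome
ordinal); mean RPKM is the default and a total-read-depth ranking mode is
available. RPKM uses true
window length, so terminal partial windows are length-corrected.

The network is unsigned: a_ij = |Pearson r|⁴ (power 4), zero-variance
windows correlating 0 by convention. TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)
/ (min(k_i,k_j) + 1 − a_ij), verified against direct summation to 1e-12.
Modules come from average-linkage clustering of 1 − TOM with a *static*
cut at 0.99 × the maximum merge height — a declared simplification of
dynamic hybrid tree cut, validated by planted-structure recovery (two
50-window blocks at within-block r ≈ 0.9 are recovered with ≥ 95%
membership agreement; ≥ 80% of independent-noise windows stay grey).
Clusters below minModuleSize = 30 are grey. Modules whose eigengene
correlation distance is < 0.25 merge (single linkage, iterated to a fixed
point, eigengenes recomputed each round). A single block up to 15,000
windows is supported; larger inputs are rejected with guidance to lower
n_top rather than silently block-split. reassignThreshold = 0 is honoured
trivially (no post-hoc reassignment).

Eigengenes are the first principal component of the standardized member
profiles, unit variance, oriented to correlate non-negatively with the
member mean. Module–trait correlation is Pearson r with
p = 2 P(T_{n−2} ≥ |r|√(n−2)/√(1−r²)); |r| = 1 gives p = 0, zero-variance
traits give missing values.

## Pathology classification

Thresholds are control mean + 2 sample SD (n−1 denominator), computed per
tissue from the control lineage with observers pooled by default (a
per-observer flag exists). "Diseased"
requires a count strictly greater than the threshold — a literal reading
of "exceeds" — in at least 2 of 3 blinded observers. Animals diseased in
exactly one tissue are labelled single-disease, in more than one,
multiple disease. Frequencies are compared with two-sided Fisher's exact
test (scipy), which the suite checks against full hypergeometric
enumeration over all 2×2 tables with margins ≤ 30 (enumerated up to the
test's exact row/column/transpose symmetries). Under a null simulation
the diseased fraction matches the 2-of-3 binomial tail implied by the
threshold.

## Synthetic-data generator

The generator emulates exactly the structure the analysis assumes:

* genome with CpG sites as a homogeneous per-bp point process;
* per-window NB counts whose baseline is an affine function of window CpG
  count (MeDIP coverage tracks CpG density), scaled per sample to a
  target library size with log-normal variation (CV 0.2 by default);
* planted DMRs as window ranges with a group-specific 2^log₂FC mean
  shift;
* module blocks sharing a per-sample log-normal latent factor, optionally
  tracking a named trait;
* deterministic fragment placement (evenly spaced within the window) so
  counts → reads → counts is exact under containment counting;
* per-animal, per-observer Poisson abnormality counts with a case-lineage
  rate shift.

Default synthetic depth is ~10 expected reads per 1-kb window at average
CpG density: typical sperm MeDIP-Seq pools (tens of millions of reads over
a ~2.7-Gb genome tiled in 1-kb windows) imply single-digit raw coverage
per window, which fragment extension roughly doubles; 10 is taken as a
realistic round figure. Calibration
simulations instead use the condition sets stated with each benchmark
(μ = 10 for type-I, μ = 100 for recovery).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: base-level sequence and sequencing error,
fragment-length distributions, mappability and copy-number artefacts,
autocorrelated background methylation along the chromosome, batch
effects, and composition bias beyond what planted effects induce. All
randomness derives from one explicit seed via numpy `SeedSequence`
spawning; fixed seed implies bit-identical outputs.

## End-to-end pipeline and problem sizes

`run_pipeline` wires the stages on a synthetic study and writes a
manifest (config hash, seed, output hashes); re-running with the same
config in a fresh directory is byte-identical, a matching manifest skips,
and a mismatched one is refused without `force`. The demo configuration
uses a 2 × 300-kb genome (600 windows), two exposures of 6 samples each
plus 6 controls, 5 planted 3-window DMRs per exposure, two 40-window
module blocks (one trait-linked), and 10 + 10 pathology animals with 3
observers. The calibration benchmarks use 2,000-window nulls (10
replicates) and 10,000-window recovery genomes (5 replicates). These
sizes keep the whole suite and the acceptance script in the tens of
seconds while leaving every estimate's sampling error well inside the
asserted bands.

## Known limitations

* The exact test is calibrated by simulation and is not claimed
  numerically identical to MEDIPS/edgeR output; the normalization and
  dispersion variant implemented here is declared above.
* Common dispersion only; no tagwise shrinkage, GLM/quasi-likelihood, or
  TMM normalization.
* Static tree cut replaces dynamic hybrid cutting; fine-grained nested
  modules may merge.
* The cluster scan is a surrogate with invented defaults.
* Gene association ignores strand, TSS position, and distal ncRNA
  regulation.
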