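# epidmr

Differential DNA methylation analysis for MeDIP-Seq, built around the
window-based workflow used in environmental epigenetics: sperm DNA from
exposure lineages is immunoprecipitated (MeDIP), sequenced, and read
coverage per fixed 1-kb genomic window is compared between groups to find
**differentially methylated regions (DMRs)** — candidate epimutation
biomarkers of toxicant exposure and of later-life disease.

The package is aimed at epigenomics analysts who want the full pipeline as
tested, scriptable Python: window counting, the negative-binomial exact
test, DMR calling with edge extension, gene association, DMR-set
comparison across exposures/diseases, WGCNA-style methylation modules with
trait correlation, and histopathology-based disease classification. A
first-class synthetic-data generator reproduces the statistical structure
the analysis assumes, so every stage can be validated against planted
truth.

## The statistics

**Window exact test.** Counts for window *w* in sample *s* are modelled as
negative binomial with mean μ and dispersion φ (var = μ + φμ²; φ = 0 is
Poisson). After equalizing library sizes to their geometric mean, group
count sums are compared conditionally on the total *T* = S_A + S_B: the
group sum of n samples is NB(nμ, φ/n), and the two-sided p value sums the
conditional probabilities of all splits no more likely than the one
observed (the edgeR-style exact test). At φ = 0 this reduces exactly to
the conditional binomial test. A common φ is estimated across windows by
conditional maximum likelihood on a log-spaced grid (or by a pooled
method-of-moments ratio). Benjamini–Hochberg FDR is reported per
comparison.

**DMR calling.** Windows with p below a seed threshold (default 1e-06;
1e-04 for sparse comparisons) nucleate DMRs; edges are extended while any
window with p < 0.1 lies within 1000 bp of the current DMR interval, then
touching DMRs merge. Each DMR reports its span, member windows, minimum p,
seed-window q and log₂ fold change, and CpG density per 100 bp. Genes
within 10 kb are associated.

**Set comparison.** DMR sets from different exposures or diseases are
compared as genomic loci (≥ 1 bp interval intersection): multiway Venn
region counts, the asymmetric *extended overlap* (stringent rows against
another comparison's p < 0.05 windows), and a sliding-window Poisson scan
for chromosomal DMR clusters.

**Methylation modules.** The top windows by mean RPKM enter an unsigned
weighted network, a_ij = |cor(x_i, x_j)|⁴, transformed to topological
overlap; 1 − TOM is clustered (average linkage, static cut), small
clusters stay grey, correlated modules merge at eigengene distance 0.25,
and module eigengenes (first principal components) are correlated with
sample traits using Pearson r and the Student-t p value.

**Pathology.** An animal's tissue is diseased when its abnormality count
strictly exceeds the control mean + 2 SD, per observer, and at least 2 of
3 blinded observers agree; lineage disease frequencies are compared by
Fisher's exact test.

## Worked example

Simulate a 2-Mb single-chromosome study with two planted methylation
domains (one hyper-, one hypomethylated in the exposed F3 lineage), test
every window, and call DMRs:

```python
import pandas as pd
from epidmr import (GenomeDef, make_windows, StudyDesign, PlantedDMR,
                    simulate_counts, test_all_windows, call_dmrs, dmr_table)

genome = GenomeDef(["chr1"], [2_000_000])
grid = make_windows(genome, window_size=1000)
exposed = [f"F3_exposed_{i}" for i in range(1, 7)]
control = [f"F3_control_{i}" for i in range(1, 7)]
design = StudyDesign(
    samples=pd.DataFrame({"sample_id": exposed + control,
                          "exposure": ["exposed"] * 6 + ["control"] * 6}),
    groups={"exposed_vs_control": (exposed, control)},
    library_size_targets={s: 100.0 * grid.n_windows for s in exposed + control},
    planted_dmrs=[PlantedDMR(400, 405, 2.0, "exposed_vs_control"),
                  PlantedDMR(1200, 1203, -1.5, "exposed_vs_control")],
    dispersion=0.05, baseline_mu=100.0, seed=7)

counts = simulate_counts(design, grid)
stats = test_all_windows(counts, exposed, control, dispersion="grid_cml")
stats = pd.concat([grid.to_frame(), stats.drop(columns="window")], axis=1)
dmrs = call_dmrs(stats, seed_p=1e-6, extend_p=0.1, max_gap_bp=1000, genome=genome)
print(dmr_table(dmrs, "exposed_vs_control")[
    ["dmr_id", "chrom", "start", "end", "n_windows", "p_value", "log2fc"]
].to_string(index=False))
```

This prints:

```
 dmr_id chrom   start     end  n_windows      p_value    log2fc
DMR0001  chr1  400000  405000          5 2.102156e-30  2.280489
DMR0002  chr1 1200000 1203000          3 1.845474e-14 -1.673292
```

Both planted domains are recovered at their exact window boundaries; the
seed-window log₂ fold changes (+2.28, −1.67) estimate the planted effects
(+2, −1.5), and the minimum member p values are far below the 1e-06 seed
threshold.

The same workflow is available from the shell via the `epidmr` console
script (`simulate`, `count`, `test`, `call`, `annotate`, `compare`,
`comod`, `pathology`, and `all` for a config-driven end-to-end run with a
reproducibility manifest). `epidmr all --seed 1 --out run/` emits every
stage's tables plus `manifest.json` with config and output hashes.

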