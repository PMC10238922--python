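# bsamap

Bulk segregant analysis (BSA) QTL mapping for two-parent selfing
crosses, with a built-in simulator of the whole experiment.

## The problem

When two inbred isolates differ heritably in a quantitative trait, a
fast way to locate the causal region is to cross them, derive
recombinant inbred lines (RILs) by repeated selfing, phenotype the
lines, and sequence two pools: the lines at each phenotypic extreme.
Away from any trait locus both pools carry each parental allele at
frequency ~1/2; at a QTL, truncation selection drags the pools apart,
up to fixation of opposite alleles. `bsamap` implements the statistics
of that comparison and a generative model of the cross, pooling and
pooled sequencing, so the pipeline can be exercised and validated
end-to-end without any external data. The defaults emulate a
*C. elegans* experiment — 200 F5 RILs from a CB4932 × JU1242 cross
phenotyped for the final position of the QR.pap neuron (0–27 V-cell
scale), 40 + 40 extreme pools at ~20× coverage, and a QTL on
chromosome IV — but genome, trait model and design are all
configurable.

## The statistic

Per pool, the JU1242 allele frequency at each SNP is var/tot (or
1 − var/tot when the ascertained variant comes from CB4932), filtered
to sites with coverage > 10 in both pools and smoothed in 200 bp
windows stepped 1 bp. With smoothed frequencies f₁, f₂ and
mᵢ = fᵢ·n for n = 40 RILs per pool, the pools are compared by the
pseudocounted log-odds ratio

    LOR = ln[(m₁+ε)/(n−m₁+ε)] − ln[(m₂+ε)/(n−m₂+ε)],  ε = 10⁻⁶,

which is finite even at fixation (LOR = 2·ln(4.0000001×10⁷) ≈ 35.0 at
f₁ = 1, f₂ = 0). Significance uses a genome-wide threshold: the
two-sided p = 0.001 quantile of LOR under m₁, m₂ ~ Binomial(n, ½),
estimated from 10⁶ draws and cross-checked against exact enumeration
of all 41 × 41 outcomes. Runs of positions beyond the threshold become
QTL intervals, with sub-regions at ≥ 0.98 frequency flagged as fixed.
Companion phenotype statistics (Wilcoxon rank-sum, Dunn's test with
Bonferroni adjustment, compact letter display) cover the two-isolate
and dominance-test comparisons that precede mapping.

## Worked example

`examples/02_bsa_scan.py` runs the full pipeline on a simulated cross
with a true QTL at IV:5.2 Mb:

```
pool means: anterior 4.05, posterior 5.69
significance threshold: |LOR| > 1.578
called interval containing the QTL: IV:2,599,900-11,450,099 (pool2 = posterior pool carries the JU1242 allele)
fixed sub-regions (posterior-pool JU1242 frequency >= 0.98): 10, spanning IV:4,849,900-7,700,099
```

The two pools separate by ~1.6 phenotype units; the scan calls a
chromosome-IV interval containing the true QTL, and within it the
posterior pool is fixed for the JU1242 allele across a span covering
5.2 Mb — the signature this method is designed to reveal. The other
examples show the cross simulator (`01`, residual F5 heterozygosity
0.058 ≈ 1/16, genotype-class means 4.15/5.27/5.53), the phenotype
statistics (`03`, Dunn letters grouping heterozygotes with the
dominant parent), and near-isogenic-line predictions (`04`, swapping
chromosome IV swaps the predicted phenotype between 4.16 and 5.54).

A thin CLI wraps the same stages: `bsamap simulate | threshold | bsa |
stats | run` (see `bsamap --help`).

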