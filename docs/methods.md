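# Methods

`bsamap` maps a quantitative trait locus (QTL) by bulk segregant
analysis (BSA) in a two-isolate selfing cross: recombinant inbred lines
(RILs) are phenotyped, the two phenotypic extremes are pooled and
sequenced, and a genomic region linked to the trait reveals itself as a
divergence — up to fixation — of parental allele frequencies between
the pools. The package implements both the mapping statistics and a
generative model of the whole experiment, so every stage can be tested
end-to-end against known truth. The motivating system is the final
anteroposterior position of the QR.pap neuron in *C. elegans*, scored
on a 0–27 scale defined by the V seam-cell nuclei, diverging between
the wild isolates CB4932 (anterior, allele code A) and JU1242
(posterior, allele code B); nothing in the code is specific to that
trait beyond the defaults.

## Cross simulation

**Genome.** Six chromosomes at *C. elegans* physical scale (chromosome
IV: 17.5 Mb) with a genetic length of 50 cM each and a linear bp↔cM
map. Markers (the SNPs segregating between the parents) are evenly
spaced; the module default is one per 10 kb, and the end-to-end test
configuration uses one per 50 kb (≈2,060 genome-wide sites), a scale
chosen to keep full 20-replicate pipelines in seconds while leaving
every chromosome with hundreds of independently segregating blocks.

**Meiosis.** Crossover counts per chromosome are Poisson with mean
equal to the genetic length in Morgans, breakpoints uniform on the
genetic map — the Haldane no-interference model. Two closed forms
follow and are used as oracles: the recombination fraction between
markers at distance *d* cM is r = (1 − e^(−2d/100))/2, and the
recombinant fraction among fully inbred selfed RILs is 2r/(1 + 2r)
(Haldane–Waddington). Real *C. elegans* meiosis has strong crossover
interference (approximately one crossover per bivalent); Haldane is
used because it is the standard neutral default with exact oracle
formulas, and at whole-chromosome resolution the difference affects
recombinant spacing, not the allele-frequency logic under test.

**Inbreeding.** Lines descend from independent F1 selfing chains with
single-individual descent; per-marker heterozygosity halves each
generation, leaving (1/2)^4 = 1/16 at F5 (the default genotyped
generation). Phenotyping the next (F6) generation is represented by
phenotyping the F5 diplotype directly; one extra selfing round is
available through `n_generations` if the 1/32 residual matters.

**Randomness.** One root seed; stage streams are spawned with
`numpy.random.SeedSequence`, one per (generation, gamete) during the
cross and one per pipeline stage, so runs are bit-reproducible while
meiosis stays vectorised across lines.

**Trait model.** A single QTL with genotype means mean_AA, mean_BB and
heterozygote mean mean_AA + h·(mean_BB − mean_AA); each animal adds
Normal(0, residual_sd) noise and is clamped to [0, 27]. Defaults:
mean_AA = 4.16, mean_BB = 5.54 (the two isolates' published means),
h = 0.85 and residual_sd = 0.6. The last two are calibration choices,
not measured facts: h is set so heterozygotes sit near 5.33, the
observed mostly-dominant F1 behaviour, and residual_sd is chosen so
that parental distributions of 50 animals overlap slightly but
separate decisively, matching published mean ± s.d. bars that were
printed without a numeric s.d. A line's QTL genotype is read at the
nearest marker at or left of the QTL position (deterministic
tie-break; positions before the first marker fall back to it).

## Pooling and sequencing model

The 40 lines with the lowest line-mean phenotype form pool 1
(anterior) and the 40 highest pool 2 (posterior); ties break by line
id. Within a pool every line contributes equal DNA (a per-line
Dirichlet weighting could be added, but there is no information to
calibrate it, so it is omitted). Per site, sequencing depth is
Poisson(mean_depth = 20) independently per pool, and the variant-read
count is Binomial(depth, p) where p is the pool frequency of the
ascertained variant allele perturbed by a symmetric error rate
(default 0.001). Sites alternate JU1242- and CB4932-ascertained
variants so both frequency-orientation rules are always exercised; the
orientation handling is checked by an involution property (flipping
origin and counts leaves JU1242 frequencies unchanged). No read-level
artefacts (mapping bias, duplicates, base qualities) are modelled —
the package's contract starts at allele-depth counts.

## The scan

1. **Coverage filter.** Keep sites with depth strictly greater than 10
   in both pools ("higher than ten" read literally).
2. **JU1242 frequency.** var/tot at JU1242-ascertained sites,
   1 − var/tot at CB4932-ascertained ones.
3. **Smoothing.** Unweighted mean of SNP frequencies in 200 bp
   windows stepped 1 bp; windows are 1-based half-open
   [anchor, anchor+200), empty windows emit nothing, and the emitted
   coordinate is the window midpoint. Only non-empty windows are
   materialised, so the 1 bp step costs O(SNPs × window) rather than
   O(genome). Smoothing precedes the statistic.
4. **Statistic.** With smoothed frequencies f1, f2 and m_i = f_i·n for
   n = 40 RILs per pool,
   LOR = ln[(m1+ε)/(n−m1+ε)] − ln[(m2+ε)/(n−m2+ε)], ε = 10⁻⁶.
   Natural log (the base rescales statistic and threshold identically,
   so interval calls are base-invariant). The pseudocount keeps the
   statistic finite at fixation: LOR(f1=1, f2=0) = 2·ln(4.0000001×10⁷)
   ≈ 35.009.
5. **Threshold.** The null takes m1, m2 ~ Binomial(40, 1/2)
   independently — the allele count among 40 homozygous RILs at a
   neutral locus. 10⁶ Monte-Carlo draws give the genome-wide two-sided
   p = 0.001 threshold as the 0.999 quantile of |LOR| (under the
   exactly symmetric null this equals the per-tail 0.0005/0.9995
   quantile pair, with half the Monte-Carlo error and exactly
   symmetric output). An exact alternative enumerates all 41×41
   (m1, m2) outcomes; the Monte-Carlo threshold is required to agree
   within one attainable-value spacing, and does.
6. **Intervals.** Maximal runs of emitted positions beyond a threshold
   become intervals, labelled by which pool carries the JU1242 allele;
   sub-runs where that pool's smoothed frequency is within
   fixation_eps = 0.02 of 1 are flagged as fixed. A single genome-wide
   simulated threshold is used, not per-site FDR, replicating the
   published procedure.

## Calibration limits of the binomial null

The Binomial(40, 1/2) null models RIL sampling only. At a site read to
depth D, the estimated pool frequency carries additional variance
≈ f(1−f)/D; at 20× with ≤1 SNP per 200 bp window this roughly triples
the per-site variance of the statistic, and the acceptance script
measures a per-site exceedance of ≈0.06 under a no-QTL cross against
the nominal 0.001. This is a real property of the procedure as
published, tolerable there because the sought signal is fixation
(|LOR| ≈ 35 against a threshold of 1.58) and false crossings are
short, scattered runs. Two consequences are documented rather than
papered over: the no-QTL calibration test in the acceptance suite
fails by design of the method itself, and `simulate_threshold`
accepts `null_model="read_depth"`, which resamples each null count
through Poisson(20×) binomial read noise; its wider threshold (≈3.36)
restores the nominal rate (measured ≈0.0008). The read-depth null is
not the default because the binomial null is what the procedure
specifies and what the exact-enumeration cross-check pins down.

## Phenotype statistics

Wilcoxon's rank-sum W is the Mann–Whitney U of the first-named group
(rank sum minus n_x(n_x+1)/2), computed by `scipy.stats.mannwhitneyu`
with the normal approximation, tie correction and continuity
correction — the convention of R's `wilcox.test` for tied or large
samples, which the suite cross-checks against frozen R 4.3.3 values;
an exact mode is available for small untied samples. Dunn's (1964)
post-hoc test is implemented directly (no installed package provides
it): pooled mid-ranks, Z = (R̄_a − R̄_b)/SE with the tie-corrected
SE = sqrt[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_a + 1/n_b)], two-sided
normal p-values, Bonferroni multiplied by the number of pairs and
capped at 1. The compact letter display uses the insert-and-absorb
algorithm; letters are validated structurally (groups share a letter
iff their adjusted difference is non-significant) rather than against
any published figure, whose exact letter assignments are not
recoverable.

## What passing tests do and do not show

The generator realises the study design (200 RILs, 40+40 pools, 20×)
with idealised ingredients: evenly spaced biallelic markers, no
segregation distortion or selection during inbreeding, equal DNA per
pooled line, Poisson depth, symmetric sequencing error, no
interference. Passing tests therefore demonstrate that the statistics
and interval logic are correct and that the design has power to
localise a strong, mostly dominant QTL under those conditions; they do
not validate robustness to mapping bias, uneven pooling, hyperdivergent
regions, or phenotype exclusion rules applied to real lines. Real
analyses should also expect the genome-wide false-positive behaviour
discussed above at moderate coverage.

## Problem sizes and numerical choices

End-to-end tests and the acceptance script use the 50 kb marker
spacing (≈2,060 sites), 20 no-QTL replicates and 50 QTL replicates;
inbreeding oracles use 5,000 lines (heterozygosity at F5, map
expansion at 15 selfing generations where the Haldane–Waddington limit
has converged). Monte-Carlo assertions use 3-standard-error bands with
fixed seeds. Degenerate inputs fail loudly: zero-coverage sites,
empty pools, empty post-filter tables and n_generations < 1 raise
errors rather than propagate NaNs.
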