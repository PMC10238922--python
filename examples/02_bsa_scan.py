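"""Full bulk-segregant scan: extreme pools, pooled reads, QTL intervals.

Runs the whole pipeline on a simulated cross: select the 40 most
anterior and 40 most posterior lines, simulate ~20x pooled allelic
depths at every SNP, smooth JU1242 allele frequencies in 200 bp
windows, compare pools with the pseudocounted log-odds ratio, and call
intervals against the simulated p = 0.001 genome-wide threshold.
"""

from bsamap import BsaParams, QtlModel, RunConfig, default_genome, run_pipeline

config = RunConfig(
    genome=default_genome(marker_spacing_bp=50_000),
    qtl=QtlModel(),          # true QTL at IV:5.2 Mb
    n_lines=200,
    pool_size=40,
    mean_depth=20.0,
    bsa=BsaParams(),         # 200 bp / 1 bp windows, p=0.001, 1e6 null draws
    seed=1,
)
result = run_pipeline(config)

print(f"pool means: anterior {result.summary['pool_low_mean']:.2f}, "
      f"posterior {result.summary['pool_high_mean']:.2f}")
print(f"significance threshold: |LOR| > {result.scan.threshold_high:.3f}")

iv = result.scan.intervals.query("chrom == 'IV' and start <= 5_200_000 <= end")
row = iv.iloc[0]
print(f"called interval containing the QTL: IV:{row.start:,}-{row.end:,} "
      f"({row.direction} = posterior pool carries the JU1242 allele)")
fixed = result.scan.fixed_regions.query(
    "chrom == 'IV' and @row.start <= start and end <= @row.end"
)
print(f"fixed sub-regions (posterior-pool JU1242 frequency >= 0.98): "
      f"{len(fixed)}, spanning IV:{fixed['start'].min():,}-{fixed['end'].max():,}")
print("The span of fixation covers the simulated QTL at 5.2 Mb — the analogue")
print("of the fixed 4.5-6 Mb region this kind of scan is designed to reveal.")
print(f"(total intervals genome-wide: {len(result.scan.intervals)}; at 20x")
print(" coverage the RIL-only null is permissive - see docs/methods.md)")
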