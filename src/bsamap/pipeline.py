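"""Seeded end-to-end driver: simulate RILs -> pool -> sequence -> scan.

One :class:`RunConfig` fully determines a run; a single root seed is
split per stage with ``numpy.random.SeedSequence`` and every stage's
parameters land in the JSON summary, which alone suffices to rerun the
pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .bsa import BsaParams, LorResult, bsa_scan
from .genome import GenomeSpec, QtlModel, default_genome
from .pools import PoolSpec, make_pool_counts, select_pools
from .ril import RilPopulation, simulate_ril_population


class PipelineError(RuntimeError):
    """Raised with a stage label when any pipeline stage fails."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs, YAML round-trippable."""

    genome: GenomeSpec = field(default_factory=default_genome)
    qtl: QtlModel | None = field(default_factory=QtlModel)
    n_lines: int = 200
    n_generations: int = 4
    n_animals_per_line: int = 20
    pool_size: int = 40
    mean_depth: float = 20.0
    error_rate: float = 0.001
    bsa: BsaParams = field(default_factory=BsaParams)
    fixation_eps: float = 0.02
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if 2 * self.pool_size > self.n_lines:
            raise ValueError("2 * pool_size must not exceed n_lines")

    def to_dict(self) -> dict:
        return {
            "genome": io.genome_to_dict(self.genome),
            "qtl": None if self.qtl is None else io.qtl_to_dict(self.qtl),
            "n_lines": self.n_lines,
            "n_generations": self.n_generations,
            "n_animals_per_line": self.n_animals_per_line,
            "pool_size": self.pool_size,
            "mean_depth": self.mean_depth,
            "error_rate": self.error_rate,
            "bsa": vars(self.bsa).copy(),
            "fixation_eps": self.fixation_eps,
            "seed": self.seed,
            "outdir": self.outdir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["genome"] = io.genome_from_dict(d["genome"])
        d["qtl"] = None if d.get("qtl") is None else io.qtl_from_dict(d["qtl"])
        d["bsa"] = BsaParams(**d.get("bsa", {}))
        return cls(**d)

    def save(self, path) -> None:
        io.save_yaml(self.to_dict(), path)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(io.load_yaml(path))


@dataclass
class PipelineResult:
    population: RilPopulation
    pool_low: list[str]
    pool_high: list[str]
    counts: "object"
    scan: LorResult
    summary: dict


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - re-labelled, not swallowed
                raise PipelineError(f"[{name}] {e}") from e
        return wrapper
    return deco


def run_pipeline(config: RunConfig, write_vcf: bool = False) -> PipelineResult:
    """Execute the full flow; optionally write all artifacts to outdir.

    Stage order: RIL simulation, extreme-pool selection, pooled read
    simulation, BSA scan, reporting. Identical configs give identical
    outputs (files byte-identical).
    """
    seeds = np.random.SeedSequence(config.seed).spawn(3)

    sim = _stage("simulate")(simulate_ril_population)
    pop = sim(config.genome, config.qtl, config.n_lines, config.n_generations,
              config.n_animals_per_line, seeds[0])

    pool = _stage("pool")(select_pools)
    low, high = pool(pop, PoolSpec(config.pool_size, "lowest", "anterior"),
                     PoolSpec(config.pool_size, "highest", "posterior"))

    reads = _stage("sequence")(make_pool_counts)
    counts = reads(pop, low, high, config.mean_depth, config.error_rate, seeds[1])

    scan = _stage("bsa")(bsa_scan)(
        counts, config.bsa, seeds[2], config.fixation_eps
    )

    means = pop.line_means()
    idx = {lid: i for i, lid in enumerate(pop.line_ids)}
    summary = {
        "config": config.to_dict(),
        "threshold_low": scan.threshold_low,
        "threshold_high": scan.threshold_high,
        "pool_low_mean": float(np.mean([means[idx[l]] for l in low])),
        "pool_high_mean": float(np.mean([means[idx[l]] for l in high])),
        "n_sites_scanned": int(len(scan.track)),
        "intervals": scan.intervals.to_dict(orient="records"),
        "fixed_regions": scan.fixed_regions.to_dict(orient="records"),
    }

    if config.outdir is not None:
        _write_outputs(config, pop, counts, scan, summary, write_vcf)
    return PipelineResult(pop, low, high, counts, scan, summary)


@_stage("report")
def _write_outputs(config, pop, counts, scan, summary, write_vcf) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_genotypes_tsv(pop, out / "genotypes.tsv")
    if pop.phenotypes is not None:
        io.write_phenotypes_csv(pop, out / "phenotypes.csv")
    io.write_pool_counts_tsv(counts, out / "pool_counts.tsv")
    if write_vcf:
        io.write_pool_counts_vcf(counts, out / "pool_counts.vcf",
                                 ("anterior", "posterior"), config.genome)
    scan.track.to_csv(out / "frequency_track.tsv", sep="\t", index=False)
    scan.track[["chrom", "pos", "lor"]].to_csv(out / "lor.tsv", sep="\t", index=False)
    io.write_bed(scan.intervals, out / "qtl_intervals.bed")
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
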