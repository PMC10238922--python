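"""Extreme-phenotype pool selection and pooled short-read count simulation.

Emulates the study design: from 200 phenotyped RILs, the 40 lines with the
most anterior trait means form one pool and the 40 most posterior the
other; each pool is sequenced to ~20x mean coverage and per-SNP allelic
depths are tallied. Read counts, not reads, are the unit — mapping and
variant calling sit upstream of this package's contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .ril import RilPopulation, _as_rng

#: canonical PoolCounts column order (pool1 = low/anterior, pool2 = high/posterior)
POOL_COUNT_COLUMNS = ["chrom", "pos", "origin", "var1", "tot1", "var2", "tot2"]
ORIGIN_JU = "JU1242"
ORIGIN_CB = "CB4932"


@dataclass(frozen=True)
class PoolSpec:
    """How one pool is drawn: size and which phenotype extreme it takes."""

    pool_size: int = 40
    selection: str = "lowest"  # or "highest", by line mean phenotype
    label: str = "pool"

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.selection not in ("lowest", "highest"):
            raise ValueError("selection must be 'lowest' or 'highest'")


def select_pools(
    pop: RilPopulation, spec_low: PoolSpec, spec_high: PoolSpec
) -> tuple[list[str], list[str]]:
    """Line ids of the two extreme pools (disjoint; ties broken by line_id)."""
    if spec_low.selection != "lowest" or spec_high.selection != "highest":
        raise ValueError("spec_low must select 'lowest' and spec_high 'highest'")
    if spec_low.pool_size + spec_high.pool_size > pop.n_lines:
        raise ValueError("pools exceed the number of lines")
    means = pop.line_means()
    order = sorted(range(pop.n_lines), key=lambda i: (means[i], pop.line_ids[i]))
    low = [pop.line_ids[i] for i in order[: spec_low.pool_size]]
    high = [pop.line_ids[i] for i in order[-spec_high.pool_size :]]
    return low, high


def pool_allele_frequency(
    pop: RilPopulation, pool_line_ids: list[str]
) -> np.ndarray:
    """True per-marker JU1242 (B) allele frequency of a pool of lines."""
    if not pool_line_ids:
        raise ValueError("empty pool")
    index = {lid: i for i, lid in enumerate(pop.line_ids)}
    rows = [index[lid] for lid in pool_line_ids]
    return pop.dosage[rows].sum(axis=0) / (2.0 * len(rows))


def default_variant_origins(n_sites: int) -> np.ndarray:
    """Alternate ascertained-parent labels so both frequency rules are exercised."""
    return np.where(np.arange(n_sites) % 2 == 0, ORIGIN_JU, ORIGIN_CB)


def simulate_pool_reads(
    pop: RilPopulation,
    pool_line_ids: list[str],
    genome: GenomeSpec,
    mean_depth: float = 20.0,
    error_rate: float = 0.001,
    rng_seed=None,
    variant_origin: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-site (var, tot) read counts for one pool of lines.

    Depth ~ Poisson(mean_depth) per site; the variant-read count is
    Binomial(depth, p) where p is the error-perturbed pool frequency of
    the ascertained variant allele (the JU1242 allele at JU1242-origin
    sites, the CB4932 allele otherwise). Lines contribute equal DNA.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    rng = _as_rng(rng_seed)
    f_b = pool_allele_frequency(pop, pool_line_ids)  # JU1242 frequency
    chroms, pos = genome.marker_table()
    if variant_origin is None:
        variant_origin = default_variant_origins(len(pos))
    variant_origin = np.asarray(variant_origin)
    f_obs = f_b * (1.0 - error_rate) + (1.0 - f_b) * error_rate
    p_var = np.where(variant_origin == ORIGIN_JU, f_obs, 1.0 - f_obs)
    tot = rng.poisson(mean_depth, size=len(pos))
    var = rng.binomial(tot, p_var)
    return pd.DataFrame(
        {"chrom": chroms, "pos": pos, "origin": variant_origin, "var": var, "tot": tot}
    )


def make_pool_counts(
    pop: RilPopulation,
    pool1_line_ids: list[str],
    pool2_line_ids: list[str],
    mean_depth: float = 20.0,
    error_rate: float = 0.001,
    rng_seed=None,
    variant_origin: np.ndarray | None = None,
) -> pd.DataFrame:
    """PoolCounts table for two pools over all simulated markers."""
    root = np.random.SeedSequence(rng_seed) if not isinstance(rng_seed, np.random.SeedSequence) else rng_seed
    s1, s2 = root.spawn(2)
    if variant_origin is None:
        variant_origin = default_variant_origins(pop.genome.n_markers)
    r1 = simulate_pool_reads(
        pop, pool1_line_ids, pop.genome, mean_depth, error_rate,
        np.random.default_rng(s1), variant_origin,
    )
    r2 = simulate_pool_reads(
        pop, pool2_line_ids, pop.genome, mean_depth, error_rate,
        np.random.default_rng(s2), variant_origin,
    )
    df = pd.DataFrame(
        {
            "chrom": r1["chrom"],
            "pos": r1["pos"],
            "origin": r1["origin"],
            "var1": r1["var"],
            "tot1": r1["tot"],
            "var2": r2["var"],
            "tot2": r2["tot"],
        }
    )
    validate_pool_counts(df)
    return df


def validate_pool_counts(df: pd.DataFrame) -> None:
    """Schema and invariant checks for a PoolCounts table."""
    missing = [c for c in POOL_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PoolCounts missing columns: {missing}")
    for v, t in (("var1", "tot1"), ("var2", "tot2")):
        if (df[v] < 0).any() or (df[v] > df[t]).any():
            raise ValueError(f"need 0 <= {v} <= {t} at every site")
    if not set(df["origin"]).issubset({ORIGIN_JU, ORIGIN_CB}):
        raise ValueError("origin must be JU1242 or CB4932")
    for _, sub in df.groupby("chrom", sort=False):
        if np.any(np.diff(sub["pos"].to_numpy()) <= 0):
            raise ValueError("positions must be sorted and unique within chromosome")


def flip_origin(df: pd.DataFrame) -> pd.DataFrame:
    """Swap the ascertained parent at every site, flipping counts to match.

    An involution: downstream JU1242 frequencies are unchanged, which is
    the consistency check for the origin bookkeeping.
    """
    out = df.copy()
    out["origin"] = np.where(df["origin"] == ORIGIN_JU, ORIGIN_CB, ORIGIN_JU)
    out["var1"] = df["tot1"] - df["var1"]
    out["var2"] = df["tot2"] - df["var2"]
    return out
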