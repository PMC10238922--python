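"""Readers and writers: genotype/phenotype tables, pool counts (TSV and a
minimal VCF dialect with AD fields), BED intervals, YAML configuration.

Coordinates are 1-based inclusive everywhere inside the package; BED
output converts to 0-based half-open at the boundary. All writer/reader
pairs round-trip losslessly on valid data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import Chromosome, GenomeSpec, QtlModel
from .pools import ORIGIN_CB, ORIGIN_JU, POOL_COUNT_COLUMNS, validate_pool_counts
from .ril import RilPopulation

_GT_CODE = {0: "AA", 1: "AB", 2: "BB"}
_GT_DOSAGE = {"AA": 0, "AB": 1, "BB": 2}


# ---------------------------------------------------------------------------
# genotypes and phenotypes
# ---------------------------------------------------------------------------

def write_genotypes_tsv(pop: RilPopulation, path) -> None:
    """Long-format TSV: line_id, chrom, pos, genotype in {AA, AB, BB}."""
    chroms, pos = pop.genome.marker_table()
    dosage = pop.dosage
    frames = []
    for i, lid in enumerate(pop.line_ids):
        frames.append(pd.DataFrame({
            "line_id": lid, "chrom": chroms, "pos": pos,
            "genotype": [_GT_CODE[d] for d in dosage[i]],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path, genome: GenomeSpec) -> RilPopulation:
    """Rebuild a population's genotypes (unphased; AB stored as A/B)."""
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "chrom": str})
    chroms, pos = genome.marker_table()
    key = pd.DataFrame({"chrom": chroms, "pos": pos})
    line_ids = list(dict.fromkeys(df["line_id"]))
    haps = np.empty((len(line_ids), 2, genome.n_markers), dtype=np.int8)
    for i, lid in enumerate(line_ids):
        sub = df.loc[df["line_id"] == lid].merge(key, on=["chrom", "pos"], how="right")
        if sub["genotype"].isna().any() or len(sub) != genome.n_markers:
            raise ValueError(f"genotypes for {lid} do not match the genome's markers")
        d = sub["genotype"].map(_GT_DOSAGE).to_numpy()
        haps[i, 0] = (d >= 1)
        haps[i, 1] = (d == 2)
    return RilPopulation(genome, line_ids, haps)


def write_phenotypes_csv(pop: RilPopulation, path) -> None:
    """CSV of line_id, animal_index (1-based), phenotype."""
    if pop.phenotypes is None:
        raise ValueError("population has no phenotypes")
    n_animals = pop.phenotypes.shape[1]
    pd.DataFrame({
        "line_id": np.repeat(pop.line_ids, n_animals),
        "animal_index": np.tile(np.arange(1, n_animals + 1), pop.n_lines),
        "phenotype": pop.phenotypes.ravel(),
    }).to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    """Phenotype table (line_id, animal_index, phenotype); preserves row order."""
    df = pd.read_csv(path, dtype={"line_id": str})
    required = {"line_id", "animal_index", "phenotype"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype CSV needs columns {sorted(required)}")
    return df


def read_group_values_csv(path) -> pd.DataFrame:
    """Two-column (group, value) CSV for the statistics module.

    Also accepts a (line_id, animal_index, phenotype) file, treating each
    line as a group — the layout the supplementary phenotype sheets use.
    """
    df = pd.read_csv(path)
    if {"group", "value"}.issubset(df.columns):
        return df[["group", "value"]]
    if {"line_id", "phenotype"}.issubset(df.columns):
        return df.rename(columns={"line_id": "group", "phenotype": "value"})[["group", "value"]]
    raise ValueError("need columns (group, value) or (line_id, animal_index, phenotype)")


# ---------------------------------------------------------------------------
# pool counts: TSV and minimal VCF dialect
# ---------------------------------------------------------------------------

_TSV_HEADER = ["CHROM", "POS", "ORIGIN", "VAR1", "TOT1", "VAR2", "TOT2"]


def write_pool_counts_tsv(counts: pd.DataFrame, path) -> None:
    validate_pool_counts(counts)
    out = counts[POOL_COUNT_COLUMNS].copy()
    out.columns = _TSV_HEADER
    out.to_csv(path, sep="\t", index=False)


def read_pool_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    if list(df.columns) != _TSV_HEADER:
        raise ValueError(f"pool-counts TSV must have columns {_TSV_HEADER}")
    df.columns = POOL_COUNT_COLUMNS
    validate_pool_counts(df)
    return df


def write_pool_counts_vcf(
    counts: pd.DataFrame, path, pool_labels=("pool1", "pool2"),
    genome: GenomeSpec | None = None,
) -> None:
    """Minimal VCF 4.2 with per-pool AD (allelic depth) sample fields.

    REF carries the CB4932 base and ALT the variant base only as
    placeholders (A/T): this dialect transports counts, not sequence.
    AD is (ref_depth, alt_depth) with alt = the ascertained variant, so
    ref_depth = TOT - VAR. Variant origin is kept in INFO/ORIGIN.
    """
    validate_pool_counts(counts)
    lines = ["##fileformat=VCFv4.2"]
    if genome is not None:
        for c in genome.chromosomes:
            lines.append(f"##contig=<ID={c.name},length={c.length_bp}>")
    else:
        for chrom in dict.fromkeys(counts["chrom"]):
            length = int(counts.loc[counts["chrom"] == chrom, "pos"].max())
            lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##INFO=<ID=ORIGIN,Number=1,Type=String,'
                 'Description="Parent of origin of the ascertained variant allele">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref, variant)">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(pool_labels))
    for row in counts.itertuples(index=False):
        ad1 = f"{row.tot1 - row.var1},{row.var1}"
        ad2 = f"{row.tot2 - row.var2},{row.var2}"
        lines.append(f"{row.chrom}\t{row.pos}\t.\tA\tT\t.\t.\t"
                     f"ORIGIN={row.origin}\tAD\t{ad1}\t{ad2}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_counts(path) -> pd.DataFrame:
    """Parse the minimal AD-dialect VCF back into a PoolCounts table."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 2:
        raise ValueError(f"{path}: expected exactly 2 pool samples, got {len(vcf.samples)}")
    rows = []
    for v in vcf:
        site = f"{v.CHROM}:{v.POS}"
        origin = v.INFO.get("ORIGIN")
        if origin not in (ORIGIN_JU, ORIGIN_CB):
            raise ValueError(f"{path}: {site}: missing or invalid ORIGIN")
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ValueError(f"{path}: {site}: AD field missing")
        ad = np.asarray(ad, dtype=np.int64)
        if ad.shape != (2, 2) or (ad < 0).any():
            raise ValueError(f"{path}: {site}: malformed AD field")
        rows.append((v.CHROM, v.POS, origin,
                     ad[0, 1], ad[0].sum(), ad[1, 1], ad[1].sum()))
    df = pd.DataFrame(rows, columns=POOL_COUNT_COLUMNS)
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    validate_pool_counts(df)
    return df


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

def write_bed(intervals: pd.DataFrame, path) -> None:
    """Intervals (1-based inclusive) as BED (0-based half-open).

    A 1-based inclusive interval [start, end] becomes the BED line
    ``chrom  start-1  end``; the name field carries the direction.
    """
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            name = getattr(row, "direction", ".")
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{name}\n")


def read_bed(path) -> pd.DataFrame:
    """BED back to 1-based inclusive (chrom, start, end, direction)."""
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{i}: malformed BED line")
        rows.append((fields[0], int(fields[1]) + 1, int(fields[2]),
                     fields[3] if len(fields) > 3 else "."))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def genome_to_dict(genome: GenomeSpec) -> dict:
    return {
        "chromosomes": [
            {"name": c.name, "length_bp": c.length_bp, "length_cM": c.length_cM}
            for c in genome.chromosomes
        ],
        "markers": {name: [int(p) for p in pos] for name, pos in genome.markers.items()},
    }


def genome_from_dict(d: dict) -> GenomeSpec:
    chroms = [Chromosome(c["name"], int(c["length_bp"]), float(c["length_cM"]))
              for c in d["chromosomes"]]
    markers = {name: np.asarray(pos, dtype=np.int64) for name, pos in d["markers"].items()}
    return GenomeSpec(chroms, markers)


def qtl_to_dict(qtl: QtlModel) -> dict:
    return {
        "chromosome": qtl.chromosome, "position_bp": qtl.position_bp,
        "mean_AA": qtl.mean_AA, "mean_BB": qtl.mean_BB,
        "dominance_h": qtl.dominance_h, "residual_sd": qtl.residual_sd,
    }


def qtl_from_dict(d: dict) -> QtlModel:
    return QtlModel(**d)


def save_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
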