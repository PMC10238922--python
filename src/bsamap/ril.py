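"""Recombinant inbred line (RIL) simulation for a two-isolate selfing cross.

The cross emulated: CB4932 x JU1242 F1 heterozygotes are selfed with
single-worm descent for several generations (F1 -> F5 by default, i.e. four
selfing rounds), leaving ~1/16 residual heterozygosity per marker; each line
is then phenotyped on the 0-27 V-cell scale in a fixed number of animals.

Meiosis uses a Poisson crossover count per chromosome (mean = genetic
length in Morgans) with breakpoints uniform on the genetic map — the
Haldane no-interference model, for which closed-form recombination
fractions exist and are used as test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import ALLELE_A, ALLELE_B, GenomeSpec, QtlModel

PHENOTYPE_MIN = 0.0
PHENOTYPE_MAX = 27.0  # relative V seam-cell scale


@dataclass
class Diplotype:
    """Phased pair of haplotypes over the genome's concatenated marker axis.

    ``haplotypes`` has shape (2, n_markers) with entries in {0 (A, CB4932),
    1 (B, JU1242)}. The pair is unordered: AB and BA are the same genotype,
    and ``dosage`` (B-allele count per marker) is the phase-free view.
    """

    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != 2:
            raise ValueError("haplotypes must have shape (2, n_markers)")

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def dosage(self) -> np.ndarray:
        """B-allele count per marker, in {0, 1, 2}."""
        return self.haplotypes.sum(axis=0)

    def heterozygosity(self) -> float:
        return float(np.mean(self.dosage == 1))

    @classmethod
    def f1(cls, genome: GenomeSpec) -> "Diplotype":
        """Fully heterozygous F1 of the two parents."""
        m = genome.n_markers
        return cls(np.stack([np.full(m, ALLELE_A), np.full(m, ALLELE_B)]).astype(np.int8))

    @classmethod
    def homozygous(cls, genome: GenomeSpec, allele: int) -> "Diplotype":
        m = genome.n_markers
        return cls(np.full((2, m), allele, dtype=np.int8))


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _chromosome_gametes(
    haps: np.ndarray, gpos_cM: np.ndarray, length_cM: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised meiosis for one chromosome across N individuals.

    haps: (N, 2, M) phased haplotypes; gpos_cM: (M,) marker genetic
    positions. Returns (N, M) gametes. Crossover count ~ Poisson(L/100),
    breakpoints uniform on [0, L] cM, chromatid chosen uniformly at the
    left end and switched at each breakpoint.
    """
    n, _, m = haps.shape
    if m == 0:
        raise ValueError("empty marker list")
    if length_cM < 0:
        raise ValueError("negative genetic length")
    start = rng.integers(0, 2, size=n)
    if length_cM == 0:
        strand = np.broadcast_to(start[:, None], (n, m))
    else:
        counts = rng.poisson(length_cM / 100.0, size=n)
        kmax = int(counts.max())
        if kmax == 0:
            strand = np.broadcast_to(start[:, None], (n, m))
        else:
            breaks = rng.uniform(0.0, length_cM, size=(n, kmax))
            breaks[np.arange(kmax)[None, :] >= counts[:, None]] = np.inf
            # crossovers left of each marker, in chunks to bound memory
            crossed = np.empty((n, m), dtype=np.int64)
            step = max(1, int(5e7 // (kmax * m + 1)))
            for i in range(0, n, step):
                crossed[i : i + step] = (
                    breaks[i : i + step, :, None] <= gpos_cM[None, None, :]
                ).sum(axis=1)
            strand = (start[:, None] + crossed) % 2
    return np.take_along_axis(haps, strand[:, None, :], axis=1)[:, 0, :]


def gametes(haps: np.ndarray, genome: GenomeSpec, rng: np.random.Generator) -> np.ndarray:
    """One gamete per individual; haps (N, 2, n_markers) -> (N, n_markers)."""
    out = np.empty((haps.shape[0], genome.n_markers), dtype=np.int8)
    for name, sl in genome.marker_slices().items():
        c = genome.chromosome(name)
        out[:, sl] = _chromosome_gametes(
            haps[:, :, sl], genome.genetic_positions(name), c.length_cM, rng
        )
    return out


def simulate_gamete(diplotype: Diplotype, genome: GenomeSpec, rng_seed) -> np.ndarray:
    """Single meiotic product of a diplotype (per-marker origin codes)."""
    rng = _as_rng(rng_seed)
    return gametes(diplotype.haplotypes[None, :, :], genome, rng)[0]


def self_to_generation(
    founder: Diplotype, n_generations: int, genome: GenomeSpec, rng_seed
) -> Diplotype:
    """Diplotype of one F(1+n) individual after n rounds of self-fertilisation."""
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1 (the founder is the F1)")
    rng = _as_rng(rng_seed)
    haps = founder.haplotypes[None, :, :]
    for _ in range(n_generations):
        haps = np.stack([gametes(haps, genome, rng), gametes(haps, genome, rng)], axis=1)
    return Diplotype(haps[0])


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

@dataclass
class RilPopulation:
    """A set of RILs: phased genotypes plus per-animal phenotypes.

    ``haplotypes``: (n_lines, 2, n_markers) int8; ``phenotypes``:
    (n_lines, n_animals) float, clamped to the 0-27 scale; ``generation``
    is the filial generation of the genotyped individuals (5 = F5).
    """

    genome: GenomeSpec
    line_ids: list[str]
    haplotypes: np.ndarray
    phenotypes: np.ndarray | None = None
    generation: int = 5

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape[0] != len(self.line_ids):
            raise ValueError("one haplotype pair per line required")
        if self.phenotypes is not None:
            self.phenotypes = np.asarray(self.phenotypes, dtype=float)
            if self.phenotypes.ndim != 2 or self.phenotypes.shape[0] != len(self.line_ids):
                raise ValueError("phenotypes must be (n_lines, n_animals)")
            if self.phenotypes.shape[1] < 1:
                raise ValueError("each line needs >= 1 phenotype")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def dosage(self) -> np.ndarray:
        """(n_lines, n_markers) B-allele dosage in {0, 1, 2}."""
        return self.haplotypes.sum(axis=1)

    def line_means(self) -> np.ndarray:
        if self.phenotypes is None:
            raise ValueError("population has no phenotypes")
        return self.phenotypes.mean(axis=1)

    def heterozygosity(self) -> float:
        """Mean per-marker heterozygous fraction across lines."""
        return float(np.mean(self.dosage == 1))

    def b_allele_frequency(self) -> np.ndarray:
        """Per-marker JU1242 (B) allele frequency across lines."""
        return self.dosage.mean(axis=0) / 2.0


def assign_phenotypes(
    pop: RilPopulation, qtl: QtlModel, n_animals_per_line: int, rng_seed
) -> RilPopulation:
    """Draw per-animal phenotypes from the QTL model.

    The line's QTL genotype is read at the nearest marker at or left of
    the QTL position; each animal's value is the genotype mean plus
    Normal(0, residual_sd) noise, clamped to [0, 27].
    """
    if n_animals_per_line < 1:
        raise ValueError("n_animals_per_line must be >= 1")
    if qtl.chromosome not in pop.genome.chrom_names:
        raise ValueError(f"QTL chromosome {qtl.chromosome!r} absent from genome")
    rng = _as_rng(rng_seed)
    idx = pop.genome.marker_index(qtl.chromosome, qtl.position_bp)
    means = qtl.genotype_mean(pop.dosage[:, idx])
    values = means[:, None] + rng.normal(0.0, qtl.residual_sd, size=(pop.n_lines, n_animals_per_line))
    np.clip(values, PHENOTYPE_MIN, PHENOTYPE_MAX, out=values)
    return RilPopulation(pop.genome, pop.line_ids, pop.haplotypes, values, pop.generation)


def simulate_ril_population(
    genome: GenomeSpec,
    qtl: QtlModel | None,
    n_lines: int = 200,
    n_generations: int = 4,
    n_animals_per_line: int = 20,
    rng_seed=None,
) -> RilPopulation:
    """Simulate independent RILs from independent F1 selfing chains.

    n_generations counts selfing rounds from the F1 (4 -> F5 genotypes).
    Randomness is split per (generation, gamete) stage from one root
    SeedSequence so the run is reproducible and lines are exchangeable.
    When ``qtl`` is None the population carries no phenotypes.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    root = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
            else np.random.SeedSequence(rng_seed))
    stage_seeds = root.spawn(2 * n_generations + 1)
    m = genome.n_markers
    haps = np.empty((n_lines, 2, m), dtype=np.int8)
    haps[:, 0, :] = ALLELE_A
    haps[:, 1, :] = ALLELE_B
    for g in range(n_generations):
        g1 = gametes(haps, genome, np.random.default_rng(stage_seeds[2 * g]))
        g2 = gametes(haps, genome, np.random.default_rng(stage_seeds[2 * g + 1]))
        haps = np.stack([g1, g2], axis=1)
    ids = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    pop = RilPopulation(genome, ids, haps, None, generation=1 + n_generations)
    if qtl is not None:
        pop = assign_phenotypes(
            pop, qtl, n_animals_per_line, np.random.default_rng(stage_seeds[-1])
        )
    return pop


# ---------------------------------------------------------------------------
# introgression (near-isogenic) lines
# ---------------------------------------------------------------------------

def simulate_introgression_line(
    genome: GenomeSpec,
    donor_chromosome: str,
    donor_allele: int = ALLELE_B,
    residual_donor_rate: float = 0.0,
    rng_seed=None,
) -> Diplotype:
    """Idealised NIL: homozygous donor on one chromosome, recipient elsewhere.

    ``residual_donor_rate`` optionally leaves behind unlinked donor
    markers on the recipient background (per-marker probability), crudely
    emulating incomplete backcross cleanup.
    """
    if donor_chromosome not in genome.chrom_names:
        raise KeyError(f"unknown chromosome {donor_chromosome!r}")
    recipient = ALLELE_A if donor_allele == ALLELE_B else ALLELE_B
    haps = np.full((2, genome.n_markers), recipient, dtype=np.int8)
    sl = genome.marker_slices()[donor_chromosome]
    haps[:, sl] = donor_allele
    if residual_donor_rate > 0:
        rng = _as_rng(rng_seed)
        keep = rng.random(genome.n_markers) < residual_donor_rate
        keep[sl] = False
        haps[:, keep] = donor_allele
    return Diplotype(haps)


def predicted_line_mean(diplotype: Diplotype, qtl: QtlModel, genome: GenomeSpec) -> float:
    """Zero-noise expected phenotype of a line under the QTL model."""
    idx = genome.marker_index(qtl.chromosome, qtl.position_bp)
    return float(qtl.genotype_mean(diplotype.dosage[idx]))
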