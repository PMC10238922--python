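"""Genome and trait-model descriptions for a two-parent selfing cross.

The physical map (bp) carries marker and QTL coordinates; the genetic map
(cM) drives recombination. Within a chromosome the two maps are related
linearly (uniform recombination rate), which is adequate at the whole-
chromosome resolution this package works at.

Parental-origin coding throughout the package: allele ``A`` is the CB4932
(anterior-parent) allele and ``B`` the JU1242 (posterior-parent) allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: integer codes for parental origin of an allele
ALLELE_A = 0  # CB4932
ALLELE_B = 1  # JU1242


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: physical length in bp, genetic length in cM."""

    name: str
    length_bp: int
    length_cM: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"{self.name}: length_bp must be >= 1")
        if self.length_cM < 0:
            raise ValueError(f"{self.name}: genetic length must be >= 0")


@dataclass
class GenomeSpec:
    """Chromosomes plus per-chromosome sorted marker positions (1-based bp).

    Markers are the loci at which genotypes are simulated and at which
    pooled read counts are later generated (each marker is a segregating
    SNP between the two parents).
    """

    chromosomes: list[Chromosome]
    markers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for c in self.chromosomes:
            pos = np.asarray(self.markers.get(c.name, ()), dtype=np.int64)
            if pos.size == 0:
                raise ValueError(f"{c.name}: empty marker list")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{c.name}: marker positions must be strictly increasing")
            if pos[0] < 1 or pos[-1] > c.length_bp:
                raise ValueError(f"{c.name}: marker positions outside [1, length_bp]")
            self.markers[c.name] = pos

    # -- indexing helpers ------------------------------------------------

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    @property
    def n_markers(self) -> int:
        return sum(len(self.markers[c.name]) for c in self.chromosomes)

    def marker_slices(self) -> dict[str, slice]:
        """Slice of the concatenated marker axis belonging to each chromosome."""
        out, start = {}, 0
        for c in self.chromosomes:
            n = len(self.markers[c.name])
            out[c.name] = slice(start, start + n)
            start += n
        return out

    def marker_table(self):
        """(chrom, pos) arrays over the concatenated marker axis."""
        chroms = np.concatenate(
            [np.repeat(c.name, len(self.markers[c.name])) for c in self.chromosomes]
        )
        pos = np.concatenate([self.markers[c.name] for c in self.chromosomes])
        return chroms, pos

    def genetic_positions(self, name: str) -> np.ndarray:
        """Marker positions on the genetic map (cM), linear in bp."""
        c = self.chromosome(name)
        return self.markers[name] * (c.length_cM / c.length_bp)

    def marker_index(self, chrom: str, position_bp: int) -> int:
        """Concatenated-axis index of the nearest marker at or left of a position.

        Falls back to the chromosome's first marker when the position lies
        before it.
        """
        pos = self.markers[self.chromosome(chrom).name]
        local = int(np.searchsorted(pos, position_bp, side="right")) - 1
        local = max(local, 0)
        return self.marker_slices()[chrom].start + local


# C. elegans chromosome scale; 50 cM genetic length apiece is the standard
# map length for this species.
_CELEGANS = [
    ("I", 15_100_000),
    ("II", 15_300_000),
    ("III", 13_800_000),
    ("IV", 17_500_000),
    ("V", 20_900_000),
    ("X", 17_700_000),
]


def default_genome(marker_spacing_bp: int = 10_000, length_cM: float = 50.0) -> GenomeSpec:
    """Six-chromosome genome at C. elegans physical scale, evenly spaced markers."""
    chroms = [Chromosome(n, l, length_cM) for n, l in _CELEGANS]
    markers = {
        c.name: np.arange(marker_spacing_bp, c.length_bp + 1, marker_spacing_bp, dtype=np.int64)
        for c in chroms
    }
    return GenomeSpec(chroms, markers)


@dataclass
class QtlModel:
    """Single additive-with-dominance QTL on the 0-27 V-cell position scale.

    ``dominance_h`` places the heterozygote between the homozygote means:
    phenotype(AB) = mean_AA + h * (mean_BB - mean_AA). h=0 means the A
    (CB4932) allele is fully dominant, h=1 the B (JU1242) allele.
    """

    chromosome: str = "IV"
    position_bp: int = 5_200_000
    mean_AA: float = 4.16
    mean_BB: float = 5.54
    dominance_h: float = 0.85
    residual_sd: float = 0.6

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if not 0.0 <= self.dominance_h <= 1.0:
            raise ValueError("dominance_h must lie in [0, 1]")

    def genotype_mean(self, dosage) -> np.ndarray:
        """Expected phenotype for a B-allele dosage in {0, 1, 2}."""
        d = np.asarray(dosage)
        w = np.where(d == 2, 1.0, np.where(d == 1, self.dominance_h, 0.0))
        return self.mean_AA + w * (self.mean_BB - self.mean_AA)
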