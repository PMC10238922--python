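import numpy as np
import pytest
from scipy.stats import gaussian_kde

from bsamap import (
    ALLELE_A,
    ALLELE_B,
    Diplotype,
    QtlModel,
    RilPopulation,
    assign_phenotypes,
    predicted_line_mean,
    self_to_generation,
    simulate_gamete,
    simulate_introgression_line,
    simulate_ril_population,
)
from conftest import two_marker_genome
from oracles import haldane_d, haldane_r, selfing_ril_recombinant_fraction


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def test_zero_genetic_length_gives_intact_parental_haplotypes():
    g = two_marker_genome(0.0)
    f1 = Diplotype.f1(g)
    rng = np.random.default_rng(0)
    picks = []
    for _ in range(2000):
        gam = simulate_gamete(f1, g, rng)
        assert gam[0] == gam[1]  # no recombination possible
        picks.append(gam[0])
    frac_b = np.mean(picks)
    assert abs(frac_b - 0.5) < 3 * np.sqrt(0.25 / 2000)


def test_homozygous_diplotype_yields_identical_gamete():
    g = two_marker_genome(30.0)
    hom = Diplotype.homozygous(g, ALLELE_A)
    for seed in range(5):
        assert np.all(simulate_gamete(hom, g, seed) == ALLELE_A)


@pytest.mark.parametrize("d_cM", [5.0, 20.0, 50.0])
def test_gamete_recombinant_fraction_matches_haldane(d_cM):
    """Recombination between two markers follows the Haldane map function."""
    g = two_marker_genome(d_cM)
    f1 = Diplotype.f1(g)
    rng = np.random.default_rng(42)
    n = 10_000
    rec = sum(gam[0] != gam[1] for gam in (simulate_gamete(f1, g, rng) for _ in range(n)))
    expected = haldane_r(d_cM)
    assert abs(rec / n - expected) < 3 * np.sqrt(expected * (1 - expected) / n)


# ---------------------------------------------------------------------------
# selfing
# ---------------------------------------------------------------------------

def test_selfing_requires_at_least_one_generation():
    g = two_marker_genome(10.0)
    with pytest.raises(ValueError):
        self_to_generation(Diplotype.f1(g), 0, g, 0)


def test_heterozygosity_halves_each_selfing_generation(study_genome):
    # exact recursion: E[het] after n selfings is (1/2)^n
    for n_gen, n_lines in ((1, 1000), (4, 1000)):
        pop = simulate_ril_population(
            study_genome, None, n_lines=n_lines, n_generations=n_gen, rng_seed=7
        )
        expected = 0.5**n_gen
        se = np.sqrt(expected * (1 - expected) / n_lines)
        assert abs(pop.heterozygosity() - expected) < 3 * se


def test_ril_map_expansion_haldane_waddington():
    """Homozygous-RIL recombinant fraction approaches 2r/(1+2r)."""
    r = 0.2
    g = two_marker_genome(haldane_d(r))
    pop = simulate_ril_population(g, None, n_lines=4000, n_generations=15, rng_seed=3)
    dos = pop.dosage
    hom = (dos[:, 0] != 1) & (dos[:, 1] != 1)
    rec = np.mean(dos[hom, 0] != dos[hom, 1])
    expected = selfing_ril_recombinant_fraction(r)
    se = np.sqrt(expected * (1 - expected) / hom.sum())
    assert abs(rec - expected) < 3 * se


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _single_line_pop(genome, dosage_code):
    hap0 = np.full(genome.n_markers, 1 if dosage_code == 2 else 0, dtype=np.int8)
    hap1 = np.full(genome.n_markers, 1 if dosage_code >= 1 else 0, dtype=np.int8)
    return RilPopulation(genome, ["L1"], np.stack([hap0, hap1])[None])


@pytest.mark.parametrize(
    "dosage,expected", [(0, 4.16), (2, 5.54)]
)
def test_parental_genotype_means_in_low_noise_limit(dosage, expected):
    g = two_marker_genome(10.0)
    qtl = QtlModel(chromosome="chr1", position_bp=1, residual_sd=1e-9)
    pop = assign_phenotypes(_single_line_pop(g, dosage), qtl, 50, rng_seed=0)
    assert pop.line_means()[0] == pytest.approx(expected, abs=1e-6)


def test_complete_dominance_heterozygote_matches_bb_mean():
    g = two_marker_genome(10.0)
    qtl = QtlModel(chromosome="chr1", position_bp=1, dominance_h=1.0, residual_sd=1e-9)
    pop = assign_phenotypes(_single_line_pop(g, 1), qtl, 10, rng_seed=0)
    assert pop.line_means()[0] == pytest.approx(5.54, abs=1e-6)


def test_phenotype_preconditions():
    g = two_marker_genome(10.0)
    pop = _single_line_pop(g, 0)
    with pytest.raises(ValueError):
        assign_phenotypes(pop, QtlModel(chromosome="chr1", position_bp=1), 0, 0)
    with pytest.raises(ValueError, match="absent"):
        assign_phenotypes(pop, QtlModel(chromosome="IV"), 10, 0)


def test_phenotypes_clamped_to_v_cell_scale():
    g = two_marker_genome(10.0)
    qtl = QtlModel(chromosome="chr1", position_bp=1, mean_AA=0.5, mean_BB=26.5,
                   residual_sd=5.0)
    pop = assign_phenotypes(_single_line_pop(g, 0), qtl, 500, rng_seed=1)
    assert pop.phenotypes.min() >= 0.0 and pop.phenotypes.max() <= 27.0


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def test_same_seed_gives_bit_identical_population(study_genome, paper_qtl):
    a = simulate_ril_population(study_genome, paper_qtl, 50, rng_seed=11)
    b = simulate_ril_population(study_genome, paper_qtl, 50, rng_seed=11)
    assert np.array_equal(a.haplotypes, b.haplotypes)
    assert np.array_equal(a.phenotypes, b.phenotypes)
    c = simulate_ril_population(study_genome, paper_qtl, 50, rng_seed=12)
    assert not np.array_equal(a.haplotypes, c.haplotypes)


def test_neutral_b_allele_frequency_near_half(study_genome):
    pop = simulate_ril_population(study_genome, None, n_lines=1000, rng_seed=5)
    freqs = pop.b_allele_frequency()
    se = np.sqrt(0.25 / 1000)
    assert abs(freqs.mean() - 0.5) < 3 * se
    assert np.all(np.abs(freqs - 0.5) < 5 * se)  # every marker, wide band


def test_line_mean_distribution_is_bimodal_at_parental_means(study_genome, paper_qtl):
    pop = simulate_ril_population(study_genome, paper_qtl, 200, rng_seed=2)
    kde = gaussian_kde(pop.line_means())
    grid = np.linspace(3.0, 7.0, 400)
    dens = kde(grid)
    peaks = grid[1:-1][(dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])]
    assert any(abs(p - 4.16) < 0.3 for p in peaks)
    assert any(abs(p - 5.54) < 0.3 for p in peaks)


def test_qtl_effect_recovery_from_line_means(study_genome, paper_qtl):
    """Grouping line means by QTL genotype recovers the genotype means."""
    pop = simulate_ril_population(study_genome, paper_qtl, 200, rng_seed=9)
    idx = study_genome.marker_index(paper_qtl.chromosome, paper_qtl.position_bp)
    dos = pop.dosage[:, idx]
    means = pop.line_means()
    for d, expected in ((0, 4.16), (2, 5.54), (1, 4.16 + 0.85 * (5.54 - 4.16))):
        if np.any(dos == d):
            group = means[dos == d]
            tol = 3 * paper_qtl.residual_sd / np.sqrt(20 * group.size) + 0.02
            assert abs(group.mean() - expected) < tol


# ---------------------------------------------------------------------------
# introgression lines
# ---------------------------------------------------------------------------

def test_nil_predicted_means_match_parental_phenotypes(study_genome, paper_qtl):
    # JU1242 chrIV in CB4932 background: posterior phenotype
    nil = simulate_introgression_line(study_genome, "IV", donor_allele=ALLELE_B)
    assert predicted_line_mean(nil, paper_qtl, study_genome) == pytest.approx(5.54)
    # reciprocal swap recapitulates the anterior CB4932 phenotype
    rev = simulate_introgression_line(study_genome, "IV", donor_allele=ALLELE_A)
    assert predicted_line_mean(rev, paper_qtl, study_genome) == pytest.approx(4.16)
    # swapping a chromosome without the QTL leaves the recipient phenotype
    other = simulate_introgression_line(study_genome, "II", donor_allele=ALLELE_B)
    assert predicted_line_mean(other, paper_qtl, study_genome) == pytest.approx(4.16)
    with pytest.raises(KeyError):
        simulate_introgression_line(study_genome, "chr7")
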