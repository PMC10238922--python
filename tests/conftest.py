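import numpy as np
import pytest

from bsamap import Chromosome, GenomeSpec, QtlModel, default_genome


@pytest.fixture(scope="session")
def study_genome() -> GenomeSpec:
    """Six C. elegans-scale chromosomes, ~2,000 markers (1 per 50 kb)."""
    return default_genome(marker_spacing_bp=50_000)


@pytest.fixture(scope="session")
def paper_qtl() -> QtlModel:
    """The calibrated QTL: parental means 4.16 / 5.54, h = 0.85, sd 0.6."""
    return QtlModel()


def two_marker_genome(d_cM: float, length_cM: float | None = None) -> GenomeSpec:
    """One chromosome with two markers separated by d_cM on the genetic map."""
    total = length_cM if length_cM is not None else d_cM
    length_bp = 1_000_000
    if total > 0:
        p2 = int(round(length_bp * d_cM / total))
    else:
        p2 = length_bp // 2
    markers = {"chr1": np.array([1, max(p2, 2)], dtype=np.int64)}
    return GenomeSpec([Chromosome("chr1", length_bp, total)], markers)
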