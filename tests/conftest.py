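import numpy as np
import pytest

from chromoscene import make_structure


def random_structure(rng, n_chroms=2, bins_per_chrom=50, resolution=100, id="rand"):
    """Random multi-chromosome structure with gaussian coordinates."""
    n = n_chroms * bins_per_chrom
    chroms = np.repeat([f"chr{i+1}" for i in range(n_chroms)], bins_per_chrom)
    start = np.tile(np.arange(bins_per_chrom) * resolution, n_chroms)
    return make_structure(
        rng.normal(size=(n, 3)),
        genomic={"chrom": chroms, "start": start, "end": start + resolution},
        id=id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def chr1_structure():
    """5 uniform 100-bp bins on chr1 with simple coordinates."""
    start = np.arange(5) * 100
    return make_structure(
        np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)]),
        genomic={"chrom": ["chr1"] * 5, "start": start, "end": start + 100},
        id="chr1_demo",
    )
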