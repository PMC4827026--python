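import numpy as np
import pandas as pd
import pytest

from histcoloc import BinGrid, GenomeLayout, ReadSet, si_track
from histcoloc.genomic_io import make_gene_table
from histcoloc.synthetic_data import SimulationConfig, simulate


@pytest.fixture
def tiny_layout():
    return GenomeLayout(("chr1", "chr2"), (10_000, 8_000))


@pytest.fixture
def tiny_grid(tiny_layout):
    return BinGrid(tiny_layout, 1000)


@pytest.fixture
def toy_genes():
    # one + and one - strand gene per chromosome
    return make_gene_table(
        ["gA", "gB", "gC", "gD"],
        ["chr1", "chr1", "chr2", "chr2"],
        [2000, 6000, 1000, 5000],
        [4000, 9000, 3000, 7000],
        ["+", "-", "+", "-"],
    )


@pytest.fixture(scope="session")
def small_sim():
    """Scaled-down synthetic dataset shared by module tests."""
    cfg = SimulationConfig(
        seed=11, n_chroms=2, chrom_length=400_000, n_genes=80,
        gene_length_range=(2000, 6000), n_reads_chip=120_000,
        n_reads_input=120_000, n_sites=200,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def full_sim():
    """The study-scale dataset: 2 x 5 Mb, 1000 genes, 1e6 + 1e6 reads."""
    return simulate(SimulationConfig(seed=20160418))


@pytest.fixture(scope="session")
def full_si_200(full_sim):
    grid = BinGrid(full_sim.layout, 200)
    return si_track(full_sim.chip_reads, full_sim.input_reads, grid)


def uniform_reads(layout, n, seed=0):
    """ReadSet of n uniform 5' positions over the layout."""
    rng = np.random.default_rng(seed)
    lens = np.asarray(layout.chrom_lengths, np.int64)
    flat = rng.integers(0, lens.sum(), size=n)
    bounds = np.concatenate(([0], np.cumsum(lens)))
    ci = np.searchsorted(bounds, flat, "right") - 1
    chroms = np.asarray(layout.chrom_names, dtype=object)[ci]
    return ReadSet.from_records(chroms, flat - bounds[ci])
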