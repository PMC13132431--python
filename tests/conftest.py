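import numpy as np
import pandas as pd
import pytest

from cobind.binning import GenomeLayout, PeakSet, tile_genome
from cobind.simulate import Scenario, simulate


@pytest.fixture
def toy_layout():
    return GenomeLayout({"chr1": 10_000, "chr2": 5_000})


@pytest.fixture
def toy_index(toy_layout):
    return tile_genome(toy_layout, 300)


def make_peakset(name, rows):
    """rows: (chrom, start, end, score) tuples."""
    return PeakSet(
        name,
        pd.DataFrame(rows, columns=["chrom", "start", "end", "score"]),
    )


@pytest.fixture
def occupancy_small():
    """Hand-built occupancy matrix over the 11 default tracks."""
    tracks = [
        "TRB1", "TRB2", "TRB3", "UBP5", "EPCR1", "PWWP1",
        "HAM1", "EPL1B", "CLF", "SWN", "JMJ14",
    ]
    rng = np.random.default_rng(42)
    mat = rng.integers(0, 11, size=(60, len(tracks)))
    mat[mat < 6] = 0  # plenty of unbound entries
    df = pd.DataFrame(mat, columns=tracks)
    df.index.name = "bin_id"
    return df


@pytest.fixture(scope="session")
def small_scenario():
    """Scaled-down study: one 300-kb chromosome, fewer genes, fast to simulate."""
    return Scenario(
        seed=7,
        chrom_lengths={"chr1": 300_000},
        n_target_bins={"PEAT": 80, "NuA4": 60, "PRC2": 70, "JMJ14": 60},
        n_genes=400,
        n_deg=150,
        n_terms=50,
    )


@pytest.fixture(scope="session")
def small_sim(small_scenario):
    return simulate(small_scenario)
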