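import numpy as np
import pytest

from issrpop import BandMatrix, SimulationConfig, simulate_dataset


def make_matrix(data, pops=None, primer=None):
    """Build a BandMatrix from a plain array with generated labels.

    ``pops`` maps individual index -> population label (default: all "A").
    ``primer`` maps locus index -> primer name (default: all "P1").
    """
    data = np.asarray(data, dtype=float)
    n, L = data.shape
    ids = [f"i{k + 1}" for k in range(n)]
    loci = [f"L{j + 1}" for j in range(L)]
    population_of = {ids[k]: (pops[k] if pops else "A") for k in range(n)}
    primer_of = {loci[j]: (primer[j] if primer else "P1") for j in range(L)}
    return BandMatrix(data, ids, loci, primer_of, population_of)


@pytest.fixture
def tiny_matrix():
    return make_matrix([[1, 0], [0, 1]], pops=["A", "B"])


@pytest.fixture(scope="session")
def study_sim():
    """Study-scale synthetic panel: 11 pops x 4, ~510 loci, K=3,
    F = (0.19, 0.37, 0.40)."""
    return simulate_dataset(SimulationConfig(seed=7))
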