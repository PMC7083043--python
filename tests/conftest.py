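import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from snpdiag.panel import GenotypeMatrix, SpeciesPanel
from snpdiag.simulate import Replicon, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_species_config():
    """Tiny noiseless two-species panel for exact truth-recovery checks."""
    return SimulationConfig(
        seed=11,
        species_tree="(A:0.05,B:0.05);",
        accessions_per_species={"A": 2, "B": 2},
        within_species_diversity={"A": 0.002, "B": 0.0},
        replicons=[Replicon("chr1", 4000)],
        mean_depth=30.0,
        depth_dispersion=0.0,
        dropout_rate=0.0,
        error_rate=0.0,
    )


def random_matrix(rng, n_accessions=8, n_sites=300, n_species=3, seed_alleles=None):
    """Random genotype matrix + matching panel for classification tests."""
    accs = [f"acc{i:02d}" for i in range(n_accessions)]
    species = {a: f"sp{i % n_species}" for i, a in enumerate(accs)}
    alleles = rng.integers(0, 4, size=(n_sites, n_accessions), dtype=np.uint8)
    sites = [("chr1", i + 1, "A") for i in range(n_sites)]
    matrix = GenotypeMatrix(sites, alleles, accs)
    panel = SpeciesPanel(accs, species)
    return matrix, panel
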