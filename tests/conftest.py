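import numpy as np
import pytest

from cypred.chemio import standardize_structure
from cypred.featurize import build_dual_graph
from cypred.synthetic import GeneratorConfig, generate_molecules, plant_labels


@pytest.fixture(scope="session")
def small_molecules():
    """A small fixed molecule panel covering rings, fused rings, heteroatoms."""
    smiles = [
        "CCO", "CCCO", "c1ccccc1", "c1ccncc1", "CCN", "c1cc[nH]c1",
        "C1CCNCC1", "CC(=O)O", "c1ccc2c(c1)OCO2", "CCCC",
        "c1ccc2[nH]ccc2c1", "c1cnccn1", "Cc1ccccc1", "OCc1ccncc1",
    ]
    return [standardize_structure(s) for s in smiles]


@pytest.fixture(scope="session")
def small_graphs(small_molecules):
    return [build_dual_graph(m) for m in small_molecules]


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Seeded 150-molecule synthetic set with planted labels (noise 5)."""
    cfg = GeneratorConfig(n_molecules=150, noise_sd=5.0, seed=11)
    mols = generate_molecules(cfg)
    truth = plant_labels(mols, cfg)
    return cfg, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
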