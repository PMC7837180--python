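import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from phylocore import PipelineConfig, SimConfig, simulate_dataset
from phylocore.orthology import ScoringScheme


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme.blosum62()


@pytest.fixture(scope="session")
def small_simulation():
    """A 6-strain simulated dataset with decoys, shared across tests."""
    cfg = SimConfig(n_taxa=6, n_core_genes=8, gene_length=120,
                    n_decoy_genes=3, tree_depth=0.25, seed=11)
    proteomes, truth = simulate_dataset(cfg)
    return cfg, proteomes, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(1234))
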