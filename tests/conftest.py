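import numpy as np
import pandas as pd
import pytest

from stpls import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_cfg():
    return sd.SimulationConfig(n=36, p=120, block_size=10, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """A small simulated genotype matrix with a planted sparse phenotype."""
    X = sd.simulate_genotype_matrix(small_cfg)
    y, truth = sd.simulate_phenotypes(X, small_cfg)
    return X, y, truth


@pytest.fixture
def tiny_scores():
    scores = pd.DataFrame(
        {
            "genome_id": ["g1", "g1", "g2", "g2", "g3"],
            "gene_id": ["A", "B", "A", "B", "A"],
            "score": [300.0, 30.0, 150.0, 40.0, 75.0],
        }
    )
    refs = pd.DataFrame(
        {"self_score": [300, 100]}, index=pd.Index(["A", "B"], name="gene_id")
    )
    return scores, refs
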