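import warnings

import numpy as np
import pandas as pd
import pytest

from phytodiv.occurrence import FeatureTable
from phytodiv.spectra import CompoundSimilarityMatrix
from phytodiv.synthetic import SyntheticConfig, generate_dataset

warnings.filterwarnings("ignore", message=".*boundary fit.*")


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Reduced design: 4 species x 3 plants x 4 organs, 77 compounds."""
    return SyntheticConfig(
        n_species=4, n_plants_per_species=3, n_core_compounds=60,
        n_fruit_specific=10, n_leaf_specific=4,
        n_species_specific_per_species=2, n_structural_classes=6, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_table(small_dataset) -> FeatureTable:
    return small_dataset[0]


@pytest.fixture(scope="session")
def small_library(small_dataset):
    return small_dataset[1]


@pytest.fixture(scope="session")
def small_truth(small_dataset):
    return small_dataset[2]


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Deterministic limit: every pool fully expressed, no bit-flip noise."""
    cfg = SyntheticConfig(
        n_species=3, n_plants_per_species=2, n_core_compounds=30,
        n_fruit_specific=8, n_leaf_specific=3,
        n_species_specific_per_species=2, p_core_present=1.0,
        organ_effect=1.0, noise_rate=0.0, n_structural_classes=4, seed=5)
    return cfg, *generate_dataset(cfg)


def random_binary_table(rng: np.random.Generator, n_samples: int = 8,
                        n_compounds: int = 12) -> FeatureTable:
    """Random valid binary table (every sample keeps >= 1 compound)."""
    pres = rng.integers(0, 2, size=(n_samples, n_compounds))
    for i in range(n_samples):
        if pres[i].sum() == 0:
            pres[i, rng.integers(n_compounds)] = 1
    sample_ids = [f"s{i:02d}" for i in range(n_samples)]
    organs = ["leaf", "seed", "unripe_pulp", "ripe_pulp"]
    meta = pd.DataFrame({
        "species": [f"sp{i % 2}" for i in range(n_samples)],
        "plant": [f"sp{i % 2}_p{i // 2}" for i in range(n_samples)],
        "organ": [organs[i % 4] for i in range(n_samples)],
    }, index=sample_ids)
    presence = pd.DataFrame(pres, index=sample_ids,
                            columns=[f"c{j:02d}" for j in range(n_compounds)])
    return FeatureTable(presence=presence, metadata=meta)


def random_epsilon(rng: np.random.Generator, compound_ids) -> CompoundSimilarityMatrix:
    n = len(compound_ids)
    a = rng.random((n, n))
    eps = (a + a.T) / 2.0
    np.fill_diagonal(eps, 1.0)
    return CompoundSimilarityMatrix(compound_ids=list(compound_ids), epsilon=eps)
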