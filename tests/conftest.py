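import numpy as np
import pytest

import pigatlas as pa


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def five_cluster_config(seed: int = 0, noise_sd_log2: float = 0.25) -> pa.AtlasSimConfig:
    """The recovery study conditions: 8 tissues x 2 replicates, five
    50-gene tissue-specific clusters at 16-fold, 100 unique-profile genes."""
    clusters = tuple(
        pa.PlantedCluster(50, "tissue_specific", (t,), 16.0) for t in range(5)
    )
    return pa.AtlasSimConfig(
        n_tissues=8,
        replicates_per_tissue=2,
        planted_clusters=clusters,
        noise_sd_log2=noise_sd_log2,
        n_unique_genes=100,
        seed=seed,
    )


@pytest.fixture
def small_atlas():
    matrix, meta, truth = pa.generate_atlas(five_cluster_config(seed=7))
    return matrix, meta, truth


def random_matrix(rng, n_genes: int, n_samples: int, prefix: str = "g") -> pa.ExpressionMatrix:
    values = rng.lognormal(mean=4.0, sigma=1.0, size=(n_genes, n_samples))
    return pa.ExpressionMatrix(
        [f"{prefix}{i:04d}" for i in range(n_genes)],
        [f"s{j:02d}" for j in range(n_samples)],
        values,
    )
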