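import numpy as np
import pytest

from bsp.core import Dataset, ExpressionMatrix, SpotCoordinates
from bsp.sim3d import Sim3DConfig, simulate_dataset_3d


@pytest.fixture
def collinear_coords():
    """Three collinear spots at x = 0, 1, 2, flagged rescaled for direct use."""
    return SpotCoordinates(
        spot_ids=np.array(["a", "b", "c"], dtype=object),
        positions=np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
        is_rescaled=True,
    )


@pytest.fixture
def collinear_gene():
    """One gene with values (0, 1, 0) over the collinear spots, pre-normalized."""
    return ExpressionMatrix(
        gene_ids=np.array(["g"], dtype=object),
        spot_ids=np.array(["a", "b", "c"], dtype=object),
        values=np.array([[0.0, 1.0, 0.0]]),
        normalization_state="minmax",
    )


def random_dataset(n_genes: int, n_spots: int, seed: int, d: int = 2) -> Dataset:
    """Unstructured random dataset for invariance checks."""
    rng = np.random.default_rng(seed)
    coords = SpotCoordinates(
        spot_ids=np.array([f"s{i}" for i in range(n_spots)], dtype=object),
        positions=rng.uniform(0, 10, size=(n_spots, d)),
    )
    expr = ExpressionMatrix(
        gene_ids=np.array([f"g{j}" for j in range(n_genes)], dtype=object),
        spot_ids=coords.spot_ids,
        values=rng.gamma(2.0, 1.0, size=(n_genes, n_spots)),
    )
    return Dataset(expression=expr, coordinates=coords)


@pytest.fixture(scope="session")
def sim3d_moderate():
    """Scaled 3D replicate at moderate settings, shared across tests."""
    config = Sim3DConfig(n_svg=100, nulls_per_svg=9, noise_tau=1.0, seed=3)
    return simulate_dataset_3d(config)
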