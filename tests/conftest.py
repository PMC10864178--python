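import numpy as np
import pytest
import scipy.sparse as sp

from sevdrop.io_droplets import DropletMatrix, DropletPartition
from sevdrop.simulator import (
    ReferenceProfiles,
    SimulationConfig,
    make_reference_profiles,
    simulate_droplets,
)


def all_candidate_partition(m: DropletMatrix) -> DropletPartition:
    """Treat every droplet of a simulated sample as a candidate cell-free one."""
    return DropletPartition(cell_droplets=[], candidate_free_droplets=list(m.barcodes))


def random_droplet_matrix(
    n_droplets: int = 30, n_genes: int = 20, density: float = 0.2, seed: int = 0
) -> DropletMatrix:
    rng = np.random.default_rng(seed)
    counts = sp.random(
        n_droplets,
        n_genes,
        density=density,
        random_state=np.random.RandomState(seed),
        data_rvs=lambda k: rng.integers(1, 9, size=k),
    )
    return DropletMatrix(
        sp.csr_matrix(counts),
        [f"BC{i:04d}" for i in range(n_droplets)],
        [f"G{i:04d}" for i in range(n_genes)],
        f"rand{seed}",
    )


@pytest.fixture(scope="session")
def small_ref() -> ReferenceProfiles:
    return make_reference_profiles(n_genes=400, n_signature=60, fold_up=4.0, seed=3)


@pytest.fixture(scope="session")
def small_sim(small_ref):
    cfg = SimulationConfig(
        umi_lambda=100.0, dropout=0.3, n_droplets=600, sev_fraction=0.25, seed=9
    )
    return simulate_droplets(cfg, small_ref, sample_id="small")
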