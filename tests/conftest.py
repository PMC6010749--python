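import numpy as np
import pytest

import phylobeta as pb


@pytest.fixture
def quartet():
    return pb.parse_newick("((A,B),(C,D));")


@pytest.fixture
def quick_mcmc():
    """Short two-chain schedule for structural tests."""
    return pb.McmcConfig(n_chains=2, burn_in=150, kept_per_chain=150, thin=1, seed=11)


@pytest.fixture(scope="session")
def small_truth():
    """One moderate synthetic dataset shared across tests: 10 taxa, 60 sites."""
    cfg = pb.SimConfig(n_taxa=10, n_sites=60, seed=42)
    return pb.simulate_dataset(cfg)


def random_topology(n_leaves: int, seed: int) -> pb.Topology:
    return pb.simulate_tree(n_leaves, seed)


def tiny_data(seed: int = 0, n_sites: int = 12, n_taxa: int = 3) -> pb.OccurrenceData:
    rng = np.random.default_rng(seed)
    occ = rng.integers(0, 2, size=(n_sites, n_taxa))
    occ[0, :] = 1  # keep every taxon observed
    return pb.OccurrenceData(
        occ,
        rng.normal(size=n_sites),
        taxon_ids=[chr(ord("A") + j) for j in range(n_taxa)],
    )
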