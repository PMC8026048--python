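import numpy as np
import pytest

from spacerlaw.distributions import DistributionSpec, sample


@pytest.fixture(scope="session")
def tpl_spec():
    """The pooled-data law: truncated power law alpha=2.57, lambda=0.004."""
    return DistributionSpec("truncated_powerlaw", {"alpha": 2.57, "lam": 0.004})


@pytest.fixture(scope="session")
def tpl_sample_large(tpl_spec):
    """10^5 iid draws from the pooled-data law (fixed seed)."""
    return sample(tpl_spec, 100_000, seed=42)


@pytest.fixture
def small_dataset():
    from spacerlaw.data_io import SpacerCountDataset
    return SpacerCountDataset.from_records([
        ("MG000001", "Marine", "arr000001", 3),
        ("MG000001", "Marine", "arr000002", 12),
        ("MG000002", "Fresh Water", "arr000001", 7),
    ], provenance="fixture")
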