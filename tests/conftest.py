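import numpy as np
import pandas as pd
import pytest

import glioedit as g


@pytest.fixture(scope="session")
def small_config():
    return g.SimulationConfig(
        n_sites=80,
        n_samples_per_subtype=(20, 20, 20),
        n_discriminative_idh=8,
        n_discriminative_codel=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Catalog, cohort (with survival), counts, truth for a 80x60 cohort."""
    return g.simulate_dataset(small_config)


@pytest.fixture()
def toy_counts():
    """3-site x 4-sample tensor with hand-checkable values."""
    sites = ["chr1:100", "chr1:200", "chr2:50"]
    samples = ["s1", "s2", "s3", "s4"]
    edited = pd.DataFrame(
        [[5, 0, 3, 2], [0, 0, 0, 0], [10, 4, 0, 1]],
        index=sites, columns=samples)
    total = pd.DataFrame(
        [[10, 10, 12, 4], [0, 20, 15, 9], [20, 40, 11, 2]],
        index=sites, columns=samples)
    return g.CountTensor(edited, total)
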