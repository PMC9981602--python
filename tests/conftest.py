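import numpy as np
import pandas as pd
import pytest

from parastage import (
    DesignConfig,
    HostDevelopmentParams,
    estimate_stage_distribution,
    generate_exposure_dataset,
    generate_reference_table,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20230302)


@pytest.fixture(scope="session")
def exchangeable_params():
    """Host development with no seed-quality effect (treatments exchangeable)."""
    return HostDevelopmentParams.exchangeable()


@pytest.fixture(scope="session")
def exchangeable_table(exchangeable_params):
    """Stage distribution table estimated from a large exchangeable reference."""
    r = np.random.default_rng(7_000_001)
    ref = generate_reference_table(exchangeable_params, 200, r)
    return estimate_stage_distribution(ref)


@pytest.fixture(scope="session")
def small_dataset(exchangeable_params):
    """A 12-replicate exchangeable exposure table (2016 hosts)."""
    cfg = DesignConfig(n_replicates=12, seed=424242)
    return generate_exposure_dataset(cfg, dev_params=exchangeable_params)


@pytest.fixture(scope="session")
def usable_dataset(small_dataset):
    """Rows that reach the analysis: alive hosts still inside their seed."""
    df = small_dataset
    return df[~df["host_died"].astype(bool) & ~df["host_emerged"].astype(bool)].reset_index(
        drop=True
    )


def make_exposure_frame(time, event, group, stage="L4"):
    """Hand-build a minimal staged exposure frame for hazard tests."""
    n = len(time)
    return pd.DataFrame(
        {
            "host_id": [f"h{i}" for i in range(n)],
            "replicate": 1,
            "quality": group,
            "age_at_exposure": time,
            "host_died": False,
            "host_emerged": False,
            "parasitized": np.asarray(event, bool),
            "stage_at_parasitism": stage,
            "n_eggs": 1,
        }
    )
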