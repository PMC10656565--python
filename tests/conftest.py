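import numpy as np
import pytest

from uavpheno.pipeline import extract_feature_table
from uavpheno.synthetic_field import (
    DetectorParams,
    FieldConfig,
    WeightModelParams,
    generate_field,
)


@pytest.fixture(scope="session")
def small_config():
    return FieldConfig(
        n_rows=4, n_cols=4, timepoints_dat=(12, 40, 54, 80, 101), seed=7
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_field(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """Default study conditions: 10x10 plants, 8 flights, 5% detector misses."""
    return generate_field(FieldConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Same field with detector misses, jitter and weight noise switched off."""
    return generate_field(
        FieldConfig(
            seed=11,
            detector=DetectorParams(miss_rate=0.0, jitter_sd_m=0.0),
            weight_model=WeightModelParams(noise_sd=0.0),
        )
    )


@pytest.fixture(scope="session")
def default_pipeline(default_bundle):
    return extract_feature_table(default_bundle, seed=0)


@pytest.fixture(scope="session")
def noiseless_pipeline(noiseless_bundle):
    return extract_feature_table(noiseless_bundle, seed=0)
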