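import numpy as np
import pytest

from cenchrom import ArraySpec, PlantedDomain, ReadModel, generate_methylation_track


@pytest.fixture(scope="session")
def lcl_spec():
    return ArraySpec(length_bp=1_000_000)


@pytest.fixture(scope="session")
def planted_domains():
    # three LCL-like dips: 60% baseline down to ~20%
    return [
        PlantedDomain(150_000, 180_000, dip_depth_pct=40.0),
        PlantedDomain(300_000, 322_000, dip_depth_pct=40.0),
        PlantedDomain(430_000, 470_000, dip_depth_pct=40.0),
    ]


@pytest.fixture(scope="session")
def lcl_track(lcl_spec, planted_domains):
    return generate_methylation_track(lcl_spec, planted_domains, seed=11)


@pytest.fixture(scope="session")
def read_model():
    return ReadModel()
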