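import numpy as np
import pytest

from homingdrive import DriveParams, FitnessModel, FitnessSpec


@pytest.fixture
def measured_params() -> DriveParams:
    """Measured drive rates (sex-averaged conversion 76.7%, germline
    resistance 22.2%, embryo cut 52.2%, off-target cut rate 1)."""
    return DriveParams()


@pytest.fixture
def neutral() -> FitnessSpec:
    return FitnessSpec()


@pytest.fixture
def viability_cost() -> FitnessSpec:
    """The cage-fitted viability model (drive homozygote viability 80%)."""
    return FitnessSpec(FitnessModel.DIRECT_VIABILITY, 0.80)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220408)
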