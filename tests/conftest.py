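import numpy as np
import pytest

from dcvwalk.params import ModelParams


@pytest.fixture
def wt_params() -> ModelParams:
    """Beta shapes fitted to the wild-type strain, on the default lattice."""
    return ModelParams(alpha=8.19, beta=12.95)


@pytest.fixture
def strain_params() -> dict[str, ModelParams]:
    return {
        "wild_type": ModelParams(alpha=8.19, beta=12.95),
        "klc1": ModelParams(alpha=3.18, beta=4.15),
        "klc2": ModelParams(alpha=5.12, beta=12.87),
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
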