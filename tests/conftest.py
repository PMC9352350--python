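import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from glomtune.containers import OBResponse, ResponseDataset
from glomtune.synthetic_data import SimConfig, generate_ground_truth, generate_responses


@pytest.fixture(scope="session")
def noise_free_config() -> SimConfig:
    """Study-scale config with noise-free spectra and every type present in
    every OB, used for parameter-recovery checks."""
    return SimConfig(seed=7, detection_noise_sd=0.0, presence_prob=1.0)


@pytest.fixture(scope="session")
def noise_free_truth(noise_free_config):
    return generate_ground_truth(noise_free_config)


@pytest.fixture(scope="session")
def noise_free_dataset(noise_free_config, noise_free_truth):
    return generate_responses(noise_free_truth, noise_free_config)


@pytest.fixture(scope="session")
def default_truth():
    config = SimConfig(seed=1)
    return config, generate_ground_truth(config)


def make_ob(matrix: dict, ob_id: str, mouse_id: str, positions=None) -> OBResponse:
    """Build an OBResponse from {glomerulus: {odorant: value}}."""
    responses = pd.DataFrame(matrix).T.astype(float)
    if positions is None:
        positions = pd.DataFrame(
            {
                "ml_um": np.linspace(100, 900, len(responses)),
                "ap_um": np.linspace(100, 900, len(responses)),
            },
            index=responses.index,
        )
    return OBResponse(
        responses=responses, positions=positions, ob_id=ob_id, mouse_id=mouse_id
    )


def make_dataset(obs) -> ResponseDataset:
    return ResponseDataset(list(obs))
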