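import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from isps.design import build_default_design
from isps.io import apply_mask
from isps.simulate import default_spec, simulate_group


@pytest.fixture(scope="session")
def design():
    return build_default_design()


@pytest.fixture(scope="session")
def planted_group(design):
    """Desk-scale planted-network group: 24 subjects, 3 networks, no jitter,
    signal/noise amplitude ratio 1.  Shared across tests (read-only)."""
    spec = default_spec(seed=1)
    series, truth = simulate_group(spec, design)
    return spec, series, truth


@pytest.fixture(scope="session")
def planted_matrices(planted_group):
    spec, series, truth = planted_group
    mask = np.ones(spec.grid_dims, dtype=bool)
    mats = [apply_mask(s, mask) for s in series]
    net_masks = [
        apply_mask(net.mask[..., None].astype(float), mask)[:, 0] > 0
        for net in truth.networks
    ]
    return mats, net_masks, truth
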