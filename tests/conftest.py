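import numpy as np
import pytest

from dynmod.synthetic_bold import StateSpec, SwitchingGroundTruth, generate_bold


@pytest.fixture(scope="session")
def two_block_state():
    """Balanced 20-node 2-block state with strong contrast."""
    cmap = np.array([1] * 10 + [2] * 10)
    return StateSpec(state_id=1, community_map=cmap, rho_in=0.8, rho_out=-0.3)


@pytest.fixture(scope="session")
def stationary_series(two_block_state):
    """Noise-free stationary series from the 2-block state (T=100)."""
    truth = SwitchingGroundTruth.from_sequence(np.ones(100, dtype=int), [two_block_state])
    return generate_bold(truth, noise_sd=0.0, smoothing_halfwidth=1, seed=7)


@pytest.fixture(scope="session")
def periodic_series():
    """Series whose volumes repeat with period 11: every length-11 window holds
    the same sample set, so all windowed graphs are identical."""
    rng = np.random.default_rng(3)
    block = rng.standard_normal((11, 6))
    data = np.tile(block, (10, 1))[:100]
    from dynmod.synthetic_bold import RoiTimeSeries

    return RoiTimeSeries(data=data, tr_seconds=3.0, region_ids=[f"r{i}" for i in range(6)])
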