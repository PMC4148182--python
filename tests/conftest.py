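import numpy as np
import pytest

import evbcold as ec


@pytest.fixture(scope="session")
def symmetric_toy():
    """Bath-free symmetric Marcus pair: reorg 32, dG0 0, H12 2."""
    return ec.make_toy_system(32.0, 0.0, 2.0)


@pytest.fixture(scope="session")
def ladder_300(symmetric_toy):
    """Moderately sampled 26-window ladder at 300 K, shared by the
    profile tests."""
    lams = np.linspace(0.0, 1.0, 26)
    return ec.run_ladder(symmetric_toy, lams, temperature=300.0, seed=11,
                         n_prod=8000)


@pytest.fixture
def aligned_trajectory():
    """Small superposed synthetic trajectory with per-residue noise."""
    traj = ec.synth_trajectory(12, 50, radial_sigma=lambda r: 0.3 + 0 * r,
                               seed=5)
    return ec.superpose(traj)
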