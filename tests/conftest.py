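"""Shared fixtures: small synthetic layouts and tracks built in memory."""

import numpy as np
import pytest

from damidephys.core import ProbeLayout, RatioTrack
from damidephys.synthetic_damid import ArraySimConfig


@pytest.fixture
def layout200() -> ProbeLayout:
    """One arm, 200 probes at exact 55 bp spacing, 60 bp probes."""
    starts = np.arange(200, dtype=np.int64) * 55
    return ProbeLayout(arm_id="2L", starts=starts,
                       lengths=np.full(200, 60, dtype=np.int64))


@pytest.fixture
def track_factory(layout200):
    def make(values, replicate_id="rep1", dye_swapped=False):
        values = np.asarray(values, dtype=float)
        assert values.size == layout200.n_probes
        return RatioTrack(replicate_id=replicate_id, arm_id=layout200.arm_id,
                          values=values, dye_swapped=dye_swapped)
    return make


@pytest.fixture
def tiny_sim_config() -> ArraySimConfig:
    """Noise-free single-arm config for exact recovery checks."""
    return ArraySimConfig(n_arms=1, probes_per_arm=300, noise_sd=0.0,
                          dye_swap_replicate=2, seed=11)
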