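import numpy as np
import pandas as pd
import pytest

import wormcircuit as wc
from wormcircuit.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def rim_tree():
    return wc.load_rim_fixture_tree()


@pytest.fixture(scope="session")
def transmission_p():
    return wc.estimate_transmission(39 / 181, 18).p


@pytest.fixture
def small_cfg():
    """Short, small-volume config for fast movie tests."""
    return SimulationConfig(random_seed=42, duration=120.0,
                            voxel_counts=(24, 24, 9),
                            neuron_positions=((8, 12, 4), (16, 12, 4)))


def annotations_for(cfg) -> pd.DataFrame:
    return pd.DataFrame(
        [{"t_index": ti, "neuron_id": f"neuron{i}", "x_vox": p[0],
          "y_vox": p[1], "z_vox": p[2]}
         for ti in range(cfg.n_volumes)
         for i, p in enumerate(cfg.neuron_positions)])


@pytest.fixture
def annotations(small_cfg):
    return annotations_for(small_cfg)
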