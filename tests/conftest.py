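import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from sgquant.synth import FluorSceneParams, generate_fluorescence_scene


@pytest.fixture(scope="session")
def single_cell():
    """One isolated noise-free cell: (scene, ground truth)."""
    params = FluorSceneParams(n_cells=1, seed=4)
    return generate_fluorescence_scene(params)


@pytest.fixture(scope="session")
def touching_pair():
    """Two cells whose membranes share a ridge segment."""
    params = FluorSceneParams(n_cells=2, cluster_layout="pairs", seed=9)
    return generate_fluorescence_scene(params)


@pytest.fixture()
def two_square_labels():
    """Hand-built label map: two touching 6x6 squares on a 20x20 raster."""
    labels = np.zeros((20, 20), dtype=np.int32)
    labels[5:11, 4:10] = 1
    labels[5:11, 10:16] = 2
    return labels
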