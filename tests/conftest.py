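import numpy as np
import pytest

import phylopom as pp


@pytest.fixture(scope="session")
def balanced4():
    """Balanced ultrametric 4-tip tree of unit depth."""
    return pp.parse_newick("((A:0.5,B:0.5):0.5,(C:0.7,D:0.7):0.3);")


@pytest.fixture(scope="session")
def yule50():
    return pp.simulate_tree(50, seed=42)


@pytest.fixture(scope="session")
def study14():
    """Canonical study-shaped simulation: 27 species x 14 sites."""
    return pp.study_mimic(11, n_sites=14, n_trees=5)


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 species x 2 sites hand-built dataset covering both methods."""
    Y = np.array([[[1, 0], [2, 0]],     # mist_net
                  [[0, 1], [0, 0]]])    # aru
    N = np.array([[2, 3], [1, 2]])
    mask = np.array([[True, False], [False, True]])
    return pp.DetectionDataset(["sp1", "sp2"], ["s1", "s2"], Y, N, mask)
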