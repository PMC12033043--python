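import numpy as np
import pytest

from uedindex.crystal import parse_cif
from uedindex.workbench import (SyntheticTruth, default_truth_setting,
                                make_synthetic_project)

CUBIC_CARBON_CIF = """\
data_cubic_carbon
_cell_length_a 10
_cell_length_b 10
_cell_length_c 10
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 C 0 0 0
"""


@pytest.fixture(scope="session")
def cubic_carbon():
    return parse_cif(CUBIC_CARBON_CIF)


@pytest.fixture(scope="session")
def truth_setting():
    return default_truth_setting()


@pytest.fixture(scope="session")
def synth_project(tmp_path_factory, truth_setting):
    """Noisy synthetic project with known truth (seed 1)."""
    out = tmp_path_factory.mktemp("synth")
    truth = SyntheticTruth(setting=truth_setting, seed=1)
    return make_synthetic_project(truth, out, with_image=False)


@pytest.fixture(scope="session")
def clean_project(tmp_path_factory, truth_setting):
    """Noise-free synthetic project (exact merged simulation)."""
    out = tmp_path_factory.mktemp("synth_clean")
    truth = SyntheticTruth(setting=truth_setting, intensity_noise=0.0,
                           centroid_jitter=0.0, seed=7)
    return make_synthetic_project(truth, out, with_image=False)


def random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
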