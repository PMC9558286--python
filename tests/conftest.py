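"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from t1synth import phantom
from t1synth.volumes import Volume


@pytest.fixture(scope="session")
def default_spec():
    return phantom.PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def anatomy(default_spec):
    """One audited phantom anatomy (labels + mask)."""
    return phantom.generate_anatomy(default_spec, seed=3)


@pytest.fixture(scope="session")
def three_class_flair(default_spec, anatomy):
    """Noise-free FLAIR render with partial-volume shells collapsed into
    their dominant tissue, leaving exactly three intensity classes."""
    lab3 = anatomy.data.copy()
    lab3[lab3 == phantom.PV_CSF_GM] = phantom.GM
    lab3[lab3 == phantom.PV_GM_WM] = phantom.WM
    vol = Volume(lab3, anatomy.affine, anatomy.mask)
    return phantom.render_modality(vol, default_spec.contrast_flair, 0.0, 0.0, seed=5), lab3


@pytest.fixture(scope="session")
def phantom_case(default_spec):
    """One audited longitudinal phantom case."""
    return phantom.make_longitudinal_case(default_spec, case_seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
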