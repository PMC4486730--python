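import numpy as np
import pytest

from pinnicomp.geometry import MorphometricProfile
from pinnicomp.synth import NoiseModel, default_truth, make_seal


@pytest.fixture
def cylinder_profile():
    """A circular cylinder, r = 10 cm: every hand-checkable volume is exact.

    Sites are spaced 20 cm apart along the axis (equal radii, so
    curvilinear == straight); sculp depth 3 cm at all interior sites.
    """
    n = 8
    girth = np.full((1, n), 2 * np.pi * 10.0)
    height = np.full((1, n), 20.0)
    width = np.full((1, n), 20.0)
    lc = np.array([[10.0, 30.0, 50.0, 70.0, 90.0, 110.0, 130.0, 150.0]])
    us = np.full((1, n), 3.0)
    us[0, 0] = us[0, -1] = np.nan
    return MorphometricProfile(
        animal_id="cyl", girth=girth, height=height, width=width,
        curvilinear=lc, total_length=np.array([160.0]), mass=500.0,
        us_dorsal=us, us_lateral=us.copy(),
    )


@pytest.fixture
def truth():
    return default_truth()


@pytest.fixture
def clean_profile(truth):
    """Zero-noise synthetic seal: pipeline must recover truth exactly."""
    return make_seal(truth, NoiseModel().zero())


@pytest.fixture
def noisy_profile(truth):
    return make_seal(truth, NoiseModel(), seed=11)
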