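import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pinnicomp.geometry import (DORSAL_CALIBRATION, DegenerateBodyError,
                                DegenerateSegmentError, DepthSource, Extent,
                                Shape, UltrasoundCalibration, body_volume,
                                convert_ultrasound_depth, end_cone_volume,
                                frustum_volume, partition_volumes,
                                straight_length)

positive = st.floats(0.1, 50.0, allow_nan=False)


@pytest.mark.parametrize("lc, r1, r2, expected", [
    (5.0, 4.0, 1.0, 4.0),       # 3-4-5 triangle
    (10.0, 3.0, 3.0, 10.0),     # equal radii: straight == curvilinear
    (13.0, 6.0, 1.0, 12.0),     # 5-12-13 triangle
])
def test_straight_length_right_triangle(lc, r1, r2, expected):
    assert straight_length(lc, r1, r2) == pytest.approx(expected)


def test_straight_length_degenerate_raises():
    with pytest.raises(DegenerateSegmentError):
        straight_length(2.0, 5.0, 1.0)


@pytest.mark.parametrize("a1, b1, a2, b2, ls, expected", [
    (1, 1, 1, 1, 3, 3 * np.pi),        # unit-circle cylinder
    (1, 2, 0, 0, 3, 2 * np.pi),        # degenerates to the end cone
    (2, 1, 1, 0.5, 6, 7 * np.pi),      # quadrature-checked frustum
])
def test_frustum_volume_closed_forms(a1, b1, a2, b2, ls, expected):
    assert frustum_volume(a1, b1, a2, b2, ls) == pytest.approx(expected)


@pytest.mark.parametrize("a, b, ls, expected", [
    (1, 1, 3, np.pi),
    (2, 1, 3, 2 * np.pi),
    (0, 1, 5, 0.0),
])
def test_end_cone_volume(a, b, ls, expected):
    assert end_cone_volume(a, b, ls) == pytest.approx(expected)


def test_negative_inputs_rejected():
    with pytest.raises(ValueError):
        frustum_volume(-1, 1, 1, 1, 2)
    with pytest.raises(ValueError):
        end_cone_volume(1, -1, 2)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(a1=positive, b1=positive, a2=positive, b2=positive, ls=positive)
def test_frustum_equals_integral_of_cross_sections(a1, b1, a2, b2, ls):
    """The closed form equals the integral of pi*a(t)*b(t) with linear axes."""
    t = np.linspace(0.0, 1.0, 5)  # integrand quadratic: Simpson exact
    a = a1 + (a2 - a1) * t
    b = b1 + (b2 - b1) * t
    from scipy.integrate import simpson
    oracle = simpson(np.pi * a * b, x=t * ls)
    assert frustum_volume(a1, b1, a2, b2, ls) == pytest.approx(oracle, rel=1e-10)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(a=positive, b=positive, ls=positive)
def test_frustum_limits(a, b, ls):
    """Cylinder limit and cone limit of the frustum formula."""
    assert frustum_volume(a, b, a, b, ls) == pytest.approx(np.pi * a * b * ls)
    assert frustum_volume(a, b, 0, 0, ls) == pytest.approx(end_cone_volume(a, b, ls))


def test_frustum_monotone_in_each_axis():
    base = frustum_volume(2, 1, 1, 0.5, 6)
    for bump in [(0.1, 0, 0, 0, 0), (0, 0.1, 0, 0, 0), (0, 0, 0.1, 0, 0),
                 (0, 0, 0, 0.1, 0), (0, 0, 0, 0, 0.1)]:
        args = np.array([2, 1, 1, 0.5, 6]) + np.array(bump)
        assert frustum_volume(*args) > base


class TestBodyVolume:
    def test_cylinder_neck_to_pelvis(self, cylinder_profile):
        # pelvis -> neck spans 100 cm of a r=10 cylinder
        v, detail = body_volume(cylinder_profile, Shape.CIRCULAR,
                                Extent.NECK_TO_PELVIS)
        assert v == pytest.approx(np.pi * 100 * 100)
        assert len(detail) == 5

    def test_circular_equals_elliptical_when_round(self, cylinder_profile):
        v_c, _ = body_volume(cylinder_profile, Shape.CIRCULAR, Extent.FULL_BODY)
        v_e, _ = body_volume(cylinder_profile, Shape.ELLIPTICAL, Extent.FULL_BODY)
        assert v_c == pytest.approx(v_e, rel=1e-12)

    def test_full_body_adds_end_cones(self, cylinder_profile):
        v, detail = body_volume(cylinder_profile, Shape.CIRCULAR, Extent.FULL_BODY)
        assert "tail_cone" in detail and "nose_cone" in detail
        assert detail["tail_cone"] == pytest.approx(np.pi * 100 * 10 / 3)
        assert v > body_volume(cylinder_profile, Shape.CIRCULAR,
                               Extent.NECK_TO_PELVIS)[0]

    def test_matches_piecewise_linear_integration_oracle(self, clean_profile):
        """Stacked frusta equal quadrature over the piecewise-linear body."""
        from scipy.integrate import simpson
        a, b = clean_profile.semi_axes(Shape.ELLIPTICAL)
        m = clean_profile.site_means()
        lc = m["curvilinear"]
        total = 0.0
        for i in range(7):
            ls = straight_length(lc[i + 1] - lc[i], b[i], b[i + 1])
            t = np.linspace(0, ls, 9)
            at = a[i] + (a[i + 1] - a[i]) * t / ls
            bt = b[i] + (b[i + 1] - b[i]) * t / ls
            total += simpson(np.pi * at * bt, x=t)
        total += end_cone_volume(a[0], b[0], lc[0])
        total += end_cone_volume(a[-1], b[-1], m["total_length"] - lc[-1])
        v, _ = body_volume(clean_profile, Shape.ELLIPTICAL, Extent.FULL_BODY)
        assert v == pytest.approx(total, rel=1e-8)


class TestPartition:
    def test_cylinder_annuli(self, cylinder_profile):
        # r=10 over 100 cm, skin 1 cm, sculp 3 cm: annulus areas 19pi/32pi/49pi
        part = partition_volumes(cylinder_profile, skin_depth=1.0,
                                 shape=Shape.CIRCULAR,
                                 extent=Extent.NECK_TO_PELVIS)
        assert part.v_skin == pytest.approx(1900 * np.pi)
        assert part.v_blubber == pytest.approx(3200 * np.pi)
        assert part.v_core == pytest.approx(4900 * np.pi)

    def test_zero_depths_all_core(self, cylinder_profile):
        prof = cylinder_profile
        prof.us_dorsal[:, 1:-1] = 0.0
        prof.us_lateral[:, 1:-1] = 0.0
        part = partition_volumes(prof, skin_depth=0.0, shape=Shape.CIRCULAR,
                                 extent=Extent.NECK_TO_PELVIS)
        assert part.v_skin == 0.0
        assert part.v_blubber == pytest.approx(0.0, abs=1e-9)
        assert part.v_core == pytest.approx(part.v_total)

    def test_additivity_on_random_profiles(self, truth):
        from pinnicomp.synth import NoiseModel, make_seal
        for seed in range(5):
            prof = make_seal(truth, NoiseModel(), seed=seed)
            part = partition_volumes(prof, skin_depth=1.32)
            total = part.v_skin + part.v_blubber + part.v_core
            assert total == pytest.approx(part.v_total, rel=1e-12)
            assert min(part.v_skin, part.v_blubber, part.v_core) >= 0

    def test_excessive_skin_depth_raises(self, cylinder_profile):
        with pytest.raises(DegenerateBodyError):
            partition_volumes(cylinder_profile, skin_depth=11.0)

    def test_clamping_flags_extreme_depths(self, cylinder_profile):
        prof = cylinder_profile
        prof.us_dorsal[:, 3] = 25.0  # deeper than the radius
        with pytest.warns(RuntimeWarning):
            part = partition_volumes(prof, skin_depth=1.0,
                                     shape=Shape.CIRCULAR,
                                     extent=Extent.NECK_TO_PELVIS)
        assert part.clamped
        assert part.v_core >= 0

    def test_mean_depth_source_matches_hand_arithmetic(self, cylinder_profile):
        prof = cylinder_profile
        prof.us_dorsal[:, 1:-1] = 2.0
        prof.us_lateral[:, 1:-1] = 4.0
        part = partition_volumes(prof, skin_depth=0.0, shape=Shape.CIRCULAR,
                                 extent=Extent.NECK_TO_PELVIS,
                                 depth_source=DepthSource.MEAN)
        # mean depth 3 cm: blubber annulus pi*(100-49) per unit length
        assert part.v_blubber == pytest.approx(np.pi * 51 * 100)


class TestUltrasoundCalibration:
    def test_table_point_conversion(self):
        # dorsal pelvis: 0.873 * 2 + 1.26
        assert convert_ultrasound_depth(2.0, "pelvis", DORSAL_CALIBRATION) \
            == pytest.approx(3.006)

    def test_zero_reading_returns_intercept(self):
        assert convert_ultrasound_depth(0.0, "neck", DORSAL_CALIBRATION) \
            == pytest.approx(0.540)

    def test_identity_calibration(self):
        ident = UltrasoundCalibration(slope=1.0, intercepts={"mid": 0.0})
        assert convert_ultrasound_depth(3.7, "mid", ident) == 3.7

    def test_unknown_site_raises(self):
        with pytest.raises(KeyError):
            convert_ultrasound_depth(1.0, "flipper", DORSAL_CALIBRATION)

    def test_posterior_draws_propagate(self):
        rng = np.random.default_rng(0)
        draws = np.column_stack([
            0.9 + 0.05 * rng.standard_normal(4000),
            1.2 + 0.2 * rng.standard_normal(4000),
        ])
        draws -= draws.mean(axis=0) - [0.9, 1.2]
        cal = UltrasoundCalibration(slope=0.9, intercepts={"mid": 1.2},
                                    draws=draws)
        out = convert_ultrasound_depth(2.0, "mid", cal)
        assert out.shape == (4000,)
        assert out.mean() == pytest.approx(0.9 * 2 + 1.2, abs=1e-6)
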