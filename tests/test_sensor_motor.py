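"""Scene rendering, space-code encoding, and the motor readout dynamics."""

import numpy as np
import pytest
from matplotlib.colors import rgb_to_hsv

from dynfield.geometry import FieldGeometry
from dynfield.sensor_motor import (
    Effector,
    ReadoutState,
    SceneObject,
    SceneSpec,
    encode_space_code,
    peak_centroid,
    proprioceptive_input,
    readout_rate,
    render_scene,
)
from tests.conftest import gaussian_bump


def one_disk_scene(hue=0.33, sat=1.0, center=(0.5, 0.5), radius=6.0):
    return SceneSpec(
        image_size=(48, 48),
        objects=(SceneObject(center=center, radius=radius, hue=hue,
                             saturation=sat),),
    )


class TestRenderScene:
    def test_empty_scene_is_uniform_gray(self):
        img = render_scene(SceneSpec(image_size=(32, 32)))
        assert img.shape == (32, 32, 3)
        np.testing.assert_allclose(img, 0.5)

    def test_disk_center_pixel_round_trips_hue_and_saturation(self):
        img = render_scene(one_disk_scene(hue=0.33, sat=0.8))
        hsv = rgb_to_hsv(img[24, 24])
        assert hsv[0] == pytest.approx(0.33, abs=1 / 255)
        assert hsv[1] == pytest.approx(0.8, abs=1 / 255)
        assert hsv[2] == pytest.approx(1.0, abs=1 / 255)

    def test_disjoint_disk_areas_add(self):
        spec = SceneSpec(
            image_size=(64, 64),
            objects=(
                SceneObject(center=(0.25, 0.25), radius=6.0, hue=0.0),
                SceneObject(center=(0.75, 0.75), radius=6.0, hue=0.33),
            ),
        )
        img = render_scene(spec)
        sat = rgb_to_hsv(img)[..., 1]
        colored = (sat > 0.5).sum()
        assert colored == pytest.approx(2 * np.pi * 6.0**2, rel=0.1)

    def test_later_object_wins_overlaps(self):
        spec = SceneSpec(
            image_size=(48, 48),
            objects=(
                SceneObject(center=(0.5, 0.5), radius=8.0, hue=0.0),
                SceneObject(center=(0.5, 0.5), radius=4.0, hue=0.33),
            ),
        )
        hsv = rgb_to_hsv(render_scene(spec))
        assert hsv[24, 24, 0] == pytest.approx(0.33, abs=1 / 255)

    def test_rendering_is_deterministic(self):
        a = render_scene(one_disk_scene())
        b = render_scene(one_disk_scene())
        np.testing.assert_array_equal(a, b)


class TestSpaceCode:
    def _geometry(self, nx=48, ny=48, nh=16):
        return FieldGeometry(
            ("x", "y", "hue"), (0.0, 0.0, 0.0), (1.0, 1.0, 1.0),
            (nx, ny, nh), (False, False, True),
        )

    def test_zero_saturation_image_encodes_to_zero(self):
        geo = self._geometry()
        img = render_scene(SceneSpec(image_size=(48, 48)))
        code = encode_space_code(img, geo, gain=2.0)
        np.testing.assert_array_equal(code.tensor, 0.0)

    def test_single_disk_lands_in_matching_hue_bin_with_saturation_value(self):
        geo = self._geometry()
        hue, gain = 0.33, 2.0
        img = render_scene(one_disk_scene(hue=hue))
        code = encode_space_code(img, geo, hue_smoothing_sigma=0.0, gain=gain)
        hsv = rgb_to_hsv(img)
        sat = hsv[..., 1]
        matching_bin = geo.nearest_index(2, hue)
        nz = np.nonzero(code.tensor)
        # non-zero entries only in the disk footprint ...
        assert set(zip(*nz[:2])) == set(zip(*np.nonzero(sat)))
        # ... in the hue bins matching each pixel's hue (one bin per column)
        for ix, iy in zip(*np.nonzero(sat)):
            column = code.tensor[ix, iy]
            hits = np.nonzero(column)[0]
            assert len(hits) == 1
            assert column[hits[0]] == pytest.approx(gain * sat[ix, iy])
        # interior pixels hit the bin of the requested hue
        assert code.tensor[24, 24, matching_bin] == pytest.approx(gain, abs=0.02)

    def test_encoding_conserves_saturation_mass(self):
        geo = self._geometry()
        img = render_scene(one_disk_scene(sat=0.7))
        sat = rgb_to_hsv(img)[..., 1]
        gain = 3.0
        code = encode_space_code(img, geo, gain=gain)
        assert code.tensor.sum() == pytest.approx(gain * sat.sum(), rel=1e-12)
        smoothed = encode_space_code(img, geo, hue_smoothing_sigma=0.05,
                                     gain=gain)
        # circular smoothing preserves each column's mass
        np.testing.assert_allclose(
            smoothed.tensor.sum(axis=2), code.tensor.sum(axis=2), atol=1e-6
        )

    def test_finer_images_are_average_pooled(self):
        geo = self._geometry(nx=24, ny=24)
        img = render_scene(one_disk_scene())
        code = encode_space_code(img, geo, gain=1.0)
        assert code.tensor.shape == (24, 24, 16)
        assert code.tensor.max() == pytest.approx(1.0, abs=0.05)

    def test_incompatible_image_size_rejected(self):
        geo = self._geometry(nx=20, ny=20)
        with pytest.raises(ValueError, match="multiple"):
            encode_space_code(np.zeros((48, 48, 3)), geo)


class TestPeakCentroid:
    def test_symmetric_blob_centroid_at_center(self, geo2d):
        out = gaussian_bump(geo2d, (0.4, 0.6), (0.08, 0.08))
        res = peak_centroid(out, geo2d)
        assert res.defined
        np.testing.assert_allclose(
            res.x_cmd, [0.4, 0.6], atol=0.5 * geo2d.spacing[0]
        )

    def test_zero_output_is_flagged_undefined_without_dividing(self, geo2d):
        res = peak_centroid(np.zeros(geo2d.shape), geo2d)
        assert res.N == 0.0 and not res.defined and res.x_cmd is None

    def test_two_equal_blobs_average_to_the_midpoint(self, geo2d):
        out = gaussian_bump(geo2d, (0.25, 0.5), (0.05, 0.05)) + gaussian_bump(
            geo2d, (0.75, 0.5), (0.05, 0.05)
        )
        res = peak_centroid(out, geo2d)
        # documents why a selection decision must precede the readout
        np.testing.assert_allclose(res.x_cmd, [0.5, 0.5], atol=0.03)


class TestReadoutDynamics:
    def test_rate_vanishes_for_zero_output(self, geo2d):
        state = ReadoutState(np.array([0.3, 0.9]))
        rate = readout_rate(state, np.zeros(geo2d.shape), geo2d)
        np.testing.assert_array_equal(rate, 0.0)

    def test_centroid_is_a_fixed_point(self, geo2d):
        out = gaussian_bump(geo2d, (0.4, 0.6), (0.08, 0.08))
        res = peak_centroid(out, geo2d)
        rate = readout_rate(ReadoutState(res.x_cmd), out, geo2d)
        np.testing.assert_allclose(rate, 0.0, atol=1e-12)

    def test_single_integral_equals_stiffness_times_error(self, geo2d, rng):
        """The normalization-free rate equals -N (x_ctrl - x_cmd) for any
        suprathreshold pattern with N > 0 (the algebraic identity that
        removes the need to ever compute the centroid)."""
        for _ in range(100):
            out = np.clip(rng.random(geo2d.shape) - 0.5, 0.0, 1.0)
            res = peak_centroid(out, geo2d)
            x_ctrl = rng.uniform(0, 1, size=2)
            rate = readout_rate(ReadoutState(x_ctrl), out, geo2d)
            expected = -res.N * (x_ctrl - res.x_cmd)
            np.testing.assert_allclose(rate, expected, atol=1e-8)

    def test_integrating_converges_to_centroid_and_freezes_at_zero(self, geo2d):
        out = gaussian_bump(geo2d, (0.7, 0.3), (0.08, 0.08))
        res = peak_centroid(out, geo2d)
        state = ReadoutState(np.array([0.1, 0.9]), tau_ctrl=50.0)
        dt = 5.0
        for _ in range(int(12 * state.tau_ctrl / res.N / dt)):
            state.x_ctrl = state.x_ctrl + (dt / state.tau_ctrl) * readout_rate(
                state, out, geo2d
            )
        np.testing.assert_allclose(state.x_ctrl, res.x_cmd,
                                   atol=geo2d.spacing[0])
        frozen = state.x_ctrl.copy()
        for _ in range(100):
            state.x_ctrl = state.x_ctrl + (dt / state.tau_ctrl) * readout_rate(
                state, np.zeros(geo2d.shape), geo2d
            )
        np.testing.assert_array_equal(state.x_ctrl, frozen)

    def test_pinned_coordinates_do_not_move(self, geo2d):
        out = gaussian_bump(geo2d, (0.7, 0.3), (0.08, 0.08))
        state = ReadoutState(np.array([0.1, 0.9]), fixed_components={1: 0.9})
        rate = readout_rate(state, out, geo2d)
        assert rate[0] != 0.0 and rate[1] == 0.0


class TestEffector:
    def test_stationary_control_gives_stationary_bump(self, geo2d):
        a = proprioceptive_input((0.4, 0.6), geo2d, 2.0, 0.07)
        b = proprioceptive_input((0.4, 0.6), geo2d, 2.0, 0.07)
        np.testing.assert_array_equal(a, b)

    def test_bump_maximum_tracks_position(self, geo2d, rng):
        for _ in range(100):
            pos = rng.uniform(0.1, 0.9, size=2)
            bump = proprioceptive_input(pos, geo2d, 1.0, 0.07)
            ij = np.unravel_index(bump.argmax(), bump.shape)
            cell = np.array([geo2d.coords(0)[ij[0]], geo2d.coords(1)[ij[1]]])
            assert np.all(np.abs(cell - pos) <= np.array(geo2d.spacing) / 2 + 1e-12)

    def test_bump_mass_position_independent_in_interior(self, geo2d, rng):
        masses = [
            proprioceptive_input(rng.uniform(0.3, 0.7, 2), geo2d, 1.0, 0.05).sum()
            for _ in range(20)
        ]
        assert np.ptp(masses) / np.mean(masses) < 1e-6

    def test_default_effector_is_the_control_variable(self):
        eff = Effector((0.5, 0.5))
        pos = eff.step(np.array([0.2, 0.8]), dt=10.0)
        np.testing.assert_array_equal(pos, [0.2, 0.8])

    def test_lagged_effector_relaxes_first_order(self):
        eff = Effector((0.0, 0.0), tau_lag=100.0)
        target = np.array([1.0, 0.0])
        for _ in range(10):
            eff.step(target, dt=10.0)
        assert eff.position[0] == pytest.approx(1 - 0.9**10, rel=1e-12)
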