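import math

import numpy as np
import pytest

import spindlequant as sq
from spindlequant.geometry import Pole, PolePair, PoleTrack


class TestDetectPoles:
    def test_bipolar_centers_within_half_pixel(self, quiet_bipolar):
        img, mf = quiet_bipolar
        px = mf.pixel_size_um
        found = sq.detect_poles(img, "poles")
        truth = {tuple(np.round(np.array(p[:2]) / px, 0))
                 for p in mf.pole_positions_um}
        for pole in (found.p1, found.p2):
            best = min(
                (math.hypot(pole.x - tx / px, pole.y - ty / px)
                 for tx, ty in mf.pole_positions_um), default=None)
            assert best is not None and best <= 0.5

    def test_blank_image_raises(self):
        img = sq.CalibratedImage(np.zeros((1, 32, 32)),
                                 ("channel", "y", "x"),
                                 sq.Calibration(pixel_size_xy=0.1), ["poles"])
        with pytest.raises(ValueError, match="blank|candidate"):
            sq.detect_poles(img, "poles")

    def test_monopolar_single_pole(self):
        m = sq.MonopolarManifest(seed=4, noise=sq.NoiseModel.off(),
                                 background_level=0.0)
        img, mf = sq.simulate_monopolar_cell(m)
        pole = sq.detect_poles(img, "poles", expected=1)
        px = mf.pixel_size_um
        cx, cy = mf.pole_position_um
        assert math.hypot(pole.x - cx / px, pole.y - cy / px) <= 0.5


class TestSpindleLength:
    def test_closed_form(self, cal):
        pair = PolePair(Pole(0, 0), Pole(100, 0))
        assert sq.spindle_length(pair, cal) == pytest.approx(10.0)

    def test_coincident_poles_invalid(self):
        with pytest.raises(ValueError, match="coincide"):
            PolePair(Pole(5, 5), Pole(5, 5))

    def test_manifest_recovery(self):
        m = sq.BipolarManifest(seed=9, spindle_length_um=12.0,
                               noise=sq.NoiseModel.off(),
                               background_level=0.0)
        img, _ = sq.simulate_bipolar_cell(m)
        poles = sq.detect_poles(img, "poles")
        assert sq.spindle_length(poles, img.calibration) == pytest.approx(
            12.0, abs=0.1)

    def test_scales_linearly_with_pixel_size(self):
        pair = PolePair(Pole(0, 0), Pole(100, 0))
        c1 = sq.Calibration(pixel_size_xy=0.1)
        c2 = sq.Calibration(pixel_size_xy=0.2)
        assert sq.spindle_length(pair, c2) == pytest.approx(
            2 * sq.spindle_length(pair, c1))


class TestPoleAxisAngle:
    # (Δx, Δy, Δz) in µm at pixel 0.1 µm / z-step 0.25 µm → expected degrees
    @pytest.mark.parametrize("d_um,expected", [
        ((10, 0, 0), 0.0),
        ((0, 0, 2), 90.0),
        ((3, 0, 4), 53.13),
    ])
    def test_closed_forms(self, cal, d_um, expected):
        dx, dy, dz = d_um
        pair = PolePair(Pole(0, 0, 0),
                        Pole(dx / 0.1, dy / 0.1, dz / 0.25))
        assert sq.pole_axis_angle(pair, cal) == pytest.approx(expected,
                                                              abs=0.01)

    def test_missing_z_calibration(self):
        pair = PolePair(Pole(0, 0, 0), Pole(10, 0, 4))
        with pytest.raises(Exception, match="z_step"):
            sq.pole_axis_angle(pair, sq.Calibration(pixel_size_xy=0.1))

    def test_invariant_to_pole_swap_and_xy_rotation(self, cal):
        pair = PolePair(Pole(3, 7, 1), Pole(40, 22, 9))
        a = sq.pole_axis_angle(pair, cal)
        assert sq.pole_axis_angle(pair.swapped(), cal) == pytest.approx(a)
        # rotate both poles by 73° about the origin in xy
        t = math.radians(73)
        rot = lambda p: Pole(p.x * math.cos(t) - p.y * math.sin(t),  # noqa
                             p.x * math.sin(t) + p.y * math.cos(t), p.z)
        rpair = PolePair(rot(pair.p1), rot(pair.p2))
        assert sq.pole_axis_angle(rpair, cal) == pytest.approx(a, abs=1e-9)


class TestRotationDisplacement:
    def test_stationary_track_is_zero(self, cal):
        track = PoleTrack(np.arange(30), np.tile([50.0, 50.0], (30, 1)))
        assert sq.rotation_displacement(track, cal) == 0.0

    def test_uniform_advance(self, cal):
        # 1 µm (= 10 px) per 1-min frame
        xs = 10.0 * np.arange(10)
        track = PoleTrack(np.arange(10), np.column_stack([xs, np.zeros(10)]))
        assert sq.rotation_displacement(track, cal) == pytest.approx(1.0)

    def test_single_frame_invalid(self, cal):
        with pytest.raises(ValueError, match="2 frames"):
            sq.rotation_displacement(PoleTrack([0], [[1.0, 1.0]]), cal)

    def test_translation_invariance(self, cal):
        rng = np.random.default_rng(3)
        xy = rng.uniform(40, 60, size=(12, 2))
        t1 = PoleTrack(np.arange(12), xy)
        t2 = PoleTrack(np.arange(12), xy + [13.0, -4.0])
        assert sq.rotation_displacement(t2, cal) == pytest.approx(
            sq.rotation_displacement(t1, cal))

    def test_rotation_fixture_chord_rate(self):
        """Tracked displacement matches the 2·r·sin(θ/2) chord oracle."""
        m = sq.RotationManifest(seed=1, rotation_rate_deg_per_min=6.0,
                                spindle_length_um=10.0,
                                noise=sq.NoiseModel.off())
        mov, mf = sq.simulate_rotation_movie(m)
        p0 = np.array(mf.pole_positions_um)[0, 0] / mf.pixel_size_um
        track = sq.track_pole(mov, start_xy=tuple(p0))
        disp = sq.rotation_displacement(track, mov.calibration)
        assert disp == pytest.approx(2 * 5 * math.sin(math.radians(3)),
                                     rel=0.05)


class TestRandomManifestRecovery:
    def test_length_and_angle_on_random_spindles(self):
        """Noise-free length within 1% and angle within 1° across 100 cells."""
        rng = np.random.default_rng(0)
        n_z, z_step, px = 9, 0.25, 0.1083
        for trial in range(100):
            length_xy = rng.uniform(7.0, 11.0)
            theta = rng.uniform(0, math.pi)
            z1, z2 = rng.integers(1, n_z - 1, size=2)
            m = sq.BipolarManifest(
                seed=int(rng.integers(2 ** 31)), shape=(128, 128),
                pixel_size_um=px, n_z=n_z, z_step_um=z_step,
                channels=("poles",), spindle_length_um=length_xy,
                axis_angle_deg=math.degrees(theta),
                pole_z_um=(z1 * z_step, z2 * z_step),
                noise=sq.NoiseModel.off(), background_level=0.0)
            img, mf = sq.simulate_bipolar_cell(m)
            poles = sq.detect_poles(img, "poles")
            truth = np.array(mf.pole_positions_um)
            d = truth[1] - truth[0]
            true_len = float(np.linalg.norm(d))
            true_ang = math.degrees(math.asin(abs(d[2]) / true_len))
            got_len = sq.spindle_length(poles, img.calibration)
            got_ang = sq.pole_axis_angle(poles, img.calibration)
            assert got_len == pytest.approx(true_len, rel=0.01)
            assert abs(got_ang - true_ang) <= 1.0
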