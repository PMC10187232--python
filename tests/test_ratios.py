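import numpy as np
import pytest

import spindlequant as sq
from spindlequant.ratios import QuartileLine, make_band
from tests.conftest import uniform_image


def _disk_roi(mf):
    h, w = mf.shape
    px = mf.pixel_size_um
    cx, cy = mf.pole_position_um
    yy, xx = np.mgrid[0:h, 0:w]
    return sq.RoiMask(((xx * px - cx) ** 2 + (yy * px - cy) ** 2)
                      <= mf.dna_radius_um ** 2)


def _square_roi(shape, y0, y1, x0, x1):
    m = np.zeros(shape, dtype=bool)
    m[y0:y1, x0:x1] = True
    return sq.RoiMask(m)


class TestBackgroundSubtractedMean:
    def test_closed_form(self):
        arr = np.full((1, 64, 64), 20.0)
        arr[0, 10:20, 10:20] = 100.0
        img = sq.CalibratedImage(arr, ("channel", "y", "x"),
                                 sq.Calibration(pixel_size_xy=0.1), ["k"])
        roi = _square_roi((64, 64), 10, 20, 10, 20)
        bg = _square_roi((64, 64), 40, 50, 40, 50)
        assert sq.background_subtracted_mean(img, "k", roi, bg) == \
            pytest.approx(80.0)

    def test_uniform_image_gives_zero(self):
        img = uniform_image(55.0)
        roi = _square_roi((64, 64), 5, 15, 5, 15)
        bg = _square_roi((64, 64), 40, 50, 40, 50)
        assert sq.background_subtracted_mean(img, "ch", roi, bg) == \
            pytest.approx(0.0)

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(10, 50, size=(64, 64))
        roi = _square_roi((64, 64), 5, 15, 5, 15)
        bg = _square_roi((64, 64), 40, 50, 40, 50)
        cal = sq.Calibration(pixel_size_xy=0.1)
        img1 = sq.CalibratedImage(base[None], ("channel", "y", "x"), cal, ["c"])
        img2 = sq.CalibratedImage(base[None] + 50.0, ("channel", "y", "x"),
                                  cal, ["c"])
        assert sq.background_subtracted_mean(img2, "c", roi, bg) == \
            pytest.approx(sq.background_subtracted_mean(img1, "c", roi, bg))

    def test_overlapping_rois_rejected(self):
        img = uniform_image()
        roi = _square_roi((64, 64), 5, 20, 5, 20)
        bg = _square_roi((64, 64), 15, 30, 15, 30)
        with pytest.raises(ValueError, match="overlap"):
            sq.background_subtracted_mean(img, "ch", roi, bg)


class TestBandConstruction:
    def test_band_width_in_pixels_matches_calibration(self):
        """A 2.5 µm band at 0.25 µm/px is a 10-px ring."""
        inner = _square_roi((128, 128), 50, 70, 50, 70)
        broi = make_band(inner, 2.5, 0.25)
        cols = broi.band.mask[60]          # row through the ROI center
        left_band = np.flatnonzero(cols[:50])
        assert len(left_band) == 10
        assert not (broi.inner.mask & broi.band.mask).any()

    def test_band_clipped_by_border_rejected(self):
        inner = _square_roi((64, 64), 2, 20, 2, 20)
        with pytest.raises(ValueError, match="fit"):
            make_band(inner, 2.5, 0.25)


class TestBandRatio:
    def test_uniform_image_ratio_one(self):
        img = uniform_image(9.0, shape=(128, 128))
        inner = _square_roi((128, 128), 55, 75, 55, 75)
        assert sq.band_ratio(img, "ch", inner, 1.0) == pytest.approx(1.0)

    def test_monopolar_enrichment_two_recovered(self):
        """Density ratio 2 with noise off → measured ratio 2.0 ± 5%."""
        m = sq.MonopolarManifest(seed=2, peripheral_to_inner_density=2.0,
                                 noise=sq.NoiseModel.off(),
                                 background_level=0.0)
        img, mf = sq.simulate_monopolar_cell(m)
        r = sq.band_ratio(img, "EB1", _disk_roi(mf), mf.band_width_um)
        assert r == pytest.approx(2.0, rel=0.05)

    def test_invariant_to_global_scaling(self):
        m = sq.MonopolarManifest(seed=5, peripheral_to_inner_density=2.0,
                                 noise=sq.NoiseModel.off())
        img, mf = sq.simulate_monopolar_cell(m)
        roi = _disk_roi(mf)
        r1 = sq.band_ratio(img, "EB1", roi, mf.band_width_um)
        scaled = sq.CalibratedImage(img.data * 3.7, img.axes,
                                    img.calibration, img.channel_names)
        r2 = sq.band_ratio(scaled, "EB1", roi, mf.band_width_um)
        assert r2 == pytest.approx(r1, rel=1e-9)


def _body_ellipse_roi(mf):
    """The generative spindle-body ellipse as a measurement ROI."""
    px = mf.pixel_size_um
    h, w = mf.shape
    (x1, y1), (x2, y2) = mf.pole_positions_um
    cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
    yy, xx = np.mgrid[0:h, 0:w]
    u = xx * px - cx
    v = yy * px - cy
    a = mf.spindle_length_um / 2
    b = mf.lateral_halfwidth_um + 0.5
    return sq.RoiMask((u / a) ** 2 + (v / b) ** 2 <= 1.0)


class TestTubulinDensity:
    def test_equal_shell_and_body(self):
        m = sq.BipolarManifest(seed=1, peripheral_to_inner_intensity=1.0,
                               shell_width_um=5.0,
                               noise=sq.NoiseModel.off())
        img, mf = sq.simulate_bipolar_cell(m)
        roi = _body_ellipse_roi(mf)
        bg = _square_roi(mf.shape, 4, 24, 4, 24)
        spindle, periph = sq.tubulin_density(img, "tubulin", roi, bg,
                                             band_width_um=4.5)
        assert periph == pytest.approx(spindle, rel=0.05)

    def test_background_only_image_near_zero(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(100, 2, size=(1, 128, 128)).clip(0)
        img = sq.CalibratedImage(arr, ("channel", "y", "x"),
                                 sq.Calibration(pixel_size_xy=0.1), ["t"])
        roi = _square_roi((128, 128), 50, 70, 50, 70)
        bg = _square_roi((128, 128), 5, 25, 5, 25)
        spindle, periph = sq.tubulin_density(img, "t", roi, bg, 2.0)
        assert abs(spindle) < 1.0 and abs(periph) < 1.0

    def test_half_intensity_shell_recovered(self):
        """Shell at 0.5× body intensity → peripheral/spindle ≈ 0.5."""
        m = sq.BipolarManifest(seed=3, peripheral_to_inner_intensity=0.5,
                               shell_width_um=5.0,
                               noise=sq.NoiseModel.off())
        img, mf = sq.simulate_bipolar_cell(m)
        roi = _body_ellipse_roi(mf)
        bg = _square_roi(mf.shape, 4, 24, 4, 24)
        spindle, periph = sq.tubulin_density(img, "tubulin", roi, bg,
                                             band_width_um=4.5)
        assert periph / spindle == pytest.approx(0.5, rel=0.05)


class TestExpressionLevel:
    def test_control_cell_is_unity(self):
        img = uniform_image(10.0)
        img.data[0, 10:20, 10:20] = 110.0
        roi = _square_roi((64, 64), 10, 20, 10, 20)
        bg = _square_roi((64, 64), 40, 50, 40, 50)
        bs = sq.background_subtracted_mean(img, "ch", roi, bg)
        assert sq.expression_level(img, "ch", roi, bg, bs) == pytest.approx(1.0)

    def test_double_signal_is_two(self):
        cal = sq.Calibration(pixel_size_xy=0.1)
        base = np.full((64, 64), 10.0)
        base[10:20, 10:20] = 60.0      # signal 50 over background
        double = np.full((64, 64), 10.0)
        double[10:20, 10:20] = 110.0   # signal 100 over background
        roi = _square_roi((64, 64), 10, 20, 10, 20)
        bg = _square_roi((64, 64), 40, 50, 40, 50)
        i1 = sq.CalibratedImage(base[None], ("channel", "y", "x"), cal, ["k"])
        i2 = sq.CalibratedImage(double[None], ("channel", "y", "x"), cal, ["k"])
        control = sq.background_subtracted_mean(i1, "k", roi, bg)
        assert sq.expression_level(i2, "k", roi, bg, control) == \
            pytest.approx(2.0)

    def test_nonpositive_control_rejected(self):
        img = uniform_image()
        roi = _square_roi((64, 64), 10, 20, 10, 20)
        bg = _square_roi((64, 64), 40, 50, 40, 50)
        with pytest.raises(ValueError, match="control_mean"):
            sq.expression_level(img, "ch", roi, bg, 0.0)

    def test_control_cohort_self_normalizes_to_one(self):
        """Mean normalized expression of a control cohort is 1 by construction."""
        rng = np.random.default_rng(7)
        cal = sq.Calibration(pixel_size_xy=0.1)
        roi = _square_roi((64, 64), 10, 30, 10, 30)
        bg = _square_roi((64, 64), 45, 60, 45, 60)
        cells, raw = [], []
        for _ in range(20):
            arr = np.full((64, 64), 20.0) + rng.normal(0, 1, (64, 64))
            arr[10:30, 10:30] += rng.uniform(80, 120)
            img = sq.CalibratedImage(arr.clip(0)[None], ("channel", "y", "x"),
                                     cal, ["k"])
            cells.append(img)
            raw.append(sq.background_subtracted_mean(img, "k", roi, bg))
        control_mean = float(np.mean(raw))
        normed = [sq.expression_level(c, "k", roi, bg, control_mean)
                  for c in cells]
        assert np.mean(normed) == pytest.approx(1.0, abs=1e-9)


class TestLinescanQuartileRatio:
    @staticmethod
    def _image_from_columns(cols):
        """64-row image whose every row equals `cols`."""
        arr = np.tile(np.asarray(cols, dtype=float), (64, 1))
        return sq.CalibratedImage(arr[None], ("channel", "y", "x"),
                                  sq.Calibration(pixel_size_xy=0.1), ["g"])

    def test_uniform_profile_ratio_one(self):
        img = self._image_from_columns(np.full(64, 5.0))
        line = QuartileLine((32, 32), (1, 0), 40)
        assert sq.linescan_quartile_ratio(img, "g", line) == pytest.approx(1.0)

    def test_signal_only_in_middle_gives_zero(self):
        cols = np.zeros(64)
        cols[22:42] = 1.0     # only the middle half of a 40-px line at x=32
        img = self._image_from_columns(cols)
        line = QuartileLine((32, 32), (1, 0), 40)
        assert sq.linescan_quartile_ratio(img, "g", line) == pytest.approx(0.0)

    def test_triangular_peripheral_peaks_match_discrete_oracle(self):
        cols = np.full(64, 0.1)
        cols[12:16] = [0.5, 1.0, 1.0, 0.5]     # left outer 10%
        cols[48:52] = [0.5, 1.0, 1.0, 0.5]     # right outer 10%
        img = self._image_from_columns(cols)
        line = QuartileLine((32, 32), (1, 0), 40)
        got = sq.linescan_quartile_ratio(img, "g", line)
        # brute-force oracle on the same unit-spaced samples
        s = np.arange(41.0)
        xs = 12.0 + s
        vals = cols[xs.astype(int)]
        pos = s / s[-1]
        outer = (pos < 0.25) | (pos > 0.75)
        oracle = vals[outer].mean() / vals[~outer].mean()
        assert got == pytest.approx(oracle, rel=1e-6)

    def test_middle_zero_is_degenerate(self):
        cols = np.zeros(64)
        cols[12:18] = 1.0      # only outer-left quarter
        img = self._image_from_columns(cols)
        line = QuartileLine((32, 32), (1, 0), 40)
        with pytest.raises(ZeroDivisionError):
            sq.linescan_quartile_ratio(img, "g", line)

    def test_monopolar_enrichment_recovery_and_monotonicity(self):
        """Cohort-mean line-scan ratio tracks the generative density ratio."""
        means = []
        for r in (0.5, 2.0):
            vals = []
            for seed in range(8):
                m = sq.MonopolarManifest(seed=seed,
                                         peripheral_to_inner_density=r,
                                         noise=sq.NoiseModel.off(),
                                         background_level=0.0)
                img, mf = sq.simulate_monopolar_cell(m)
                px = mf.pixel_size_um
                cx, cy = mf.pole_position_um
                line = QuartileLine((cx / px, cy / px), (1, 0),
                                    4 * mf.dna_radius_um / px)
                vals.append(sq.linescan_quartile_ratio(img, "EB1", line))
            means.append(np.mean(vals))
        assert means[0] == pytest.approx(0.5, rel=0.10)
        assert means[1] == pytest.approx(2.0, rel=0.10)
        assert means[0] < means[1]
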