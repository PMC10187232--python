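import math

import numpy as np
import pytest

import spindlequant as sq
from spindlequant.geometry import Pole, PolePair
from spindlequant.profiles import FWHM_FACTOR
from tests.conftest import uniform_image


class TestExtractAxisProfile:
    def test_uniform_image_gives_constant_profile(self):
        img = uniform_image(7.0)
        poles = PolePair(Pole(5, 30), Pole(55, 30))
        prof = sq.extract_axis_profile(img, "ch", poles, width_px=5)
        np.testing.assert_allclose(prof.intensities, 7.0)

    def test_single_pixel_line_recovered_at_width_one(self):
        data = np.zeros((1, 32, 32))
        data[0, 16, 4:28] = np.arange(24, dtype=float) + 1
        img = sq.CalibratedImage(data, ("channel", "y", "x"),
                                 sq.Calibration(pixel_size_xy=0.1), ["ch"])
        poles = PolePair(Pole(4, 16), Pole(27, 16))
        prof = sq.extract_axis_profile(img, "ch", poles, width_px=1)
        np.testing.assert_allclose(prof.intensities,
                                   np.arange(24, dtype=float) + 1)

    def test_profile_peak_near_spindle_midpoint(self):
        # dense plate so the discrete-puncta profile has a stable peak
        m = sq.BipolarManifest(seed=7, n_kinetochores=400,
                               noise=sq.NoiseModel.off(),
                               background_level=0.0)
        img, mf = sq.simulate_bipolar_cell(m)
        poles = sq.detect_poles(img, "poles")
        prof = sq.extract_axis_profile(img, "kinetochores", poles)
        peak_um = prof.positions_um[np.argmax(prof.intensities)]
        assert peak_um == pytest.approx(mf.spindle_length_um / 2, abs=0.3)

    def test_segment_exiting_bounds_raises(self):
        img = uniform_image()
        poles = PolePair(Pole(-10, 30), Pole(60, 30))
        with pytest.raises(ValueError, match="bounds"):
            sq.extract_axis_profile(img, "ch", poles)


class TestNormalizeProfile:
    def test_divides_by_maximum(self):
        prof = sq.LineProfile([0.0, 1.0, 2.0], [2.0, 4.0, 8.0])
        out = sq.normalize_profile(prof)
        np.testing.assert_allclose(out.intensities, [0.25, 0.5, 1.0])
        assert out.normalized

    def test_idempotent(self):
        prof = sq.LineProfile([0.0, 1.0, 2.0], [0.25, 0.5, 1.0])
        out = sq.normalize_profile(sq.normalize_profile(prof))
        np.testing.assert_allclose(out.intensities, [0.25, 0.5, 1.0])

    def test_all_zero_profile_rejected(self):
        prof = sq.LineProfile([0.0, 1.0, 2.0], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="no positive signal"):
            sq.normalize_profile(prof)


def _grid_search_sigma(x, y):
    """Independent coarse-grid SSE minimizer over (A, µ, σ, c)."""
    best = (np.inf, None)
    for A in np.linspace(0.5 * y.max(), 1.5 * y.max(), 12):
        for mu in np.linspace(x[0], x[-1], 25):
            for sigma in np.linspace(0.2, (x[-1] - x[0]) / 2, 40):
                for c in np.linspace(0, 0.5 * y.max(), 6):
                    sse = float(((y - (A * np.exp(-(x - mu) ** 2 /
                                                  (2 * sigma ** 2)) + c)) ** 2
                                 ).sum())
                    if sse < best[0]:
                        best = (sse, sigma)
    return best[1]


class TestGaussianFit:
    def test_exact_gaussian_recovers_fwhm(self):
        x = np.linspace(0, 12, 120)
        y = np.exp(-((x - 6) ** 2) / (2 * 2.0 ** 2))
        fit = sq.fit_gaussian_fwhm(sq.LineProfile(x, y))
        assert fit.converged
        assert fit.fwhm_um == pytest.approx(2 * math.sqrt(2 * math.log(2)) * 2,
                                            abs=1e-6)

    def test_noisy_gaussian_matches_grid_search_oracle(self):
        """SNR-10 fits track σ=2 µm on average and agree with a grid oracle."""
        x = np.linspace(0, 12, 120)
        clean = np.exp(-((x - 6) ** 2) / (2 * 2.0 ** 2))
        truth = 2 * math.sqrt(2 * math.log(2)) * 2.0
        fwhms = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = np.clip(clean + rng.normal(0, 0.1, x.size), 0, None)  # SNR 10
            fit = sq.fit_gaussian_fwhm(sq.LineProfile(x, y))
            assert fit.converged
            fwhms.append(fit.fwhm_um)
            if seed == 0:
                oracle_sigma = _grid_search_sigma(x, y)
                assert fit.sigma_um == pytest.approx(oracle_sigma, rel=0.1)
        assert np.mean(fwhms) == pytest.approx(truth, rel=0.05)

    def test_constant_profile_flagged_unconverged(self):
        prof = sq.LineProfile(np.arange(10.0), np.full(10, 3.0))
        fit = sq.fit_gaussian_fwhm(prof)
        assert not fit.converged
        assert "unidentifiable" in fit.message

    def test_fwhm_invariant_to_rescaling(self):
        x = np.linspace(0, 10, 80)
        rng = np.random.default_rng(5)
        y = np.exp(-((x - 5) ** 2) / 3.0) + rng.normal(0, 0.02, x.size) + 0.1
        y = np.clip(y, 0, None)
        f1 = sq.fit_gaussian_fwhm(sq.LineProfile(x, y))
        f2 = sq.fit_gaussian_fwhm(sq.LineProfile(x, 37.0 * y))
        assert f1.fwhm_um == pytest.approx(f2.fwhm_um, rel=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="5 samples"):
            sq.fit_gaussian_fwhm(sq.LineProfile([0, 1, 2, 3],
                                                [0, 1, 1, 0]))


class TestAlignmentMetric:
    def test_pole_swap_symmetry(self, quiet_bipolar):
        img, _ = quiet_bipolar
        poles = sq.detect_poles(img, "poles")
        a = sq.alignment_metric(img, poles)
        b = sq.alignment_metric(img, poles.swapped())
        assert a["fwhm_um"] == pytest.approx(b["fwhm_um"], rel=1e-6)
        assert a["spindle_length_um"] == pytest.approx(
            b["spindle_length_um"])

    def test_fwhm_invariant_to_cell_orientation(self):
        recs = []
        for angle in (0.0, 35.0):
            m = sq.BipolarManifest(seed=21, axis_angle_deg=angle,
                                   noise=sq.NoiseModel.off(),
                                   background_level=0.0)
            img, _ = sq.simulate_bipolar_cell(m)
            poles = sq.detect_poles(img, "poles")
            recs.append(sq.alignment_metric(img, poles)["fwhm_um"])
        # same seed draws the same kinetochores in spindle coordinates
        assert recs[0] == pytest.approx(recs[1], rel=0.05)

    def test_mean_fwhm_increases_with_spread(self):
        means = []
        for sigma in (1.0, 2.0, 3.0):
            vals = []
            for seed in range(8):
                m = sq.BipolarManifest(
                    seed=seed, kinetochore_spread_sigma_um=sigma,
                    spindle_length_um=max(12.0, 6 * sigma),
                    noise=sq.NoiseModel.off(), background_level=0.0)
                img, _ = sq.simulate_bipolar_cell(m)
                poles = sq.detect_poles(img, "poles")
                vals.append(sq.alignment_metric(img, poles)["fwhm_um"])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_cohort_recovery_with_noise(self):
        """Mean FWHM of 20 noisy σ=1.5 cells within 10% of 2√(2 ln2)·1.5."""
        vals = []
        for seed in range(20):
            m = sq.BipolarManifest(seed=100 + seed,
                                   kinetochore_spread_sigma_um=1.5)
            img, _ = sq.simulate_bipolar_cell(m)
            poles = sq.detect_poles(img, "poles")
            vals.append(sq.alignment_metric(img, poles)["fwhm_um"])
        assert np.mean(vals) == pytest.approx(FWHM_FACTOR * 1.5, rel=0.10)
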