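"""Ground-truth recovery studies on synthetic cohorts.

Each function builds seeded synthetic cohorts with the generators in
:mod:`spindlequant.simulate`, runs the corresponding measurement pipeline
exactly as a user would, and reports recovery statistics against the
manifests.  These are the package's evidence that the estimators are
calibrated; the test suite asserts on their outputs.

Cohort design notes:

* FWHM cohorts scale the spindle with the spread, ``L = max(12 µm, 6σ)``,
  so the poles always flank the kinetochore distribution — the defining
  geometry of a metaphase cell, and what the pole-to-pole profile line
  assumes.
* Rotation discrimination uses the recorded true pole trajectories with
  Gaussian localization jitter (tracking noise), the statistical contract
  of manual point-tracking; full image-based tracking is validated
  separately in the unit tests.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import simulate as sim
from .geometry import PoleTrack, detect_poles, rotation_displacement
from .io import Calibration, RoiMask
from .kymograph import detect_runs
from .profiles import FWHM_FACTOR, alignment_metric
from .ratios import QuartileLine, band_ratio, linescan_quartile_ratio
from .timing import compare_groups

__all__ = [
    "fwhm_recovery",
    "ratio_recovery",
    "velocity_recovery",
    "rotation_discrimination",
]


def _sub_seed(seed: int, *parts: int) -> int:
    """Deterministic < 2**31 stream id from a base seed and indices."""
    h = np.uint64(seed)
    for p in parts:
        h = (h * np.uint64(1000003) + np.uint64(p) + np.uint64(1)) \
            % np.uint64(2 ** 31 - 1)
    return int(h)


def fwhm_recovery(seed: int = 0, n_cells: int = 50,
                  spread_levels=(1.0, 1.5, 2.0, 3.0)) -> pd.DataFrame:
    """Chromosome-alignment FWHM recovery across spread levels (noise on).

    Returns one row per level: the cohort-mean fitted FWHM, the expected
    2√(2 ln2)·σ, and the relative bias.
    """
    rows = []
    for li, sigma in enumerate(spread_levels):
        vals = []
        for i in range(n_cells):
            m = sim.BipolarManifest(
                seed=_sub_seed(seed, 1, li, i),
                kinetochore_spread_sigma_um=sigma,
                spindle_length_um=max(12.0, 6.0 * sigma),
                channels=("poles", "kinetochores"))
            img, _ = sim.simulate_bipolar_cell(m)
            poles = detect_poles(img, "poles")
            vals.append(alignment_metric(img, poles)["fwhm_um"])
        expected = FWHM_FACTOR * sigma
        mean = float(np.mean(vals))
        rows.append({"spread_sigma_um": sigma, "n_cells": n_cells,
                     "mean_fwhm_um": mean, "expected_fwhm_um": expected,
                     "rel_bias": mean / expected - 1.0})
    return pd.DataFrame(rows)


def _monopolar_measurements(m: sim.MonopolarManifest):
    img, mf = sim.simulate_monopolar_cell(m)
    px = mf.pixel_size_um
    cx, cy = mf.pole_position_um
    h, w = mf.shape
    yy, xx = np.mgrid[0:h, 0:w]
    inner = RoiMask(((xx * px - cx) ** 2 + (yy * px - cy) ** 2)
                    <= mf.dna_radius_um ** 2)
    br = band_ratio(img, "EB1", inner, mf.band_width_um)
    line = QuartileLine((cx / px, cy / px), (1.0, 0.0),
                        4.0 * mf.dna_radius_um / px)
    lr = linescan_quartile_ratio(img, "EB1", line)
    return br, lr


def ratio_recovery(seed: int = 0, enrichment_levels=(0.5, 1.0, 2.0, 4.0),
                   n_noise_off: int = 12,
                   n_noise_on: int = 20) -> pd.DataFrame:
    """Band and line-scan ratio recovery on monopolar fixtures.

    Noise-off cohorts measure estimator accuracy (cohort-mean vs the
    generative density ratio); noise-on cohorts are reported for the
    monotonicity check across enrichment levels.
    """
    rows = []
    for li, r in enumerate(enrichment_levels):
        off_b, off_l, on_b, on_l = [], [], [], []
        for i in range(n_noise_off):
            m = sim.MonopolarManifest(
                seed=_sub_seed(seed, 2, li, i), peripheral_to_inner_density=r,
                noise=sim.NoiseModel.off(), background_level=0.0)
            br, lr = _monopolar_measurements(m)
            off_b.append(br)
            off_l.append(lr)
        for i in range(n_noise_on):
            m = sim.MonopolarManifest(
                seed=_sub_seed(seed, 3, li, i), peripheral_to_inner_density=r)
            br, lr = _monopolar_measurements(m)
            on_b.append(br)
            on_l.append(lr)
        rows.append({
            "enrichment": r,
            "band_ratio_noise_off": float(np.mean(off_b)),
            "linescan_ratio_noise_off": float(np.mean(off_l)),
            "band_ratio_noise_on": float(np.mean(on_b)),
            "linescan_ratio_noise_on": float(np.mean(on_l)),
        })
    return pd.DataFrame(rows)


def velocity_recovery(seed: int = 0,
                      velocity_levels=(0.02, 0.05, 0.1, 0.2),
                      n_runs: int = 100,
                      run_length_um: float = 2.0) -> pd.DataFrame:
    """Automated kymograph velocity recovery at SNR 10.

    Each simulated run is detected with :func:`detect_runs`; the
    least-squares ridge-fit velocity is the recovery estimator, and the
    bounding-rectangle velocity is reported alongside.
    """
    rows = []
    for li, v in enumerate(velocity_levels):
        fits, rects, found = [], [], 0
        for i in range(n_runs):
            m = sim.KymographManifest(
                seed=_sub_seed(seed, 4, li, i),
                runs=[sim.KymographRunSpec(0.5, 3, v, run_length_um)])
            ky, _ = sim.simulate_kymograph(m)
            moving = [r for r in detect_runs(ky) if r.is_moving]
            if len(moving) == 1:
                found += 1
                fits.append(moving[0].velocity_fit_um_s)
                rects.append(moving[0].velocity_um_s)
        rows.append({
            "true_velocity_um_s": v,
            "n_runs": n_runs,
            "n_detected": found,
            "mean_velocity_fit": float(np.mean(fits)),
            "mean_velocity_rect": float(np.mean(rects)),
            "rel_bias_fit": float(np.mean(fits)) / v - 1.0,
        })
    return pd.DataFrame(rows)


def _jittered_displacement(manifest: sim.RotationManifest,
                           jitter_px: float,
                           rng: np.random.Generator) -> float:
    """Displacement of pole 1 from true positions + localization jitter."""
    _, mf = sim.simulate_rotation_movie(_positions_only(manifest))
    truth = np.array(mf.pole_positions_um)[:, 0, :]   # (T, 2) µm
    px = mf.pixel_size_um
    xy_px = truth / px + rng.normal(0.0, jitter_px, size=truth.shape)
    track = PoleTrack(np.arange(len(xy_px)), xy_px)
    cal = Calibration(pixel_size_xy=px,
                      frame_interval=mf.frame_interval_min, time_unit="min")
    return rotation_displacement(track, cal)


def _positions_only(manifest: sim.RotationManifest) -> sim.RotationManifest:
    """Shrink the render field: only the recorded trajectory is used."""
    import dataclasses
    side = int(math.ceil((manifest.spindle_length_um + 2.0)
                         / manifest.pixel_size_um))
    return dataclasses.replace(manifest, shape=(side, side),
                               noise=sim.NoiseModel.off(),
                               background_level=0.0)


def rotation_discrimination(seed: int = 0, n_reps: int = 100,
                            n_cells: int = 15,
                            rates=(0.0, 6.0),
                            jitter_px: float = 0.2) -> dict:
    """Can the rotation assay separate stationary from rotating cohorts?

    For each repetition, two ``n_cells`` cohorts (rotation rates in
    ``rates``, °/min at 1 min/frame) are measured as per-cell displacement
    (true pole track + ``jitter_px`` localization noise) and compared with
    one-way ANOVA + Tukey.  Reports the fraction of repetitions with
    adjusted p < 0.05 and the grand mean displacement of each cohort.
    """
    hits = 0
    cohort_means = {r: [] for r in rates}
    for rep in range(n_reps):
        rows = []
        rng = np.random.default_rng(_sub_seed(seed, 5, rep))
        for gi, rate in enumerate(rates):
            for i in range(n_cells):
                m = sim.RotationManifest(
                    seed=_sub_seed(seed, 6, rep, gi * 1000 + i),
                    rotation_rate_deg_per_min=rate)
                disp = _jittered_displacement(m, jitter_px, rng)
                rows.append((f"rate_{rate}", f"rep{i % 3}",
                             f"c{gi}_{i}", "displacement", disp))
        tab = pd.DataFrame(rows, columns=["condition", "replicate",
                                          "cell_id", "metric", "value"])
        for rate in rates:
            cohort_means[rate].append(
                tab.loc[tab["condition"] == f"rate_{rate}", "value"].mean())
        report = compare_groups(tab, "displacement", "parametric")
        if (report.pairwise["p_adj"] < 0.05).all():
            hits += 1
    return {
        "fraction_significant": hits / n_reps,
        "mean_displacement_um_min": {
            r: float(np.mean(v)) for r, v in cohort_means.items()},
        "n_reps": n_reps,
        "n_cells": n_cells,
    }
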