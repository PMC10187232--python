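"""Synthetic fluorescence fixtures with recorded ground truth.

Every generator takes a *manifest* describing the world to render (pole
geometry, kinetochore spread, puncta densities, noise model) and returns the
rendered :class:`~spindlequant.io.CalibratedImage` (or
:class:`~spindlequant.kymograph.Kymograph`) together with the manifest,
augmented with the realized random draws (kinetochore positions, puncta
counts, per-frame pole tracks).  Measurement modules are validated by
recovering these recorded truths.

Modelling choices (documented, deliberately simple):

* The point-spread function is an isotropic 2-D Gaussian, default
  ``psf_sigma_px = 1.3`` — a diffraction-limited spot at 60×-like sampling.
  No 3-D PSF; z-stacks attenuate spots with an axial Gaussian instead.
* Noise is Poisson shot noise on (signal + background) followed by Gaussian
  read noise; both are switchable off so exact recovery tests are possible.
* Random streams are split per channel from the manifest seed with a fixed
  rule, so adding a channel never perturbs the draws of another.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import CalibratedImage, Calibration
from .kymograph import Kymograph

__all__ = [
    "NoiseModel",
    "BipolarManifest",
    "MonopolarManifest",
    "RotationManifest",
    "KymographRunSpec",
    "KymographManifest",
    "simulate_bipolar_cell",
    "simulate_monopolar_cell",
    "simulate_rotation_movie",
    "simulate_kymograph",
    "save_manifest",
    "load_manifest",
]

MANIFEST_SCHEMA_VERSION = 1

#: fixed channel → stream-key map; never reorder (determinism contract)
_STREAM_KEYS = {
    "poles": 0, "kinetochores": 1, "tubulin": 2, "GFP": 3, "DNA": 4,
    "EB1": 5, "noise": 64, "kymo": 96,
}


def _rng(seed: int, stream: str, sub: int = 0) -> np.random.Generator:
    key = _STREAM_KEYS[stream]
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(key, sub)))


@dataclass
class NoiseModel:
    """Poisson shot noise on (signal+background), then Gaussian read noise."""

    poisson: bool = True
    read_sigma: float = 10.0

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(clean, dtype=float)
        if self.poisson:
            out = rng.poisson(np.clip(out, 0, None)).astype(float)
        if self.read_sigma > 0:
            out = out + rng.normal(0.0, self.read_sigma, size=out.shape)
        return np.clip(out, 0.0, None)

    @property
    def enabled(self) -> bool:
        return self.poisson or self.read_sigma > 0

    @staticmethod
    def off() -> "NoiseModel":
        return NoiseModel(poisson=False, read_sigma=0.0)


# ---------------------------------------------------------------------------
# low-level rendering

def _add_spot(img: np.ndarray, y: float, x: float, amp: float,
              sigma: float) -> None:
    """Accumulate an isotropic 2-D Gaussian spot; patch-local for speed."""
    h, w = img.shape
    r = int(math.ceil(4.0 * sigma))
    y0, x0 = int(round(y)), int(round(x))
    ylo, yhi = max(0, y0 - r), min(h, y0 + r + 1)
    xlo, xhi = max(0, x0 - r), min(w, x0 + r + 1)
    if ylo >= yhi or xlo >= xhi:
        return
    yy = np.arange(ylo, yhi, dtype=float) - y
    xx = np.arange(xlo, xhi, dtype=float) - x
    g = np.exp(-(yy[:, None] ** 2 + xx[None, :] ** 2) / (2.0 * sigma ** 2))
    img[ylo:yhi, xlo:xhi] += amp * g


def _ellipse_mask(shape: tuple[int, int], cy: float, cx: float,
                  a_px: float, b_px: float, theta: float) -> np.ndarray:
    """Mask of an ellipse: semi-axis ``a`` along direction theta, ``b`` across."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dy, dx = yy - cy, xx - cx
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def _axial_weights(n_z: int, z_step: float, z_um: float,
                   sigma_z: float) -> np.ndarray:
    zs = np.arange(n_z) * z_step
    return np.exp(-((zs - z_um) ** 2) / (2.0 * sigma_z ** 2))


# ---------------------------------------------------------------------------
# manifests

@dataclass
class BipolarManifest:
    """Stated world for a bipolar metaphase cell.

    Defaults emulate a HeLa-like metaphase spindle imaged at 60×:
    256×256 field at 0.1083 µm/px, 12 µm spindle, 46 kinetochores whose
    axial positions spread Normal(midpoint, 1.5 µm) along the pole axis.
    """

    seed: int = 0
    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1083
    n_z: int = 1
    z_step_um: float = 0.25
    channels: tuple[str, ...] = ("poles", "kinetochores", "tubulin", "DNA")
    spindle_length_um: float = 12.0
    axis_angle_deg: float = 0.0
    center_um: tuple[float, float] | None = None   # (x, y); default field center
    pole_z_um: tuple[float, float] | None = None   # z of each pole (z-stacks)
    kinetochore_spread_sigma_um: float = 1.5
    n_kinetochores: int = 92   # 46 chromosomes × 2 sister kinetochores
    lateral_halfwidth_um: float = 2.0
    pole_amplitude: float = 2000.0
    kinetochore_amplitude: float = 500.0
    body_intensity: float = 300.0
    peripheral_to_inner_intensity: float = 1.0
    shell_width_um: float = 1.5
    dna_intensity: float = 300.0
    background_level: float = 100.0
    psf_sigma_px: float = 1.3
    axial_sigma_um: float = 0.6
    noise: NoiseModel = field(default_factory=NoiseModel)
    # realized ground truth, filled by the generator
    pole_positions_um: list | None = None          # [(x, y[, z]), (x, y[, z])]
    kinetochore_axial_um: list | None = None       # offsets from spindle midpoint
    kinetochore_lateral_um: list | None = None
    schema_version: int = MANIFEST_SCHEMA_VERSION

    def validate(self) -> None:
        if self.kinetochore_spread_sigma_um <= 0:
            raise ValueError("kinetochore_spread_sigma_um must be > 0")
        fov = min(self.shape) * self.pixel_size_um
        if self.spindle_length_um >= fov:
            raise ValueError(
                f"spindle ({self.spindle_length_um} µm) does not fit the "
                f"{fov:.1f} µm field of view")
        bad = set(self.channels) - {"poles", "kinetochores", "tubulin",
                                    "GFP", "DNA"}
        if bad:
            raise ValueError(f"unknown channels {sorted(bad)}")


@dataclass
class MonopolarManifest:
    """Stated world for a monastrol-collapsed monopolar cell.

    The DNA forms a disk of radius ``dna_radius_um`` around the single pole
    (a monastrol rosette is ~10 µm across, hence the 5 µm default); EB1-like
    puncta are placed with local density ``inner_density_per_um2`` inside
    the disk and ``peripheral_to_inner_density`` times that everywhere
    outside it, out to ``annulus_outer_um`` (default: far enough to cover
    both the 2.5 µm measurement band and the quartile line-scan, whose
    outer quarters reach 2× the DNA radius).  Puncta counts are
    deterministic (``round(density × area)``, no Poisson count noise) and
    centers keep a ``margin_um`` (≈ one PSF σ) gap at the inner/outer
    boundary so PSF spill cannot mix the two densities; the density ratio
    is then the exact measurable ground truth for both ratio estimators.
    """

    seed: int = 0
    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1083
    channels: tuple[str, ...] = ("poles", "DNA", "EB1")
    center_um: tuple[float, float] | None = None
    dna_radius_um: float = 5.0
    band_width_um: float = 2.5
    margin_um: float = 0.15
    annulus_outer_um: float | None = None
    inner_density_per_um2: float = 8.0
    peripheral_to_inner_density: float = 1.0
    pole_amplitude: float = 2000.0
    puncta_amplitude: float = 500.0
    dna_intensity: float = 300.0
    background_level: float = 100.0
    psf_sigma_px: float = 1.3
    noise: NoiseModel = field(default_factory=NoiseModel)
    # realized ground truth
    pole_position_um: tuple[float, float] | None = None
    n_inner_puncta: int | None = None
    n_band_puncta: int | None = None
    schema_version: int = MANIFEST_SCHEMA_VERSION

    @property
    def annulus_outer(self) -> float:
        if self.annulus_outer_um is not None:
            return self.annulus_outer_um
        # cover the band and the line-scan's outer reach (2×radius) with a
        # shoulder for the 20-px sampling width
        return max(self.dna_radius_um + self.band_width_um,
                   2.0 * self.dna_radius_um) + 1.2

    def validate(self) -> None:
        if self.dna_radius_um <= 0 or self.band_width_um <= 0:
            raise ValueError("dna_radius_um and band_width_um must be > 0")
        if self.peripheral_to_inner_density < 0:
            raise ValueError("peripheral_to_inner_density must be ≥ 0")
        fov = min(self.shape) * self.pixel_size_um
        if 2 * self.annulus_outer >= fov:
            raise ValueError("DNA disk plus peripheral annulus does not "
                             "fit the field of view")


@dataclass
class RotationManifest:
    """Stated world for a live rotation time-lapse.

    Defaults follow the live rotation assay: one frame per minute for
    30 minutes (31 frames), a 10 µm spindle rotating rigidly in the
    xy-plane about its centroid.
    """

    seed: int = 0
    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1083
    n_frames: int = 31
    frame_interval_min: float = 1.0
    spindle_length_um: float = 10.0
    center_um: tuple[float, float] | None = None
    rotation_rate_deg_per_min: float = 0.0
    initial_angle_deg: float = 0.0
    pole_amplitude: float = 2000.0
    background_level: float = 100.0
    psf_sigma_px: float = 1.3
    noise: NoiseModel = field(default_factory=NoiseModel)
    # realized ground truth: per-frame [(x1,y1),(x2,y2)] in µm
    pole_positions_um: list | None = None
    schema_version: int = MANIFEST_SCHEMA_VERSION

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be ≥ 1")
        fov = min(self.shape) * self.pixel_size_um
        if self.spindle_length_um >= fov:
            raise ValueError("spindle does not fit the field of view")


@dataclass
class KymographRunSpec:
    """One constant-velocity run: where it starts and how far it goes."""

    start_um: float
    start_frame: int
    velocity_um_s: float
    run_length_um: float

    @property
    def duration_s(self) -> float:
        if self.velocity_um_s == 0:
            raise ValueError("stationary run: give duration via n_frames")
        return self.run_length_um / abs(self.velocity_um_s)


@dataclass
class KymographManifest:
    """Stated world for a single-molecule kymograph.

    Defaults follow TIRF acquisition at 10 frames/s with 0.1 µm pixels.
    ``snr`` is peak run amplitude over the Gaussian noise σ.
    """

    seed: int = 0
    pixel_size_um: float = 0.1
    frame_interval_s: float = 0.1
    length_um: float = 6.0
    n_frames: int | None = None
    runs: list = field(default_factory=list)   # KymographRunSpec or dicts
    stationary_frames: int = 50                # duration used when v == 0
    amplitude: float = 100.0
    background_level: float = 10.0
    ridge_sigma_px: float = 1.0
    snr: float = 10.0
    noise_on: bool = True
    schema_version: int = MANIFEST_SCHEMA_VERSION

    def run_specs(self) -> list[KymographRunSpec]:
        out = []
        for r in self.runs:
            out.append(r if isinstance(r, KymographRunSpec)
                       else KymographRunSpec(**r))
        return out

    def validate(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration values must be > 0")
        for r in self.run_specs():
            end = r.start_um + r.velocity_um_s * (
                0 if r.velocity_um_s == 0 else r.duration_s)
            if not (0 <= r.start_um <= self.length_um and
                    0 <= end <= self.length_um):
                raise ValueError(f"run {r} leaves the [0, {self.length_um}] µm track")


# ---------------------------------------------------------------------------
# generators

def _field_center(shape, pixel_size) -> tuple[float, float]:
    return ((shape[1] - 1) / 2.0 * pixel_size,
            (shape[0] - 1) / 2.0 * pixel_size)


def _render_region(shape, mask, intensity, psf_sigma) -> np.ndarray:
    from scipy.ndimage import gaussian_filter
    return gaussian_filter(mask.astype(float) * intensity, psf_sigma)


def simulate_bipolar_cell(
        manifest: BipolarManifest) -> tuple[CalibratedImage, BipolarManifest]:
    """Render a bipolar spindle cell and record its ground truth.

    The pole channel carries two PSF-sized spots at the pole positions; the
    kinetochore channel sums ``n_kinetochores`` puncta whose positions along
    the pole axis are drawn Normal(midpoint, spread σ) and lie laterally
    within the spindle body; the tubulin channel is an elliptical spindle
    body plus a peripheral shell scaled by ``peripheral_to_inner_intensity``.
    Background and noise are applied last, per channel.
    """
    m = dataclasses.replace(manifest)
    m.validate()
    px = m.pixel_size_um
    h, w = m.shape
    cx, cy = m.center_um if m.center_um is not None else _field_center(m.shape, px)
    theta = math.radians(m.axis_angle_deg)
    ux, uy = math.cos(theta), math.sin(theta)
    nx, ny = -uy, ux
    half = m.spindle_length_um / 2.0
    p1 = (cx - half * ux, cy - half * uy)
    p2 = (cx + half * ux, cy + half * uy)
    if m.n_z > 1:
        z1, z2 = m.pole_z_um if m.pole_z_um is not None else (
            (m.n_z - 1) / 2.0 * m.z_step_um,) * 2
        m.pole_positions_um = [[p1[0], p1[1], z1], [p2[0], p2[1], z2]]
    else:
        m.pole_positions_um = [list(p1), list(p2)]

    rng_k = _rng(m.seed, "kinetochores")
    axial = rng_k.normal(0.0, m.kinetochore_spread_sigma_um,
                         size=m.n_kinetochores)
    # metaphase plate = uniform disk of radius `lateral_halfwidth_um` in the
    # (lateral, z) plane; the rendered 2-D image is its projection, so the
    # in-image lateral coordinate follows the disk's semicircle marginal
    r_lat = m.lateral_halfwidth_um * np.sqrt(
        rng_k.uniform(0.0, 1.0, size=m.n_kinetochores))
    phi = rng_k.uniform(0.0, 2.0 * math.pi, size=m.n_kinetochores)
    lateral = r_lat * np.cos(phi)
    m.kinetochore_axial_um = [float(v) for v in axial]
    m.kinetochore_lateral_um = [float(v) for v in lateral]

    mid_z = (m.n_z - 1) / 2.0 * m.z_step_um
    planes: dict[str, np.ndarray] = {}
    stacks: dict[str, np.ndarray] = {}

    def blank():
        return np.zeros((h, w), dtype=float)

    for ch in m.channels:
        img = blank()
        if ch == "poles":
            if m.n_z > 1:
                # each pole focused at its own z
                stack = np.zeros((m.n_z, h, w), dtype=float)
                for pos in m.pole_positions_um:
                    zw = _axial_weights(m.n_z, m.z_step_um, pos[2],
                                        m.axial_sigma_um)
                    spot = blank()
                    _add_spot(spot, pos[1] / px, pos[0] / px,
                              m.pole_amplitude, m.psf_sigma_px)
                    stack += zw[:, None, None] * spot[None, :, :]
                stacks[ch] = stack
            for (pxu, pyu) in (p1, p2):
                _add_spot(img, pyu / px, pxu / px, m.pole_amplitude,
                          m.psf_sigma_px)
        elif ch == "kinetochores":
            for a, l in zip(axial, lateral):
                x = cx + a * ux + l * nx
                y = cy + a * uy + l * ny
                _add_spot(img, y / px, x / px, m.kinetochore_amplitude,
                          m.psf_sigma_px)
        elif ch in ("tubulin", "GFP"):
            a_in = half / px
            b_in = (m.lateral_halfwidth_um + 0.5) / px
            body = _ellipse_mask((h, w), cy / px, cx / px, a_in, b_in, theta)
            outer = _ellipse_mask((h, w), cy / px, cx / px,
                                  a_in + m.shell_width_um / px,
                                  b_in + m.shell_width_um / px, theta)
            shell = outer & ~body
            img = _render_region((h, w), body, m.body_intensity,
                                 m.psf_sigma_px)
            img += _render_region(
                (h, w), shell,
                m.body_intensity * m.peripheral_to_inner_intensity,
                m.psf_sigma_px)
        elif ch == "DNA":
            plate = _ellipse_mask(
                (h, w), cy / px, cx / px,
                max(2.0 * m.kinetochore_spread_sigma_um, 0.5) / px,
                m.lateral_halfwidth_um / px, theta)
            img = _render_region((h, w), plate, m.dna_intensity,
                                 m.psf_sigma_px)
        planes[ch] = img

    data = _assemble(m, planes, mid_z, stacks)
    cal = Calibration(pixel_size_xy=px,
                      z_step=m.z_step_um if m.n_z > 1 else None)
    axes = (("channel", "z", "y", "x") if m.n_z > 1 else ("channel", "y", "x"))
    return CalibratedImage(data, axes, cal, list(m.channels)), m


def _assemble(m, planes: dict[str, np.ndarray], mid_z: float,
              stacks: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Stack per-channel planes, expand to z if requested, add bg + noise.

    Channels with a prebuilt z-stack in ``stacks`` (per-structure focus)
    bypass the shared mid-plane axial attenuation.
    """
    n_z = getattr(m, "n_z", 1)
    stacks = stacks or {}
    out = []
    for ch in m.channels:
        sig = planes[ch]
        noise_rng = _rng(m.seed, "noise", _STREAM_KEYS.get(ch, 32) + 1)
        if n_z > 1:
            if ch in stacks:
                stack = stacks[ch] + m.background_level
            else:
                zw = _axial_weights(n_z, m.z_step_um, mid_z, m.axial_sigma_um)
                stack = sig[None, :, :] * zw[:, None, None] + m.background_level
            if m.noise.enabled:
                stack = m.noise.apply(stack, noise_rng)
            out.append(stack)
        else:
            plane = sig + m.background_level
            if m.noise.enabled:
                plane = m.noise.apply(plane, noise_rng)
            out.append(plane)
    return np.stack(out, axis=0)


def simulate_monopolar_cell(
        manifest: MonopolarManifest) -> tuple[CalibratedImage, MonopolarManifest]:
    """Render a monopolar (monastrol-collapsed) cell.

    DNA is a disk around the single pole; EB1 puncta are laid down with
    density ``inner_density_per_um2`` inside the disk and
    ``peripheral_to_inner_density`` times that in the surrounding band.
    """
    m = dataclasses.replace(manifest)
    m.validate()
    px = m.pixel_size_um
    h, w = m.shape
    cx, cy = m.center_um if m.center_um is not None else _field_center(m.shape, px)
    m.pole_position_um = (float(cx), float(cy))
    R, mar = m.dna_radius_um, m.margin_um
    outer = m.annulus_outer

    # local densities are exact: counts = density × populated area
    area_in = math.pi * max(R - mar, 0.0) ** 2
    area_out = math.pi * (outer ** 2 - (R + mar) ** 2)
    n_in = int(round(m.inner_density_per_um2 * area_in))
    n_band = int(round(m.inner_density_per_um2 *
                       m.peripheral_to_inner_density * area_out))
    m.n_inner_puncta, m.n_band_puncta = n_in, n_band

    rng = _rng(m.seed, "EB1")

    def draw_annulus(n, r_lo, r_hi):
        # area-uniform radii in [r_lo, r_hi]
        u = rng.uniform(r_lo ** 2, r_hi ** 2, size=n)
        r = np.sqrt(u)
        phi = rng.uniform(0, 2 * math.pi, size=n)
        return cx + r * np.cos(phi), cy + r * np.sin(phi)

    xi, yi = draw_annulus(n_in, 0.0, max(R - mar, 0.0))
    xo, yo = draw_annulus(n_band, R + mar, outer)

    planes: dict[str, np.ndarray] = {}
    for ch in m.channels:
        img = np.zeros((h, w), dtype=float)
        if ch == "poles":
            _add_spot(img, cy / px, cx / px, m.pole_amplitude, m.psf_sigma_px)
        elif ch == "DNA":
            yy, xx = np.mgrid[0:h, 0:w]
            disk = ((xx * px - cx) ** 2 + (yy * px - cy) ** 2) <= R ** 2
            img = _render_region((h, w), disk, m.dna_intensity, m.psf_sigma_px)
        elif ch in ("EB1", "GFP"):
            for x, y in zip(np.concatenate([xi, xo]), np.concatenate([yi, yo])):
                _add_spot(img, y / px, x / px, m.puncta_amplitude,
                          m.psf_sigma_px)
        planes[ch] = img

    data = _assemble(m, planes, 0.0)
    cal = Calibration(pixel_size_xy=px)
    return CalibratedImage(data, ("channel", "y", "x"), cal,
                           list(m.channels)), m


def simulate_rotation_movie(
        manifest: RotationManifest) -> tuple[CalibratedImage, RotationManifest]:
    """Render a pole-channel time-lapse of a rigidly rotating spindle.

    The spindle rotates in the xy-plane about its centroid at
    ``rotation_rate_deg_per_min``; the true per-frame pole positions are
    recorded in the manifest.
    """
    m = dataclasses.replace(manifest)
    m.validate()
    px = m.pixel_size_um
    h, w = m.shape
    cx, cy = m.center_um if m.center_um is not None else _field_center(m.shape, px)
    r = m.spindle_length_um / 2.0
    truth = []
    frames = []
    for t in range(m.n_frames):
        ang = math.radians(m.initial_angle_deg +
                           m.rotation_rate_deg_per_min * m.frame_interval_min * t)
        p1 = (cx + r * math.cos(ang), cy + r * math.sin(ang))
        p2 = (cx - r * math.cos(ang), cy - r * math.sin(ang))
        truth.append([list(p1), list(p2)])
        img = np.zeros((h, w), dtype=float)
        for (pxu, pyu) in (p1, p2):
            _add_spot(img, pyu / px, pxu / px, m.pole_amplitude, m.psf_sigma_px)
        img += m.background_level
        frames.append(img)
    m.pole_positions_um = truth
    data = np.stack(frames, axis=0)
    if m.noise.enabled:
        data = m.noise.apply(data, _rng(m.seed, "noise"))
    cal = Calibration(pixel_size_xy=px, frame_interval=m.frame_interval_min,
                      time_unit="min")
    return CalibratedImage(data, ("time", "y", "x"), cal, []), m


def simulate_kymograph(
        manifest: KymographManifest) -> tuple[Kymograph, KymographManifest]:
    """Render a position × time kymograph with constant-velocity runs.

    Each run is a Gaussian ridge (σ ``ridge_sigma_px``) advancing
    ``velocity_um_s`` per second on a noisy background; the true
    (start, end, velocity) of every run is in the manifest.
    """
    m = dataclasses.replace(manifest)
    m.validate()
    px, dt = m.pixel_size_um, m.frame_interval_s
    n_cols = int(math.ceil(m.length_um / px)) + 1
    specs = m.run_specs()
    if m.n_frames is not None:
        n_frames = m.n_frames
    else:
        last = 1
        for r in specs:
            dur = (m.stationary_frames if r.velocity_um_s == 0
                   else int(math.ceil(r.duration_s / dt)) + 1)
            last = max(last, r.start_frame + dur)
        n_frames = last + 2
    mat = np.full((n_frames, n_cols), float(m.background_level))
    cols = np.arange(n_cols, dtype=float)
    for r in specs:
        dur_frames = (m.stationary_frames if r.velocity_um_s == 0
                      else int(math.ceil(r.duration_s / dt)) + 1)
        for k in range(dur_frames):
            t = r.start_frame + k
            if t >= n_frames:
                break
            x_um = r.start_um + r.velocity_um_s * k * dt
            c = x_um / px
            mat[t] += m.amplitude * np.exp(
                -((cols - c) ** 2) / (2.0 * m.ridge_sigma_px ** 2))
    if m.noise_on and m.snr > 0:
        sigma = m.amplitude / m.snr
        mat = mat + _rng(m.seed, "kymo").normal(0.0, sigma, size=mat.shape)
        mat = np.clip(mat, 0.0, None)
    return Kymograph(mat, pixel_size_um=px, frame_interval_s=dt), m


# ---------------------------------------------------------------------------
# manifest persistence

_MANIFEST_TYPES = {
    "BipolarManifest": BipolarManifest,
    "MonopolarManifest": MonopolarManifest,
    "RotationManifest": RotationManifest,
    "KymographManifest": KymographManifest,
}


def save_manifest(manifest, path: str | Path) -> Path:
    """Serialize a manifest (with its realized ground truth) to JSON."""
    d = dataclasses.asdict(manifest)
    d["__type__"] = type(manifest).__name__
    path = Path(path)
    path.write_text(json.dumps(d, indent=2, default=_jsonify))
    return path


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def load_manifest(path: str | Path):
    d = json.loads(Path(path).read_text())
    cls = _MANIFEST_TYPES[d.pop("__type__")]
    if "noise" in d and isinstance(d["noise"], dict):
        d["noise"] = NoiseModel(**d["noise"])
    for key in ("shape", "channels", "center_um", "pole_z_um",
                "pole_position_um"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    if "runs" in d:
        d["runs"] = [KymographRunSpec(**r) if isinstance(r, dict) else r
                     for r in d["runs"]]
    return cls(**d)
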