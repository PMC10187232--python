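"""ROI- and line-scan-based intensity quantification.

Covers four fixed-cell assays that share one toolbox:

* ``band_ratio`` — EB1/GFP peripheral-to-inner ratio in monopolar cells:
  mean intensity in a 2.5 µm band around the DNA ROI over the mean inside
  the ROI.
* ``tubulin_density`` — background-subtracted spindle-body and 4.5 µm-band
  tubulin intensities, reported separately.
* ``expression_level`` — background-subtracted spindle intensity
  normalized to the control-condition mean.
* ``linescan_quartile_ratio`` — peripheral/spindle localization from a
  20-px-wide line twice the kinetochore-mass length: outer quarters of the
  normalized position axis over the middle half.

Bands are built with a Euclidean distance transform sampled in µm, so a
stated physical width is isotropic regardless of pixel size.  Quartile
boundaries use exact quarters with half-open intervals ([0, 0.25),
[0.25, 0.75], (0.75, 1]); boundary samples belong to the middle half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import CalibratedImage, RoiMask
from .profiles import _sample_line

__all__ = [
    "BandRoi",
    "QuartileLine",
    "make_band",
    "background_subtracted_mean",
    "band_ratio",
    "tubulin_density",
    "expression_level",
    "linescan_quartile_ratio",
    "otsu_roi",
    "auto_background_roi",
]


@dataclass
class BandRoi:
    """An inner ROI plus the disjoint morphological band around it."""

    inner: RoiMask
    band: RoiMask
    width_um: float

    def __post_init__(self) -> None:
        if (self.inner.mask & self.band.mask).any():
            raise ValueError("inner and band ROIs must be disjoint")


@dataclass
class QuartileLine:
    """The localization line-scan geometry.

    Centered over the kinetochore mass, directed along the pole axis, with
    length twice the kinetochore-mass extent and a 20-px sampling width.
    """

    center_px: tuple[float, float]     # (x, y)
    direction: tuple[float, float]     # unit vector along pole axis
    length_px: float
    width_px: int = 20

    def endpoints(self) -> tuple[tuple[float, float], tuple[float, float]]:
        dx, dy = self.direction
        norm = math.hypot(dx, dy)
        if norm == 0:
            raise ValueError("direction vector is zero")
        dx, dy = dx / norm, dy / norm
        cx, cy = self.center_px
        h = self.length_px / 2.0
        return (cx - h * dx, cy - h * dy), (cx + h * dx, cy + h * dy)


def _as_plane(image, channel) -> np.ndarray:
    if isinstance(image, np.ndarray):
        return np.asarray(image, dtype=float)
    img = image.get_channel(channel) if channel is not None else image
    if "z" in img.axes:
        return np.asarray(img.data, dtype=float).max(axis=img.axis_index("z"))
    return img.plane()


def make_band(inner: RoiMask, width_um: float, pixel_size_um: float) -> BandRoi:
    """Build the ring of stated physical width around an inner ROI.

    Uses the Euclidean distance transform with µm sampling (isotropic in
    physical units); band = pixels at distance (0, width_um] from the ROI.
    Raises if the band would be clipped by the image border.
    """
    inner.require_nonempty("inner")
    if width_um <= 0:
        raise ValueError("band width must be > 0 µm")
    dist = ndimage.distance_transform_edt(
        ~inner.mask, sampling=(pixel_size_um, pixel_size_um))
    band = (dist > 0) & (dist <= width_um)
    edge = np.zeros_like(inner.mask)
    edge[0, :] = edge[-1, :] = True
    edge[:, 0] = edge[:, -1] = True
    if (band & edge).any() or (inner.mask & edge).any():
        raise ValueError("band of requested width does not fit in the image")
    return BandRoi(inner, RoiMask(band), width_um)


def background_subtracted_mean(image, channel, roi: RoiMask,
                               background_roi: RoiMask) -> float:
    """mean(channel over roi) − mean(channel over background ROI).

    May legitimately be negative (reported as-is); invariant to adding a
    constant to the whole image.
    """
    roi.require_nonempty("measurement")
    background_roi.require_nonempty("background")
    if (roi.mask & background_roi.mask).any():
        raise ValueError("measurement and background ROIs overlap")
    arr = _as_plane(image, channel)
    return float(arr[roi.mask].mean() - arr[background_roi.mask].mean())


def band_ratio(image, channel, inner_roi: RoiMask, band_width_um: float,
               background_roi: RoiMask | None = None) -> float:
    """mean(band) / mean(inner) for a band of stated µm width.

    By default no background subtraction (pure ratio form); pass a
    background ROI to subtract its mean from both regions first.
    """
    arr = _as_plane(image, channel)
    broi = make_band(inner_roi, band_width_um,
                     _pixel_size(image))
    bg = 0.0
    if background_roi is not None:
        background_roi.require_nonempty("background")
        bg = float(arr[background_roi.mask].mean())
    inner_mean = float(arr[broi.inner.mask].mean()) - bg
    band_mean = float(arr[broi.band.mask].mean()) - bg
    if inner_mean == 0:
        raise ZeroDivisionError(
            "inner ROI mean is zero: degenerate input for a ratio")
    return band_mean / inner_mean


def _pixel_size(image) -> float:
    if isinstance(image, CalibratedImage):
        return image.calibration.pixel_size_xy
    raise TypeError(
        "band operations need a CalibratedImage (physical band width)")


def tubulin_density(image, tubulin_channel, spindle_roi: RoiMask,
                    background_roi: RoiMask,
                    band_width_um: float = 4.5) -> tuple[float, float]:
    """Background-subtracted spindle and peripheral (band) tubulin means.

    The band is the 4.5 µm ring around the spindle ROI; background is an
    ROI in a region containing no cells.  The two values are returned
    separately (each is compared across conditions on its own).
    """
    arr = _as_plane(image, tubulin_channel)
    broi = make_band(spindle_roi, band_width_um, _pixel_size(image))
    background_roi.require_nonempty("background")
    bg = float(arr[background_roi.mask].mean())
    spindle = float(arr[broi.inner.mask].mean()) - bg
    peripheral = float(arr[broi.band.mask].mean()) - bg
    return spindle, peripheral


def expression_level(image, channel, spindle_roi: RoiMask,
                     background_roi: RoiMask, control_mean: float) -> float:
    """Background-subtracted spindle intensity over the control mean."""
    if not (control_mean > 0):
        raise ValueError(f"control_mean must be > 0, got {control_mean}")
    return background_subtracted_mean(image, channel, spindle_roi,
                                      background_roi) / control_mean


def linescan_quartile_ratio(image, channel, line: QuartileLine) -> float:
    """Peripheral/spindle ratio from the quartile line-scan.

    The profile is averaged over the line's 20-px width, positions are
    rescaled to [0, 1], and the ratio is the mean intensity on
    [0, 0.25) ∪ (0.75, 1] over the mean on [0.25, 0.75].
    """
    arr = _as_plane(image, channel)
    p0, p1 = line.endpoints()
    s, vals = _sample_line(arr, p0, p1, line.width_px)
    pos = s / s[-1]
    outer = (pos < 0.25) | (pos > 0.75)
    middle = ~outer
    mid_mean = float(vals[middle].mean())
    if mid_mean == 0:
        raise ZeroDivisionError(
            "middle-half mean is zero: degenerate input for a ratio")
    return float(vals[outer].mean()) / mid_mean


# ---------------------------------------------------------------------------
# ROI provenance helpers (the wet-lab workflow draws these by hand)

def otsu_roi(image, channel, close_px: int = 3) -> RoiMask:
    """Largest connected component above the Otsu threshold."""
    arr = _as_plane(image, channel)
    mask = arr > threshold_otsu(arr)
    if close_px:
        mask = ndimage.binary_closing(mask, structure=np.ones((close_px,) * 2))
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("Otsu segmentation found no foreground")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    return RoiMask(labels == (1 + int(np.argmax(sizes))))


def auto_background_roi(image, channel, tile_px: int = 32) -> RoiMask:
    """Darkest ``tile_px``-square tile containing no segmented foreground."""
    arr = _as_plane(image, channel)
    try:
        fg = otsu_roi(image, channel).mask
    except ValueError:
        fg = np.zeros_like(arr, dtype=bool)
    h, w = arr.shape
    best, best_mean = None, np.inf
    for y in range(0, h - tile_px + 1, tile_px):
        for x in range(0, w - tile_px + 1, tile_px):
            if fg[y:y + tile_px, x:x + tile_px].any():
                continue
            m = arr[y:y + tile_px, x:x + tile_px].mean()
            if m < best_mean:
                best, best_mean = (y, x), m
    if best is None:
        raise ValueError("no foreground-free tile for automatic background")
    mask = np.zeros_like(arr, dtype=bool)
    mask[best[0]:best[0] + tile_px, best[1]:best[1] + tile_px] = True
    return RoiMask(mask)
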