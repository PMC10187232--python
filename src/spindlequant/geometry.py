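"""Spindle pole detection, length, inter-pole angle, and rotation.

Coordinates are 0-based pixel indices ``(x, y[, z])`` referring to pixel
centers; all vector math happens in µm after applying the calibration
(x, y scaled by ``pixel_size_xy``, z by ``z_step`` — the ~0.25 µm z-step
vs ~0.11 µm pixels makes raw-index angles meaningless).

The inter-pole angle reproduces the manual-click contract: given the two
poles' (x, y, slice) triplets, the angle between the pole-to-pole vector
and the focal (xy) plane is computed from the dot product of the vector
with its xy-projection, in [0°, 90°].

Rotation displacement is the *full polyline path length* of a pole track
divided by elapsed minutes — not net start-to-end displacement; the two
differ for wobbling spindles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .io import CalibratedImage, Calibration

__all__ = [
    "Pole",
    "PolePair",
    "PoleTrack",
    "detect_poles",
    "spindle_length",
    "pole_axis_angle",
    "rotation_displacement",
    "track_pole",
]


@dataclass(frozen=True)
class Pole:
    """One spindle pole in pixel/slice coordinates."""

    x: float
    y: float
    z: float | None = None


@dataclass(frozen=True)
class PolePair:
    """The two poles of a bipolar spindle; p1 ≠ p2."""

    p1: Pole
    p2: Pole

    def __post_init__(self) -> None:
        if (self.p1.z is None) != (self.p2.z is None):
            raise ValueError("both poles must agree on having a z coordinate")
        if (self.p1.x, self.p1.y, self.p1.z) == (self.p2.x, self.p2.y, self.p2.z):
            raise ValueError("poles coincide; not a valid pole pair")

    @property
    def has_z(self) -> bool:
        return self.p1.z is not None

    def swapped(self) -> "PolePair":
        return PolePair(self.p2, self.p1)

    def vector_um(self, cal: Calibration) -> np.ndarray:
        """Pole-to-pole vector in µm; (dx, dy) or (dx, dy, dz)."""
        dx = (self.p2.x - self.p1.x) * cal.pixel_size_xy
        dy = (self.p2.y - self.p1.y) * cal.pixel_size_xy
        if self.has_z:
            cal.require("z_step")
            return np.array([dx, dy, (self.p2.z - self.p1.z) * cal.z_step])
        return np.array([dx, dy])


@dataclass
class PoleTrack:
    """Ordered (frame, x, y) positions of one tracked pole."""

    frames: np.ndarray
    xy_px: np.ndarray  # shape (n, 2), columns (x, y)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy_px = np.asarray(self.xy_px, dtype=float)
        if self.xy_px.shape != (len(self.frames), 2):
            raise ValueError("xy_px must be (n_frames, 2)")
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")


# ---------------------------------------------------------------------------
# detection

def _refine_centroid(arr: np.ndarray, y: int, x: int, half: int = 2
                     ) -> tuple[float, float]:
    """Sub-pixel refinement: intensity centroid of a 5×5 window."""
    h, w = arr.shape
    ylo, yhi = max(0, y - half), min(h, y + half + 1)
    xlo, xhi = max(0, x - half), min(w, x + half + 1)
    win = arr[ylo:yhi, xlo:xhi].astype(float)
    win = win - win.min()
    tot = win.sum()
    if tot <= 0:
        return float(y), float(x)
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    return float((yy * win).sum() / tot), float((xx * win).sum() / tot)


def detect_poles(image: CalibratedImage, channel="poles",
                 expected: int = 2, min_separation_px: int = 5,
                 threshold_rel: float = 0.2):
    """Locate the brightest well-separated pole spots.

    Returns a :class:`PolePair` for ``expected=2`` or a single
    :class:`Pole` for ``expected=1``.  Centers are refined to sub-pixel by
    the intensity centroid of a 5×5 window; for z-stacks the xy search
    runs on the max projection and each pole's z is the slice of maximal
    in-focus intensity at its xy position.

    Raises if fewer than ``expected`` maxima rise above
    ``threshold_rel × max`` (after light smoothing) — e.g. on a blank image.
    """
    if expected not in (1, 2):
        raise ValueError("expected must be 1 or 2")
    img = image.get_channel(channel) if channel is not None else image
    has_z = "z" in img.axes
    if has_z:
        stack = np.asarray(img.data, dtype=float)
        arr = stack.max(axis=img.axis_index("z"))
    else:
        arr = img.plane()
        stack = None
    sm = ndimage.gaussian_filter(arr, 1.0)
    if sm.max() <= sm.min():
        raise ValueError("no intensity structure in pole channel (blank image)")
    peaks = peak_local_max(sm, min_distance=min_separation_px,
                           threshold_abs=sm.min() + threshold_rel * (sm.max() - sm.min()),
                           num_peaks=expected + 3)
    if len(peaks) < expected:
        raise ValueError(
            f"found {len(peaks)} candidate pole(s), expected {expected}")
    # peak_local_max returns peaks sorted by decreasing intensity
    chosen = peaks[:expected]
    poles = []
    for (py, pxi) in chosen:
        cy, cx = _refine_centroid(arr, int(py), int(pxi))
        z = None
        if has_z:
            zi = img.axis_index("z")
            # mean in a 3×3 xy window per slice, at this pole
            y0, x0 = int(round(cy)), int(round(cx))
            sl = [slice(None)] * stack.ndim
            sl[img.axis_index("y")] = slice(max(0, y0 - 1), y0 + 2)
            sl[img.axis_index("x")] = slice(max(0, x0 - 1), x0 + 2)
            prof = stack[tuple(sl)].mean(
                axis=tuple(i for i in range(stack.ndim) if i != zi))
            z = float(np.argmax(prof))
        poles.append(Pole(cx, cy, z))
    if expected == 1:
        return poles[0]
    return PolePair(poles[0], poles[1])


# ---------------------------------------------------------------------------
# geometry

def spindle_length(poles: PolePair, cal: Calibration) -> float:
    """Euclidean pole-to-pole distance in µm (xy-plane if no z)."""
    return float(np.linalg.norm(poles.vector_um(cal)))


def pole_axis_angle(poles: PolePair, cal: Calibration) -> float:
    """Angle (degrees, [0, 90]) between the inter-pole axis and the focal plane.

    Computed via the dot product of the µm-scaled inter-pole vector with
    its xy-projection.  Requires z coordinates on both poles and a z-step
    calibration.
    """
    if not poles.has_z:
        raise ValueError("pole-axis angle needs z coordinates on both poles")
    v = poles.vector_um(cal)
    vxy = np.array([v[0], v[1], 0.0])
    nv = np.linalg.norm(v)
    nxy = np.linalg.norm(vxy)
    if nv == 0:
        raise ValueError("poles coincide")
    if nxy == 0:
        return 90.0
    cosang = float(np.dot(v, vxy) / (nv * nxy))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def rotation_displacement(track: PoleTrack, cal: Calibration) -> float:
    """Pole displacement in µm/min: polyline path length over elapsed time."""
    if len(track.frames) < 2:
        raise ValueError("need ≥ 2 frames to measure displacement")
    steps = np.diff(track.xy_px, axis=0) * cal.pixel_size_xy
    path_um = float(np.sqrt((steps ** 2).sum(axis=1)).sum())
    elapsed_min = (track.frames[-1] - track.frames[0]) * cal.frame_interval_min
    return path_um / elapsed_min


# ---------------------------------------------------------------------------
# tracking

def track_pole(movie: CalibratedImage, channel=None,
               start_xy: tuple[float, float] | None = None,
               search_radius_um: float = 2.0) -> PoleTrack:
    """Track one pole through a time-lapse by nearest-maximum linking.

    Each frame's candidate maxima within ``search_radius_um`` of the
    previous position are ranked by distance (ties broken by brightness);
    the chosen maximum is refined to sub-pixel by 5×5 centroid.  Frames
    with no candidate in range keep the previous position.
    """
    img = movie.get_channel(channel) if channel is not None else movie
    if "time" not in img.axes:
        raise ValueError("movie has no time axis")
    n_t = img.shape[img.axis_index("time")]
    px = movie.calibration.pixel_size_xy
    radius_px = search_radius_um / px
    positions = []
    prev = None
    for t in range(n_t):
        arr = img.get_frame(t).plane()
        sm = ndimage.gaussian_filter(arr, 1.0)
        peaks = peak_local_max(sm, min_distance=3,
                               threshold_abs=sm.min() + 0.2 * (sm.max() - sm.min()))
        if t == 0:
            if start_xy is not None:
                ref = np.array([start_xy[1], start_xy[0]], dtype=float)
                d = np.linalg.norm(peaks - ref, axis=1)
                pick = peaks[int(np.argmin(d))]
            elif len(peaks):
                pick = peaks[0]  # brightest
            else:
                raise ValueError("no pole candidate in first frame")
        else:
            if len(peaks) == 0:
                positions.append(prev)
                continue
            d = np.linalg.norm(peaks - np.array([prev[1], prev[0]]), axis=1)
            inside = np.nonzero(d <= radius_px)[0]
            if len(inside) == 0:
                positions.append(prev)
                continue
            dmin = d[inside].min()
            # ties (within a tenth of a pixel) broken by brightness
            tied = inside[d[inside] <= dmin + 0.1]
            pick = tied[int(np.argmax(sm[peaks[tied, 0], peaks[tied, 1]]))]
            pick = peaks[pick]
        cy, cx = _refine_centroid(arr, int(pick[0]), int(pick[1]))
        prev = (cx, cy)
        positions.append(prev)
    return PoleTrack(np.arange(n_t), np.array(positions, dtype=float))
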