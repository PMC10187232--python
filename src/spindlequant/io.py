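"""Calibrated image and table I/O shared by every assay.

Conventions
-----------
* Pixel indices are 0-based and refer to pixel *centers*; physical positions
  are ``index * calibration`` in µm.
* In-memory axis order is normalized to ``(channel, time, z, y, x)`` with
  absent axes dropped.  ``y`` and ``x`` are always present.
* Calibration supplied by config takes precedence over TIFF metadata, since
  fixed-cell and live assays are typically acquired on different optics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "Calibration",
    "CalibratedImage",
    "RoiMask",
    "read_calibrated_tiff",
    "write_calibrated_tiff",
    "load_calibration",
    "validate_event_table",
    "validate_group_table",
    "write_results_table",
    "read_results_table",
]

#: canonical axis order; absent axes are dropped, never reordered
AXIS_ORDER = ("channel", "time", "z", "y", "x")

#: single-letter codes used in TIFF metadata (ImageJ/OME style)
_AXIS_CODES = {"C": "channel", "T": "time", "Z": "z", "Y": "y", "X": "x",
               "S": "channel", "Q": "z", "I": "time"}


class CalibrationError(ValueError):
    """A required physical calibration field is missing or invalid."""


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of an acquisition.

    Parameters
    ----------
    pixel_size_xy : float
        Lateral pixel size, µm/pixel. Required, strictly positive.
    z_step : float, optional
        Axial step, µm/slice. Only needed for z-stack geometry.
    frame_interval : float, optional
        Time between frames, in ``time_unit`` per frame.
    time_unit : str
        ``"s"`` or ``"min"``; unit of ``frame_interval``.
    """

    pixel_size_xy: float
    z_step: float | None = None
    frame_interval: float | None = None
    time_unit: str = "s"

    def __post_init__(self) -> None:
        if not (self.pixel_size_xy > 0):
            raise CalibrationError(
                f"pixel_size_xy must be > 0, got {self.pixel_size_xy!r}")
        if self.z_step is not None and not (self.z_step > 0):
            raise CalibrationError(f"z_step must be > 0, got {self.z_step!r}")
        if self.frame_interval is not None and not (self.frame_interval > 0):
            raise CalibrationError(
                f"frame_interval must be > 0, got {self.frame_interval!r}")
        if self.time_unit not in ("s", "min"):
            raise CalibrationError(
                f"time_unit must be 's' or 'min', got {self.time_unit!r}")

    def require(self, *fields: str) -> None:
        """Fail loudly if any named calibration field is absent.

        Operations never assume a default for a missing physical scale.
        """
        for name in fields:
            if getattr(self, name) is None:
                raise CalibrationError(
                    f"operation requires calibration field {name!r}, "
                    f"which is not set")

    @property
    def frame_interval_min(self) -> float:
        """Frame interval expressed in minutes."""
        self.require("frame_interval")
        return (self.frame_interval / 60.0 if self.time_unit == "s"
                else float(self.frame_interval))

    @property
    def frame_interval_s(self) -> float:
        """Frame interval expressed in seconds."""
        self.require("frame_interval")
        return (float(self.frame_interval) if self.time_unit == "s"
                else self.frame_interval * 60.0)


@dataclass
class CalibratedImage:
    """Intensity data with named axes and physical calibration.

    ``data`` axes follow :data:`AXIS_ORDER` restricted to ``axes``.
    Intensities must be finite and non-negative (unitless reals; camera
    bit depth is deliberately not modelled).
    """

    data: np.ndarray
    axes: tuple[str, ...]
    calibration: Calibration
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.axes = tuple(self.axes)
        if len(self.axes) != self.data.ndim:
            raise ValueError(
                f"{len(self.axes)} axis names for {self.data.ndim}-d data")
        if len(set(self.axes)) != len(self.axes):
            raise ValueError(f"duplicate axis names in {self.axes}")
        unknown = set(self.axes) - set(AXIS_ORDER)
        if unknown:
            raise ValueError(f"unknown axis names {sorted(unknown)}")
        if self.axes != tuple(a for a in AXIS_ORDER if a in self.axes):
            raise ValueError(
                f"axes must follow canonical order {AXIS_ORDER}, got {self.axes}")
        if "y" not in self.axes or "x" not in self.axes:
            raise ValueError("y and x axes are mandatory")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if "channel" in self.axes:
            nc = self.data.shape[self.axes.index("channel")]
            if self.channel_names and len(self.channel_names) != nc:
                raise ValueError(
                    f"{len(self.channel_names)} channel names for {nc} channels")
            if not self.channel_names:
                self.channel_names = [f"ch{i}" for i in range(nc)]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def axis_index(self, name: str) -> int:
        try:
            return self.axes.index(name)
        except ValueError:
            raise KeyError(f"image has no {name!r} axis (axes={self.axes})")

    def get_channel(self, channel: int | str) -> "CalibratedImage":
        """Extract one channel, dropping the channel axis."""
        if "channel" not in self.axes:
            if channel in (0, self.channel_names[0] if self.channel_names else None):
                return self
            raise KeyError("image has no channel axis")
        if isinstance(channel, str):
            try:
                channel = self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"no channel {channel!r}; have {self.channel_names}")
        idx = self.axis_index("channel")
        data = np.take(self.data, channel, axis=idx)
        axes = tuple(a for a in self.axes if a != "channel")
        return CalibratedImage(data, axes, self.calibration, [])

    def get_frame(self, t: int) -> "CalibratedImage":
        """Extract one timepoint, dropping the time axis."""
        idx = self.axis_index("time")
        data = np.take(self.data, t, axis=idx)
        axes = tuple(a for a in self.axes if a != "time")
        return CalibratedImage(data, axes, self.calibration,
                               list(self.channel_names))

    def plane(self, channel: int | str | None = None, t: int | None = None,
              z: int | None = None) -> np.ndarray:
        """Return a single (y, x) plane as a float array."""
        img = self
        if channel is not None:
            img = img.get_channel(channel)
        if t is not None:
            img = img.get_frame(t)
        if z is not None:
            data = np.take(img.data, z, axis=img.axis_index("z"))
        elif "z" in img.axes:
            raise ValueError("z-stack: specify which z plane")
        else:
            data = img.data
        if data.ndim != 2:
            raise ValueError(f"not reducible to a plane; axes left: {img.axes}")
        return np.asarray(data, dtype=float)


@dataclass
class RoiMask:
    """Boolean raster congruent with one y–x plane."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-d (y, x)")

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    def require_nonempty(self, what: str = "ROI") -> None:
        if self.is_empty:
            raise ValueError(f"{what} mask is empty; cannot measure intensity")


# ---------------------------------------------------------------------------
# calibration configs

def load_calibration(source: str | Path | Mapping) -> Calibration:
    """Build a :class:`Calibration` from a YAML/JSON file or a mapping.

    Raises :class:`CalibrationError` naming the missing field when
    ``pixel_size_xy`` is absent.
    """
    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        text = Path(source).read_text()
        cfg = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(cfg, Mapping):
            raise CalibrationError(f"config {source} is not a mapping")
        cfg = dict(cfg)
    if "pixel_size_xy" not in cfg or cfg["pixel_size_xy"] is None:
        raise CalibrationError(
            "calibration config missing required field 'pixel_size_xy'")
    known = {"pixel_size_xy", "z_step", "frame_interval", "time_unit"}
    extra = set(cfg) - known
    if extra:
        raise CalibrationError(f"unknown calibration fields {sorted(extra)}")
    return Calibration(**cfg)


# ---------------------------------------------------------------------------
# TIFF I/O

def _axes_from_string(s: str) -> tuple[str, ...]:
    out = []
    for ch in s.upper():
        if ch not in _AXIS_CODES:
            raise ValueError(f"cannot interpret TIFF axis code {ch!r} in {s!r}")
        out.append(_AXIS_CODES[ch])
    return tuple(out)


def _normalize_axes(data: np.ndarray, axes: Sequence[str]) -> tuple[np.ndarray, tuple[str, ...]]:
    axes = tuple(axes)
    order = [axes.index(a) for a in AXIS_ORDER if a in axes]
    if len(order) != data.ndim:
        raise ValueError(f"axes {axes} do not cover {data.ndim}-d data")
    return np.transpose(data, order), tuple(axes[i] for i in order)


def read_calibrated_tiff(
    path: str | Path,
    calibration: Calibration | str | Path | Mapping,
    axes: str | Sequence[str] | None = None,
    channel_names: Sequence[str] | None = None,
) -> CalibratedImage:
    """Read a (multi-page) TIFF into a :class:`CalibratedImage`.

    Axis layout is taken from TIFF metadata unless ``axes`` overrides it
    (single-letter codes like ``"ctzyx"`` or a sequence of names).  The axis
    layout must be resolvable from one of the two, else this raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not isinstance(calibration, Calibration):
        calibration = load_calibration(calibration)
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        meta_axes = series.axes  # e.g. "CYX"
        names = None
        shaped = tf.shaped_metadata
        if shaped and "spindlequant_channels" in shaped[0]:
            names = json.loads(shaped[0]["spindlequant_channels"])
    if axes is not None:
        if isinstance(axes, str):
            axes_t = _axes_from_string(axes)
        else:
            axes_t = tuple(_AXIS_CODES[a.upper()] if len(a) == 1 else a
                           for a in axes)
    else:
        try:
            axes_t = _axes_from_string(meta_axes)
        except ValueError as e:
            raise ValueError(
                f"axis layout of {path} is ambiguous ({meta_axes!r}); "
                f"pass axes= explicitly") from e
    if len(axes_t) != data.ndim:
        raise ValueError(
            f"declared axes {axes_t} do not match {data.ndim}-d data in {path}")
    data, axes_t = _normalize_axes(data, axes_t)
    if channel_names is not None:
        names = list(channel_names)
    return CalibratedImage(data, axes_t, calibration, list(names or []))


def write_calibrated_tiff(image: CalibratedImage, path: str | Path) -> Path:
    """Write a :class:`CalibratedImage` to TIFF, preserving axes and names."""
    path = Path(path)
    codes = {"channel": "C", "time": "T", "z": "Z", "y": "Y", "x": "X"}
    axstr = "".join(codes[a] for a in image.axes)
    meta: dict = {"axes": axstr}
    if image.channel_names:
        meta["spindlequant_channels"] = json.dumps(image.channel_names)
    tifffile.imwrite(str(path), image.data, metadata=meta,
                     photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# tables

EVENT_COLUMNS = ["cell_id", "neb_frame", "anaphase_frame", "movie_end_frame"]
GROUP_COLUMNS = ["condition", "replicate", "cell_id", "metric", "value"]


def validate_event_table(events: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-cell event table (NEB / anaphase-onset frames).

    ``neb_frame`` and ``anaphase_frame`` may be missing (NaN); when both are
    present anaphase must come strictly after NEB, and no event may exceed
    ``movie_end_frame``.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    ev = events.copy()
    if ev["movie_end_frame"].isna().any():
        raise ValueError("movie_end_frame is required for every cell")
    both = ev["neb_frame"].notna() & ev["anaphase_frame"].notna()
    bad = both & (ev["anaphase_frame"] <= ev["neb_frame"])
    if bad.any():
        raise ValueError(
            f"anaphase_frame must be > neb_frame; offending cells: "
            f"{ev.loc[bad, 'cell_id'].tolist()}")
    for col in ("neb_frame", "anaphase_frame"):
        over = ev[col].notna() & (ev[col] > ev["movie_end_frame"])
        if over.any():
            raise ValueError(
                f"{col} exceeds movie_end_frame for cells "
                f"{ev.loc[over, 'cell_id'].tolist()}")
    return ev


def validate_group_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the long-format results table used by the statistics stage."""
    missing = [c for c in GROUP_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"group table missing columns {missing}")
    key = ["condition", "replicate", "cell_id", "metric"]
    dup = table.duplicated(subset=key)
    if dup.any():
        raise ValueError(
            f"duplicate (condition, replicate, cell, metric) rows: "
            f"{table.loc[dup, key].to_dict('records')[:5]}")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValueError("group table values must be finite reals")
    return table


def write_results_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a validated group table as CSV with stable column order."""
    table = validate_group_table(table) if len(table) else table
    missing = [c for c in GROUP_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"group table missing columns {missing}")
    path = Path(path)
    table.loc[:, GROUP_COLUMNS].to_csv(path, index=False)
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_group_table(df) if len(df) else df
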