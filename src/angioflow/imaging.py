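"""Image-sequence I/O, calibration and coordinate conventions.

Every other module relies on the conventions fixed here:

* Coordinates are 0-based ``(row, col)``; ranges are half-open.
* Time index 0 is acquisition start; frame *k* is sampled at ``k * frame_interval_s``.
* Pixel spacing is isotropic (cm per pixel). Anisotropic metadata is rejected
  rather than silently averaged, because downstream distance and area math
  assume a single scale.
* Intensities are arbitrary linear detector units, stored as float64.

Supported containers:

* native compressed array archive (``.npz``) — the canonical lossless format,
* multi-page TIFF (read/write, calibration carried in the image description),
* multi-frame grayscale DICOM (read-only; frame time and pixel spacing taken
  from standard tags, no vendor private-tag dialects).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import os
from pathlib import Path

import numpy as np

from .errors import CalibrationError

__all__ = [
    "Modality",
    "ImageSequence",
    "ROI",
    "read_sequence",
    "write_sequence",
    "load_config",
    "save_config",
]


class Modality(str, enum.Enum):
    """Imaging mode: subtracted angiography or unsubtracted fluoroscopy.

    DSA frames are background-subtracted, so contrast arrival *increases*
    intensity. Fluoroscopic frames show the vessel darkening on a bright
    background; polarity handling lives in :mod:`angioflow.tdc` and
    :mod:`angioflow.geometry`.
    """

    DSA = "DSA"
    FLUORO = "FLUORO"


@dataclasses.dataclass(frozen=True)
class ImageSequence:
    """A time-ordered stack of 2-D frames with temporal/spatial calibration.

    Parameters
    ----------
    frames
        3-D array ``(time, rows, cols)`` of finite intensities (arbitrary
        linear detector units).
    frame_interval_s
        Seconds per sample (the sampling interval Δt).
    pixel_spacing_cm
        Isotropic centimetres per pixel.
    modality
        :class:`Modality` tag (accepts the enum or its string value).
    """

    frames: np.ndarray
    frame_interval_s: float
    pixel_spacing_cm: float
    modality: Modality = Modality.DSA

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (time, rows, cols); got shape {frames.shape}")
        if frames.shape[0] < 2:
            raise ValueError("an image sequence needs at least 2 frames")
        if not np.all(np.isfinite(frames)):
            raise ValueError("frames contain non-finite intensities")
        if not (np.isfinite(self.frame_interval_s) and self.frame_interval_s > 0):
            raise CalibrationError(f"frame_interval_s must be > 0; got {self.frame_interval_s}")
        if not (np.isfinite(self.pixel_spacing_cm) and self.pixel_spacing_cm > 0):
            raise CalibrationError(f"pixel_spacing_cm must be > 0; got {self.pixel_spacing_cm}")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_interval_s", float(self.frame_interval_s))
        object.__setattr__(self, "pixel_spacing_cm", float(self.pixel_spacing_cm))
        object.__setattr__(self, "modality", Modality(self.modality))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times_s(self) -> np.ndarray:
        """Sample times, frame 0 at acquisition start (t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageSequence):
            return NotImplemented
        return (
            self.frames.shape == other.frames.shape
            and np.array_equal(self.frames, other.frames)
            and self.frame_interval_s == other.frame_interval_s
            and self.pixel_spacing_cm == other.pixel_spacing_cm
            and self.modality == other.modality
        )


@dataclasses.dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, 0-based half-open pixel ranges."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.row_start < self.row_end and self.col_start < self.col_end):
            raise ValueError(f"empty or inverted ROI: {self}")
        if min(self.row_start, self.col_start) < 0:
            raise ValueError(f"negative ROI indices: {self}")

    def validate_within(self, frame_shape: tuple[int, int]) -> None:
        rows, cols = frame_shape
        if self.row_end > rows or self.col_end > cols:
            raise ValueError(f"ROI {self} exceeds frame shape {frame_shape}")

    @property
    def center_row(self) -> float:
        return (self.row_start + self.row_end - 1) / 2.0

    @property
    def center_col(self) -> float:
        return (self.col_start + self.col_end - 1) / 2.0

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_start, self.row_end), slice(self.col_start, self.col_end)


_TIFF_SUFFIXES = {".tif", ".tiff"}
_DICOM_SUFFIXES = {".dcm", ".dicom"}


def write_sequence(seq: ImageSequence, path: str | os.PathLike) -> None:
    """Write a sequence to the native archive (``.npz``) or a TIFF stack.

    The native archive round-trips bit-identically. TIFF stores the
    calibration as JSON in the image-description tag.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npz":
        np.savez_compressed(
            path,
            frames=seq.frames,
            frame_interval_s=np.float64(seq.frame_interval_s),
            pixel_spacing_cm=np.float64(seq.pixel_spacing_cm),
            modality=np.str_(seq.modality.value),
        )
    elif suffix in _TIFF_SUFFIXES:
        import tifffile

        meta = {
            "frame_interval_s": seq.frame_interval_s,
            "pixel_spacing_cm": seq.pixel_spacing_cm,
            "modality": seq.modality.value,
        }
        tifffile.imwrite(
            path, seq.frames, photometric="minisblack", description=json.dumps(meta)
        )
    else:
        raise ValueError(f"unsupported output format: {path.name!r} (use .npz or .tif)")


def read_sequence(path: str | os.PathLike, overrides: dict | None = None) -> ImageSequence:
    """Read an image sequence from disk and validate it.

    Calibration (frame interval, pixel spacing, modality) is taken from file
    metadata when present, else from ``overrides``
    (keys ``frame_interval_s``, ``pixel_spacing_cm``, ``modality``).
    Missing calibration with no override raises :class:`CalibrationError`.
    """
    path = Path(path)
    overrides = dict(overrides or {})
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".npz":
        frames, meta = _read_npz(path)
    elif suffix in _TIFF_SUFFIXES:
        frames, meta = _read_tiff(path)
    elif suffix in _DICOM_SUFFIXES:
        frames, meta = _read_dicom(path)
    else:
        raise ValueError(f"unrecognized sequence format: {path.name!r}")

    def pick(key: str):
        if meta.get(key) is not None:
            return meta[key]
        if key in overrides:
            return overrides[key]
        raise CalibrationError(f"{key} not present in {path.name} and no override given")

    if frames.ndim == 2:
        raise ValueError(f"{path.name} holds a single frame; a sequence needs >= 2")
    modality = meta.get("modality") or overrides.get("modality") or Modality.DSA
    return ImageSequence(
        frames=frames,
        frame_interval_s=float(pick("frame_interval_s")),
        pixel_spacing_cm=float(pick("pixel_spacing_cm")),
        modality=Modality(modality),
    )


def _read_npz(path: Path):
    with np.load(path) as npz:
        frames = np.asarray(npz["frames"])
        meta = {
            "frame_interval_s": float(npz["frame_interval_s"]),
            "pixel_spacing_cm": float(npz["pixel_spacing_cm"]),
            "modality": str(npz["modality"]),
        }
    return frames, meta


def _read_tiff(path: Path):
    import tifffile

    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        desc = tif.pages[0].description or ""
    meta: dict = {}
    try:
        parsed = json.loads(desc)
        if isinstance(parsed, dict):
            meta = {
                "frame_interval_s": parsed.get("frame_interval_s"),
                "pixel_spacing_cm": parsed.get("pixel_spacing_cm"),
                "modality": parsed.get("modality"),
            }
    except (json.JSONDecodeError, TypeError):
        pass
    return np.asarray(frames), meta


def _read_dicom(path: Path):
    import pydicom

    ds = pydicom.dcmread(path)
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    if n_frames < 2:
        raise ValueError(f"{path.name}: multi-frame DICOM required (NumberOfFrames >= 2)")
    frames = ds.pixel_array.astype(np.float64)
    if frames.ndim != 3:
        raise ValueError(f"{path.name}: expected grayscale multi-frame pixel data")

    meta: dict = {"frame_interval_s": None, "pixel_spacing_cm": None, "modality": None}
    frame_time_ms = getattr(ds, "FrameTime", None)
    if frame_time_ms:
        meta["frame_interval_s"] = float(frame_time_ms) / 1000.0
    elif getattr(ds, "CineRate", None):
        meta["frame_interval_s"] = 1.0 / float(ds.CineRate)

    spacing = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
    if spacing is not None:
        sr, sc = float(spacing[0]), float(spacing[1])
        if abs(sr - sc) > 1e-9 * max(sr, sc):
            raise CalibrationError(
                f"{path.name}: anisotropic pixel spacing {sr} x {sc} mm is not supported"
            )
        meta["pixel_spacing_cm"] = sr / 10.0  # DICOM spacing is mm
    return frames, meta


# ---------------------------------------------------------------------------
# Flat key-value configuration files


def _coerce(value: str):
    low = value.strip()
    if low.lower() in {"true", "false"}:
        return low.lower() == "true"
    for cast in (int, float):
        try:
            return cast(low)
        except ValueError:
            continue
    return low


def load_config(path: str | os.PathLike) -> dict:
    """Parse a flat ``key = value`` text configuration.

    Lines starting with ``#`` (or blank lines) are ignored; values are
    auto-coerced to int/float/bool where possible.
    """
    config: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line (expected 'key = value'): {raw!r}")
        key, _, value = line.partition("=")
        config[key.strip()] = _coerce(value)
    return config


def save_config(config: dict, path: str | os.PathLike) -> None:
    lines = [f"{key} = {value}" for key, value in config.items()]
    Path(path).write_text("\n".join(lines) + "\n")
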