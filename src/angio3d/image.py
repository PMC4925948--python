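"""Grayscale angiogram raster with pixel-spacing metadata, plus file readers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Image2D:
    """A 2D grayscale image, intensities in [0, 1], row-major 0-based (row, col).

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Intensities normalized to [0, 1].
    pixel_spacing_mm : tuple of float
        Physical size of a pixel along (row, col), in millimetres.
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D expects a 2D array")
        if min(self.pixels.shape) < 16:
            raise ValueError("image dimensions must both be >= 16")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]; normalize first")
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def normalize_intensities(raw: np.ndarray) -> np.ndarray:
    """Rescale an arbitrary-range array to [0, 1] (constant input maps to 0)."""
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-30:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def load_image(path, pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)) -> Image2D:
    """Read a grayscale PNG/TIFF image and normalize intensities to [0, 1]."""
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:  # collapse RGB(A) to luminance
        raw = raw[..., :3].mean(axis=-1)
    return Image2D(normalize_intensities(raw), pixel_spacing_mm)


def load_dicom(path, frame: int = 0):
    """Read a DICOM file: image plus acquisition geometry when present.

    Returns ``(Image2D, dict)`` where the dict carries ``sid_mm``,
    ``pixel_size_mm``, ``primary_angle_deg``, ``secondary_angle_deg`` for the
    tags found in the file.  Requires the optional ``pydicom`` dependency.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "DICOM input requires the optional 'pydicom' package "
            "(pip install angio3d[dicom])"
        ) from exc

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim == 3:  # cine: pick one frame
        arr = arr[frame]
    geom: dict = {}
    if "DistanceSourceToDetector" in ds:
        geom["sid_mm"] = float(ds.DistanceSourceToDetector)
    if "ImagerPixelSpacing" in ds:
        geom["pixel_size_mm"] = float(ds.ImagerPixelSpacing[0])
    elif "PixelSpacing" in ds:
        geom["pixel_size_mm"] = float(ds.PixelSpacing[0])
    if "PositionerPrimaryAngle" in ds:
        geom["primary_angle_deg"] = float(ds.PositionerPrimaryAngle)
    if "PositionerSecondaryAngle" in ds:
        geom["secondary_angle_deg"] = float(ds.PositionerSecondaryAngle)
    spacing = geom.get("pixel_size_mm", 1.0)
    return Image2D(normalize_intensities(arr), (spacing, spacing), meta=geom), geom
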