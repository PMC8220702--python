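"""Reading CT slices and display windowing.

Coordinates are 0-based ``(row, col)`` everywhere in this package. Pixel
spacing is carried in cm/px; DICOM stores it in mm. Slices with
non-square pixels are resampled to the finer spacing so the 32-pixel size
criterion downstream always refers to isotropic pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "CTSlice",
    "FormatError",
    "MetadataError",
    "read_ct_slice",
    "apply_window",
    "DEFAULT_WINDOW_CENTER",
    "DEFAULT_WINDOW_WIDTH",
]

# conventional lung window, used when the file carries no window tags
DEFAULT_WINDOW_CENTER = -600.0
DEFAULT_WINDOW_WIDTH = 1500.0


class FormatError(ValueError):
    """File is not a usable single-frame image with pixel data."""


class MetadataError(ValueError):
    """Required metadata (e.g. PixelSpacing) is missing."""


@dataclass
class CTSlice:
    """A calibrated CT slice: intensity grid plus measurement metadata."""

    pixels: np.ndarray
    spacing_cm: tuple[float, float]  # (row, col), cm per pixel
    window_center: float = DEFAULT_WINDOW_CENTER
    window_width: float = DEFAULT_WINDOW_WIDTH
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if self.spacing_cm[0] <= 0 or self.spacing_cm[1] <= 0:
            raise ValueError("pixel spacings must be positive")
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")

    @property
    def iso_spacing_cm(self) -> float:
        """Isotropic spacing; valid after reader normalization."""
        r, c = self.spacing_cm
        if abs(r - c) > 1e-9 * max(r, c):
            raise ValueError("slice has non-square pixels; resample first")
        return r


def _first_number(value) -> float:
    """DICOM window tags may be multi-valued; take the first entry."""
    try:
        return float(value[0])
    except (TypeError, IndexError):
        return float(value)


def read_ct_slice(
    path: str | Path,
    window_center: float | None = None,
    window_width: float | None = None,
) -> CTSlice:
    """Read a single-frame DICOM into a :class:`CTSlice`.

    Applies RescaleSlope/Intercept, converts PixelSpacing mm to cm, fills
    missing window tags with the lung-window defaults, and resamples
    non-square pixels to the finer spacing (bicubic) so measurement can
    assume isotropic pixels.

    Raises
    ------
    FormatError
        if the file does not parse or has no pixel data.
    MetadataError
        if PixelSpacing is absent (physical measurement is impossible).
    """
    import pydicom

    try:
        ds = pydicom.dcmread(str(path), force=True)
        pixels = ds.pixel_array.astype(float)
    except Exception as exc:
        raise FormatError(f"cannot read pixel data from {path}: {exc}") from exc
    if pixels.ndim != 2:
        raise FormatError(f"{path}: expected a single-frame 2-D image")

    if "PixelSpacing" not in ds:
        raise MetadataError(f"{path}: PixelSpacing tag missing; cannot measure")
    row_mm, col_mm = (float(v) for v in ds.PixelSpacing)

    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = pixels * slope + intercept

    wc = window_center
    ww = window_width
    if wc is None:
        wc = _first_number(ds.WindowCenter) if "WindowCenter" in ds else DEFAULT_WINDOW_CENTER
    if ww is None:
        ww = _first_number(ds.WindowWidth) if "WindowWidth" in ds else DEFAULT_WINDOW_WIDTH

    spacing = (row_mm / 10.0, col_mm / 10.0)
    if abs(spacing[0] - spacing[1]) > 1e-9 * max(spacing):
        fine = min(spacing)
        zoom = (spacing[0] / fine, spacing[1] / fine)
        pixels = ndimage.zoom(pixels, zoom, order=3, grid_mode=True, mode="nearest")
        spacing = (fine, fine)

    return CTSlice(
        pixels=pixels,
        spacing_cm=spacing,
        window_center=float(wc),
        window_width=float(ww),
        source_id=str(getattr(ds, "SOPInstanceUID", Path(path).name)),
    )


def apply_window(ct: CTSlice) -> np.ndarray:
    """Map calibrated intensities to display range [0, 1].

    ``value = clip((p - (center - width/2)) / width, 0, 1)`` — the linear
    window/level transform, monotone non-decreasing in the input.
    """
    lo = ct.window_center - ct.window_width / 2.0
    return np.clip((ct.pixels - lo) / ct.window_width, 0.0, 1.0)
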