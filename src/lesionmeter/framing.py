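"""Geometric canonicalization: cm↔px conversion, bicubic rescaling,
128×128 framing, and label-preserving training augmentation.

The central convention: a lesion whose measured diameter is ``M_px``
pixels is brought to a canonical apparent size of exactly 32 px by
magnifying the image ``32 / M_px`` times with bicubic interpolation, then
cropping a 128×128 frame centered on the measurement point. Training
frames are generated by perturbing that canonical magnification (zoom)
and the frame center (shift), which keeps the larger/smaller-than-32-px
label computable exactly from the zoom factor.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "SizeLabel",
    "Frame",
    "AugmentationPolicy",
    "cm_to_pixels",
    "canonical_magnification",
    "resample",
    "crop_frame",
    "extract_frame",
    "prepare_training_frames",
    "write_frame_manifest",
    "read_annotations",
]

FRAME_SIZE = 32 * 4  # 128: four canonical lesion diameters across the frame
SIZE_THRESHOLD_PX = 32.0
PAD_FILL = 0.0  # air-like, after windowing


class SizeLabel(str, Enum):
    SMALLER = "SMALLER"
    LARGER = "LARGER"


@dataclass
class Frame:
    """A 128×128 patch at a known magnification, optionally labeled."""

    patch: np.ndarray
    magnification: float
    source_spacing_cm: float = float("nan")
    frame_center_source: tuple[float, float] = (float("nan"), float("nan"))
    label: SizeLabel | None = None
    apparent_size_px: float | None = None
    zoom: float | None = None
    shift: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.patch.shape != (FRAME_SIZE, FRAME_SIZE):
            raise ValueError(f"patch must be {FRAME_SIZE}x{FRAME_SIZE}")
        if self.label is not None and self.apparent_size_px is not None:
            expected = SizeLabel.LARGER if self.apparent_size_px > SIZE_THRESHOLD_PX else SizeLabel.SMALLER
            if self.label is not expected and self.apparent_size_px != SIZE_THRESHOLD_PX:
                raise ValueError("label inconsistent with apparent_size_px")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Zoom/shift augmentation settings for training-frame generation.

    Zoom factors default to a geometric grid over [0.5, 2.0] (apparent
    sizes 16–64 px), symmetric about the 32-px decision boundary. Frames
    whose apparent size falls within ``exclusion_band_px`` of the
    boundary are dropped: their labels would be arbitrary.
    """

    zoom_factors: tuple[float, ...] = tuple(float(z) for z in np.geomspace(0.5, 2.0, 16))
    max_shift_px: int = 32
    per_image_count: int = 16
    balance: bool = False
    exclusion_band_px: float = 0.5

    def __post_init__(self) -> None:
        if self.per_image_count < 1:
            raise ValueError("per_image_count must be >= 1")
        if self.max_shift_px < 0:
            raise ValueError("max_shift_px must be >= 0")
        if self.exclusion_band_px < 0:
            raise ValueError("exclusion_band_px must be >= 0")
        if any(z <= 0 for z in self.zoom_factors):
            raise ValueError("zoom factors must be positive")


def cm_to_pixels(measurement_cm: float, spacing_cm: float) -> float:
    """Convert a physical measurement to pixels: ``M_px = cm / spacing``."""
    if measurement_cm <= 0 or spacing_cm <= 0:
        raise ValueError("measurement and spacing must be positive")
    return measurement_cm / spacing_cm


def canonical_magnification(m_px: float) -> float:
    """Magnification ``32 / M_px`` that renders the lesion exactly 32 px."""
    if m_px <= 0:
        raise ValueError("M_px must be positive")
    return SIZE_THRESHOLD_PX / m_px


def resample(image: np.ndarray, magnification: float, fill: float = PAD_FILL) -> np.ndarray:
    """Bicubic rescale; output dimensions are ``round(input × magnification)``.

    Grid-cell semantics: pixel-to-pixel distances scale by the (effective)
    magnification factor.
    """
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    image = np.asarray(image, dtype=float)
    out_shape = tuple(int(round(s * magnification)) for s in image.shape)
    if min(out_shape) < 1:
        raise ValueError("magnification collapses the image below 1x1")
    return ndimage.zoom(
        image, magnification, order=3, grid_mode=True, mode="grid-constant", cval=fill
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def map_point(point: tuple[float, float], in_shape, out_shape) -> tuple[int, int]:
    """Map a source pixel index into a rescaled grid (round half away from zero)."""
    out = []
    for p, n_in, n_out in zip(point, in_shape, out_shape):
        scale = n_out / n_in
        out.append(_round_half_away((p + 0.5) * scale - 0.5))
    return tuple(out)


def crop_frame(
    image: np.ndarray,
    center: tuple[int, int],
    size: int = FRAME_SIZE,
    fill: float = PAD_FILL,
) -> np.ndarray:
    """``size``×``size`` window with ``center`` at index ``size // 2``.

    Out-of-bounds regions are padded with ``fill``.
    """
    image = np.asarray(image, dtype=float)
    r, c = int(center[0]), int(center[1])
    if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
        raise ValueError(f"center {center} outside image of shape {image.shape}")
    half = size // 2
    out = np.full((size, size), fill, dtype=float)
    r0, r1 = r - half, r - half + size
    c0, c1 = c - half, c - half + size
    sr0, sr1 = max(r0, 0), min(r1, image.shape[0])
    sc0, sc1 = max(c0, 0), min(c1, image.shape[1])
    out[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = image[sr0:sr1, sc0:sc1]
    return out


def extract_frame(
    image: np.ndarray,
    seed: tuple[int, int],
    magnification: float,
    shift: tuple[int, int] = (0, 0),
    spacing_cm: float = float("nan"),
    fill: float = PAD_FILL,
) -> Frame:
    """Resample around ``seed`` at ``magnification`` and crop a 128×128 frame.

    Equivalent to rescaling the whole image and cropping at the mapped
    seed (shifted by ``shift`` frame pixels), but only the neighbourhood
    of the seed that can reach the frame is resampled.
    """
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    image = np.asarray(image, dtype=float)
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
        raise ValueError(f"seed {seed} outside image of shape {image.shape}")

    reach = FRAME_SIZE // 2 + max(abs(shift[0]), abs(shift[1])) + 8
    h = int(math.ceil(reach / magnification)) + 4
    side = 2 * h + 1

    win = np.full((side, side), fill, dtype=float)
    r0, c0 = r - h, c - h
    sr0, sr1 = max(r0, 0), min(r0 + side, image.shape[0])
    sc0, sc1 = max(c0, 0), min(c0 + side, image.shape[1])
    win[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = image[sr0:sr1, sc0:sc1]

    big = ndimage.zoom(win, magnification, order=3, grid_mode=True, mode="grid-constant", cval=fill)
    center = map_point((h, h), win.shape, big.shape)
    center = (
        int(np.clip(center[0] + shift[0], 0, big.shape[0] - 1)),
        int(np.clip(center[1] + shift[1], 0, big.shape[1] - 1)),
    )
    patch = crop_frame(big, center, fill=fill)
    return Frame(
        patch=patch,
        magnification=magnification,
        source_spacing_cm=spacing_cm,
        frame_center_source=(float(r), float(c)),
        shift=tuple(shift),
    )


def label_for_apparent_size(apparent_size_px: float) -> SizeLabel:
    """Exactly 32 px ties break to LARGER (fixed convention)."""
    return SizeLabel.LARGER if apparent_size_px >= SIZE_THRESHOLD_PX else SizeLabel.SMALLER


def prepare_training_frames(
    image: np.ndarray,
    center: tuple[int, int],
    m_px: float,
    policy: AugmentationPolicy = AugmentationPolicy(),
    rng_seed: int = 0,
    spacing_cm: float = float("nan"),
) -> list[Frame]:
    """Build labeled training frames from one annotated image.

    Each frame is the image rescaled by ``z · 32 / M_px`` for a zoom
    factor ``z`` (cycled from the policy grid), cropped at the shifted
    measurement center; its apparent lesion size is ``z · 32`` px and its
    label follows the 32-px rule. Frames inside the exclusion band are
    dropped; with ``balance`` the majority class is subsampled (seeded)
    to equalize SMALLER/LARGER counts.
    """
    if m_px <= 0:
        raise ValueError("M_px must be positive")
    rng = np.random.default_rng(rng_seed)
    base = canonical_magnification(m_px)
    frames: list[Frame] = []
    for i in range(policy.per_image_count):
        z = policy.zoom_factors[i % len(policy.zoom_factors)]
        apparent = z * SIZE_THRESHOLD_PX
        if abs(apparent - SIZE_THRESHOLD_PX) < policy.exclusion_band_px:
            continue
        if policy.max_shift_px > 0:
            shift = tuple(int(s) for s in rng.integers(-policy.max_shift_px, policy.max_shift_px + 1, 2))
        else:
            shift = (0, 0)
        fr = extract_frame(image, center, z * base, shift=shift, spacing_cm=spacing_cm)
        fr.apparent_size_px = apparent
        fr.label = label_for_apparent_size(apparent)
        fr.zoom = z
        frames.append(fr)

    if policy.balance and frames:
        smaller = [f for f in frames if f.label is SizeLabel.SMALLER]
        larger = [f for f in frames if f.label is SizeLabel.LARGER]
        k = min(len(smaller), len(larger))
        kept = []
        for group in (smaller, larger):
            idx = rng.choice(len(group), size=k, replace=False) if len(group) > k else np.arange(len(group))
            kept.extend(group[j] for j in sorted(idx))
        frames = kept
    return frames


def balance_frames(frames: list[Frame], rng_seed: int = 0) -> list[Frame]:
    """Equalize SMALLER/LARGER counts over a pooled frame set (seeded)."""
    rng = np.random.default_rng(rng_seed)
    smaller = [f for f in frames if f.label is SizeLabel.SMALLER]
    larger = [f for f in frames if f.label is SizeLabel.LARGER]
    k = min(len(smaller), len(larger))
    kept: list[Frame] = []
    for group in (smaller, larger):
        idx = rng.choice(len(group), size=k, replace=False) if len(group) > k else np.arange(len(group))
        kept.extend(group[j] for j in sorted(idx))
    return kept


def write_frame_manifest(frames: list[Frame], directory: str | Path) -> Path:
    """Persist a frame set as .npy patches plus a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_id", "label", "apparent_size_px", "zoom", "shift_row", "shift_col"])
        for i, fr in enumerate(frames):
            fid = f"frame-{i:06d}"
            np.save(directory / f"{fid}.npy", fr.patch.astype(np.float32))
            w.writerow(
                [
                    fid,
                    fr.label.value if fr.label else "",
                    "" if fr.apparent_size_px is None else f"{fr.apparent_size_px:.3f}",
                    "" if fr.zoom is None else f"{fr.zoom:.6f}",
                    fr.shift[0],
                    fr.shift[1],
                ]
            )
    return manifest


def read_annotations(csv_path: str | Path):
    """Read an annotation table (case_id, path, seed_row, seed_col,
    true_diameter_cm, spacing_cm, ...) as a pandas DataFrame."""
    import pandas as pd

    df = pd.read_csv(csv_path)
    required = {"case_id", "seed_row", "seed_col", "true_diameter_cm", "spacing_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df
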