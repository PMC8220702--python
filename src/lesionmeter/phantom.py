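"""Synthetic lesion phantoms with exact ground-truth longest diameters.

A phantom is a single cross-sectional slice on an HU-like intensity scale:
a bright lesion on textured parenchyma-like background. The lesion mask is
built analytically, the ground-truth unidirectional diameter is the exact
longest chord over the noiseless mask's pixel centers, and the noisy render
is what downstream measurement sees. Four shape families emulate the
morphologies that make endpoint placement ambiguous in practice: smooth
ellipses, spiculated masses, two adjacent lesions sharing a field of view,
and lesions with a dense central core.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

__all__ = [
    "ShapeFamily",
    "InvasionGroup",
    "PhantomSpec",
    "PhantomCase",
    "SizingError",
    "synthesize_lesion",
    "sample_dataset",
    "write_phantom_dicom",
    "write_annotations",
    "longest_chord",
]

# HU-like intensity levels (arbitrary linear scale standing in for HU)
BACKGROUND_LEVEL = -700.0
LESION_LEVEL = 20.0
CORE_BOOST = 60.0
TEXTURE_SD = 30.0
TEXTURE_SIGMA = 3.0


class ShapeFamily(str, Enum):
    SMOOTH_ELLIPSE = "smooth_ellipse"
    SPICULATED = "spiculated"
    ADJACENT_PAIR = "adjacent_pair"
    CENTRAL_DENSITY = "central_density"


class InvasionGroup(str, Enum):
    """Arbitrary A–F grouping label used only to exercise group statistics."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"


class SizingError(ValueError):
    """Lesion does not fit inside the requested image."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic lesion slice.

    ``true_diameter_cm`` is the requested longest diameter; the rendered
    case records the exact rasterized chord, which coincides with the
    request whenever the extreme boundary points fall on pixel centers
    (always true for axis-aligned ellipses with integer pixel radii).
    """

    shape_family: ShapeFamily = ShapeFamily.SMOOTH_ELLIPSE
    true_diameter_cm: float = 3.2
    aspect_ratio: float = 1.0
    rotation_deg: float = 0.0
    spiculation_count: int = 0
    spiculation_length_frac: float = 0.2
    noise_sd: float = 40.0
    pixel_spacing_cm: float = 0.1
    image_size_px: int = 256
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.true_diameter_cm <= 0:
            raise ValueError("true_diameter_cm must be positive")
        if not 0.4 <= self.aspect_ratio <= 1.0:
            raise ValueError("aspect_ratio must lie in [0.4, 1.0]")
        if not 0 <= self.rotation_deg < 180:
            raise ValueError("rotation_deg must lie in [0, 180)")
        if self.spiculation_count < 0:
            raise ValueError("spiculation_count must be >= 0")
        if not 0 <= self.spiculation_length_frac <= 0.5:
            raise ValueError("spiculation_length_frac must lie in [0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pixel_spacing_cm <= 0:
            raise ValueError("pixel_spacing_cm must be positive")
        if self.image_size_px < 256:
            raise ValueError("image_size_px must be >= 256")
        if self.true_diameter_cm / self.pixel_spacing_cm > self.image_size_px:
            raise SizingError(
                f"lesion of {self.true_diameter_cm} cm at "
                f"{self.pixel_spacing_cm} cm/px exceeds a "
                f"{self.image_size_px}px image"
            )


@dataclass
class PhantomCase:
    """A rendered phantom slice with its measurement ground truth."""

    image: np.ndarray  # HU-like int grid
    spacing_cm: float
    seed_point: tuple[int, int]  # (row, col), 0-based, strictly inside mask
    true_diameter_cm: float
    true_endpoints: tuple[tuple[float, float], tuple[float, float]]
    shape_family: ShapeFamily
    invasion_group: InvasionGroup = InvasionGroup.A
    mask: np.ndarray | None = None  # noiseless foreground mask
    case_id: str = ""

    @property
    def true_diameter_px(self) -> float:
        return self.true_diameter_cm / self.spacing_cm


def longest_chord(mask: np.ndarray) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Exact longest chord (px) between pixel centers of a boolean mask.

    Boundary pixels are reduced to their convex hull; the maximum pairwise
    distance over hull vertices equals the maximum over all mask pixels.
    """
    boundary = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(boundary).astype(float)
    if len(pts) < 2:
        raise ValueError("mask has fewer than 2 boundary pixels")
    if len(pts) > 3:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # collinear degenerate masks
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    return float(np.sqrt(d2[i, j])), (pts[i], pts[j])


def _rotated_coords(n: int, rotation_deg: float) -> tuple[np.ndarray, np.ndarray]:
    c = n // 2
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    y, x = rr - c, cc - c
    th = np.deg2rad(rotation_deg)
    # u along the major axis, v across it
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    return u, v


# relative slack so boundary pixels at exactly the nominal radius are
# included despite floating-point division (e.g. 2.4/0.1 = 23.999...996)
_EDGE_TOL = 1e-9


def _ellipse_mask(n: int, a: float, b: float, rotation_deg: float) -> np.ndarray:
    u, v = _rotated_coords(n, rotation_deg)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0 + _EDGE_TOL


def _build_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.image_size_px
    R = spec.true_diameter_cm / spec.pixel_spacing_cm / 2.0  # px

    if spec.shape_family in (ShapeFamily.SMOOTH_ELLIPSE, ShapeFamily.CENTRAL_DENSITY):
        return _ellipse_mask(n, R, spec.aspect_ratio * R, spec.rotation_deg)

    if spec.shape_family == ShapeFamily.SPICULATED:
        if spec.spiculation_count == 0 or spec.spiculation_length_frac == 0:
            return _ellipse_mask(n, R, spec.aspect_ratio * R, spec.rotation_deg)
        u, v = _rotated_coords(n, spec.rotation_deg)
        rho = np.hypot(u, v)
        phi = np.arctan2(v, u)  # angle in the lesion frame
        a = R * (1.0 - spec.spiculation_length_frac)
        b = spec.aspect_ratio * a
        # base ellipse radius as a function of angle
        base = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
        radial = base.copy()
        k = max(int(spec.spiculation_count), 2)
        angles = np.arange(k) * 2.0 * np.pi / k
        half_width = np.pi / k * 0.5
        # the two axis spikes reach exactly R so the tip-to-tip chord is
        # the requested diameter; the rest get random sub-maximal reach
        reaches = R * (1.0 - 0.5 * spec.spiculation_length_frac * rng.random(k))
        reaches[0] = R
        opposite = int(round(k / 2)) % k
        reaches[opposite] = R
        angles[opposite] = np.pi
        for ang, reach in zip(angles, reaches):
            d = np.angle(np.exp(1j * (phi - ang)))
            base_at = a * b / np.sqrt((b * np.cos(ang)) ** 2 + (a * np.sin(ang)) ** 2)
            spike = (reach - base_at) * np.clip(1.0 - np.abs(d) / half_width, 0.0, None)
            radial = np.maximum(radial, base + spike)
        return rho <= radial * (1.0 + _EDGE_TOL)

    if spec.shape_family == ShapeFamily.ADJACENT_PAIR:
        # two lobes along the rotation axis; outer tips at +/-R from center,
        # every lobe point within R of center, so the longest chord is the
        # tip-to-tip axis segment of length 2R
        u, v = _rotated_coords(n, spec.rotation_deg)
        r1 = 0.45 * R  # r1 + r2 < R keeps the lobes disjoint
        r2 = 0.35 * R
        m1 = (u + (R - r1)) ** 2 + v**2 <= r1**2 * (1.0 + _EDGE_TOL)
        m2 = (u - (R - r2)) ** 2 + v**2 <= r2**2 * (1.0 + _EDGE_TOL)
        return m1 | m2

    raise ValueError(f"unknown shape family {spec.shape_family}")


def _pick_seed_point(mask: np.ndarray) -> tuple[int, int]:
    """Interior mask pixel nearest the image center."""
    interior = ndimage.binary_erosion(mask)
    if not interior.any():
        interior = mask
    pts = np.argwhere(interior)
    c = np.array(mask.shape) // 2
    idx = int(np.argmin(((pts - c) ** 2).sum(1)))
    return int(pts[idx][0]), int(pts[idx][1])


def synthesize_lesion(spec: PhantomSpec) -> PhantomCase:
    """Render a phantom slice and record its exact ground truth.

    Deterministic given ``spec.rng_seed``. The lesion interior sits at
    least 5 noise standard deviations above the background level before
    noise is added, and ground truth is defined on the noiseless mask.
    """
    contrast = LESION_LEVEL - BACKGROUND_LEVEL
    if spec.noise_sd > 0 and contrast < 5.0 * spec.noise_sd:
        raise ValueError(
            f"noise_sd {spec.noise_sd} leaves less than 5 SD of figure/ground contrast"
        )
    rng = np.random.default_rng(spec.rng_seed)
    mask = _build_mask(spec, rng)

    chord_px, (p1, p2) = longest_chord(mask)
    true_cm = chord_px * spec.pixel_spacing_cm

    n = spec.image_size_px
    texture = ndimage.gaussian_filter(rng.standard_normal((n, n)), TEXTURE_SIGMA)
    texture *= TEXTURE_SD / max(texture.std(), 1e-12)
    img = np.full((n, n), BACKGROUND_LEVEL) + texture
    img[mask] = LESION_LEVEL + 0.2 * texture[mask]

    if spec.shape_family == ShapeFamily.CENTRAL_DENSITY:
        R = spec.true_diameter_cm / spec.pixel_spacing_cm / 2.0
        core = _ellipse_mask(n, 0.25 * R, 0.25 * R, 0.0)
        img[core & mask] += CORE_BOOST

    if spec.noise_sd > 0:
        img += spec.noise_sd * rng.standard_normal((n, n))
    img = np.rint(np.clip(img, -1024, 3071)).astype(np.int16)

    return PhantomCase(
        image=img,
        spacing_cm=spec.pixel_spacing_cm,
        seed_point=_pick_seed_point(mask),
        true_diameter_cm=true_cm,
        true_endpoints=((float(p1[0]), float(p1[1])), (float(p2[0]), float(p2[1]))),
        shape_family=spec.shape_family,
        mask=mask,
    )


def sample_dataset(
    n: int,
    diameter_range_cm: tuple[float, float] = (1.37, 5.44),
    spacing_range_cm: tuple[float, float] = (0.051, 0.137),
    master_seed: int = 0,
    image_size_px: int = 256,
    noise_sd: float = 40.0,
) -> list[PhantomCase]:
    """Draw a reproducible phantom cohort.

    Diameters and pixel spacings are uniform over their ranges (defaults
    span the measurement range and in-plane CT resolutions typical of
    public lung-CT collections); shape families and the six invasion-type
    group labels are cycled so every group is populated once ``n >= 6``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for lo, hi in (diameter_range_cm, spacing_range_cm):
        if not 0 < lo < hi:
            raise ValueError("ranges must satisfy 0 < lo < hi")

    families = list(ShapeFamily)
    groups = list(InvasionGroup)
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n)
    cases = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        d = float(rng.uniform(*diameter_range_cm))
        s = float(rng.uniform(*spacing_range_cm))
        # keep the lesion inside the image at the drawn spacing
        s = max(s, 1.05 * d / image_size_px)
        fam = families[i % len(families)]
        spec = PhantomSpec(
            shape_family=fam,
            true_diameter_cm=d,
            aspect_ratio=float(rng.uniform(0.5, 1.0)),
            rotation_deg=float(rng.uniform(0, 180)),
            spiculation_count=int(rng.integers(4, 11)),
            spiculation_length_frac=float(rng.uniform(0.1, 0.3)),
            noise_sd=noise_sd,
            pixel_spacing_cm=s,
            image_size_px=image_size_px,
            rng_seed=int(child.generate_state(1)[0] % (2**31)),
        )
        case = synthesize_lesion(spec)
        case.invasion_group = groups[i % len(groups)]
        case.case_id = f"phantom-{i:04d}"
        cases.append(case)
    return cases


def write_phantom_dicom(case: PhantomCase, path: str | Path) -> Path:
    """Write a phantom as a single-frame secondary-capture-style DICOM.

    PixelSpacing is stored in mm (``spacing_cm * 10``); pixel values are
    stored as signed 16-bit with identity rescale, so reading the file
    back recovers the grid exactly.
    """
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    path = Path(path)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = pydicom.Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.SeriesDescription = "synthetic lesion phantom"
    ds.PatientName = case.case_id or "phantom"
    ds.PatientID = case.case_id or "phantom"
    ds.Rows, ds.Columns = case.image.shape
    ds.PixelSpacing = [case.spacing_cm * 10.0, case.spacing_cm * 10.0]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.RescaleSlope = 1
    ds.RescaleIntercept = 0
    ds.WindowCenter = -600
    ds.WindowWidth = 1500
    ds.PixelData = np.ascontiguousarray(case.image.astype(np.int16)).tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def write_annotations(cases: list[PhantomCase], paths: list[str | Path], csv_path: str | Path) -> Path:
    """Companion annotation table for a written phantom cohort."""
    csv_path = Path(csv_path)
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "case_id", "path", "seed_row", "seed_col",
                "true_diameter_cm", "spacing_cm", "shape_family", "invasion_group",
            ]
        )
        for case, p in zip(cases, paths):
            w.writerow(
                [
                    case.case_id, str(p), case.seed_point[0], case.seed_point[1],
                    f"{case.true_diameter_cm:.6f}", f"{case.spacing_cm:.6f}",
                    case.shape_family.value, case.invasion_group.value,
                ]
            )
    return csv_path
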