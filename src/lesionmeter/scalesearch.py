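"""The measurement algorithm: find the magnification at which the
larger/smaller-than-32-px decision flips, and convert it to centimeters.

Given a seed point inside the lesion, the slice is rescaled to a ladder
of magnifications chosen so the hypothesized sizes span a measurable
range (default 1.0–5.5 cm, geometric). Each rung yields a 128×128 frame
classified for "larger than 32 px"; the probability sequence is made
monotone by isotonic regression over log-magnification and the
0.5-crossing — where classification flips — is located by linear
interpolation, optionally sharpened by bisection between the bracketing
rungs. The size estimate is then ``(32 / flip_magnification) × pixel
spacing``: at the flip, the lesion's apparent size is exactly 32 px.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .ctio import CTSlice, apply_window
from .framing import SIZE_THRESHOLD_PX, extract_frame
from .sizeclassifier import SizeClassifier

__all__ = [
    "LadderConfig",
    "FlipEstimate",
    "MeasurementResult",
    "OutOfRange",
    "build_ladder",
    "classify_ladder",
    "estimate_flip",
    "measure_lesion",
]


class OutOfRange(str, Enum):
    """Flip clamped at a ladder end: the lesion is outside the range."""

    BELOW_MIN = "below_min"  # every rung voted SMALLER
    ABOVE_MAX = "above_max"  # every rung voted LARGER


@dataclass(frozen=True)
class LadderConfig:
    """Magnification-ladder settings.

    ``n_rungs`` hypothesized sizes span [min_size_cm, max_size_cm]
    (geometric grid by default, matching the percent-difference error
    currency); ``refine`` bisects between the bracketing rungs until the
    implied apparent-size uncertainty drops below ``refine_tol_px``.
    ``interpolate=False`` snaps the flip to the nearest rung instead.
    """

    n_rungs: int = 16
    min_size_cm: float = 1.0
    max_size_cm: float = 5.5
    spacing_mode: str = "geometric"  # or "linear"
    refine: bool = True
    refine_tol_px: float = 0.25
    interpolate: bool = True
    max_refine_steps: int = 24

    def __post_init__(self) -> None:
        if self.n_rungs < 2:
            raise ValueError("n_rungs must be >= 2")
        if not 0 < self.min_size_cm < self.max_size_cm:
            raise ValueError("need 0 < min_size_cm < max_size_cm")
        if self.spacing_mode not in ("geometric", "linear"):
            raise ValueError("spacing_mode must be 'geometric' or 'linear'")
        if self.refine_tol_px <= 0:
            raise ValueError("refine_tol_px must be positive")


@dataclass
class FlipEstimate:
    flip_magnification: float
    monotone_violations: int
    out_of_range: OutOfRange | None = None
    bracket: tuple[float, float] | None = None  # (m_lo, m_hi) around the flip


@dataclass
class MeasurementResult:
    """Outcome of one semi-automatic measurement."""

    size_cm: float
    flip_magnification: float
    rung_magnifications: list[float]
    rung_probs: list[float]
    monotone_violations: int
    seed_point: tuple[int, int]
    spacing_cm: float
    out_of_range: OutOfRange | None = None
    n_classifier_calls: int = 0

    def to_dict(self) -> dict:
        return {
            "size_cm": self.size_cm,
            "flip_magnification": self.flip_magnification,
            "rung_magnifications": list(self.rung_magnifications),
            "rung_probs": list(self.rung_probs),
            "monotone_violations": self.monotone_violations,
            "seed_point": list(self.seed_point),
            "spacing_cm": self.spacing_cm,
            "out_of_range": self.out_of_range.value if self.out_of_range else None,
        }


def build_ladder(config: LadderConfig, spacing_cm: float) -> np.ndarray:
    """Ascending magnifications covering the hypothesized size range.

    A rung hypothesizing size ``s`` uses magnification
    ``32 / (s / spacing)``; larger sizes map to smaller magnifications,
    so the returned array ascends from the max-size rung to the min-size
    rung.
    """
    if spacing_cm <= 0:
        raise ValueError("spacing_cm must be positive")
    if config.spacing_mode == "geometric":
        sizes = np.geomspace(config.min_size_cm, config.max_size_cm, config.n_rungs)
    else:
        sizes = np.linspace(config.min_size_cm, config.max_size_cm, config.n_rungs)
    mags = SIZE_THRESHOLD_PX / (sizes / spacing_cm)
    return np.sort(mags)


def classify_ladder(
    ct: CTSlice,
    seed: tuple[int, int],
    ladder: np.ndarray,
    clf: SizeClassifier,
) -> list[float]:
    """Probability of "larger than 32 px" at each ladder magnification.

    The windowed slice is rescaled per rung, the seed mapped into the
    rescaled grid (round to nearest) and a 128×128 frame cropped there.
    """
    windowed = apply_window(ct)
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < windowed.shape[0] and 0 <= c < windowed.shape[1]):
        raise ValueError(f"seed {seed} outside slice of shape {windowed.shape}")
    spacing = ct.iso_spacing_cm
    probs = []
    for m in ladder:
        frame = extract_frame(windowed, (r, c), float(m), spacing_cm=spacing)
        probs.append(float(clf.predict_prob(frame)))
    return probs


def estimate_flip(ladder: np.ndarray, probs: list[float]) -> FlipEstimate:
    """Locate the 0.5-crossing of the classifier response on the ladder.

    The raw probabilities are projected onto the nearest monotone
    non-decreasing sequence over log-magnification (isotonic regression,
    least squares); the flip is the log-magnification where the fitted
    curve crosses 0.5, interpolated linearly between the bracketing
    rungs. All-SMALLER / all-LARGER sequences clamp to the nearest
    ladder end and are flagged rather than raised. Adjacent hard-label
    inversions in the raw sequence are counted as monotone violations.
    """
    ladder = np.asarray(ladder, dtype=float)
    probs_arr = np.asarray(probs, dtype=float)
    if ladder.shape != probs_arr.shape:
        raise ValueError("ladder and probs must have equal length")
    if np.any(np.diff(ladder) <= 0):
        raise ValueError("ladder must be strictly ascending")

    from sklearn.isotonic import IsotonicRegression

    x = np.log(ladder)
    fitted = IsotonicRegression(increasing=True, out_of_bounds="clip").fit_transform(x, probs_arr)

    hard = probs_arr > 0.5
    violations = int(np.sum(hard[:-1] & ~hard[1:]))

    above = np.nonzero(fitted >= 0.5)[0]
    if len(above) == 0:
        return FlipEstimate(float(ladder[-1]), violations, OutOfRange.BELOW_MIN)
    j = int(above[0])
    if j == 0:
        return FlipEstimate(float(ladder[0]), violations, OutOfRange.ABOVE_MAX)
    y0, y1 = fitted[j - 1], fitted[j]
    t = (0.5 - y0) / (y1 - y0)
    flip = float(np.exp(x[j - 1] + t * (x[j] - x[j - 1])))
    return FlipEstimate(flip, violations, None, bracket=(float(ladder[j - 1]), float(ladder[j])))


def measure_lesion(
    ct: CTSlice,
    seed: tuple[int, int],
    clf: SizeClassifier,
    config: LadderConfig = LadderConfig(),
) -> MeasurementResult:
    """Measure the lesion under the seed point.

    Composes ladder construction, per-rung classification and flip
    estimation; with ``config.refine`` the bracketing interval is
    bisected (in log-magnification, querying the classifier at each
    midpoint) until the implied apparent-size uncertainty is below
    ``refine_tol_px``. The final estimate satisfies
    ``size_cm × flip_magnification / spacing_cm = 32`` exactly.
    """
    spacing = ct.iso_spacing_cm
    ladder = build_ladder(config, spacing)
    probs = classify_ladder(ct, seed, ladder, clf)
    est = estimate_flip(ladder, probs)
    n_calls = len(ladder)

    flip = est.flip_magnification
    if est.out_of_range is None and est.bracket is not None:
        if not config.interpolate:
            m_lo, m_hi = est.bracket
            flip = m_lo if abs(math.log(flip / m_lo)) <= abs(math.log(m_hi / flip)) else m_hi
        if config.refine:
            windowed = apply_window(ct)
            m_lo, m_hi = est.bracket
            for _ in range(config.max_refine_steps):
                if SIZE_THRESHOLD_PX / m_lo - SIZE_THRESHOLD_PX / m_hi <= config.refine_tol_px:
                    break
                m_mid = math.sqrt(m_lo * m_hi)
                frame = extract_frame(windowed, seed, m_mid, spacing_cm=spacing)
                p = float(clf.predict_prob(frame))
                n_calls += 1
                if p > 0.5:  # appears larger than 32 px: flip is at lower magnification
                    m_hi = m_mid
                else:
                    m_lo = m_mid
            flip = math.sqrt(m_lo * m_hi)

    size_cm = (SIZE_THRESHOLD_PX / flip) * spacing
    return MeasurementResult(
        size_cm=float(size_cm),
        flip_magnification=float(flip),
        rung_magnifications=[float(m) for m in ladder],
        rung_probs=[float(p) for p in probs],
        monotone_violations=est.monotone_violations,
        seed_point=(int(seed[0]), int(seed[1])),
        spacing_cm=float(spacing),
        out_of_range=est.out_of_range,
        n_classifier_calls=n_calls,
    )
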