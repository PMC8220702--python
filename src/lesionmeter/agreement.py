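"""Radiologist-agreement statistics for paired measurements.

Implements the evaluation battery used to compare an automated reader
with a human one: symmetric percent differences with Bland-Altman
±1.96·SD limits of agreement, pixel-difference summaries, intraclass
correlation ICC(2,1) (two-way random effects, absolute agreement, single
measurement) with an F-based 95% CI, and Bonferroni-corrected pairwise
Welch t-tests of measurement error across lesion groups.

The percent difference between readers is symmetric in the pair mean:

    d% = 200 · (m_dl − m_human) / (m_dl + m_human)

so a 5-pixel disagreement on a 5 cm lesion at 0.1 cm/px is 10% while the
same 5 pixels on a 2 cm lesion is 25% — percent differences, unlike raw
pixel differences, are comparable across lesion sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MeasurementPair",
    "AgreementReport",
    "percent_difference",
    "bland_altman",
    "pixel_difference_percent",
    "mean_pixel_difference",
    "icc_two_way_random",
    "bonferroni_pairwise",
    "compute_agreement",
    "bland_altman_plot",
]

LOA_FACTOR = 1.96  # 95% limits of agreement


@dataclass(frozen=True)
class MeasurementPair:
    """One lesion measured by both readers (cm), with its pixel spacing."""

    case_id: str
    m_human: float
    m_dl: float
    spacing_cm: float
    invasion_group: str | None = None

    def __post_init__(self) -> None:
        if self.m_human <= 0 or self.m_dl <= 0 or self.spacing_cm <= 0:
            raise ValueError("measurements and spacing must be positive")


@dataclass
class AgreementReport:
    icc: float
    icc_ci: tuple[float, float]
    mean_pct_diff: float
    sd_pct_diff: float
    loa: tuple[float, float]
    n_outside_loa: int
    mean_px_diff: float
    sd_px_diff: float
    n: int
    icc_degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "icc_ci": list(self.icc_ci),
            "mean_pct_diff": self.mean_pct_diff,
            "sd_pct_diff": self.sd_pct_diff,
            "loa_lower": self.loa[0],
            "loa_upper": self.loa[1],
            "n_outside_loa": self.n_outside_loa,
            "mean_px_diff": self.mean_px_diff,
            "sd_px_diff": self.sd_px_diff,
            "n": self.n,
        }


def percent_difference(m_dl: float, m_human: float) -> float:
    """Symmetric percent difference ``200·(m_dl − m_human)/(m_dl + m_human)``.

    Antisymmetric under swapping the readers; bounded in (−200, 200) for
    positive measurements.
    """
    s = m_dl + m_human
    if s <= 0:
        raise ValueError("sum of measurements must be positive")
    return 200.0 * (m_dl - m_human) / s


def bland_altman(
    pairs: list[MeasurementPair],
) -> tuple[float, float, tuple[float, float], list[int]]:
    """Bland-Altman summary of per-pair percent differences.

    Returns the mean (systematic difference), sample SD (n−1), the
    ±1.96·SD limits of agreement, and the indices of pairs strictly
    outside the LOA interval.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    d = np.array([percent_difference(p.m_dl, p.m_human) for p in pairs])
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (mean - LOA_FACTOR * sd, mean + LOA_FACTOR * sd)
    outside = [int(i) for i in np.nonzero((d < loa[0]) | (d > loa[1]))[0]]
    return mean, sd, loa, outside


def pixel_difference_percent(diff_px: float, spacing_cm: float, size_cm: float) -> float:
    """Percent disagreement implied by a pixel difference at a lesion size:
    ``100 · diff_px · spacing / size``."""
    if spacing_cm <= 0 or size_cm <= 0:
        raise ValueError("spacing and size must be positive")
    return 100.0 * (diff_px * spacing_cm) / size_cm


def mean_pixel_difference(pairs: list[MeasurementPair], signed: bool = False) -> tuple[float, float]:
    """Mean and sample SD of per-pair (absolute) pixel differences."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    d = np.array([(p.m_dl - p.m_human) / p.spacing_cm for p in pairs])
    if not signed:
        d = np.abs(d)
    return float(d.mean()), float(d.std(ddof=1))


def icc_two_way_random(matrix: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float, bool]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    For an n×k matrix (targets × raters) the two-way ANOVA decomposition
    gives mean squares for rows (MS_R), columns (MS_C) and residual
    (MS_E), and

        ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E))

    The CI uses the standard F-based method (Satterthwaite degrees of
    freedom for the lower/upper bounds). Returns
    ``(icc, ci_lo, ci_hi, degenerate)`` — ``degenerate`` marks an
    all-identical matrix, reported as perfect agreement.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("matrix must be n>=2 targets by k>=2 raters")
    if np.isnan(m).any():
        raise ValueError("matrix must have no missing cells")
    n, k = m.shape

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        # no variance anywhere: identical measurements, perfect agreement
        return 1.0, float("nan"), float("nan"), True
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:
        # exact agreement between raters: CI collapses
        return float(icc), float(icc), float(icc), False

    a = (k * icc) / (n * (1 - icc)) if icc < 1 else float("inf")
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else float("inf")
    if not np.isfinite(a) or not np.isfinite(b):
        return float(icc), float(icc), float(icc), False
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return float(icc), float(lower), float(upper), False


@dataclass(frozen=True)
class PairwiseComparison:
    group_i: str
    group_j: str
    raw_p: float
    adjusted_p: float
    significant: bool


def bonferroni_pairwise(
    errors_by_group: dict[str, list[float]], alpha: float = 0.05
) -> list[PairwiseComparison]:
    """Bonferroni-corrected pairwise Welch t-tests of group errors.

    Groups with fewer than 2 observations are skipped. Adjusted p-values
    are ``min(1, raw_p × n_pairs)``; significance is declared at the
    stated alpha after adjustment.
    """
    eligible = {g: np.asarray(v, dtype=float) for g, v in errors_by_group.items() if len(v) >= 2}
    if len(eligible) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations each")
    groups = sorted(eligible)
    pairs = list(itertools.combinations(groups, 2))
    n_pairs = len(pairs)
    out = []
    for gi, gj in pairs:
        t, p = stats.ttest_ind(eligible[gi], eligible[gj], equal_var=False)
        adj = min(1.0, float(p) * n_pairs)
        out.append(PairwiseComparison(gi, gj, float(p), adj, adj < alpha))
    return out


def compute_agreement(pairs: list[MeasurementPair]) -> AgreementReport:
    """Full agreement report between the two readers over a paired set."""
    mean, sd, loa, outside = bland_altman(pairs)
    matrix = np.array([[p.m_human, p.m_dl] for p in pairs])
    icc, lo, hi, degenerate = icc_two_way_random(matrix)
    mean_px, sd_px = mean_pixel_difference(pairs)
    return AgreementReport(
        icc=icc,
        icc_ci=(lo, hi),
        mean_pct_diff=mean,
        sd_pct_diff=sd,
        loa=loa,
        n_outside_loa=len(outside),
        mean_px_diff=mean_px,
        sd_px_diff=sd_px,
        n=len(pairs),
        icc_degenerate=degenerate,
    )


def bland_altman_plot(pairs: list[MeasurementPair], path: str, histogram: bool = True) -> str:
    """Write a Bland-Altman scatter (and difference histogram) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean, sd, loa, outside = bland_altman(pairs)
    d = [percent_difference(p.m_dl, p.m_human) for p in pairs]
    avg = [(p.m_dl + p.m_human) / 2 for p in pairs]

    ncols = 2 if histogram else 1
    fig, axes = plt.subplots(1, ncols, figsize=(6 * ncols, 4.5), squeeze=False)
    ax = axes[0][0]
    ax.scatter(avg, d, s=14, alpha=0.7)
    ax.axhline(mean, color="k", label=f"mean {mean:.2f}%")
    for y in loa:
        ax.axhline(y, color="k", linestyle=":")
    ax.set_xlabel("mean of readers (cm)")
    ax.set_ylabel("percent difference (%)")
    ax.legend()
    if histogram:
        axh = axes[0][1]
        axh.hist(d, bins=30)
        axh.axvline(mean, color="k")
        axh.set_xlabel("percent difference (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
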