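"""Reader-agreement statistics: percent differences, Bland-Altman,
pixel differences, ICC(2,1), Bonferroni pairwise comparisons."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lesionmeter.agreement import (
    MeasurementPair,
    bland_altman,
    bonferroni_pairwise,
    compute_agreement,
    icc_two_way_random,
    mean_pixel_difference,
    percent_difference,
    pixel_difference_percent,
)


def _pair_with_pct_diff(d, m_human=3.0, spacing=0.1, case_id="x"):
    """Construct a pair whose symmetric percent difference is exactly d."""
    m_dl = m_human * (200.0 + d) / (200.0 - d)
    return MeasurementPair(case_id, m_human, m_dl, spacing)


class TestPercentDifference:
    def test_equal_measurements_give_zero(self):
        assert percent_difference(3.0, 3.0) == 0.0

    def test_two_vs_one(self):
        assert percent_difference(2.0, 1.0) == pytest.approx(200.0 / 3.0)

    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=0.1, max_value=50.0),
    )
    def test_antisymmetric_and_bounded(self, a, b):
        d = percent_difference(a, b)
        assert d == pytest.approx(-percent_difference(b, a))
        assert abs(d) < 200.0


class TestBlandAltman:
    def test_identical_pairs_degenerate(self):
        pairs = [MeasurementPair(str(i), 3.0, 3.0, 0.1) for i in range(5)]
        mean, sd, loa, outside = bland_altman(pairs)
        assert (mean, sd) == (0.0, 0.0)
        assert loa == (0.0, 0.0)
        assert outside == []

    def test_hand_computed_loa(self):
        pairs = [_pair_with_pct_diff(d) for d in (-1.0, 0.0, 1.0)]
        mean, sd, loa, outside = bland_altman(pairs)
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert sd == pytest.approx(1.0)
        assert loa[0] == pytest.approx(-1.96)
        assert loa[1] == pytest.approx(1.96)
        assert outside == []

    def test_normal_coverage_near_95_percent(self):
        rng = np.random.default_rng(11)
        pairs = [_pair_with_pct_diff(d) for d in rng.normal(0, 8.0, 10_000)]
        _, _, _, outside = bland_altman(pairs)
        assert len(outside) / 10_000 == pytest.approx(0.05, abs=0.01)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([_pair_with_pct_diff(0.0)])


class TestPixelDifference:
    def test_five_pixels_on_large_lesion(self):
        assert pixel_difference_percent(5, 0.1, 5.0) == pytest.approx(10.0)

    def test_five_pixels_on_small_lesion(self):
        assert pixel_difference_percent(5, 0.1, 2.0) == pytest.approx(25.0)

    def test_zero_difference(self):
        assert pixel_difference_percent(0, 0.07, 3.3) == 0.0

    def test_mean_pixel_difference(self):
        pairs = [
            MeasurementPair("a", 3.0, 3.1, 0.1),
            MeasurementPair("b", 2.0, 1.9, 0.1),
            MeasurementPair("c", 4.0, 4.1, 0.1),
        ]
        mean, sd = mean_pixel_difference(pairs)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_signed_variant_keeps_direction(self):
        pairs = [MeasurementPair("a", 3.0, 3.1, 0.1), MeasurementPair("b", 3.0, 2.9, 0.1)]
        mean, _ = mean_pixel_difference(pairs, signed=True)
        assert mean == pytest.approx(0.0, abs=1e-9)


def _naive_icc21(m):
    """From-scratch two-way ANOVA ICC(2,1), written with explicit loops."""
    n, k = m.shape
    grand = m.mean()
    msr = sum(k * (m[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (m[i, j] - m[i].mean() - m[:, j].mean() + grand) ** 2
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestICC:
    def test_identical_raters_give_one(self):
        col = np.array([1.0, 2.0, 5.0, 3.0, 4.0])
        icc, lo, hi, degenerate = icc_two_way_random(np.column_stack([col, col]))
        assert icc == 1.0
        assert not degenerate

    def test_constant_matrix_degenerate(self):
        icc, lo, hi, degenerate = icc_two_way_random(np.full((4, 2), 7.0))
        assert icc == 1.0
        assert degenerate

    def test_pure_bias_drives_icc_down(self):
        base = np.array([3.0, 3.01, 2.99, 3.0, 3.02])
        m = np.column_stack([base, base + 2.0])
        icc, *_ = icc_two_way_random(m)
        assert icc < 0.01  # absolute agreement punishes a constant offset

    def test_matches_naive_anova_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            m = rng.normal(3, 1, (10, 2)) + rng.normal(0, 0.5, (10, 1))
            icc, *_ = icc_two_way_random(m)
            assert icc == pytest.approx(_naive_icc21(m), abs=1e-10)

    def test_matches_pingouin_reference(self):
        pd = pytest.importorskip("pandas")
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        m = rng.normal(3, 1, (12, 2)) + rng.normal(0, 0.4, (12, 1))
        icc, lo, hi, _ = icc_two_way_random(m)
        df = pd.DataFrame(
            {"t": np.repeat(np.arange(12), 2), "r": np.tile([0, 1], 12), "y": m.ravel()}
        )
        ref = pg.intraclass_corr(df, targets="t", raters="r", ratings="y").set_index("Type")
        assert icc == pytest.approx(float(ref.loc["ICC(A,1)", "ICC"]), abs=1e-12)
        ref_lo, ref_hi = ref.loc["ICC(A,1)", "CI95"]
        assert lo == pytest.approx(float(ref_lo), abs=0.01)  # pingouin rounds its CI
        assert hi == pytest.approx(float(ref_hi), abs=0.01)

    def test_invariance_under_affine_rescaling(self):
        rng = np.random.default_rng(8)
        m = rng.normal(3, 1, (10, 2)) + rng.normal(0, 0.5, (10, 1))
        icc, *_ = icc_two_way_random(m)
        icc_shift, *_ = icc_two_way_random(m + 100.0)
        icc_scale, *_ = icc_two_way_random(m * 7.5)
        assert icc_shift == pytest.approx(icc, abs=1e-9)
        assert icc_scale == pytest.approx(icc, abs=1e-9)

    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            icc_two_way_random(np.zeros((1, 2)))
        with pytest.raises(ValueError):
            icc_two_way_random(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestBonferroni:
    def test_six_groups_yield_fifteen_comparisons(self):
        rng = np.random.default_rng(1)
        groups = {g: list(rng.normal(0, 5, 10)) for g in "ABCDEF"}
        out = bonferroni_pairwise(groups)
        assert len(out) == 15

    def test_adjusted_p_bounds(self):
        rng = np.random.default_rng(2)
        groups = {g: list(rng.normal(0, 5, 12)) for g in "ABCD"}
        for c in bonferroni_pairwise(groups):
            assert c.raw_p <= c.adjusted_p <= 1.0

    def test_detects_large_shift(self):
        rng = np.random.default_rng(3)
        groups = {
            "A": list(rng.normal(0, 1, 20)),
            "B": list(rng.normal(3, 1, 20)),  # 3 SD shift
        }
        (cmp,) = bonferroni_pairwise(groups)
        assert cmp.significant

    def test_small_groups_skipped(self):
        groups = {"A": [1.0, 2.0, 1.5], "B": [0.5], "C": [2.0, 2.5, 1.8]}
        out = bonferroni_pairwise(groups)
        assert {(c.group_i, c.group_j) for c in out} == {("A", "C")}

    def test_fewer_than_two_eligible_groups_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_pairwise({"A": [1.0, 2.0], "B": [0.5]})


def test_full_report_internal_consistency():
    rng = np.random.default_rng(4)
    pairs = [
        MeasurementPair(str(i), h, h * rng.uniform(0.9, 1.1), 0.1)
        for i, h in enumerate(rng.uniform(1.5, 5.0, 40))
    ]
    rep = compute_agreement(pairs)
    assert rep.loa[0] == pytest.approx(rep.mean_pct_diff - 1.96 * rep.sd_pct_diff)
    assert rep.loa[1] == pytest.approx(rep.mean_pct_diff + 1.96 * rep.sd_pct_diff)
    assert 0 <= rep.n_outside_loa <= rep.n == 40
    assert -1 <= rep.icc <= 1
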