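"""Magnification ladder, flip localization, and the measurement loop."""

import numpy as np
import pytest

from conftest import slice_of
from lesionmeter.ctio import CTSlice
from lesionmeter.phantom import PhantomSpec, ShapeFamily, synthesize_lesion
from lesionmeter.scalesearch import (
    LadderConfig,
    OutOfRange,
    build_ladder,
    classify_ladder,
    estimate_flip,
    measure_lesion,
)
from lesionmeter.sizeclassifier import oracle_classifier, phantom_size_lookup


class TestBuildLadder:
    def test_rung_magnification_from_hypothesized_size(self):
        # hypothesized 3.2 cm at 0.1 cm/px -> 32 px -> magnification 1
        ladder = build_ladder(LadderConfig(n_rungs=2, min_size_cm=3.2, max_size_cm=5.5), 0.1)
        assert max(ladder) == pytest.approx(1.0)

    def test_two_rung_endpoints(self):
        ladder = build_ladder(LadderConfig(n_rungs=2, min_size_cm=1.0, max_size_cm=5.5), 0.1)
        assert sorted(ladder) == pytest.approx(sorted([3.2, 32 / 55]))

    def test_geometric_mode_has_constant_ratio(self):
        ladder = build_ladder(LadderConfig(n_rungs=16), 0.08)
        ratios = np.diff(np.log(ladder))
        assert np.allclose(ratios, ratios[0])
        assert np.all(np.diff(ladder) > 0)

    def test_linear_mode_spans_linearly_in_size(self):
        ladder = build_ladder(LadderConfig(n_rungs=5, spacing_mode="linear"), 0.1)
        sizes = 32 * 0.1 / ladder
        assert np.allclose(np.diff(sorted(sizes)), (5.5 - 1.0) / 4)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LadderConfig(n_rungs=1)
        with pytest.raises(ValueError):
            LadderConfig(min_size_cm=5.0, max_size_cm=1.0)
        with pytest.raises(ValueError):
            build_ladder(LadderConfig(), 0.0)


class TestClassifyLadder:
    def test_hard_oracle_step_sequence(self, circle_case):
        """0 below the canonical magnification, 1 above (32 px boundary)."""
        ct = slice_of(circle_case)
        clf = oracle_classifier(phantom_size_lookup(circle_case.true_diameter_cm, 0.1))
        ladder = build_ladder(LadderConfig(), 0.1)
        probs = classify_ladder(ct, circle_case.seed_point, ladder, clf)
        assert len(probs) == len(ladder)
        expected = [1.0 if m * 32.0 > 32.0 else 0.0 for m in ladder]
        assert probs == expected

    def test_seed_outside_rejected(self, circle_case):
        ct = slice_of(circle_case)
        clf = oracle_classifier(lambda f: 40.0)
        with pytest.raises(ValueError):
            classify_ladder(ct, (-1, 5), build_ladder(LadderConfig(), 0.1), clf)


def _bruteforce_monotone_fit(probs):
    """Least-squares monotone step-function fit by exhaustive search.

    Enumerates every partition of the sequence into consecutive blocks
    (depth-first, pruning non-monotone block means), each block fitted by
    its mean — the best such function over all partitions is the exact
    monotone least-squares projection, found without any isotonic
    machinery.
    """
    n = len(probs)
    p = np.asarray(probs, dtype=float)
    best = {"sse": np.inf, "fit": None}

    def extend(start, prev_mean, fit, sse):
        if sse >= best["sse"]:
            return
        if start == n:
            best["sse"] = sse
            best["fit"] = list(fit)
            return
        for end in range(start + 1, n + 1):
            mean = p[start:end].mean()
            if mean < prev_mean - 1e-12:
                continue
            block_sse = float(((p[start:end] - mean) ** 2).sum())
            extend(end, mean, fit + [mean] * (end - start), sse + block_sse)

    extend(0, -np.inf, [], 0.0)
    return np.array(best["fit"])


def _crossing_from_fit(ladder, fit):
    """0.5-crossing of a fitted curve, by the same interpolation rule."""
    x = np.log(np.asarray(ladder, dtype=float))
    above = np.nonzero(fit >= 0.5)[0]
    if len(above) == 0:
        return float(ladder[-1])
    j = int(above[0])
    if j == 0:
        return float(ladder[0])
    t = (0.5 - fit[j - 1]) / (fit[j] - fit[j - 1])
    return float(np.exp(x[j - 1] + t * (x[j] - x[j - 1])))


class TestEstimateFlip:
    def test_clean_step_interpolates_geometric_mean(self):
        ladder = np.geomspace(0.5, 2.0, 6)
        est = estimate_flip(ladder, [0, 0, 0, 1, 1, 1])
        assert est.flip_magnification == pytest.approx(np.sqrt(ladder[2] * ladder[3]))
        assert est.monotone_violations == 0
        assert est.out_of_range is None

    def test_all_larger_clamps_to_smallest_rung(self):
        ladder = np.geomspace(0.5, 2.0, 6)
        est = estimate_flip(ladder, [1] * 6)
        assert est.flip_magnification == ladder[0]
        assert est.out_of_range is OutOfRange.ABOVE_MAX

    def test_all_smaller_clamps_to_largest_rung(self):
        ladder = np.geomspace(0.5, 2.0, 6)
        est = estimate_flip(ladder, [0] * 6)
        assert est.flip_magnification == ladder[-1]
        assert est.out_of_range is OutOfRange.BELOW_MIN

    def test_monotone_violations_counted(self):
        ladder = np.geomspace(0.5, 2.0, 6)
        est = estimate_flip(ladder, [0, 1, 0, 1, 1, 1])
        assert est.monotone_violations == 1

    def test_monotone_input_reduces_to_first_crossing(self):
        """Isotonic projection is a no-op on already-monotone responses."""
        ladder = np.geomspace(0.3, 3.0, 8)
        probs = [0.0, 0.1, 0.2, 0.4, 0.6, 0.9, 1.0, 1.0]
        est = estimate_flip(ladder, probs)
        x = np.log(ladder)
        t = (0.5 - 0.4) / (0.6 - 0.4)
        expected = np.exp(x[3] + t * (x[4] - x[3]))
        assert est.flip_magnification == pytest.approx(expected)

    def test_flip_matches_exhaustive_monotone_fit(self):
        """Flip equals the crossing of the brute-force monotone projection."""
        rng = np.random.default_rng(7)
        for trial in range(200):
            n = int(rng.integers(3, 13))
            ladder = np.sort(rng.uniform(0.2, 4.0, n))
            if len(np.unique(ladder)) < n:
                continue
            probs = (
                (rng.random(n) < 0.5).astype(float) if trial % 2 else rng.random(n)
            )
            est = estimate_flip(ladder, list(probs))
            fit = _bruteforce_monotone_fit(probs)
            assert est.flip_magnification == pytest.approx(
                _crossing_from_fit(ladder, fit), rel=1e-9
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_flip(np.array([1.0, 2.0]), [0.5])


class TestMeasureLesion:
    def _oracle(self, case):
        return oracle_classifier(phantom_size_lookup(case.true_diameter_cm, case.spacing_cm))

    def test_recovers_circle_diameter(self, circle_case):
        res = measure_lesion(slice_of(circle_case), circle_case.seed_point, self._oracle(circle_case))
        assert res.out_of_range is None
        assert res.size_cm == pytest.approx(3.2, rel=0.01)

    def test_size_flip_spacing_identity(self, small_cohort):
        for case in small_cohort[:4]:
            res = measure_lesion(slice_of(case), case.seed_point, self._oracle(case))
            assert res.size_cm * res.flip_magnification / case.spacing_cm == pytest.approx(
                32.0, abs=1e-9
            )
            assert len(res.rung_probs) == len(res.rung_magnifications) == 16

    def test_robust_to_choice_of_interior_seed(self, circle_case):
        clf = self._oracle(circle_case)
        ct = slice_of(circle_case)
        r, c = circle_case.seed_point
        a = measure_lesion(ct, (r, c), clf)
        b = measure_lesion(ct, (r - 6, c + 9), clf)  # still inside the 32 px disc
        assert b.size_cm == pytest.approx(a.size_cm, rel=0.01)

    def test_scale_equivariance_across_pixel_spacings(self):
        # a circle keeps the rasterized chord identical at both spacings,
        # so any size disagreement is attributable to the method itself
        sizes = {}
        for spacing in (0.05, 0.1):
            spec = PhantomSpec(
                shape_family=ShapeFamily.SMOOTH_ELLIPSE,
                true_diameter_cm=2.4,
                aspect_ratio=1.0,
                pixel_spacing_cm=spacing,
                rng_seed=5,
            )
            case = synthesize_lesion(spec)
            res = measure_lesion(slice_of(case), case.seed_point, self._oracle(case))
            sizes[spacing] = res.size_cm
        assert sizes[0.05] == pytest.approx(sizes[0.1], rel=0.01)

    def test_lesion_below_range_flagged(self):
        spec = PhantomSpec(true_diameter_cm=0.5, pixel_spacing_cm=0.1, rng_seed=2)
        case = synthesize_lesion(spec)
        res = measure_lesion(slice_of(case), case.seed_point, self._oracle(case))
        assert res.out_of_range is OutOfRange.BELOW_MIN

    def test_refinement_tightens_the_estimate(self, circle_case):
        clf = self._oracle(circle_case)
        ct = slice_of(circle_case)
        coarse = measure_lesion(ct, circle_case.seed_point, clf, LadderConfig(refine=False))
        fine = measure_lesion(ct, circle_case.seed_point, clf, LadderConfig(refine=True))
        truth = circle_case.true_diameter_cm
        assert abs(fine.size_cm - truth) <= abs(coarse.size_cm - truth) + 1e-12
        assert fine.n_classifier_calls > coarse.n_classifier_calls

    def test_result_serializes(self, circle_case):
        res = measure_lesion(slice_of(circle_case), circle_case.seed_point, self._oracle(circle_case))
        d = res.to_dict()
        assert d["size_cm"] == res.size_cm
        assert d["out_of_range"] is None
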