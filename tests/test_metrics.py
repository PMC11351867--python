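"""Metric correctness against hand counts and brute-force oracles."""

import numpy as np
import pytest

from cascadeseg.metrics_eval import (LesionMatchConfig, dice_coefficient, f1,
                                     hd95, lesion_level_scores, paired_t_test,
                                     r_squared, rejection_ratio)


def brute_force_hd(pred, gt, spacing, percentile=95):
    """All-pairs oracle: boundary via explicit 4-neighbour checks, distances
    by exhaustive minimisation, percentile on the union of directed sets."""
    def boundary(m):
        pts = []
        h, w = m.shape
        for r in range(h):
            for c in range(w):
                if not m[r, c]:
                    continue
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not m[rr, cc]:
                        pts.append((r * spacing[0], c * spacing[1]))
                        break
        return np.array(pts)

    bp, bg = boundary(pred), boundary(gt)
    d = np.sqrt(((bp[:, None, :] - bg[None, :, :]) ** 2).sum(-1))
    directed = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return np.percentile(directed, percentile), directed.max()


class TestDice:
    def test_identical_nonempty(self):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = b[7, 7] = True
        assert dice_coefficient(a, b) == 0.0

    def test_shifted_square_hand_count(self):
        # 2x2 square vs one-column shift: overlap 2 -> 2*2/(4+4) = 0.5
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[2:4, 2:4] = True
        b[2:4, 3:5] = True
        assert dice_coefficient(a, b) == 0.5

    def test_empty_conventions(self):
        e = np.zeros((4, 4), bool)
        m = np.zeros((4, 4), bool)
        m[1, 1] = True
        assert dice_coefficient(e, e) == 1.0
        assert dice_coefficient(m, e) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((9, 9)) > 0.6, rng.random((9, 9)) > 0.6
        assert dice_coefficient(a, b) == dice_coefficient(b, a)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestHd95:
    def test_identical_zero(self):
        m = np.zeros((10, 10), bool)
        m[3:7, 3:7] = True
        assert hd95(m, m) == 0.0

    def test_two_pixels_three_columns_apart(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[4, 2] = True
        b[4, 5] = True
        assert hd95(a, b, (1.0, 1.0)) == pytest.approx(3.0)

    def test_spacing_linearity(self):
        rng = np.random.default_rng(5)
        a = rng.random((12, 12)) > 0.7
        b = rng.random((12, 12)) > 0.7
        d1 = hd95(a, b, (1.0, 1.0))
        d2 = hd95(a, b, (2.0, 2.0))
        assert d2 == pytest.approx(2 * d1)

    def test_empty_mask_undefined(self):
        m = np.zeros((6, 6), bool)
        n = m.copy()
        n[2, 2] = True
        assert np.isnan(hd95(m, n))
        assert np.isnan(hd95(n, m))

    def test_oracle_equivalence_random_masks(self):
        """hd95 must equal the brute-force all-pairs percentile on >= 200
        random mask pairs, and never exceed the exact Hausdorff distance."""
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 200:
            size = int(rng.integers(4, 33))
            density = rng.uniform(0.05, 0.6)
            a = rng.random((size, size)) < density
            b = rng.random((size, size)) < density
            if not (a.any() and b.any()):
                continue
            spacing = tuple(rng.uniform(0.3, 2.0, 2))
            expected, exact_hd = brute_force_hd(a, b, spacing)
            got = hd95(a, b, spacing)
            assert got == pytest.approx(expected, abs=1e-9)
            assert got <= exact_hd + 1e-9
            checked += 1


class TestLesionLevel:
    def test_perfect_single_lesion(self):
        v = np.zeros((3, 8, 8), bool)
        v[1, 2:5, 2:5] = True
        s = lesion_level_scores(v, v)
        assert (s.tpr, s.ppv, s.f1) == (1.0, 1.0, 1.0)

    def test_asymmetric_overlap_hand_case(self):
        # gt lesion 10 voxels; prediction 20 voxels overlapping 1 voxel.
        # tau=0.1: recall 1 (1/10 >= 0.1), precision 0 (1/20 < 0.1), F1 0.
        gt = np.zeros((1, 10, 10), bool)
        gt[0, 0, 0:10] = True
        pred = np.zeros((1, 10, 10), bool)
        pred[0, 0, 9] = True
        pred[0, 1, 0:10] = True
        pred[0, 2, 0:9] = True
        assert pred.sum() == 20 and gt.sum() == 10
        assert np.logical_and(pred, gt).sum() == 1
        s = lesion_level_scores(gt, pred, LesionMatchConfig(tau=0.1))
        assert s.tpr == 1.0
        assert s.ppv == 0.0
        assert s.f1 == 0.0

    def test_tpr_ppv_non_increasing_in_tau(self):
        rng = np.random.default_rng(7)
        gt = rng.random((4, 16, 16)) > 0.8
        pred = rng.random((4, 16, 16)) > 0.8
        taus = [0.0, 0.1, 0.3, 0.6, 1.0]
        scores = [lesion_level_scores(gt, pred, LesionMatchConfig(tau=t))
                  for t in taus]
        for s1, s2 in zip(scores, scores[1:]):
            assert s2.tpr <= s1.tpr + 1e-12
            assert s2.ppv <= s1.ppv + 1e-12

    def test_empty_volumes_nan_denominators(self):
        empty = np.zeros((2, 6, 6), bool)
        filled = np.zeros((2, 6, 6), bool)
        filled[0, 1:3, 1:3] = True
        assert np.isnan(lesion_level_scores(empty, filled).tpr)
        assert np.isnan(lesion_level_scores(filled, empty).ppv)

    def test_f1_consistency_of_emitted_triples(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            gt = rng.random((3, 12, 12)) > 0.85
            pred = rng.random((3, 12, 12)) > 0.85
            s = lesion_level_scores(gt, pred)
            if np.isnan(s.tpr) or np.isnan(s.ppv):
                continue
            assert s.f1 == pytest.approx(f1(s.ppv, s.tpr), abs=1e-12)


class TestF1:
    def test_equal_inputs(self):
        assert f1(0.3, 0.3) == pytest.approx(0.3)

    def test_printed_row_arithmetic(self):
        assert f1(0.935, 0.917) == pytest.approx(0.926, abs=5e-4)

    def test_zero_precision(self):
        assert f1(0.0, 1.0) == 0.0
        assert f1(0.0, 0.0) == 0.0


class TestRSquared:
    def test_perfect(self):
        d = [0.1, 0.5, 0.9]
        assert r_squared(d, d) == 1.0

    def test_mean_predictor_zero(self):
        d = np.array([0.2, 0.4, 0.9])
        s = np.full(3, d.mean())
        assert r_squared(s, d) == pytest.approx(0.0)

    def test_hand_value(self):
        assert r_squared([0.2, 0.4], [0.3, 0.5]) == pytest.approx(0.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            r_squared([0.1, 0.2], [0.5, 0.5])


class TestRejectionRatio:
    def test_none_below(self):
        assert rejection_ratio([0.5, 0.9], 0.4) == 0.0

    def test_one_third(self):
        assert rejection_ratio([0.3, 0.5, 0.9], 0.4) == pytest.approx(1 / 3)

    def test_boundary_not_counted(self):
        assert rejection_ratio([0.4, 0.5], 0.4) == 0.0

    def test_step_monotone_in_t(self):
        rng = np.random.default_rng(2)
        s = rng.random(50)
        ts = np.linspace(0, 1.1, 23)
        ratios = [rejection_ratio(s, t) for t in ts]
        assert all(b >= a for a, b in zip(ratios, ratios[1:]))
        assert ratios[0] == 0.0 and ratios[-1] == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rejection_ratio([], 0.5)


class TestPairedT:
    def test_identical_lists(self):
        assert paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_constant_shift_degenerate(self):
        with pytest.raises(ValueError):
            paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_known_shift_significant(self):
        rng = np.random.default_rng(31)
        b = rng.normal(0, 1, 1000)
        a = b + 0.3 + rng.normal(0, 0.5, 1000)
        stat, p = paired_t_test(a, b)
        assert p < 0.01
        assert stat > 0
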