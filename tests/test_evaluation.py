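import numpy as np
import pytest

from discseg.evaluation import (
    EvalConfig,
    accuracy,
    conservative_sample_size,
    discrimination,
    evaluate_dataset,
    image_correct,
    iou,
    match_instances,
)
from discseg.instance_ops import connected_components


def square(shape, r0, r1, c0, c1):
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


class TestIoU:
    def test_identity(self):
        m = square((8, 8), 1, 4, 1, 4)
        assert iou(m, m) == 1.0

    def test_disjoint(self):
        assert iou(square((8, 8), 0, 2, 0, 2), square((8, 8), 5, 7, 5, 7)) == 0.0

    def test_shifted_square(self):
        # 2x2 square vs same shifted right by one: intersection 2, union 6
        a = square((6, 6), 2, 4, 2, 4)
        b = square((6, 6), 2, 4, 3, 5)
        assert iou(a, b) == pytest.approx(2 / 6)

    def test_empty_conventions(self):
        empty = np.zeros((4, 4), dtype=bool)
        assert iou(empty, empty) == 1.0
        assert iou(empty, square((4, 4), 0, 2, 0, 2)) == 0.0

    def test_symmetric(self, rng):
        for _ in range(10):
            a = rng.random((10, 10)) < 0.4
            b = rng.random((10, 10)) < 0.4
            assert iou(a, b) == iou(b, a)

    def test_matches_pixel_count_oracle(self, rng):
        for _ in range(20):
            a = rng.random((12, 12)) < 0.4
            b = rng.random((12, 12)) < 0.4
            inter = sum(1 for r in range(12) for c in range(12) if a[r, c] and b[r, c])
            union = sum(1 for r in range(12) for c in range(12) if a[r, c] or b[r, c])
            expected = 1.0 if union == 0 else inter / union
            assert iou(a, b) == pytest.approx(expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iou(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestDiscrimination:
    def test_full_coverage(self):
        s = square((8, 8), 2, 5, 2, 5)
        r = square((8, 8), 1, 6, 1, 6)
        assert discrimination(r, s) == 1.0

    def test_no_overlap(self):
        assert discrimination(square((8, 8), 0, 2, 0, 2), square((8, 8), 5, 7, 5, 7)) == 0.0

    def test_partial_coverage_ignores_outside_pixels(self):
        s = np.zeros((10, 10), dtype=bool)
        s[0, 0:10] = True  # 10 pixels
        r = np.zeros((10, 10), dtype=bool)
        r[0, 0:7] = True  # covers 7 of them
        r[5:9, 5:9] = True  # extra pixels outside S must not change C
        assert discrimination(r, s) == pytest.approx(0.7)

    def test_asymmetric(self):
        s = square((8, 8), 2, 4, 2, 4)
        r = square((8, 8), 2, 6, 2, 6)
        assert discrimination(r, s) == 1.0
        assert discrimination(s, r) == pytest.approx(4 / 16)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discrimination(square((4, 4), 0, 2, 0, 2), np.zeros((4, 4), bool))

    def test_consistency_with_iou(self, rng):
        # |X∩Y|/|X∪Y| == C(Y,X) * |X| / |X∪Y|
        for _ in range(10):
            x = rng.random((10, 10)) < 0.5
            y = rng.random((10, 10)) < 0.5
            if not x.any() or not (x | y).any():
                continue
            lhs = iou(x, y)
            rhs = discrimination(y, x) * x.sum() / (x | y).sum()
            assert lhs == pytest.approx(rhs)


class TestImageCorrect:
    def test_all_conditions_met(self):
        assert image_correct(3, (0.9, 0.8, 0.71)) == 1

    def test_wrong_count_is_error(self):
        assert image_correct(4, None) == 0
        assert image_correct(2, None) == 0

    def test_low_coverage_is_error(self):
        assert image_correct(3, (0.9, 0.69, 0.9)) == 0

    def test_boundary_exactly_at_threshold_is_correct(self):
        assert image_correct(3, (0.70, 0.70, 0.70)) == 1

    def test_missing_coverages_with_correct_count_rejected(self):
        with pytest.raises(ValueError):
            image_correct(3, (0.9, 0.9))


class TestAccuracy:
    def test_table_arithmetic(self):
        b = [1] * 289 + [0] * 19
        B, A = accuracy(b)
        assert B == 289
        assert round(A, 3) == 0.938

    def test_all_zero(self):
        assert accuracy([0, 0, 0]) == (0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy([])

    def test_accuracy_times_t_integral(self, rng):
        b = list((rng.random(17) > 0.5).astype(int))
        B, A = accuracy(b)
        assert A * len(b) == pytest.approx(B)
        assert 0.0 <= A <= 1.0


def ref_mask():
    m = np.zeros((30, 10), dtype=np.int32)
    m[2:5, 2:8] = 1
    m[12:15, 2:8] = 2
    m[22:25, 2:8] = 3
    return m


class TestMatchInstances:
    def test_identity_pairing(self):
        ref = ref_mask()
        pairs = match_instances(ref, ref)
        assert len(pairs) == 3
        for r, s in pairs:
            assert np.array_equal(r, s)

    def test_label_permutation_restored_by_rank(self):
        ref = ref_mask()
        pred = np.zeros_like(ref)
        pred[ref == 1] = 3
        pred[ref == 2] = 1
        pred[ref == 3] = 2
        ranked = connected_components(pred > 0)
        pairs = match_instances(ranked, ref)
        for k, (r, s) in enumerate(pairs, start=1):
            assert np.array_equal(r, ref == k)

    def test_wrong_count_gives_no_pairing(self):
        ref = ref_mask()
        pred = np.where(ref == 3, 0, ref)
        assert match_instances(pred, ref) is None

    def test_bad_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            match_instances(ref_mask(), np.zeros((30, 10), dtype=np.int32))


class TestEvaluateDataset:
    def test_perfect_predictions(self):
        refs = [ref_mask(), ref_mask()]
        report = evaluate_dataset(refs, refs)
        assert report.T == 2 and report.B == 2
        assert report.A == 1.0 and report.mean_iou == 1.0

    def test_one_failure_halves_accuracy(self):
        ref = ref_mask()
        bad = np.where(ref == 1, 0, ref)  # missing an instance
        report = evaluate_dataset([ref, bad], [ref, ref])
        assert report.A == 0.5
        assert report.records[1].b_i == 0
        assert report.records[1].P_i == 2
        assert 0 < report.records[1].iou_i < 1

    def test_b_equals_record_sum(self, rng):
        ref = ref_mask()
        preds = [ref, np.where(ref == 2, 0, ref), ref]
        report = evaluate_dataset(preds, [ref] * 3)
        assert report.B == sum(r.b_i for r in report.records)
        assert report.A == report.B / report.T

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_dataset([ref_mask()], [ref_mask(), ref_mask()])

    def test_report_serialization(self, tmp_path):
        report = evaluate_dataset([ref_mask()], [ref_mask()])
        report.to_json(tmp_path / "r.json")
        report.to_csv(tmp_path / "r.csv")
        assert '"A": 1.0' in (tmp_path / "r.json").read_text()
        lines = (tmp_path / "r.csv").read_text().strip().splitlines()
        assert len(lines) == 2


class TestConservativeSampleSize:
    def test_reference_configuration(self):
        assert conservative_sample_size(0.95, 0.01, 0.0004) == 2401

    def test_margin_equal_to_z_times_sd(self):
        from scipy.stats import norm

        z = norm.ppf(0.975)
        assert conservative_sample_size(0.95, 0.01, z * 0.01) == 1

    def test_doubling_sd_quadruples_n(self):
        n1 = conservative_sample_size(0.95, 0.01, 0.0004)
        n4 = conservative_sample_size(0.95, 0.02, 0.0004)
        assert 4 * n1 - 4 <= n4 <= 4 * n1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            conservative_sample_size(margin=0.0)
        with pytest.raises(ValueError):
            conservative_sample_size(confidence=1.5)
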