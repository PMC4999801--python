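import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from ki67quant import (
    NucleusRecord,
    SampleSizeParams,
    build_nucleus_table,
    evaluate_detections,
    grade_from_percentage,
    grade_section,
    paired_t_test,
    quantify_field,
    required_sample_size,
)
from ki67quant.errors import (
    DegenerateInputError,
    DomainError,
    InsufficientDataError,
)
from ki67quant.morphology import LabelledNuclei


def _rec(cls="DAB", mean_ib=50.0, id=1):
    return NucleusRecord(id=id, cls=cls, area=100, centroid=(1.0, 1.0),
                         circularity=0.9, mean_Ib=mean_ib)


class TestBuildNucleusTable:
    def test_empty(self):
        empty = LabelledNuclei(labels=np.zeros((5, 5), dtype=np.int32), n_objects=0)
        assert build_nucleus_table({"DAB": empty}, np.zeros((5, 5))) == []

    def test_solid_square_geometry(self):
        labels = np.zeros((9, 9), dtype=np.int32)
        labels[2:7, 2:7] = 1
        ln = LabelledNuclei(labels=labels, n_objects=1)
        (rec,) = build_nucleus_table({"DAB": ln}, np.full((9, 9), 40.0))
        assert rec.area == 25
        assert rec.mean_Ib == pytest.approx(40.0)
        assert rec.centroid == pytest.approx((4.0, 4.0))
        # 5x5 square: 16 boundary pixels -> circularity = 4*pi*25/256
        assert rec.circularity == pytest.approx(4 * np.pi * 25 / 256)

    def test_scanline_id_order_across_classes(self):
        d = np.zeros((6, 6), dtype=np.int32)
        d[4, 1] = 1
        h = np.zeros((6, 6), dtype=np.int32)
        h[1, 1] = 1
        records = build_nucleus_table(
            {"DAB": LabelledNuclei(d, 1), "HEMATOXYLIN": LabelledNuclei(h, 1)},
            np.zeros((6, 6)),
        )
        assert [r.cls for r in records] == ["HEMATOXYLIN", "DAB"]
        assert [r.id for r in records] == [1, 2]


class TestQuantifyField:
    def test_three_to_one(self):
        recs = [_rec(id=i) for i in range(1, 4)] + [_rec("HEMATOXYLIN", id=4)]
        q = quantify_field(recs)
        assert q.positive_percentage == pytest.approx(75.0)

    def test_no_dab(self):
        q = quantify_field([_rec("HEMATOXYLIN", id=i) for i in range(1, 6)])
        assert q.positive_percentage == 0.0
        assert q.coloring_strength_Ib is None
        assert q.positive_level == 0.0

    def test_no_nuclei_nulls(self):
        q = quantify_field([])
        assert q.positive_percentage is None and q.coloring_strength_Ib is None

    def test_strength_and_level_arithmetic(self):
        recs = [_rec(mean_ib=40.0, id=1), _rec(mean_ib=50.0, id=2),
                _rec("HEMATOXYLIN", id=3), _rec("HEMATOXYLIN", id=4)]
        q = quantify_field(recs)
        assert q.coloring_strength_Ib == pytest.approx(45.0)
        assert q.positive_level == pytest.approx((1 - 45 / 255) * 0.5)
        assert q.positive_level == pytest.approx(0.4118, abs=1e-4)

    def test_positive_plus_negative_is_100(self):
        recs = [_rec(id=1), _rec("HEMATOXYLIN", id=2), _rec("HEMATOXYLIN", id=3)]
        q = quantify_field(recs)
        negative = 100.0 * q.n_hema / (q.n_dab + q.n_hema)
        assert q.positive_percentage + negative == pytest.approx(100.0)


class TestGradeBands:
    @pytest.mark.parametrize(
        "p, grade, level",
        [
            (0.0, "-", "low"),
            (3.0, "-", "low"),
            (5.0, "-", "low"),
            (5.1, "+", "low"),
            (25.0, "+", "low"),
            (25.1, "++", "medium"),
            (30.0, "++", "medium"),
            (50.0, "++", "medium"),
            (50.1, "+++", "high"),
            (100.0, "+++", "high"),
        ],
    )
    def test_band_boundaries(self, p, grade, level):
        assert grade_from_percentage(p) == (grade, level)

    @pytest.mark.parametrize("p", [-0.1, 100.1])
    def test_out_of_domain(self, p):
        with pytest.raises(DomainError):
            grade_from_percentage(p)

    @given(st.floats(0, 100), st.floats(0, 100))
    def test_monotone_in_percentage(self, a, b):
        order = ["-", "+", "++", "+++"]
        lo, hi = sorted((a, b))
        g_lo, _ = grade_from_percentage(lo)
        g_hi, _ = grade_from_percentage(hi)
        assert order.index(g_lo) <= order.index(g_hi)


class TestGradeSection:
    def _field(self, pct):
        n_dab = int(round(pct))
        recs = [_rec(id=i) for i in range(1, n_dab + 1)]
        recs += [_rec("HEMATOXYLIN", id=100 + i) for i in range(100 - n_dab)]
        return quantify_field(recs)

    def test_mean_then_grade(self):
        quants = [self._field(p) for p in (60, 70, 80, 55, 65)]
        s = grade_section(quants)
        assert s.mean_percentage == pytest.approx(66.0)
        assert s.grade == "+++" and s.level == "high"

    def test_single_field(self):
        s = grade_section([self._field(10)])
        assert s.grade == "+" and s.level == "low"

    def test_order_invariance(self):
        quants = [self._field(p) for p in (60, 70, 80, 55, 65)]
        a = grade_section(quants)
        b = grade_section(list(reversed(quants)))
        assert a.mean_percentage == b.mean_percentage and a.grade == b.grade

    def test_all_null_fields_error(self):
        with pytest.raises(InsufficientDataError):
            grade_section([quantify_field([])])


class TestRequiredSampleSize:
    def test_reference_parameters(self):
        n = required_sample_size(SampleSizeParams(delta=5, sigma_d=6.7))
        assert n == 19

    def test_sigma_equals_delta(self):
        assert required_sample_size(SampleSizeParams(delta=5, sigma_d=5)) == 11

    def test_zero_sigma_floors_at_one(self):
        assert required_sample_size(SampleSizeParams(delta=5, sigma_d=0)) == 1

    def test_zero_delta_domain_error(self):
        with pytest.raises(DomainError):
            SampleSizeParams(delta=0, sigma_d=5)

    @given(st.floats(0.5, 20), st.floats(0.1, 20), st.floats(0.1, 20))
    def test_monotone_in_sigma_and_delta(self, delta, s1, s2):
        lo, hi = sorted((s1, s2))
        assert required_sample_size(SampleSizeParams(delta, lo)) <= required_sample_size(
            SampleSizeParams(delta, hi)
        )
        assert required_sample_size(SampleSizeParams(delta + 1, hi)) <= required_sample_size(
            SampleSizeParams(delta, hi)
        )


class TestPairedT:
    def test_hand_arithmetic_example(self):
        t, p = paired_t_test([70, 75, 80], [72, 74, 81])
        assert t == pytest.approx(-0.7559, abs=1e-4)
        assert p == pytest.approx(0.5286, abs=1e-3)

    def test_agrees_with_library_routine(self, rng):
        x = rng.normal(70, 5, size=12)
        y = x + rng.normal(0, 2, size=12)
        t, p = paired_t_test(x, y)
        ref = sps.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_constant_shift_degenerate(self):
        x = [1.0, 2.0, 3.0]
        with pytest.raises(DegenerateInputError):
            paired_t_test(x, [v + 2 for v in x])

    def test_antisymmetry(self):
        t1, p1 = paired_t_test([70, 75, 80], [72, 74, 81])
        t2, p2 = paired_t_test([72, 74, 81], [70, 75, 80])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestEvaluateDetections:
    def _labels(self, objects, shape=(30, 30)):
        out = np.zeros(shape, dtype=np.int32)
        for i, (r0, c0, size) in enumerate(objects, start=1):
            out[r0:r0 + size, c0:c0 + size] = i
        return out

    def test_exact_match(self):
        truth = self._labels([(2, 2, 4), (10, 10, 4), (20, 20, 4)])
        far, frr, acc = evaluate_detections(truth, truth)
        assert (far, frr, acc) == (0.0, 0.0, 100.0)

    def test_counting_rule(self):
        # 10 truths; predictions match 9 of them, plus 2 spurious
        objs = [(3 * i, 3 * i, 2) for i in range(10)]
        truth = self._labels(objs, shape=(40, 40))
        pred_objs = objs[:9] + [(0, 30, 2), (30, 0, 2)]
        pred = self._labels(pred_objs, shape=(40, 40))
        far, frr, acc = evaluate_detections(pred, truth)
        assert far == pytest.approx(20.0)
        assert frr == pytest.approx(10.0)
        assert acc == pytest.approx(70.0)

    def test_relabeling_invariance(self):
        truth = self._labels([(2, 2, 4), (10, 10, 4), (20, 20, 4)])
        pred = truth.copy()
        relabel = np.array([0, 3, 1, 2])
        far, frr, acc = evaluate_detections(relabel[pred], truth)
        assert (far, frr, acc) == (0.0, 0.0, 100.0)

    def test_half_iou_threshold(self):
        truth = np.zeros((10, 10), dtype=np.int32)
        truth[0:4, 0:4] = 1
        pred = np.zeros((10, 10), dtype=np.int32)
        pred[0:4, 2:6] = 1  # IoU = 8/24 = 1/3 < 0.5: no match
        far, frr, acc = evaluate_detections(pred, truth)
        assert far == 100.0 and frr == 100.0

    def test_empty_truth_error(self):
        with pytest.raises(DomainError):
            evaluate_detections(np.ones((5, 5), dtype=np.int32), np.zeros((5, 5), dtype=np.int32))
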