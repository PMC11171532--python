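"""SAD metric, quartile subgroups, and statistical summary."""

import numpy as np
import pytest

from mammosub.evaluation import (
    CaseRecord,
    compare_and_summarize,
    evaluate_case,
    quartile_split,
    sad,
)
from mammosub.model import SMALL_CONFIG, RegistrationUNet
from mammosub.preprocess import RegistrationPair


class TestSAD:
    def test_identical_images_zero(self, rng):
        img = rng.random((8, 8))
        assert sad(img, img, np.ones((8, 8), dtype=bool)) == 0.0

    def test_unit_contrast_full_mask(self):
        assert sad(np.ones((4, 4)), np.zeros((4, 4)), np.ones((4, 4), dtype=bool)) == 1.0

    def test_hand_computed_example(self):
        a = np.array([[0, 0.5], [1, 0.25]])
        b = np.array([[0.5, 0.5], [0, 0.25]])
        assert sad(a, b, np.ones((2, 2), dtype=bool)) == pytest.approx(0.375)

    def test_symmetric_nonnegative(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        mask = rng.random((8, 8)) > 0.4
        assert sad(a, b, mask) == sad(b, a, mask) >= 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sad(np.ones((4, 4)), np.ones((4, 4)), np.zeros((4, 4), dtype=bool))


class TestEvaluateCase:
    def test_identity_model_improvement_negligible(self, rng):
        """Zero-initialised flow warps exactly: SADs agree to float eps."""
        img = rng.random((32, 32)).astype(np.float32)
        other = rng.random((32, 32)).astype(np.float32)
        pair = RegistrationPair(
            fixed=img, flipped=other, mask=np.ones((32, 32), dtype=bool), case_id="x"
        )
        model = RegistrationUNet(SMALL_CONFIG, seed=0)
        record, diff0, diff1, field = evaluate_case(model, pair)
        assert np.all(field == 0)
        assert abs(record.improvement) < 1e-6
        assert record.sad_without == pytest.approx(record.sad_with, abs=1e-6)

    def test_records_match_difference_images(self, rng):
        img = rng.random((32, 32)).astype(np.float32)
        other = rng.random((32, 32)).astype(np.float32)
        mask = np.ones((32, 32), dtype=bool)
        pair = RegistrationPair(fixed=img, flipped=other, mask=mask, case_id="x")
        model = RegistrationUNet(SMALL_CONFIG, seed=0)
        record, diff0, diff1, _ = evaluate_case(model, pair)
        assert record.sad_without == pytest.approx(diff0[mask].mean())
        assert record.sad_with == pytest.approx(diff1[mask].mean())

    def test_improvement_identity_holds_exactly(self):
        r = CaseRecord(case_id="a", sad_without=0.07, sad_with=0.052)
        assert r.improvement == 0.07 - 0.052


def _records(values, covariate="breast_area_pct"):
    return [
        CaseRecord(
            case_id=f"c{i:03d}",
            sad_without=0.05,
            sad_with=0.04,
            **{covariate: v},
        )
        for i, v in enumerate(values)
    ]


class TestQuartileSplit:
    def test_500_records_split_into_125s(self, rng):
        recs = _records(rng.random(500))
        labels = quartile_split(recs, "breast_area_pct")
        assert [int((labels == g).sum()) for g in (1, 2, 3, 4)] == [125] * 4

    def test_uneven_split_larger_groups_first(self, rng):
        recs = _records(rng.random(10))
        labels = quartile_split(recs, "breast_area_pct")
        assert [int((labels == g).sum()) for g in (1, 2, 3, 4)] == [3, 3, 2, 2]

    def test_decreasing_order_for_area(self):
        recs = _records([10.0, 40.0, 20.0, 30.0])
        labels = quartile_split(recs, "breast_area_pct")
        # Group 1 holds the largest breast area
        assert labels[1] == 1 and labels[0] == 4

    def test_increasing_order_for_baseline_sad(self):
        recs = [
            CaseRecord(case_id=f"c{i}", sad_without=v, sad_with=v / 2)
            for i, v in enumerate([0.09, 0.02, 0.05, 0.07])
        ]
        labels = quartile_split(recs, "sad_without")
        assert labels[1] == 1 and labels[0] == 4

    def test_ties_break_stably_by_case_id(self):
        recs = _records([1.0] * 8)
        labels = quartile_split(recs, "breast_area_pct")
        assert list(labels) == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_group_blocks_are_contiguous_in_sort_order(self, rng):
        recs = _records(rng.random(17))
        labels = quartile_split(recs, "breast_area_pct")
        values = np.array([r.breast_area_pct for r in recs])
        order = np.argsort(-values, kind="stable")
        assert list(np.sort(labels[order])) == list(labels[order])

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ValueError, match="unknown covariate"):
            quartile_split(_records([1, 2, 3, 4]), "shoe_size")


class TestCompareAndSummarize:
    def _cohort(self, rng, n=48, all_improve=True):
        recs = []
        for i in range(n):
            sw = rng.uniform(0.03, 0.12)
            delta = rng.uniform(0.001, 0.02) if all_improve else 0.0
            recs.append(
                CaseRecord(
                    case_id=f"c{i:03d}",
                    sad_without=sw,
                    sad_with=sw - delta,
                    breast_area_pct=rng.uniform(11, 80),
                    density_pct=rng.uniform(12, 85),
                    thickness_mm=rng.uniform(12, 84),
                )
            )
        return recs

    def test_strict_improvement_gives_minimal_p(self, rng):
        report = compare_and_summarize(self._cohort(rng, n=50))
        assert report.overall_p < 0.001

    def test_zero_improvement_gives_p_one(self, rng):
        report = compare_and_summarize(self._cohort(rng, all_improve=False))
        assert report.overall_p == 1.0

    def test_report_has_table2_shape(self, rng):
        report = compare_and_summarize(self._cohort(rng))
        assert report.table.shape[0] == 4 * 4  # 4 covariates x 4 groups
        assert {"sad_without_mean", "sad_with_mean"} <= set(report.table.columns)
        assert len(report.pairwise) == 4 * 6  # 6 group pairs per covariate

    def test_markdown_rendering(self, rng):
        md = compare_and_summarize(self._cohort(rng)).to_markdown()
        assert "Overall" in md and "Pairwise" in md
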