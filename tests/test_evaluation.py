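"""Evaluation summaries: confusion tables, error curves, item statistics."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import exam_with
from iira.classifier import ais_group, classify
from iira.evaluation import (
    ConfusionTable3,
    completeness_error_by_nli,
    confusion_grouping,
    item_count_summary,
    round1,
    table_summaries,
    ue_weakness_by_sensory_level,
)
from iira.exam_model import level_index
from iira.iira_policy import run_iira
from iira.s1_substitution import ais_grouping_with_s1
from iira.synthetic_cohort import CohortConfig, generate_cohort


class TestConfusionTable:
    def test_full_method_is_diagonal(self, small_cohort):
        table = confusion_grouping(small_cohort[:80], "full")
        assert table.total == 80
        assert np.trace(table.counts) == 80

    def test_additive_under_concatenation(self, small_cohort):
        a, b = small_cohort[:60], small_cohort[60:140]
        combined = confusion_grouping(list(a) + list(b), "s1sub")
        assert (combined.counts
                == (confusion_grouping(a, "s1sub") + confusion_grouping(b, "s1sub")).counts).all()

    def test_matches_per_case_brute_force(self, small_cohort):
        cohort = small_cohort[:120]
        pairs = [(ais_group(classify(e).ais), ais_grouping_with_s1(e)) for e in cohort]
        assert (confusion_grouping(cohort, "s1sub").counts
                == ConfusionTable3.from_pairs(pairs).counts).all()

    def test_true_b_with_absent_s1_lands_in_b_a_cell(self):
        exam = exam_with(sensory_levels=("T6", "T6"), s45=(1, 0, 0, 0))
        table = confusion_grouping([exam], "s1sub")
        assert table.counts[1, 0] == 1 and table.total == 1


class TestSummaries:
    def test_identity_table_is_perfect(self):
        stats = table_summaries(ConfusionTable3(np.eye(3, dtype=int) * 7))
        assert stats.overall_accuracy == 100.0
        assert all(v == 100.0 for v in stats.recall.values())
        assert all(v == 100.0 for v in stats.precision.values())

    def test_empty_row_and_column_are_undefined(self):
        counts = np.array([[5, 0, 0], [0, 0, 0], [2, 0, 3]])
        stats = table_summaries(ConfusionTable3(counts))
        assert stats.recall["B"] is None
        assert stats.precision["B"] is None
        assert stats.recall["A"] == 100.0

    def test_rounding_half_away_from_zero(self):
        assert round1(55.04) == 55.0
        assert round1(92.45) == 92.5
        assert round1(89.525) == 89.5  # 6290/7026


class TestCompletenessError:
    def test_full_method_has_zero_error(self, small_cohort):
        frame = completeness_error_by_nli(small_cohort[:100], "full")
        assert (frame["error_pct"] == 0.0).all()
        assert (frame["n"] > 0).all()

    def test_forced_t12_misclassification_is_total(self):
        exams = [exam_with(sensory_levels=("T12", "T12"), s45=(1, 1, 0, 0),
                           case_id=f"t12-{i}") for i in range(4)]
        frame = completeness_error_by_nli(exams, "s1sub").set_index("level")
        assert frame.loc["T12", "error_pct"] == 100.0
        assert bool(frame.loc["T12", "nli_t10_or_rostral"]) is False

    def test_rates_match_brute_force_recount(self, small_cohort):
        cohort = small_cohort[:150]
        frame = completeness_error_by_nli(cohort, "s1sub").set_index("level")
        per_level: dict[str, list[int]] = {}
        for exam in cohort:
            truth = classify(exam)
            err = (truth.ais == "A") != (ais_grouping_with_s1(exam) == "A")
            per_level.setdefault(truth.nli, []).append(int(err))
        assert set(frame.index) == set(per_level)
        for level, errs in per_level.items():
            assert frame.loc[level, "n"] == len(errs)
            assert frame.loc[level, "error_pct"] == round1(100 * sum(errs) / len(errs))


class TestUEWeakness:
    def test_normal_upper_limbs_zero_everywhere(self):
        exams = [exam_with(sensory_levels=("T6", "T6"), case_id=f"c{i}")
                 for i in range(3)]
        frame = ue_weakness_by_sensory_level(exams)
        assert (frame["weakness_pct"] == 0.0).all()

    def test_c8_weakness_at_t2_counted(self):
        motor = [[5, 5, 5, 4, 5, 0, 0, 0, 0, 0]] * 2  # C8 grade 4
        exams = [exam_with(sensory_levels=("T2", "T2"), motor=motor,
                           case_id=f"c{i}") for i in range(3)]
        frame = ue_weakness_by_sensory_level(exams).set_index("level")
        assert frame.loc["T2", "weakness_pct"] == 100.0

    def test_matches_brute_force(self, small_cohort):
        frame = ue_weakness_by_sensory_level(small_cohort).set_index("level")
        for level, row in frame.iterrows():
            n = weak = 0
            for exam in small_cohort:
                truth = classify(exam)
                rostral = min(truth.sensory_level_r, truth.sensory_level_l,
                              key=level_index)
                if rostral == level:
                    n += 1
                    weak += int((exam.motor[:, :5] < 5).any())
            assert row["n"] == n and row["n_weak"] == weak


class TestItemStats:
    def test_single_result(self, small_cohort):
        res = run_iira(small_cohort[0])
        stats = item_count_summary([res])
        assert stats.n == 1 and stats.sd_items is None
        assert stats.mean_items == res.log.total
        assert stats.mean_fraction_of_full == res.log.total / 134

    def test_two_results_closed_form(self, small_cohort):
        # Totals 40 and 44: mean 42, sample SD sqrt(8) = 2.83.
        import types

        def stub(total):
            run = run_iira(small_cohort[0])
            return types.SimpleNamespace(
                log=types.SimpleNamespace(total=total),
                anorectal_omitted=False,
                classification=run.classification)

        stats = item_count_summary([stub(40), stub(44)])
        assert stats.mean_items == 42.0
        assert stats.sd_items == pytest.approx(2.8284, abs=1e-3)

    def test_sample_sd_formula(self, small_cohort):
        results = [run_iira(e) for e in small_cohort[:10]]
        stats = item_count_summary(results)
        totals = [r.log.total for r in results]
        assert stats.mean_items == pytest.approx(np.mean(totals))
        assert stats.sd_items == pytest.approx(np.std(totals, ddof=1))

    def test_mean_below_full_exam(self, small_cohort):
        stats = item_count_summary([run_iira(e) for e in small_cohort])
        assert stats.mean_items < 134
        assert stats.by_band["cervical"]["mean"] < stats.by_band["thoracic"]["mean"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            item_count_summary([])
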