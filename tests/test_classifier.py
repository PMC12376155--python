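"""Classification engine: levels, sacral sparing, AIS, oracle equivalence."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import exam_with, normal_exam
from iira.classifier import (
    ais_grade,
    ais_group,
    classify,
    motor_level,
    nli_band,
    sacral_sparing,
    sensory_level,
)
from iira.exam_model import FullExam, KEY_MUSCLES, level_index
from iira.synthetic_cohort import CohortConfig, generate_cohort
from oracles import oracle_classify


class TestSensoryLevel:
    def test_fully_normal_side_is_intact(self):
        assert sensory_level(normal_exam(), "R") == "INT"

    def test_first_abnormal_modality_sets_level(self):
        exam = normal_exam()
        exam.lt[0, level_index("C7")] = 1
        assert sensory_level(exam, "R") == "C6"
        assert sensory_level(exam, "L") == "INT"

    def test_abnormal_c2_gives_c1(self):
        exam = normal_exam()
        exam.pp[0, 0] = 0
        assert sensory_level(exam, "R") == "C1"


class TestMotorLevel:
    def test_all_normal_is_intact(self):
        assert motor_level(normal_exam(), "R", "INT") == "INT"

    def test_most_caudal_antigravity_with_normal_rostral(self):
        motor = [[5, 3, 0, 0, 0, 0, 0, 0, 0, 0]] * 2
        exam = exam_with(sensory_levels=("C6", "C6"), motor=motor)
        assert motor_level(exam, "R", "C6") == "C6"

    def test_motor_follows_sensory_in_thoracic_segments(self):
        exam = exam_with(sensory_levels=("T6", "T6"), motor=[[5] * 10] * 2)
        assert motor_level(exam, "R", "T6") == "T6"

    def test_grade_four_caps_descent(self):
        motor = [[4, 5, 5, 5, 5, 5, 5, 5, 5, 5]] * 2
        exam = exam_with(sensory_levels=("INT", "INT"), motor=motor)
        assert motor_level(exam, "R", "INT") == "C5"


class TestSacralSparing:
    def test_none(self):
        exam = exam_with(sensory_levels=("T4", "T4"))
        assert sacral_sparing(exam) == (False, False)

    def test_single_s45_score_is_sensory_sparing(self):
        exam = exam_with(sensory_levels=("T4", "T4"), s45=(1, 0, 0, 0))
        assert sacral_sparing(exam) == (True, False)

    def test_vac_only_is_motor_sparing(self):
        exam = exam_with(sensory_levels=("T4", "T4"), vac=True)
        assert sacral_sparing(exam) == (False, True)


class TestAISGrade:
    def test_no_sparing_is_complete_a(self):
        exam = exam_with(sensory_levels=("T4", "T4"))
        c = classify(exam)
        assert c.ais == "A" and c.complete

    def test_sensory_sparing_without_motor_function_is_b(self):
        exam = exam_with(sensory_levels=("T4", "T4"), s45=(0, 0, 1, 0))
        assert classify(exam).ais == "B"

    def test_half_rule_at_c4_with_ten_strong_muscles(self):
        # VAC present, NLI C4: all 20 key muscles lie below the NLI and
        # exactly half are antigravity -- the boundary case is grade D.
        motor = [[3, 3, 3, 3, 3, 0, 0, 0, 0, 0]] * 2
        exam = exam_with(sensory_levels=("C4", "C4"), motor=motor, vac=True)
        c = classify(exam)
        assert c.nli == "C4"
        below = [exam.motor[s, k] for s in (0, 1) for k in range(10)
                 if level_index(KEY_MUSCLES[k]) > level_index("C4")]
        assert sum(g >= 3 for g in below) * 2 == len(below)
        assert c.ais == "D"
        assert oracle_classify(exam)["ais"] == "D"

    def test_one_short_of_half_is_c(self):
        motor = [[3, 3, 3, 3, 3, 0, 0, 0, 0, 0],
                 [3, 3, 3, 3, 0, 0, 0, 0, 0, 0]]
        exam = exam_with(sensory_levels=("C4", "C4"), motor=motor, vac=True)
        assert classify(exam).ais == "C"

    def test_fully_normal_is_e(self):
        c = classify(normal_exam())
        assert (c.nli, c.ais) == ("INT", "E")

    def test_hand_constructed_c6_complete(self):
        exam = exam_with(sensory_levels=("C6", "C6"),
                         motor=[[5, 5, 0, 0, 0, 0, 0, 0, 0, 0]] * 2)
        c = classify(exam)
        oracle = oracle_classify(exam)
        assert (c.nli, c.ais) == ("C6", "A") == (oracle["nli"], oracle["ais"])


_MOTOR_VARIANTS = {
    "all5": lambda p: [5] * 10,
    "follow": lambda p: [5 if level_index(m) <= p else 0 for m in KEY_MUSCLES],
    "graded": lambda p: [5 if level_index(m) < p else (3 if level_index(m) == p else 1)
                         for m in KEY_MUSCLES],
    "mixed": lambda p: [5, 4, 3, 2, 1, 0, 5, 3, 0, 1],
}


class TestOracleEquivalence:
    @pytest.mark.parametrize("motor_variant", sorted(_MOTOR_VARIANTS))
    def test_pivot_grid_matches_brute_force(self, motor_variant):
        """Exhaustive pivot grid: scores constant rostral/caudal to a pivot,
        crossed with sacral-sparing combinations."""
        mismatches = []
        for p in range(28):
            for caudal in (0, 1):
                lt = np.full((2, 28), 2, dtype=np.int8)
                lt[:, p + 1:] = caudal
                pp = lt.copy()
                motor = np.array([_MOTOR_VARIANTS[motor_variant](p)] * 2, dtype=np.int8)
                for s45 in (0, 1):
                    for dap in (False, True):
                        for vac in (False, True):
                            lt2, pp2 = lt.copy(), pp.copy()
                            lt2[0, 27] = max(lt2[0, 27], s45)
                            exam = FullExam("grid", lt2, pp2, motor, dap, vac)
                            c = classify(exam)
                            o = oracle_classify(exam)
                            got = (c.sensory_level_r, c.motor_level_r, c.nli,
                                   c.complete, c.ais)
                            want = (o["sensory"]["R"], o["motor"]["R"], o["nli"],
                                    o["complete"], o["ais"])
                            if got != want:
                                mismatches.append((p, caudal, s45, dap, vac, got, want))
        assert not mismatches, mismatches[:5]


class TestProperties:
    def test_deterministic_and_grouping_consistent(self, small_cohort):
        for exam in small_cohort[:100]:
            c1, c2 = classify(exam), classify(exam.copy())
            assert c1 == c2
            assert ais_group(c1.ais) in ("A", "B", "CD")
            assert c1.complete == (c1.ais == "A")

    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), data=st.data())
    def test_worsening_sensation_never_moves_nli_caudally(self, seed, data):
        exam = generate_cohort(CohortConfig(n=1, seed=seed))[0]
        before = level_index(classify(exam).nli)
        positive = [(arr, s, i)
                    for arr in (exam.lt, exam.pp)
                    for s in (0, 1) for i in range(28) if arr[s, i] > 0]
        arr, s, i = data.draw(st.sampled_from(positive))
        arr[s, i] -= 1
        after = level_index(classify(exam).nli)
        assert after <= before

    def test_band_assignment(self):
        assert nli_band("C5") == "cervical"
        assert nli_band("T12") == "thoracic"
        assert nli_band("L1") == nli_band("S3") == "lumbosacral"
        assert nli_band("INT") == "intact"
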