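"""Shared fixtures and exam builders."""

from __future__ import annotations

import numpy as np
import pytest

from iira.exam_model import DERMATOMES, FullExam, KEY_MUSCLES, level_index


def normal_exam(case_id: str = "normal", dap: bool = True, vac: bool = True) -> FullExam:
    """A fully normal exam (AIS E when DAP and VAC are present)."""
    return FullExam(case_id,
                    np.full((2, 28), 2), np.full((2, 28), 2),
                    np.full((2, 10), 5), dap, vac)


def exam_with(sensory_levels: tuple[str, str] = ("INT", "INT"),
              motor: list[list[int]] | str = "follow",
              s45: tuple[int, int, int, int] | None = None,
              dap: bool = False, vac: bool = False,
              case_id: str = "fixture") -> FullExam:
    """Monotone exam builder.

    Sensation is normal through each side's target level and absent
    below.  ``s45`` = (LT-R, LT-L, PP-R, PP-L) overrides the S4-5 row;
    by default it follows the sensory levels.  ``motor`` is either an
    explicit 2x10 grade table or ``"follow"``: grade 5 at key muscles
    at/rostral to the side's sensory level, 0 below.
    """
    lt = np.zeros((2, 28), dtype=np.int8)
    pp = np.zeros((2, 28), dtype=np.int8)
    mot = np.zeros((2, 10), dtype=np.int8)
    for s in (0, 1):
        idx = level_index(sensory_levels[s])
        top = min(idx, 27)
        if top >= 0:
            lt[s, :top + 1] = 2
            pp[s, :top + 1] = 2
    if motor == "follow":
        for s in (0, 1):
            idx = level_index(sensory_levels[s])
            for k, muscle in enumerate(KEY_MUSCLES):
                if level_index(muscle) <= idx:
                    mot[s, k] = 5
    else:
        mot = np.asarray(motor, dtype=np.int8)
    if s45 is not None:
        lt[0, 27], lt[1, 27], pp[0, 27], pp[1, 27] = s45
    return FullExam(case_id, lt, pp, mot, dap, vac)


@pytest.fixture(scope="session")
def small_cohort():
    from iira.synthetic_cohort import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n=300, seed=11))
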