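"""S1-substitution shortcut for AIS grouping.

The expedited-exam proposal allows the anorectal exam and S4-5
sensation to be replaced by S1 findings when grouping the AIS into
A, B and merged C/D:

* an S1 sensory score of 1 or 2 in either modality on either side is
  taken as DAP "yes" and S4-5 sensation present; bilateral S1 LT and
  PP of 0 as DAP "no" and S4-5 sensation absent;
* an S1 motor score of 1-5 on either side is taken as VAC "yes";
  bilateral 0 as VAC "no".

The substitution never consults the true S4-5, DAP or VAC items, so a
sensory-incomplete injury whose S1 findings are absent is grouped as A
-- the shortcut's characteristic misclassification.

The proposal's "NLI T10 or rostral" applicability restriction is *not*
enforced here; stratified reporting by NLI lives in
:mod:`iira.evaluation` so the restriction itself can be evaluated.
"""

from __future__ import annotations

import dataclasses

from .classifier import (
    _motor_level_idx,
    _qualifying_motor_sparing,
    _sensory_level_idx,
)
from .exam_model import FullExam, KEY_MUSCLES, level_index

_S1_DERM = level_index("S1")
_S1_MUSCLE = KEY_MUSCLES.index("S1")


@dataclasses.dataclass(frozen=True)
class SubstitutedSacral:
    """Sacral findings implied by the S1 exam.

    ``dap_sub`` and ``s45_sensation_sub`` are always equal: both are
    driven by the same S1 sensory criterion.
    """

    dap_sub: bool
    vac_sub: bool
    s45_sensation_sub: bool


def substitute_sacral_from_s1(exam: FullExam) -> SubstitutedSacral:
    """Map S1 sensory/motor findings onto the three sacral items."""
    sensation = bool((exam.lt[:, _S1_DERM] >= 1).any() or (exam.pp[:, _S1_DERM] >= 1).any())
    vac = bool((exam.motor[:, _S1_MUSCLE] >= 1).any())
    return SubstitutedSacral(dap_sub=sensation, vac_sub=vac, s45_sensation_sub=sensation)


def ais_grouping_with_s1(exam: FullExam) -> str:
    """AIS grouping (A, B or CD) with sacral items replaced by S1 findings.

    Levels are computed from the exam as usual; only the sacral-sparing
    inputs to the grade logic are substituted.
    """
    sub = substitute_sacral_from_s1(exam)
    sens_sp = sub.s45_sensation_sub or sub.dap_sub
    if not (sens_sp or sub.vac_sub):
        return "A"
    if sub.vac_sub:
        return "CD"
    sens_idx = (_sensory_level_idx(exam.lt[0], exam.pp[0]),
                _sensory_level_idx(exam.lt[1], exam.pp[1]))
    motor_idx = (_motor_level_idx(exam.motor[0], sens_idx[0]),
                 _motor_level_idx(exam.motor[1], sens_idx[1]))
    if _qualifying_motor_sparing(exam.motor, motor_idx):
        return "CD"
    return "B"
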