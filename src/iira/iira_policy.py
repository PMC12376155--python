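"""Adaptive item-reduction policy (IIRA).

Determines NLI and AIS from a minimal, adaptively chosen subset of the
134 exam items, querying a :class:`~iira.exam_model.FullExam` as the
responder.  The testing sequence is:

1. **Full motor testing** -- all 20 key muscles.
2. **Galloping sensory search**, per side (right then left), both
   modalities together at each visited dermatome: start at C2 and jump
   caudally with stride 4 (C2, C6, T2, T6, T10, L2, S1) while every
   visited dermatome is normal; at the first abnormal finding, test
   linearly from just below the last all-normal visited dermatome
   until the first abnormal dermatome is reached.  Dermatomes skipped
   inside a span whose visited endpoints are both normal are imputed
   normal; dermatomes caudal to the bracketing abnormal finding are
   left untested.
3. **S4-5** LT and PP on both sides (4 items, always).  A side that
   was normal through S1 back-fills S2 and S3 only when S4-5 turns out
   abnormal; otherwise S2/S3 are imputed normal.
4. **Anorectal items only as needed**: DAP when all four observed S4-5
   sensory scores are 0 (or when the exam so far is entirely normal,
   where DAP distinguishes grade E); VAC unless motor-incomplete
   status is already decided by observed items (sensory sacral sparing
   plus a key muscle > 0 more than three levels below the ipsilateral
   motor level).  When in doubt the item is tested, so an omitted item
   can never change the grade.

The known failure mode is inherited from the gallop: an isolated
sensory deficit inside a skipped span is imputed normal, so the
reported NLI can be caudal to the true NLI.  The AIS is still computed
from observed sacral and motor items.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .classifier import (
    Classification,
    _motor_level_idx,
    _qualifying_motor_sparing,
    classify,
)
from .exam_model import (
    DERMATOMES,
    FullExam,
    ItemKey,
    KEY_MUSCLES,
    SIDES,
    level_name,
)

#: Gallop stops (ladder indices): C2, C6, T2, T6, T10, L2, S1.
GALLOP_STOPS: tuple[int, ...] = (0, 4, 8, 12, 16, 20, 24)

_S45 = 27


@dataclasses.dataclass
class ObservationLog:
    """Ordered record of the items actually tested, with scores."""

    items: list[tuple[ItemKey, int]] = dataclasses.field(default_factory=list)

    def record(self, item: ItemKey, score: int) -> None:
        self.items.append((item, score))

    def _count(self, kind: str) -> int:
        return sum(1 for item, _ in self.items if item.kind == kind)

    @property
    def motor_items(self) -> int:
        return self._count("motor")

    @property
    def sensory_items(self) -> int:
        return self._count("sensory")

    @property
    def anorectal_items(self) -> int:
        return self._count("anorectal")

    @property
    def total(self) -> int:
        return len(self.items)


@dataclasses.dataclass
class IIRAResult:
    """Outcome of one item-reduction run."""

    classification: Classification
    log: ObservationLog
    imputed_dermatomes: frozenset[tuple[str, str]]

    @property
    def anorectal_omitted(self) -> bool:
        return self.log.anorectal_items == 0


class SensorySearch:
    """Per-side adaptive dermatome search (gallop + linear back-fill).

    Drive it by calling :meth:`next_dermatome` and feeding the observed
    scores back through :meth:`observe` until ``next_dermatome``
    returns ``None``.  If :attr:`awaiting_sacral` is then true, the
    side is normal through S1 and needs the S4-5 observation (fed
    through :meth:`observe` with index 27) to finish.
    """

    def __init__(self) -> None:
        self.tested: dict[int, tuple[int, int]] = {}
        self.imputed: set[int] = set()
        self.level_idx: int | None = None
        self._state = "gallop"
        self._g = 0
        self._last_normal: int | None = None
        self._queue: list[int] = []
        self._first_abnormal: int | None = None

    @property
    def done(self) -> bool:
        return self._state == "done"

    @property
    def awaiting_sacral(self) -> bool:
        return self._state == "sacral_wait"

    def next_dermatome(self) -> int | None:
        if self._state == "gallop":
            return GALLOP_STOPS[self._g]
        if self._state in ("backfill", "sacral_backfill"):
            return self._queue[0]
        return None

    def observe(self, idx: int, lt: int, pp: int) -> None:
        self.tested[idx] = (lt, pp)
        normal = lt == 2 and pp == 2
        if self._state == "gallop":
            stop = GALLOP_STOPS[self._g]
            if normal:
                if self._last_normal is not None:
                    self.imputed.update(range(self._last_normal + 1, stop))
                self._last_normal = stop
                self._g += 1
                if self._g == len(GALLOP_STOPS):
                    self._state = "sacral_wait"
            else:
                start = 0 if self._last_normal is None else self._last_normal + 1
                self._queue = list(range(start, stop))
                self._first_abnormal = stop
                if self._queue:
                    self._state = "backfill"
                else:
                    self._finish(stop - 1)
        elif self._state in ("backfill", "sacral_backfill"):
            assert idx == self._queue[0]
            self._queue.pop(0)
            if not normal:
                self._finish(idx - 1)
            elif not self._queue:
                self._finish(self._first_abnormal - 1)
        elif self._state == "sacral_wait":
            assert idx == _S45
            if normal:
                self.imputed.update((25, 26))
                self._finish(28)
            else:
                self._queue = [25, 26]
                self._first_abnormal = _S45
                self._state = "sacral_backfill"
        else:  # pragma: no cover - defensive
            raise RuntimeError("observation after search finished")

    def _finish(self, level_idx: int) -> None:
        self.level_idx = level_idx
        self._state = "done"


def run_iira(responder: FullExam) -> IIRAResult:
    """Run the item-reduction policy against a full exam as responder."""
    log = ObservationLog()
    lt_obs = np.zeros((2, 28), dtype=np.int8)
    pp_obs = np.zeros((2, 28), dtype=np.int8)

    # Phase 1: full motor testing.
    for s, side in enumerate(SIDES):
        for muscle in KEY_MUSCLES:
            item = ItemKey("motor", side=side, level=muscle)
            log.record(item, responder.score(item))
    motor = responder.motor.copy()

    def observe_dermatome(s: int, idx: int) -> tuple[int, int]:
        side, derm = SIDES[s], DERMATOMES[idx]
        lt_item = ItemKey("sensory", side=side, level=derm, modality="LT")
        pp_item = ItemKey("sensory", side=side, level=derm, modality="PP")
        lt, pp = responder.score(lt_item), responder.score(pp_item)
        log.record(lt_item, lt)
        log.record(pp_item, pp)
        lt_obs[s, idx], pp_obs[s, idx] = lt, pp
        return lt, pp

    # Phase 2: galloping sensory search, right side then left.
    searches = (SensorySearch(), SensorySearch())
    for s in (0, 1):
        search = searches[s]
        while (idx := search.next_dermatome()) is not None:
            search.observe(idx, *observe_dermatome(s, idx))

    # Phase 3: S4-5 on both sides, then resolve sides normal through S1.
    for s in (0, 1):
        if _S45 not in searches[s].tested:
            lt, pp = observe_dermatome(s, _S45)
            if searches[s].awaiting_sacral:
                searches[s].observe(_S45, lt, pp)
                while (idx := searches[s].next_dermatome()) is not None:
                    searches[s].observe(idx, *observe_dermatome(s, idx))

    sens_idx = (searches[0].level_idx, searches[1].level_idx)
    motor_idx = (_motor_level_idx(motor[0], sens_idx[0]),
                 _motor_level_idx(motor[1], sens_idx[1]))

    # Phase 4: anorectal items only where they can still change the result.
    s45_all_absent = not (lt_obs[:, _S45].any() or pp_obs[:, _S45].any())
    all_normal_so_far = (sens_idx[0] == 28 and sens_idx[1] == 28
                         and bool((motor == 5).all()))
    need_dap = s45_all_absent or all_normal_so_far
    dap = False
    if need_dap:
        item = ItemKey("anorectal", anorectal_item="DAP")
        dap = bool(responder.score(item))
        log.record(item, int(dap))

    sensory_sparing_observed = (not s45_all_absent) or dap
    motor_incomplete_known = (sensory_sparing_observed
                              and _qualifying_motor_sparing(motor, motor_idx))
    vac = False
    if not motor_incomplete_known:
        item = ItemKey("anorectal", anorectal_item="VAC")
        vac = bool(responder.score(item))
        log.record(item, int(vac))

    # Classification on observed items, with gallop-span imputation; untested
    # dermatomes caudal to a bracketed level stay 0 and cannot affect it.
    lt_cls, pp_cls = lt_obs.copy(), pp_obs.copy()
    imputed: set[tuple[str, str]] = set()
    for s in (0, 1):
        for idx in searches[s].imputed:
            lt_cls[s, idx] = pp_cls[s, idx] = 2
            imputed.add((SIDES[s], DERMATOMES[idx]))
    observed_exam = FullExam(responder.case_id, lt_cls, pp_cls, motor, dap, vac)
    classification = classify(observed_exam)
    return IIRAResult(classification=classification, log=log,
                      imputed_dermatomes=frozenset(imputed))


def anorectal_requirement(*, s45_scores: tuple[int, int, int, int],
                          dap_if_tested: bool | None,
                          sensory_sparing: bool,
                          qualifying_motor_sparing: bool,
                          exam_otherwise_normal: bool = False) -> tuple[bool, bool]:
    """Which anorectal items the policy still needs, given observed state.

    ``s45_scores`` are the four observed S4-5 sensory scores;
    ``dap_if_tested`` is the DAP result when it has been tested (else
    ``None``).  Exposed for inspection and testing; :func:`run_iira`
    applies the same logic inline.
    """
    s45_absent = all(v == 0 for v in s45_scores)
    need_dap = (s45_absent and dap_if_tested is None) or exam_otherwise_normal
    sparing = sensory_sparing or bool(dap_if_tested)
    need_vac = not (sparing and qualifying_motor_sparing)
    return need_dap, need_vac
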