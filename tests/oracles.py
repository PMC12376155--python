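"""Brute-force rule oracle used to cross-check the classification engine.

Deliberately naive: rules are evaluated with explicit searches over
level names and whole-list checks, independent of the engine's single
rostral-to-caudal walk.
"""

from __future__ import annotations

LEVELS = [
    "C2", "C3", "C4", "C5", "C6", "C7", "C8",
    "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9", "T10", "T11", "T12",
    "L1", "L2", "L3", "L4", "L5",
    "S1", "S2", "S3", "S4_5",
]
MUSCLE_LEVELS = ["C5", "C6", "C7", "C8", "T1", "L2", "L3", "L4", "L5", "S1"]


def _pos(level: str) -> int:
    if level == "C1":
        return -1
    if level == "INT":
        return len(LEVELS)
    return LEVELS.index(level)


def oracle_sensory_level(exam, side: str) -> str:
    """Most caudal dermatome normal in both modalities with all rostral
    dermatomes normal, by explicit candidate search."""
    s = 0 if side == "R" else 1
    normal = [exam.lt[s, i] == 2 and exam.pp[s, i] == 2 for i in range(len(LEVELS))]
    candidates = [i for i in range(len(LEVELS)) if normal[i] and all(normal[:i])]
    if not candidates:
        return "C1"
    best = max(candidates)
    return "INT" if best == len(LEVELS) - 1 else LEVELS[best]


def oracle_motor_level(exam, side: str, sensory_level: str) -> str:
    s = 0 if side == "R" else 1
    sens = _pos(sensory_level)

    def grade(i: int) -> int | None:
        return (int(exam.motor[s, MUSCLE_LEVELS.index(LEVELS[i])])
                if LEVELS[i] in MUSCLE_LEVELS else None)

    def intact(i: int) -> bool:
        g = grade(i)
        return g == 5 if g is not None else i <= sens

    def qualifies(i: int) -> bool:
        g = grade(i)
        return g >= 3 if g is not None else i <= sens

    candidates = [i for i in range(len(LEVELS))
                  if qualifies(i) and all(intact(j) for j in range(i))]
    if all(intact(i) for i in range(len(LEVELS))):
        return "INT"
    if not candidates:
        return "C1"
    return LEVELS[max(candidates)]


def oracle_classify(exam) -> dict:
    sens = {side: oracle_sensory_level(exam, side) for side in ("R", "L")}
    motor = {side: oracle_motor_level(exam, side, sens[side]) for side in ("R", "L")}
    s45 = LEVELS.index("S4_5")
    sensory_sparing = bool(
        any(exam.lt[s, s45] > 0 or exam.pp[s, s45] > 0 for s in (0, 1)) or exam.dap)
    motor_sparing = bool(exam.vac)
    complete = not (sensory_sparing or motor_sparing)
    levels = [sens["R"], sens["L"], motor["R"], motor["L"]]
    nli = min(levels, key=_pos)

    fully_normal = (all(exam.lt[s, i] == 2 and exam.pp[s, i] == 2
                        for s in (0, 1) for i in range(len(LEVELS)))
                    and all(exam.motor[s, k] == 5 for s in (0, 1) for k in range(10))
                    and exam.dap and exam.vac)

    def sparing_below_motor_level() -> bool:
        hits = []
        for side, s in (("R", 0), ("L", 1)):
            ml = _pos(motor[side])
            for k, muscle in enumerate(MUSCLE_LEVELS):
                depth = LEVELS.index(muscle) - ml
                if exam.motor[s, k] > 0 and depth > 3:
                    hits.append((side, muscle))
        return bool(hits)

    if complete:
        ais = "A"
    elif fully_normal:
        ais = "E"
    elif not (exam.vac or (sensory_sparing and sparing_below_motor_level())):
        ais = "B"
    else:
        below = [exam.motor[s, k] for s in (0, 1)
                 for k, muscle in enumerate(MUSCLE_LEVELS)
                 if _pos(muscle) > _pos(nli)]
        if not below:
            ais = "D"
        else:
            frac = sum(1 for g in below if g >= 3) / len(below)
            ais = "D" if frac >= 0.5 else "C"

    return {"sensory": sens, "motor": motor, "nli": nli, "complete": complete,
            "sensory_sparing": sensory_sparing, "motor_sparing": motor_sparing,
            "ais": ais}
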