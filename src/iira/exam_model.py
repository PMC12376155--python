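"""Data model for the ISNCSCI neurological examination.

The International Standards for Neurological Classification of Spinal
Cord Injury (ISNCSCI) examination scores 134 items: light-touch (LT)
and pinprick (PP) sensation in 28 dermatomes on each side (each scored
0 = absent, 1 = impaired, 2 = normal), manual muscle testing of 10 key
muscles on each side (0-5), and two binary findings from the digital
anorectal exam -- deep anal pressure (DAP) and voluntary anal
contraction (VAC).

Dermatome levels are kept in strict rostral-to-caudal order.  Two
sentinel level values exist for classification *results* only: ``C1``
(deficit already present at C2, the most rostral testable dermatome)
and ``INT`` (intact through S4-5).  They are never exam rows.

"Not testable" (NT) scores are rejected at validation: the cohorts this
package emulates exclude exams with NT items, and none of the level or
grade rules implemented here define NT propagation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: The 28 dermatome levels, rostral to caudal.  S4 and S5 are examined
#: as the single row S4_5, as on the standard worksheet.
DERMATOMES: tuple[str, ...] = (
    "C2", "C3", "C4", "C5", "C6", "C7", "C8",
    "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9", "T10", "T11", "T12",
    "L1", "L2", "L3", "L4", "L5",
    "S1", "S2", "S3", "S4_5",
)

#: Sentinel for "abnormal already at C2": more rostral than every dermatome.
C1 = "C1"
#: Sentinel for "intact through S4-5": more caudal than every dermatome.
INTACT = "INT"

C1_INDEX = -1
INTACT_INDEX = 28

_DERMATOME_INDEX: dict[str, int] = {name: i for i, name in enumerate(DERMATOMES)}

#: The ten key muscle levels per side.
KEY_MUSCLES: tuple[str, ...] = ("C5", "C6", "C7", "C8", "T1", "L2", "L3", "L4", "L5", "S1")

#: Ladder index of each key muscle level on the 28-level dermatome ladder.
KEY_MUSCLE_DERMATOME_INDEX: tuple[int, ...] = tuple(_DERMATOME_INDEX[m] for m in KEY_MUSCLES)

_KEY_MUSCLE_POS: dict[str, int] = {name: k for k, name in enumerate(KEY_MUSCLES)}

SIDES: tuple[str, str] = ("R", "L")
SIDE_INDEX: dict[str, int] = {"R": 0, "L": 1}

SENSORY_MAX = 2
MOTOR_MAX = 5


def level_index(name: str) -> int:
    """Ordinal ladder index of a level name; C1 -> -1, INT -> 28."""
    if name == C1:
        return C1_INDEX
    if name == INTACT:
        return INTACT_INDEX
    try:
        return _DERMATOME_INDEX[name]
    except KeyError:
        raise ValueError(f"unknown spinal level {name!r}") from None


def level_name(index: int) -> str:
    """Inverse of :func:`level_index`."""
    if index == C1_INDEX:
        return C1
    if index == INTACT_INDEX:
        return INTACT
    if 0 <= index < len(DERMATOMES):
        return DERMATOMES[index]
    raise ValueError(f"level index out of range: {index}")


def is_rostral(a: str, b: str) -> bool:
    """True if level ``a`` is strictly rostral to level ``b``."""
    return level_index(a) < level_index(b)


@dataclasses.dataclass(frozen=True)
class ItemKey:
    """Identity of one of the 134 exam items.

    Exactly one of the three kinds is populated:

    * ``sensory``: side, dermatome level and modality (``LT`` or ``PP``)
    * ``motor``: side and key muscle level
    * ``anorectal``: ``DAP`` or ``VAC``
    """

    kind: str
    side: str | None = None
    level: str | None = None
    modality: str | None = None
    anorectal_item: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "sensory":
            ok = (self.side in SIDES and self.level in _DERMATOME_INDEX
                  and self.modality in ("LT", "PP") and self.anorectal_item is None)
        elif self.kind == "motor":
            ok = (self.side in SIDES and self.level in _KEY_MUSCLE_POS
                  and self.modality is None and self.anorectal_item is None)
        elif self.kind == "anorectal":
            ok = (self.side is None and self.level is None and self.modality is None
                  and self.anorectal_item in ("DAP", "VAC"))
        else:
            ok = False
        if not ok:
            raise ValueError(f"malformed item key: {self!r}")


def all_item_keys() -> list[ItemKey]:
    """The full item universe, in worksheet order."""
    items: list[ItemKey] = []
    for modality in ("LT", "PP"):
        for side in SIDES:
            for level in DERMATOMES:
                items.append(ItemKey("sensory", side=side, level=level, modality=modality))
    for side in SIDES:
        for level in KEY_MUSCLES:
            items.append(ItemKey("motor", side=side, level=level))
    items.append(ItemKey("anorectal", anorectal_item="DAP"))
    items.append(ItemKey("anorectal", anorectal_item="VAC"))
    return items


def total_item_count() -> int:
    """Number of distinct scored items in the full exam (134)."""
    return len(all_item_keys())


def item_counts_by_kind() -> dict[str, int]:
    counts: dict[str, int] = {"sensory": 0, "motor": 0, "anorectal": 0}
    for item in all_item_keys():
        counts[item.kind] += 1
    return counts


@dataclasses.dataclass(eq=False)
class FullExam:
    """A complete 134-item examination record.

    Arrays are indexed ``[side, position]`` with side 0 = right,
    side 1 = left; sensory positions follow :data:`DERMATOMES` and
    motor positions follow :data:`KEY_MUSCLES`.
    """

    case_id: str
    lt: np.ndarray
    pp: np.ndarray
    motor: np.ndarray
    dap: bool
    vac: bool

    def __post_init__(self) -> None:
        self.lt = np.asarray(self.lt, dtype=np.int8)
        self.pp = np.asarray(self.pp, dtype=np.int8)
        self.motor = np.asarray(self.motor, dtype=np.int8)
        self.dap = bool(self.dap)
        self.vac = bool(self.vac)
        if self.lt.shape != (2, 28) or self.pp.shape != (2, 28):
            raise ValueError("sensory arrays must have shape (2, 28)")
        if self.motor.shape != (2, 10):
            raise ValueError("motor array must have shape (2, 10)")
        for arr, hi, what in ((self.lt, 2, "LT"), (self.pp, 2, "PP"), (self.motor, 5, "motor")):
            if arr.min() < 0 or arr.max() > hi:
                raise ValueError(f"{what} scores must lie in 0..{hi}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FullExam):
            return NotImplemented
        return (self.case_id == other.case_id
                and np.array_equal(self.lt, other.lt)
                and np.array_equal(self.pp, other.pp)
                and np.array_equal(self.motor, other.motor)
                and self.dap == other.dap and self.vac == other.vac)

    def copy(self) -> "FullExam":
        return FullExam(self.case_id, self.lt.copy(), self.pp.copy(),
                        self.motor.copy(), self.dap, self.vac)

    def score(self, item: ItemKey) -> int:
        """Score of a single item -- the responder interface used by the
        item-reduction policy."""
        if item.kind == "sensory":
            arr = self.lt if item.modality == "LT" else self.pp
            return int(arr[SIDE_INDEX[item.side], _DERMATOME_INDEX[item.level]])
        if item.kind == "motor":
            return int(self.motor[SIDE_INDEX[item.side], _KEY_MUSCLE_POS[item.level]])
        return int(self.dap if item.anorectal_item == "DAP" else self.vac)

    def is_fully_normal(self) -> bool:
        return (bool((self.lt == 2).all()) and bool((self.pp == 2).all())
                and bool((self.motor == 5).all()) and self.dap and self.vac)


# ---------------------------------------------------------------------------
# Worksheet schema and validation
# ---------------------------------------------------------------------------

_LEVEL_TOKENS = tuple(d.lower() for d in DERMATOMES)
_MUSCLE_TOKENS = tuple(m.lower() for m in KEY_MUSCLES)


def worksheet_columns() -> list[str]:
    """Flat (CSV) worksheet column order."""
    cols = ["case_id"]
    for modality in ("lt", "pp"):
        for side in ("r", "l"):
            cols.extend(f"{modality}_{side}_{tok}" for tok in _LEVEL_TOKENS)
    for side in ("r", "l"):
        cols.extend(f"motor_{side}_{tok}" for tok in _MUSCLE_TOKENS)
    cols.extend(("dap", "vac"))
    return cols


_COLUMNS = worksheet_columns()
_COLUMN_SET = frozenset(_COLUMNS)


@dataclasses.dataclass(frozen=True)
class ValidationIssue:
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.message}"


@dataclasses.dataclass
class ValidationReport:
    """Collected content errors for one raw record."""

    case_id: str
    issues: list[ValidationIssue]

    @property
    def ok(self) -> bool:
        return not self.issues


class WorksheetError(Exception):
    """Raised when a worksheet file cannot be read as valid exams.

    Carries ``(row, report-or-message)`` pairs so callers can see every
    offending row; valid rows are never silently kept or dropped.
    """

    def __init__(self, message: str, failures: list[tuple[int, object]] | None = None):
        super().__init__(message)
        self.failures = failures or []


def _coerce_score(raw: object, field: str, high: int,
                  issues: list[ValidationIssue]) -> int:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        issues.append(ValidationIssue(field, "missing item"))
        return 0
    text = str(raw).strip()
    if text == "":
        issues.append(ValidationIssue(field, "missing item"))
        return 0
    if text.upper() == "NT":
        issues.append(ValidationIssue(
            field, "not testable (NT) scores are not supported; "
                   "exams containing NT items are out of scope"))
        return 0
    try:
        value = int(text)
    except ValueError:
        issues.append(ValidationIssue(field, f"non-integer score {raw!r}"))
        return 0
    if not 0 <= value <= high:
        issues.append(ValidationIssue(field, f"score {value} outside 0..{high}"))
        return 0
    return value


def validate_exam(record: Mapping[str, object]) -> FullExam | ValidationReport:
    """Validate one flat raw record against the worksheet schema.

    Returns a :class:`FullExam` when all 134 items are present and in
    range, otherwise a :class:`ValidationReport` naming each violation.
    """
    issues: list[ValidationIssue] = []
    case_id = str(record.get("case_id", "") or "")
    if not case_id:
        issues.append(ValidationIssue("case_id", "missing case identifier"))

    lt = np.zeros((2, 28), dtype=np.int8)
    pp = np.zeros((2, 28), dtype=np.int8)
    motor = np.zeros((2, 10), dtype=np.int8)
    for modality, arr in (("lt", lt), ("pp", pp)):
        for side, s in (("r", 0), ("l", 1)):
            for i, tok in enumerate(_LEVEL_TOKENS):
                field = f"{modality}_{side}_{tok}"
                arr[s, i] = _coerce_score(record.get(field), field, SENSORY_MAX, issues)
    for side, s in (("r", 0), ("l", 1)):
        for k, tok in enumerate(_MUSCLE_TOKENS):
            field = f"motor_{side}_{tok}"
            motor[s, k] = _coerce_score(record.get(field), field, MOTOR_MAX, issues)
    flags = {}
    for field in ("dap", "vac"):
        flags[field] = bool(_coerce_score(record.get(field), field, 1, issues))

    for key in record:
        if key not in _COLUMN_SET and (
                key.startswith(("lt_", "pp_", "motor_")) or key in ("s4", "s5")):
            issues.append(ValidationIssue(key, "unknown level or muscle name"))

    if issues:
        return ValidationReport(case_id=case_id, issues=issues)
    return FullExam(case_id, lt, pp, motor, flags["dap"], flags["vac"])


# ---------------------------------------------------------------------------
# Worksheet I/O
# ---------------------------------------------------------------------------


def exam_to_record(exam: FullExam) -> dict[str, object]:
    """Flatten an exam to the CSV worksheet schema."""
    rec: dict[str, object] = {"case_id": exam.case_id}
    for modality, arr in (("lt", exam.lt), ("pp", exam.pp)):
        for side, s in (("r", 0), ("l", 1)):
            for i, tok in enumerate(_LEVEL_TOKENS):
                rec[f"{modality}_{side}_{tok}"] = int(arr[s, i])
    for side, s in (("r", 0), ("l", 1)):
        for k, tok in enumerate(_MUSCLE_TOKENS):
            rec[f"motor_{side}_{tok}"] = int(exam.motor[s, k])
    rec["dap"] = int(exam.dap)
    rec["vac"] = int(exam.vac)
    return rec


def exam_to_nested(exam: FullExam) -> dict[str, object]:
    """Nested (JSON) representation of an exam."""
    def sensory(arr: np.ndarray) -> dict[str, dict[str, int]]:
        return {side: {tok: int(arr[s, i]) for i, tok in enumerate(_LEVEL_TOKENS)}
                for side, s in (("r", 0), ("l", 1))}

    return {
        "case_id": exam.case_id,
        "lt": sensory(exam.lt),
        "pp": sensory(exam.pp),
        "motor": {side: {tok: int(exam.motor[s, k]) for k, tok in enumerate(_MUSCLE_TOKENS)}
                  for side, s in (("r", 0), ("l", 1))},
        "dap": int(exam.dap),
        "vac": int(exam.vac),
    }


def _flatten_nested(obj: Mapping[str, object]) -> dict[str, object]:
    rec: dict[str, object] = {"case_id": obj.get("case_id")}
    for block in ("lt", "pp", "motor"):
        data = obj.get(block)
        if isinstance(data, Mapping):
            for side, scores in data.items():
                if isinstance(scores, Mapping):
                    for tok, value in scores.items():
                        rec[f"{block}_{str(side).lower()}_{str(tok).lower()}"] = value
    for field in ("dap", "vac"):
        if field in obj:
            rec[field] = obj[field]
    return rec


def _check_records(records: Iterable[Mapping[str, object]]) -> list[FullExam]:
    exams: list[FullExam] = []
    failures: list[tuple[int, object]] = []
    seen: dict[str, int] = {}
    for row, record in enumerate(records, start=1):
        result = validate_exam(record)
        if isinstance(result, ValidationReport):
            failures.append((row, result))
            continue
        if result.case_id in seen:
            failures.append((row, f"duplicate case_id {result.case_id!r} "
                                  f"(first seen at row {seen[result.case_id]})"))
            continue
        seen[result.case_id] = row
        exams.append(result)
    if failures:
        rows = ", ".join(str(r) for r, _ in failures)
        raise WorksheetError(f"invalid worksheet rows: {rows}", failures)
    return exams


def read_exams(path: str | Path, format: str = "csv") -> list[FullExam]:
    """Read a worksheet file into validated exams.

    Raises :class:`WorksheetError` (citing row numbers) if any row is
    invalid; a header-only file yields an empty list.
    """
    path = Path(path)
    if format == "csv":
        try:
            frame = pd.read_csv(path, dtype=str)
        except pd.errors.EmptyDataError:
            raise WorksheetError(f"{path}: empty file (no header)") from None
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise WorksheetError(f"{path}: missing columns {missing[:5]}"
                                 + ("..." if len(missing) > 5 else ""))
        return _check_records(dict(row) for _, row in frame.iterrows())
    if format == "json":
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise WorksheetError(f"{path}: JSON worksheet must be an array of objects")
        return _check_records(_flatten_nested(obj) for obj in data)
    raise ValueError(f"unknown worksheet format {format!r}")


def write_exams(exams: Iterable[FullExam], path: str | Path, format: str = "csv") -> None:
    """Write exams to a worksheet file (inverse of :func:`read_exams`)."""
    path = Path(path)
    exams = list(exams)
    if format == "csv":
        frame = pd.DataFrame([exam_to_record(e) for e in exams], columns=_COLUMNS)
        frame.to_csv(path, index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump([exam_to_nested(e) for e in exams], fh, indent=1)
    else:
        raise ValueError(f"unknown worksheet format {format!r}")
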