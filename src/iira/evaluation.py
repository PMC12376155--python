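"""Accuracy analyses: confusion tables, completeness-error curves,
upper-extremity weakness frequencies, and item-count statistics.

Percentages are reported to one decimal, rounding half away from zero,
matching the convention of the printed tables these analyses mirror.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classifier import Classification, ais_group, classify, nli_band
from .exam_model import DERMATOMES, FullExam, level_index, level_name
from .iira_policy import IIRAResult, run_iira
from .s1_substitution import ais_grouping_with_s1

_GROUPS = ("A", "B", "CD")
_GROUP_INDEX = {g: i for i, g in enumerate(_GROUPS)}

METHODS = ("full", "s1sub", "iira")


def round1(x: float) -> float:
    """Round to one decimal, half away from zero."""
    return math.copysign(math.floor(abs(x) * 10 + 0.5) / 10, x)


@dataclasses.dataclass
class ConfusionTable3:
    """3x3 counts of true vs determined AIS grouping (A, B, C/D)."""

    counts: np.ndarray

    LABELS = _GROUPS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise ValueError("counts must be a 3x3 array of non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionTable3") -> "ConfusionTable3":
        return ConfusionTable3(self.counts + other.counts)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ConfusionTable3":
        counts = np.zeros((3, 3), dtype=np.int64)
        for true, determined in pairs:
            counts[_GROUP_INDEX[true], _GROUP_INDEX[determined]] += 1
        return cls(counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=[f"true_{g}" for g in _GROUPS],
                            columns=[f"determined_{g}" for g in _GROUPS])


@dataclasses.dataclass
class SummaryStats:
    """Percent summaries of a 3x3 grouping table.

    Undefined ratios (empty row or column) are ``None``, never 0.
    """

    overall_accuracy: float
    recall: dict[str, float | None]
    precision: dict[str, float | None]
    cell_fraction: dict[str, dict[str, float]]


def _determined_grouping(exam: FullExam, method: str, truth: Classification) -> str:
    if method == "full":
        return ais_group(truth.ais)
    if method == "s1sub":
        return ais_grouping_with_s1(exam)
    if method == "iira":
        return ais_group(run_iira(exam).classification.ais)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def confusion_grouping(cohort: Sequence[FullExam], method: str) -> ConfusionTable3:
    """True vs method-determined AIS grouping over a cohort."""
    counts = np.zeros((3, 3), dtype=np.int64)
    for exam in cohort:
        truth = classify(exam)
        i = _GROUP_INDEX[ais_group(truth.ais)]
        j = _GROUP_INDEX[_determined_grouping(exam, method, truth)]
        counts[i, j] += 1
    return ConfusionTable3(counts)


def table_summaries(table: ConfusionTable3) -> SummaryStats:
    """Overall accuracy, per-group recall/precision and cell fractions (%)."""
    counts = table.counts
    total = table.total
    if total == 0:
        raise ValueError("cannot summarise an empty table")
    diag = np.diag(counts)
    overall = round1(100.0 * diag.sum() / total)
    recall: dict[str, float | None] = {}
    precision: dict[str, float | None] = {}
    for i, g in enumerate(_GROUPS):
        row = counts[i].sum()
        col = counts[:, i].sum()
        recall[g] = round1(100.0 * diag[i] / row) if row else None
        precision[g] = round1(100.0 * diag[i] / col) if col else None
    cell = {gt: {gd: round1(100.0 * counts[i, j] / total)
                 for j, gd in enumerate(_GROUPS)}
            for i, gt in enumerate(_GROUPS)}
    return SummaryStats(overall_accuracy=overall, recall=recall,
                        precision=precision, cell_fraction=cell)


def completeness_error_by_nli(cohort: Sequence[FullExam], method: str) -> pd.DataFrame:
    """Per-NLI rate of incorrect completeness (A vs not-A) classification.

    Returns a tidy frame (``level``, ``n``, ``n_error``, ``error_pct``,
    ``nli_t10_or_rostral``); levels with no cases are absent, not 0 %.
    The last column flags the stratum where the expedited-exam proposal
    recommended the S1 shortcut (NLI of T10 or rostral).
    """
    per_level: dict[str, list[int]] = {}
    for exam in cohort:
        truth = classify(exam)
        determined = _determined_grouping(exam, method, truth)
        error = int((truth.ais == "A") != (determined == "A"))
        bucket = per_level.setdefault(truth.nli, [0, 0])
        bucket[0] += 1
        bucket[1] += error
    t10 = level_index("T10")
    rows = [{"level": lvl, "n": n, "n_error": e,
             "error_pct": round1(100.0 * e / n),
             "nli_t10_or_rostral": level_index(lvl) <= t10}
            for lvl, (n, e) in per_level.items()]
    rows.sort(key=lambda r: level_index(r["level"]))
    return pd.DataFrame(rows, columns=["level", "n", "n_error", "error_pct",
                                       "nli_t10_or_rostral"])


def ue_weakness_by_sensory_level(cohort: Sequence[FullExam]) -> pd.DataFrame:
    """Frequency of any C5-T1 key muscle deficit, by most rostral sensory
    level, for cases with sensory level T2 or caudal.

    Quantifies the risk of omitting upper-extremity motor testing: any
    such case would receive an incorrect NLI if arm muscles were skipped.
    """
    t2 = level_index("T2")
    per_level: dict[str, list[int]] = {}
    for exam in cohort:
        truth = classify(exam)
        most_rostral = min(level_index(truth.sensory_level_r),
                           level_index(truth.sensory_level_l))
        if not t2 <= most_rostral < len(DERMATOMES):
            continue
        weak = int(bool((exam.motor[:, :5] < 5).any()))
        bucket = per_level.setdefault(level_name(most_rostral), [0, 0])
        bucket[0] += 1
        bucket[1] += weak
    rows = [{"level": lvl, "n": n, "n_weak": w, "weakness_pct": round1(100.0 * w / n)}
            for lvl, (n, w) in per_level.items()]
    rows.sort(key=lambda r: level_index(r["level"]))
    return pd.DataFrame(rows, columns=["level", "n", "n_weak", "weakness_pct"])


@dataclasses.dataclass
class ItemStats:
    """Descriptive statistics over observation-log item totals."""

    n: int
    mean_items: float
    sd_items: float | None
    mean_fraction_of_full: float
    anorectal_omitted_pct: float
    by_band: dict[str, dict[str, float]]
    by_ais: dict[str, dict[str, float]]


def item_count_summary(results: Sequence[IIRAResult]) -> ItemStats:
    """Item-count statistics for a batch of item-reduction runs.

    SD is the sample standard deviation (n - 1), ``None`` for a single
    run.  Stratification uses each run's own classification.
    """
    if not results:
        raise ValueError("item_count_summary requires at least one result")
    totals = np.array([r.log.total for r in results], dtype=float)
    n = len(totals)
    mean = float(totals.mean())
    sd = float(totals.std(ddof=1)) if n > 1 else None
    omitted = 100.0 * sum(r.anorectal_omitted for r in results) / n

    def strata(keys: list[str]) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for key, total in zip(keys, totals):
            bucket = out.setdefault(key, {"n": 0, "mean": 0.0})
            bucket["n"] += 1
            bucket["mean"] += total
        for bucket in out.values():
            bucket["mean"] = bucket["mean"] / bucket["n"]
        return out

    return ItemStats(
        n=n,
        mean_items=mean,
        sd_items=sd,
        mean_fraction_of_full=mean / 134.0,
        anorectal_omitted_pct=omitted,
        by_band=strata([nli_band(r.classification.nli) for r in results]),
        by_ais=strata([r.classification.ais for r in results]),
    )
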