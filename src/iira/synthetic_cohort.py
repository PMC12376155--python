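"""Synthetic examination cohorts with controlled NLI/AIS targets.

Registry data cannot be redistributed, so every other module is
exercised against generated exams.  The generator constructs lesion
morphologies directly -- normal above the target level, a short
partially-impaired transition band (the sensory zone of partial
preservation), absent below, with sacral and key-muscle findings tuned
to the requested AIS grade -- and then *verifies* each exam against
the full classification engine, resampling on the rare mismatch.

Default mixtures reproduce the registry composition the accuracy
analyses assume: NLI cervical/thoracic/lumbosacral = 60.9/27.4/11.7 %
and AIS A/B/C/D = 33.5/11.5/15.9/39.2 %.  Within a band the level is
uniform, a declared modeling choice.

Morphology dials:

* ``asymmetry_prob`` -- chance the two sides' sensory levels differ
  (one side shifted caudally by up to ``asymmetry_max_offset``).
* ``isolated_deficit_prob`` -- chance of the rare morphology where a
  single abnormal dermatome just below the NLI is followed by several
  normal dermatomes before the true transition; this is the pattern
  that defeats a galloping sensory search.  Injection is restricted to
  placements that cannot change the AIS grade (see docs/methods.md),
  and for C/D cases VAC is forced present.
* ``zpp_span`` -- (lo, hi) bounds of the transition-band length.

With ``asymmetry_prob = 0`` and ``isolated_deficit_prob = 0`` every
generated exam is side-symmetric and monotone rostral-to-caudal.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterator

import numpy as np
import pandas as pd

from .classifier import classify
from .exam_model import (
    DERMATOMES,
    FullExam,
    KEY_MUSCLE_DERMATOME_INDEX,
    level_index,
    level_name,
)

#: Ladder index ranges (inclusive) of the three NLI reporting bands.
BANDS: dict[str, tuple[int, int]] = {
    "cervical": (0, 6),       # C2-C8
    "thoracic": (7, 18),      # T1-T12
    "lumbosacral": (19, 26),  # L1-S3
}
_BAND_NAMES = tuple(BANDS)

_S45 = 27
_KEY_IDX = KEY_MUSCLE_DERMATOME_INDEX
_KEY_AT_LADDER = {ladder: k for k, ladder in enumerate(_KEY_IDX)}


class GenerationError(Exception):
    """A requested (NLI, AIS) target could not be constructed."""


@dataclasses.dataclass
class CohortConfig:
    """Generator parameters.

    Mixtures must sum to one (tolerance 1e-9).  A single seeded
    generator is threaded through all sampling; no global RNG state.
    """

    n: int = 100
    seed: int = 0
    nli_mixture: tuple[float, float, float] = (0.609, 0.274, 0.117)
    ais_mixture: tuple[float, float, float, float] = (0.335, 0.115, 0.159, 0.392)
    asymmetry_prob: float = 0.2
    asymmetry_max_offset: int = 2
    isolated_deficit_prob: float = 0.02
    zpp_span: tuple[int, int] = (0, 3)
    max_attempts: int = 64

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        # The default grade mixture comes from printed one-decimal
        # percentages that sum to 100.1 %; accept rounding slack and
        # renormalize exactly at sampling time.
        for name, mix, k in (("nli_mixture", self.nli_mixture, 3),
                             ("ais_mixture", self.ais_mixture, 4)):
            if len(mix) != k or any(p < 0 for p in mix):
                raise ValueError(f"{name} must be {k} non-negative probabilities")
            if not math.isclose(sum(mix), 1.0, abs_tol=2e-3):
                raise ValueError(f"{name} must sum to 1 (within rounding slack)")
        for name, p in (("asymmetry_prob", self.asymmetry_prob),
                        ("isolated_deficit_prob", self.isolated_deficit_prob)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0 <= self.zpp_span[0] <= self.zpp_span[1]):
            raise ValueError("zpp_span must be ordered non-negative bounds")


def _keys_below(nli_idx: int) -> list[tuple[int, int]]:
    return [(s, k) for s in (0, 1)
            for k, ladder in enumerate(_KEY_IDX) if ladder > nli_idx]


def _iso_feasible(t: int, grade: str) -> bool:
    # A/B grades are level-invariant; C/D need the thoracic corridor so a
    # caudal NLI shift crosses no key muscle level (see docs/methods.md).
    if grade in ("C", "D"):
        return 7 <= t <= 15  # T1-T9, span capped at L1 below
    return t <= 20


def _attempt(case_id: str, t: int, grade: str, cfg: CohortConfig,
             rng: np.random.Generator) -> tuple[FullExam | None, dict]:
    lt = np.zeros((2, 28), dtype=np.int8)
    pp = np.zeros((2, 28), dtype=np.int8)
    motor = np.zeros((2, 10), dtype=np.int8)

    iso = bool(rng.random() < cfg.isolated_deficit_prob) and _iso_feasible(t, grade)
    asym = bool(rng.random() < cfg.asymmetry_prob) and t < 26

    if iso:
        cap = (19 - t) if grade in ("C", "D") else (25 - t)
        span = int(rng.integers(4, min(6, cap) + 1)) if cap >= 4 else 3
        side_levels = [t + span, t + span]
        deficit_side = int(rng.integers(0, 2))
    else:
        side_levels = [t, t]
        if asym:
            offset = int(rng.integers(1, cfg.asymmetry_max_offset + 1))
            side_levels[int(rng.integers(0, 2))] = min(t + offset, 26)
        deficit_side = -1

    # Sensory: normal through the side level, a partially-impaired
    # transition band (non-increasing within each modality), absent
    # below; S4-5 filled in per grade.  Without asymmetry or an
    # isolated deficit the two sides are identical.
    mirrored = not (iso or asym)
    for s in (0, 1):
        if mirrored and s == 1:
            lt[1] = lt[0]
            pp[1] = pp[0]
            break
        sl = side_levels[s]
        lt[s, :sl + 1] = 2
        pp[s, :sl + 1] = 2
        z = int(rng.integers(cfg.zpp_span[0], cfg.zpp_span[1] + 1))
        band = range(sl + 1, min(sl + z, 26) + 1)
        for arr in (lt, pp):
            values = sorted((int(rng.integers(0, 2)) for _ in band), reverse=True)
            for j, v in zip(band, values):
                arr[s, j] = v
    if iso:
        # Single abnormal dermatome just below the target NLI; the side is
        # otherwise normal down to t + span.
        if rng.random() < 0.5:
            lt[deficit_side, t + 1] = 1
        else:
            pp[deficit_side, t + 1] = 1

    # Motor: intact rostral to the NLI; the key muscle at the NLI (if any)
    # gets a partial antigravity grade so it pins the motor level.
    for s in (0, 1):
        for k, ladder in enumerate(_KEY_IDX):
            if ladder < t:
                motor[s, k] = 5
    if t in _KEY_AT_LADDER:
        motor[:, _KEY_AT_LADDER[t]] = rng.integers(3, 5, size=2)

    dap = False
    vac = False
    below = _keys_below(t)
    def draw_s45(require_some: bool) -> None:
        # Spared sacral sensation is modeled as impaired (0/1): fully
        # normal S4-5 caudal to an abnormal dermatome would be a
        # non-monotone recovery pattern, outside the generator's scope.
        while True:
            vals = rng.integers(0, 2, size=4)
            if mirrored:
                vals[1], vals[3] = vals[0], vals[2]
            if vals.any() or not require_some:
                break
        lt[0, _S45], lt[1, _S45], pp[0, _S45], pp[1, _S45] = (int(v) for v in vals)

    if grade == "B":
        if rng.random() < 0.85:
            draw_s45(require_some=True)
            dap = bool(rng.random() < 0.5)
        else:
            dap = True
    elif grade in ("C", "D"):
        m = len(below)
        need = (m + 1) // 2
        if grade == "C":
            if m == 0:
                raise GenerationError(
                    f"AIS C is infeasible at NLI {level_name(t)}: no key muscles "
                    "caudal to the NLI (vacuous half-rule yields grade D)")
            k_strong = int(rng.integers(0, need))
        else:
            k_strong = int(rng.integers(need, m + 1))
        strong_positions = set(rng.choice(m, size=k_strong, replace=False).tolist())
        for pos, (s, k) in enumerate(below):
            if pos in strong_positions:
                motor[s, k] = int(rng.integers(3, 6))
            else:
                motor[s, k] = int(rng.integers(0, 3))
        draw_s45(require_some=False)
        dap = bool(rng.random() < 0.5)
        vac = bool(iso or rng.random() < 0.6)
        if not vac:
            if not (lt[:, _S45].any() or pp[:, _S45].any() or dap):
                dap = True
            far = [(s, k) for s, k in below if _KEY_IDX[k] - t > 3]
            if not any(motor[s, k] > 0 for s, k in far):
                weak_far = [(s, k) for s, k in far if motor[s, k] == 0]
                if weak_far:
                    s, k = weak_far[int(rng.integers(0, len(weak_far)))]
                    motor[s, k] = 1
                else:
                    vac = True

    exam = FullExam(case_id, lt, pp, motor, dap, vac)
    result = classify(exam)
    info = {"isolated_deficit": iso, "asymmetric": asym and not iso}
    if result.nli == level_name(t) and result.ais == grade:
        return exam, info
    return None, info


def generate_exam(target_nli: str, target_ais: str,
                  config: CohortConfig | None = None,
                  rng: np.random.Generator | None = None,
                  case_id: str = "case") -> FullExam:
    """Construct one exam whose full classification is the requested pair.

    Raises :class:`GenerationError` for infeasible targets (AIS C with
    no key muscles below the NLI) or after ``max_attempts`` failures.
    """
    cfg = config if config is not None else CohortConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t = level_index(target_nli)
    if not 0 <= t <= 26:
        raise GenerationError(f"NLI target {target_nli!r} outside C2..S3")
    if target_ais not in ("A", "B", "C", "D"):
        raise GenerationError(f"AIS target must be A-D, got {target_ais!r}")
    for _ in range(cfg.max_attempts):
        exam, _info = _attempt(case_id, t, target_ais, cfg, rng)
        if exam is not None:
            return exam
    raise GenerationError(
        f"could not construct exam for NLI {target_nli}, AIS {target_ais} "
        f"after {cfg.max_attempts} attempts")


def _sample_targets(cfg: CohortConfig, rng: np.random.Generator) -> Iterator[tuple[int, str]]:
    p_band = np.asarray(cfg.nli_mixture, dtype=float)
    p_grade = np.asarray(cfg.ais_mixture, dtype=float)
    bands = rng.choice(3, size=cfg.n, p=p_band / p_band.sum())
    grades = rng.choice(4, size=cfg.n, p=p_grade / p_grade.sum())
    for b, g in zip(bands, grades):
        band = _BAND_NAMES[int(b)]
        grade = "ABCD"[int(g)]
        lo, hi = BANDS[band]
        if grade == "C":
            # AIS C needs a key muscle below the NLI; resample within the
            # band excluding S1-S3.
            hi = min(hi, 23)
        yield int(rng.integers(lo, hi + 1)), grade


def generate_cohort(config: CohortConfig,
                    return_manifest: bool = False) -> list[FullExam] | tuple[list[FullExam], pd.DataFrame]:
    """Generate ``config.n`` exams; identical output for identical seeds.

    With ``return_manifest=True`` also returns a DataFrame recording
    each case's target pair, band, and whether asymmetry or an isolated
    deficit was injected.
    """
    rng = np.random.default_rng(config.seed)
    exams: list[FullExam] = []
    rows: list[dict[str, object]] = []
    for i, (t, grade) in enumerate(_sample_targets(config, rng)):
        case_id = f"case{i:06d}"
        exam = None
        info: dict = {}
        for _ in range(config.max_attempts):
            exam, info = _attempt(case_id, t, grade, config, rng)
            if exam is not None:
                break
        if exam is None:
            raise GenerationError(
                f"could not construct exam for NLI {level_name(t)}, AIS {grade}")
        exams.append(exam)
        if return_manifest:
            rows.append({"case_id": case_id, "target_nli": level_name(t),
                         "target_ais": grade,
                         "band": next(b for b, (lo, hi) in BANDS.items() if lo <= t <= hi),
                         **info})
    if return_manifest:
        return exams, pd.DataFrame(rows)
    return exams
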