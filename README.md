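# iira — ISNCSCI classification with adaptive item reduction

The International Standards for Neurological Classification of Spinal
Cord Injury (ISNCSCI) characterize a spinal cord injury by its
**neurological level of injury (NLI)** and **ASIA Impairment Scale
(AIS)** grade. The full exam scores 134 items: light-touch (LT) and
pinprick (PP) sensation in 28 dermatomes per side (0–2), ten key
muscles per side (0–5), and two anorectal findings — deep anal
pressure (DAP) and voluntary anal contraction (VAC). The exam burden
is high, and the anorectal exam is the most commonly skipped part.

This package is for clinicians and researchers studying *expedited*
classification. It provides:

* **`iira.classifier`** — a deterministic engine for the full rules:
  per-side sensory level (most caudal dermatome with LT = PP = 2 and
  all rostral dermatomes normal), motor level (most caudal key muscle
  ≥ 3 with all rostral muscles graded 5; "motor follows sensory" in
  segments without key muscles), NLI = the most rostral of the four
  levels, sacral sparing, completeness, and AIS A–E. Grades C and D
  are split by the half rule: D iff at least half the key muscle
  functions below the single NLI are graded ≥ 3.
* **`iira.s1_substitution`** — the shortcut that replaces the sacral
  items with S1 findings (S1 sensation ≥ 1 anywhere → DAP/S4-5
  present; S1 motor ≥ 1 either side → VAC present) when grouping the
  AIS into {A, B, C/D}.
* **`iira.iira_policy`** — the ISNCSCI Item Reduction Algorithm: full
  motor testing, then a galloping per-side sensory search (stride 4
  from C2 with linear back-fill at the first abnormal finding), S4-5
  always, and anorectal items only when they can still change the
  grade.
* **`iira.synthetic_cohort`** — seeded generation of exam cohorts with
  controlled NLI/AIS mixtures and lesion morphology, since registry
  data cannot be redistributed.
* **`iira.evaluation`** — confusion tables, recall/precision
  summaries, completeness-error-by-NLI curves, upper-extremity
  weakness frequencies, and item-count statistics.

## Worked example

```python
>>> import numpy as np
>>> from iira import generate_exam, classify, run_iira, ais_grouping_with_s1
>>> exam = generate_exam("T4", "B", rng=np.random.default_rng(7))
>>> c = classify(exam)
>>> c.nli, c.ais, c.complete
('T4', 'B', False)
```

A sensory-incomplete (AIS B) T4 injury: sacral sensation is spared, so
the injury is incomplete, but there is no voluntary anal contraction
and no motor function more than three levels below the motor level.

```python
>>> res = run_iira(exam)
>>> res.classification.nli, res.classification.ais, res.log.total
('T4', 'B', 54)
```

The item-reduction run reaches the same classification from 54 of the
134 items (20 motor, 32 sensory, 2 anorectal): the gallop descends
C2 → C6 → T2 → T6, brackets the level by back-filling T3–T5, and stops.

```python
>>> ais_grouping_with_s1(exam)
'A'
```

This case's S1 row is completely absent (sensation 0/0, motor 0), so
the S1-substitution shortcut wrongly calls it *complete* — the
characteristic failure that makes the shortcut unreliable for true
AIS B injuries.

The same analyses are scriptable from the shell:

```sh
iira simulate --n 1000 --seed 42 --output cohort.csv
iira classify --input cohort.csv --output classifications.csv
iira reduce   --input cohort.csv --output iira_results.csv
iira evaluate --cohort cohort.csv --methods s1sub,iira --output-dir results/
```

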