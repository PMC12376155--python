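# Methods

## Classification rules

The engine evaluates each side on the 28-level dermatome ladder
C2 … S4-5 (S4 and S5 share one row, as on the standard worksheet),
with two sentinel results: `C1` (deficit already at C2) and `INT`
(intact through S4-5).

**Sensory level.** Most caudal dermatome with LT = PP = 2 whose
rostral dermatomes are all normal on that side; equivalently, the end
of the normal prefix.

**Motor level.** A single rostral-to-caudal walk. At key-muscle
levels (C5–T1, L2–S1) a level is *intact* with grade 5 and *qualifies*
as the motor level with grade ≥ 3. Levels without key muscles are
presumed intact exactly when they are at or rostral to the side's
sensory level ("motor follows sensory"). The motor level is the most
caudal qualifying level reached before the first non-intact level.
The written standard admits two readings when the sensory level lies
in a non-myotome region but key muscles below it are normal (for
example a C4 sensory level with intact arms): the presumption could
pin the motor level at the sensory level, or the muscle rule could
carry it caudally. This package adopts the unified walk (the second
reading): presumed segments are intact only up to the sensory level,
so the walk proceeds through normal key muscles and stops at the first
segment that can no longer be verified. This reading is normative for
this package; it coincides with the common cases (all-normal exams are
`INT`, a thoracic sensory level with intact arms and absent legs gives
motor level = sensory level).

**Sacral sparing and completeness.** Sensory sparing = any S4-5
sensation (either modality, either side) or DAP; motor sparing = VAC.
Complete (AIS A) iff neither is present.

**AIS.** Motor incomplete = VAC, or sensory sparing plus a key muscle
grade > 0 more than three *ladder* levels below the ipsilateral motor
level (key muscles only; non-key muscles are out of scope). B =
sensory sparing without motor-incomplete status. Among motor
incomplete, D iff at least half of the key muscle functions below the
single NLI (both sides pooled) are ≥ 3, else C; with no key muscles
below the NLI the condition is vacuously satisfied (D). E requires
every item normal/maximal. "Not testable" scores are rejected at
validation; NT propagation is not modeled.

## S1 substitution

`substitute_sacral_from_s1` maps S1 sensation ≥ 1 (any modality/side)
to "DAP yes + S4-5 sensation present" and S1 motor ≥ 1 (either side)
to "VAC yes"; bilateral zeros map to absent. `ais_grouping_with_s1`
re-runs the grade logic with only these three inputs replaced; levels
still come from the actual dermatome and muscle scores. The
"NLI T10 or rostral" applicability recommendation is deliberately not
enforced inside the operation — the evaluation module flags the
stratum instead, so the recommendation itself can be examined.

## Item-reduction policy

Order of testing: (1) all 20 key muscles; (2) per-side galloping
sensory search — stride 4 from C2 (C2, C6, T2, T6, T10, L2, S1), both
modalities together at each visited dermatome; on the first abnormal
visit, linear back-fill from just below the last all-normal visited
dermatome to the first abnormal dermatome; (3) S4-5 bilaterally
(4 items, always); a side that was normal through S1 tests S2/S3 only
if S4-5 is abnormal, otherwise S2/S3 are imputed normal; (4) DAP only
if all four observed S4-5 scores are 0 *or* everything observed so far
is normal (DAP then separates grade E from D); VAC unless
motor-incomplete status is already decided by observed items. The
omission logic is conservative: an item is only skipped when no value
of it could change the grade, which is why the reduced run's AIS
always equals the full-exam AIS. Skipped dermatomes inside a
confirmed-normal span are imputed LT = PP = 2; dermatomes caudal to a
bracketed level stay untested and cannot affect the level.

The documented failure mode is the NLI: an isolated deficit inside a
skipped span (with the contralateral side also caudal) is imputed
normal and the reported NLI falls caudal to the truth. The stride of
4 was chosen as the coarsest stride whose back-fill still yields
roughly 20 sensory items for a typical case while keeping at most
three imputed dermatomes per jump.

## Synthetic cohorts

`CohortConfig` defaults are the study conditions of the accuracy
analyses: NLI band mixture cervical/thoracic/lumbosacral =
0.609/0.274/0.117 and AIS mixture A/B/C/D = 0.335/0.115/0.159/0.392
(printed one-decimal percentages; they sum to 100.1 % and are
renormalized at sampling). Within a band the level is sampled
uniformly — no within-band distribution is published, so this is a
declared modeling choice. Grade E is not generated (new-injury
cohorts contain A–D only).

Each case is built constructively — normal above the target level, a
0–3-level partially-impaired transition band (non-increasing within
each modality), absent below, sacral and key-muscle findings set for
the target grade — then *verified* against the full engine and
resampled on mismatch, so label fidelity is exact by construction.
Key muscles rostral to the NLI are 5; a key muscle at the NLI gets
grade 3–4 (pinning the motor level; grades 1–2 there would move the
level rostral); below-NLI muscles are assigned to satisfy the C/D
half rule, with a far-caudal muscle forced > 0 (or VAC forced) when a
motor-incomplete case would otherwise lack qualifying sparing.

Morphology dials, all off by default except where noted:

* `asymmetry_prob` (default 0.2, offset ≤ 2): one side's sensory
  level shifts caudally. Asymmetry alone never defeats the per-side
  search.
* `isolated_deficit_prob` (default 0.02, matching the rarity of this
  morphology in validation-scale samples): one side carries a single
  abnormal dermatome just below the NLI followed by a normal span
  before the true transition, and the other side's level moves caudal
  with it — the pattern that produces caudal NLI errors in a galloping
  search. Injection is restricted to placements that cannot alter the
  AIS: any level for grades A and B (whose grades are
  level-invariant: A has no sparing, B has no key-muscle activity
  below the motor level), and for C/D only thoracic NLIs T1–T9 with
  the span capped at L1 and VAC forced present, so a caudally-shifted
  NLI crosses no key-muscle level and the half rule counts the same
  pooled muscle set.
* Spared sacral sensation is drawn as impaired (0/1), never 2/2: a
  fully normal S4-5 caudal to an abnormal dermatome would be a
  non-monotone recovery pattern outside the generator's scope (and
  would defeat the S1 → S4-5 imputation span by design rather than by
  the documented mechanism).

With both injection probabilities at 0, cohorts are side-symmetric
and monotone through S3 (sacral sparing is inherently a spared island
and is always tested by the policy), which is what makes the
reduced-exam NLI provably exact on such cohorts.

AIS C is structurally infeasible at NLI S1–S3 (no key muscles below
the NLI; the vacuous half rule makes motor-incomplete cases D):
`generate_exam` raises `GenerationError`, and cohort sampling draws
grade-C levels from L1–L5 within the lumbosacral band.

### What the generator does not emulate

* Correlation between S1 findings and sacral sparing. In real
  registries the substitution's premise is that S1 and sacral findings
  usually agree; here S1 scores follow only the lesion level and
  transition band, so S1-substitution error rates measured on
  synthetic cohorts are substantially worse than published registry
  rates (true-B recall in particular). The published confusion-table
  percentages are therefore reproduced from the printed counts, not
  from synthetic cohorts.
* Examiner noise, NT items, non-SCI conditions, longitudinal change,
  motor zones of partial preservation in complete injuries.
* Exact published item-count statistics (mean 41.9, SD 9.2, 44 %
  anorectal omission) depend on the unpublished original testing
  sequence and sample; this package asserts only the directional
  properties (mean ≪ 134, cervical < thoracolumbar, a nonzero
  omission fraction).

## Numerical and reporting conventions

Percentages are reported to one decimal, rounding half away from
zero. Undefined ratios (empty confusion-table row/column) are
reported as undefined (`None`), never 0. Sample SD uses n − 1 and is
undefined for a single observation. Ties for the NLI resolve to the
shared level. All randomness flows through a single seeded
`numpy.random.Generator`; identical seeds give identical cohorts.

## Problem sizes

The test suite exercises the reduction policy on 5 000 default-
condition cases and calibrates cohort mixtures on 100 000 cases (the
acceptance script uses the same size), with 3 binomial standard
errors as the acceptance band for mixture fractions — sizes chosen so
the binomial bands are narrow relative to the mixture differences
while the whole suite runs in well under a minute of generator time.
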