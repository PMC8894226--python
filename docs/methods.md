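# Methods

## Model and procedure

The pipeline operates entirely on categorical data. The observation unit is
one task session: a block-design fMRI run of one of four language tasks
(VIT, WCT, BST, SYT), visually rated per session into `left` / `right` /
`bilateral` / `none` for each of ten homotopic ROIs (MFG, IFG, FOP, S1M1,
A1, TLA, IPS, ANG, CBM, SMA). A session with no activated ROI is
*unsuccessful*. The 4 × 10 task-specific cells form the grid over which
everything else is defined.

**Cohort curation.** When a patient has several exams, only the last one is
analyzed; exams are ordered lexicographically by exam id because the session
schema carries no date column (an explicit date ordering can be imposed
upstream). Patients whose every session is unsuccessful are removed; the
curation report lists every drop with its reason. Missing ratings are hard
errors rather than implicit `none`: a silently defaulted rating would both
deflate activation counts and corrupt the concordance denominators.

**Counting and the simplified LI.** Given a set of validly lateralizing
cells (VLR), activations of member cells are counted per hemisphere across
all sessions and tasks of the exam. Bilateral activation contributes one
count to each hemisphere. The cerebellum is crossed: left and right
contributions are swapped (bilateral is a fixed point of the swap). The
laterality index LI = (L − R)/(L + R) is computed as an exact
`fractions.Fraction`, so comparisons at the band boundaries ±0.5 and ±1 are
decided exactly, never by floating-point tolerance. LI is undefined (not 0)
when no activation was counted.

**Classification bands.** A patient is not classifiable (NC) below 3 VLR
activations (bilateral counting as two). Otherwise: L iff LI = +1, R iff
LI = −1, bilateral-left for 0.5 ≤ LI < 1, bilateral for −0.5 < LI < 0.5,
bilateral-right for −1 < LI ≤ −0.5. The boundary values ±0.5 belong to the
mixed categories. These bands are the only orientation that partitions
[−1, 1]; the boundary inclusion follows the protocol's ≤/≥ notation.

**Concordance and VLR discovery.** Only L-, R- and B-classified patients
enter the concordance analysis; bilateral-left/right patients are excluded
because their activations are neither clearly confirming nor clearly
contradicting a side. Per activation: in a lateralized patient, activation
on the dominant side (after the cerebellar swap) is concordant and anything
else — including bilateral activation — is discordant; in a bilateral
patient nothing is discordant (crossed dominance permits single-sided
activation in either hemisphere). A cell is validly lateralizing when it has
zero discordant activations and at least `min_vlr_sessions` (default 10)
activated sessions, both evaluated on the same L/R/B subcohort. Dominance
for this stage is recomputed from the supplied baseline set rather than
trusted from input; a fixed dominance map can be injected for audits. The
expansion pipeline performs exactly one discovery pass (no fixed-point
iteration) and reclassifies every patient with the discovered set, reporting
per-patient count/LI/category pairs and the delta-LI summary among patients
with any degree of bilaterality.

**Task-subset simulation.** The reference classification uses all sessions
with the supplied set (default: the expanded set, matching the protocol in
which subset simulation follows reclassification); reference-NC patients are
excluded. Each of the 15 non-empty subsets reclassifies patients from the
subset's sessions only, with the ≥ 3 cutoff applied unchanged. Outcomes
compare dominance *groups* — {L}, {R}, {bilateral spectrum} — because a
shift within the bilateral spectrum changes the degree, not the side, of
bilaterality. Count monotonicity guarantees a lateralized reference patient
can never appear in the opposite lateralized group under a subset, so errors
can only be bilateral-group patients lateralized by an unlucky subset. The
order recommendation is a greedy nested chain (best singleton, best pair
containing it, ...), scored by most correct, then fewest incorrect, then the
canonical task order (VIT, WCT, BST, SYT); the greedy chain equals the
lexicographically best of all 24 nested chains because each tie-break level
is a strict total order, and the brute-force enumeration is kept as a test
oracle.

**Indicator ROIs.** For each task, every ROI outside the VLR set is reported
with two explicit numerator/denominator rates: co-activation among sessions
activating ≥ 1 VLR cell of the task, and activation among all successful
sessions of the task. Both denominators are reported side by side because
both readings are clinically used; zero denominators yield an undefined
rate, never 0.

## Synthetic cohort generator

The generator emulates the cohort structure the analysis assumes, with
defaults chosen as the study conditions:

| parameter | default | rationale |
|---|---|---|
| dominance mixture | 0.54 L / 0.21 BL-L / 0.18 B / 0.00 BL-R / 0.07 R | the classified share of the reference cohort (47/18/16/0/6 of 87) |
| tasks per exam | {1: .10, 2: .20, 3: .25, 4: .45} | 1–4 tasks measured, most exams covering 3–4 |
| sessions per task | {1: .25, 2: .40, 3: .25, 4: .10} | mean ≈ 2.2, so exams average ≈ 6.6 sessions (748 sessions / 114 exams) |
| session failure | 0.21 | the study-wide 156/748 unsuccessful-session rate |
| VLR activation probability | 0.6 per cell per session | no quantitative rates are published; chosen so planted cells comfortably clear the 10-session criterion at cohort sizes of tens of patients |
| indicator probability | 0.85 (bilateral) | indicator cells activate in the vast majority of sessions |
| discordance noise | 0.0 | valid cells show zero discordant activations by definition; noise is opt-in |
| background probability | 0.0 | non-planted, non-indicator cells are silent unless requested |

Lateralized patients activate planted cells on the anatomical side implied
by their dominance (right hemisphere for the crossed cerebellum), flipped
with the discordance-noise probability. Bilateral patients draw the side
uniformly from {left, right, bilateral}. Bilateral-left/right patients draw
from (0.75 dominant, 0.05 minor, 0.20 bilateral), giving an expected LI
around 0.58 — inside the [0.5, 1) band — while leaving band membership to
chance rather than forcing it. Seeding uses one root `SeedSequence` spawned
into per-patient substreams, so growing the cohort never reshuffles earlier
patients.

What the generator does **not** emulate: per-task difficulty and compliance
differences (tasks are structurally symmetric up to their planted cell
counts), within-exam fatigue or attrition dynamics, rater subjectivity, and
spatial structure of any kind. Consequently a passing subset-simulation test
shows the machinery is correct, not that any particular task order is
optimal for real patients; on synthetic data the winning order simply tracks
the number of planted cells per task.

`plant_expansion_scenario` is a construction, not a simulation: it
guarantees its post-condition (exactly *k* patients classifiable only under
the expanded set, every planted cell meeting both discovery criteria) by
forcing discordance noise to zero, rewriting the rare wrong-side draw that a
mixed-dominance patient can hide behind an all-left baseline classification,
stripping non-baseline activations from below-cutoff patients, and appending
single-cell concordant booster sessions (anchored on lateralized patients,
whose LI is pinned at ±1) until every planted cell reaches the session
threshold. The function verifies the post-condition by running the discovery
pipeline and raises if construction failed.

## Numerical and design choices

- Exact rational LI throughout; report tables render LI both as a 4-decimal
  string and as an exact numerator/denominator pair.
- Deterministic ordering everywhere: records sort by (patient, exam, task
  order, session); tables have fixed schemas; reruns are byte-identical
  apart from the manifest timestamp.
- Degenerate inputs are values, not errors: an empty curated cohort yields
  empty tables and an explicit "0 patients analyzable" summary; undefined
  LI and undefined indicator rates are `None`/empty, never 0.
- The CLI is a thin layer over the library; every subcommand exits nonzero
  with a stage-tagged message on invalid input.
- Test and acceptance problem sizes (cohorts of 40–114 patients, one
  2000-patient mixture-recovery check) were chosen so that binomial
  sampling error is small relative to the asserted effects while the whole
  suite stays fast.

## Known limitations

- The rating itself (visual, subjective) is upstream of this package; the
  pipeline standardizes the arithmetic on the ratings, not the ratings.
- When sessions exist in several languages, selecting which to analyze is
  an upstream decision; the package takes the supplied sessions as given.
- Exam ordering falls back to lexicographic ids; callers with true exam
  dates should encode them into sortable ids.
- Discovery is a single pass by design; iterating discovery to a fixed
  point is intentionally not offered.
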