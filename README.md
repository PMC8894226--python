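# vlrlat

Hemispheric language dominance from categorical speech-fMRI ratings.

Before epilepsy surgery near language areas, clinicians must know which
hemisphere is language-dominant. In pediatric presurgical fMRI a battery of
four language tasks — vowel identification (VIT), covert word-chain
generation (WCT), beep-story passive listening (BST) and synonym decision
(SYT) — is measured in repeated sessions, and an
experienced rater scores each of ten homotopic regions of interest (ROIs)
per session as `left`, `right`, `bilateral` or `none`. `vlrlat` implements
the count-based evaluation pipeline for these categorical ratings:

- **Simplified laterality index.** Over the validly lateralizing ROIs
  (VLR), activations are counted per hemisphere across all sessions and
  tasks of an exam; bilateral activation counts once per hemisphere, and
  cerebellar activation is counted for the opposite hemisphere (crossed
  cerebrocerebellar organization). Then

  LI = (ΣL − ΣR) / (ΣL + ΣR),

  kept as an exact rational. Patients with fewer than 3 VLR activations
  are not classifiable (NC); otherwise LI = +1 → left-dominant, −1 →
  right-dominant, 0.5 ≤ LI < 1 → bilateral-left, −0.5 < LI < 0.5 →
  bilateral, −1 < LI ≤ −0.5 → bilateral-right.
- **VLR discovery by concordance.** Using only left-, right- and
  bilateral-classified patients, every ROI activation in every session is
  labelled concordant or discordant with the patient's dominance
  (bilateral activation in a lateralized patient is discordant; nothing is
  discordant in a bilateral patient). A task-specific ROI is validly
  lateralizing when it shows **zero discordant activations** and is
  **activated in ≥ 10 sessions**. The shipped 13-member baseline set
  expands to 17 members under this analysis.
- **Task-subset simulation and measurement order.** Classification is
  re-run under all 15 task subsets; a greedy nested chain (best single
  task, best pair containing it, ...) recommends the order in which to
  measure tasks so that an examination stopped early still yields the most
  reliable result.
- **Indicator ROIs.** Frequently activated, non-lateralizing cells (A1
  under BST, SMA under WCT) are reported with explicit
  numerator/denominator pairs; their absence flags unreliable sessions.
- **Synthetic cohorts.** A seeded generator emulates the cohort structure
  (dominance mixture, 1–4 tasks per exam, repeated sessions, session
  failures, optional discordance noise, planted VLR sets) so every stage
  is testable with known ground truth.

## Worked example

```python
from vlrlat import (Activation, Roi, SessionRecord, Task, VLR_NEW,
                    classify_sessions, count_vlr_activations)

def session(task, index, **rois):
    acts = {r: Activation.NONE for r in Roi}
    for name, side in rois.items():
        acts[Roi(name)] = Activation.parse(side)
    return SessionRecord("P001", "E1", task, index, acts)

exam = [
    session(Task.VIT, 1, FOP="L", IFG="L"),
    session(Task.VIT, 2, IFG="B"),
    session(Task.WCT, 1, MFG="L", CBM="R"),
]
counts = count_vlr_activations(exam, VLR_NEW)
result = classify_sessions(exam, VLR_NEW)
print(counts.left, counts.right, result.li, result.category.value)
```

prints

```
5 1 2/3 BL_L
```

Five left counts (two left frontal activations, the bilateral IFG
contributing one per hemisphere, the left MFG, and the right cerebellum
counted left because it is crossed) against one right count give
LI = 4/6 = 2/3: six activations clear the ≥ 3 cutoff, and LI in [0.5, 1)
places the patient in the bilateral-left band.

Runnable scripts for each capability are in `examples/` (classification,
VLR discovery, task-order simulation, indicator metrics, full pipeline),
and `vlrlat --help` exposes the same stages as a command-line tool
(`validate`, `synth`, `classify`, `vlr-discover`, `simulate-subsets`,
`recommend-order`, `indicators`, `run`).

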