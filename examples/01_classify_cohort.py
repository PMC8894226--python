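"""Classify hemispheric language dominance for a small hand-built exam.

Builds one patient's exam from categorical ROI ratings, counts validly
lateralizing ROI (VLR) activations per hemisphere and prints the simplified
laterality index LI = (L - R) / (L + R) with its five-way category.
"""

from vlrlat import (
    Activation,
    Roi,
    SessionRecord,
    Task,
    VLR_NEW,
    classify_sessions,
    count_vlr_activations,
)


def session(task: Task, index: int, **rois) -> SessionRecord:
    acts = {r: Activation.NONE for r in Roi}
    for name, side in rois.items():
        acts[Roi(name)] = Activation.parse(side)
    return SessionRecord("P001", "E1", task, index, acts)


# A left-lateralized exam with one bilateral frontal activation and a
# right-sided cerebellar activation (which, being crossed, counts left).
exam = [
    session(Task.VIT, 1, FOP="L", IFG="L"),
    session(Task.VIT, 2, IFG="B"),
    session(Task.WCT, 1, MFG="L", CBM="R"),
]

counts = count_vlr_activations(exam, VLR_NEW)
result = classify_sessions(exam, VLR_NEW)

print(f"left counts:  {counts.left}")
print(f"right counts: {counts.right}")
print(f"LI = {result.li} ({float(result.li):+.3f})")
print(f"category: {result.category.value}")
# The bilateral IFG adds one count per hemisphere and the right cerebellum
# counts for the left hemisphere, so LI < +1: the patient falls in the
# bilateral-left band rather than being called fully left-dominant.
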