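"""Indicator-ROI rates: frequently activated but non-lateralizing cells.

The primary auditory cortex under passive story listening and the
supplementary motor area under covert word generation activate in nearly
every session that also activates a VLR; their absence flags a session
whose activation pattern should be interpreted with caution. Two
denominators are printed because both are informative: sessions activating
any VLR of the task, and all successful sessions of the task.
"""

from vlrlat import (
    GeneratorConfig,
    Roi,
    Task,
    VLR_NEW,
    generate_cohort,
    indicator_metrics,
)

cohort, _ = generate_cohort(GeneratorConfig(n_patients=80, seed=3))

for task, roi in ((Task.BST, Roi.A1), (Task.WCT, Roi.SMA)):
    m = next(x for x in indicator_metrics(cohort, VLR_NEW, task) if x.roi is roi)
    rate_a = m.rate_among_vlr_sessions
    rate_b = m.rate_among_successful_sessions
    print(f"{task.value} {roi.value}:")
    print(f"  among VLR-activating sessions: {m.n_coactivated}/{m.n_vlr_sessions}"
          f" ({rate_a:.0%})" if rate_a is not None else "  undefined")
    print(f"  among successful sessions:     {m.n_activated}/{m.n_successful_sessions}"
          f" ({rate_b:.0%})" if rate_b is not None else "  undefined")
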