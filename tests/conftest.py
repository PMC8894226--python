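import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vlrlat import (
    Activation,
    Cohort,
    ROI_ORDER,
    Roi,
    SessionRecord,
    TASK_ORDER,
    Task,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


def make_record(
    patient_id: str = "P1",
    exam_id: str = "E1",
    task: Task = Task.VIT,
    session_index: int = 1,
    **roi_activations,
) -> SessionRecord:
    """Session with all ROIs 'none' except the given ROI=Activation overrides."""
    acts = {r: Activation.NONE for r in Roi}
    for name, act in roi_activations.items():
        acts[Roi(name)] = act if isinstance(act, Activation) else Activation.parse(act)
    return SessionRecord(patient_id, exam_id, task, session_index, acts)


def random_cohort(
    seed: int,
    n_patients: int = 8,
    max_sessions_per_task: int = 3,
    p_task: float = 0.7,
    activation_probs=(0.25, 0.12, 0.12, 0.51),  # L, R, B, none
) -> Cohort:
    """Fully random categorical cohort, independent of the package generator.

    Used by brute-force-oracle tests: activations are drawn without any
    dominance structure so every code path (crossed ROI, bilateral, none)
    is exercised.
    """
    rng = np.random.default_rng(seed)
    sides = [Activation.LEFT, Activation.RIGHT, Activation.BILATERAL, Activation.NONE]
    probs = np.asarray(activation_probs, dtype=float)
    probs = probs / probs.sum()
    records = []
    for i in range(n_patients):
        pid = f"Q{i:03d}"
        for task in TASK_ORDER:
            if rng.random() > p_task:
                continue
            for s in range(1, int(rng.integers(1, max_sessions_per_task + 1)) + 1):
                acts = {
                    roi: sides[int(rng.choice(4, p=probs))] for roi in ROI_ORDER
                }
                records.append(SessionRecord(pid, "E1", task, s, acts))
    return Cohort(tuple(records))


def mirror_activation(act: Activation) -> Activation:
    return act.flipped()


def mirror_cohort(cohort: Cohort) -> Cohort:
    """Swap left and right in every rating (bilateral and none fixed)."""
    records = []
    for rec in cohort:
        acts = {roi: mirror_activation(a) for roi, a in rec.activations.items()}
        records.append(
            SessionRecord(rec.patient_id, rec.exam_id, rec.task, rec.session_index, acts)
        )
    return Cohort(tuple(records))


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Two patients: one strongly left-lateralized, one bilateral."""
    records = [
        make_record("PL", task=Task.VIT, session_index=1, FOP="L", IFG="L"),
        make_record("PL", task=Task.WCT, session_index=1, MFG="L", CBM="R"),
        make_record("PB", task=Task.VIT, session_index=1, FOP="L", IFG="R"),
        make_record("PB", task=Task.SYT, session_index=1, FOP="B"),
    ]
    return Cohort(tuple(records))
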