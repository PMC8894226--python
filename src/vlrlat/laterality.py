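"""VLR activation counting, the simplified laterality index, and the
five-way dominance classification.

The simplified LI replaces voxel-count indices with a count over validly
lateralizing ROI (VLR) activations across all sessions and tasks of one
exam:

    LI = (L - R) / (L + R)

where a left activation adds one to L, a right activation one to R, a
bilateral activation one to each (two activations, one per hemisphere), and
cerebellar contributions are swapped between hemispheres (crossed
cerebrocerebellar organization: right cerebellar activation indicates left
dominance). LI is kept as an exact rational so that the +-0.5 and +-1 band
boundaries are decided without floating-point tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .model import (
    Activation,
    AnalysisConfig,
    Dominance,
    SessionRecord,
    VlrSet,
)


@dataclass(frozen=True)
class ActivationCounts:
    """Per-hemisphere VLR activation tallies after bilateral expansion and
    cerebellar crossing."""

    left: int = 0
    right: int = 0

    def __post_init__(self) -> None:
        if self.left < 0 or self.right < 0:
            raise ValueError("activation counts must be non-negative")

    @property
    def total(self) -> int:
        return self.left + self.right

    def __add__(self, other: "ActivationCounts") -> "ActivationCounts":
        return ActivationCounts(self.left + other.left, self.right + other.right)


@dataclass(frozen=True)
class LateralityResult:
    """Classification outcome for one exam."""

    counts: ActivationCounts
    li: Fraction | None
    category: Dominance

    @property
    def n_activations(self) -> int:
        return self.counts.total

    @property
    def classifiable(self) -> bool:
        return self.category is not Dominance.NC


def count_vlr_activations(
    sessions: Iterable[SessionRecord], vlr: VlrSet
) -> ActivationCounts:
    """Count VLR activations per hemisphere across an exam's sessions.

    Only (task, ROI) cells in ``vlr`` contribute. Bilateral activation adds
    one count to each hemisphere. For the crossed cerebellum the left/right
    contributions are swapped; bilateral is unchanged (crossing is a
    symmetric swap).
    """
    sessions = list(sessions)
    exams = {(s.patient_id, s.exam_id) for s in sessions}
    if len(exams) > 1:
        raise ValueError(f"sessions span multiple exams: {sorted(exams)}")
    left = right = 0
    for rec in sessions:
        for (task, roi) in vlr.members:
            if task is not rec.task:
                continue
            act = rec.activations[roi]
            if act is Activation.NONE:
                continue
            if act is Activation.BILATERAL:
                left += 1
                right += 1
                continue
            if roi.crossed:
                act = act.flipped()
            if act is Activation.LEFT:
                left += 1
            else:
                right += 1
    return ActivationCounts(left, right)


def compute_li(counts: ActivationCounts) -> Fraction | None:
    """Exact rational (L - R) / (L + R); None (undefined) when L + R = 0."""
    if counts.total == 0:
        return None
    return Fraction(counts.left - counts.right, counts.total)


def classify_dominance(
    counts: ActivationCounts, config: AnalysisConfig | None = None
) -> LateralityResult:
    """Classify one exam's counts into the five dominance categories.

    NC (not classifiable) whenever fewer than ``min_vlr_activations``
    activations were observed; otherwise L iff LI = +1, R iff LI = -1,
    bilateral-left for 0.5 <= LI < 1, bilateral for -0.5 < LI < 0.5 and
    bilateral-right for -1 < LI <= -0.5 (band boundaries inclusive toward
    the mixed categories).
    """
    config = config or AnalysisConfig()
    li = compute_li(counts)
    if counts.total < config.min_vlr_activations:
        return LateralityResult(counts, li, Dominance.NC)
    assert li is not None  # total >= min >= 1
    inner = config.li_inner
    if li == 1:
        cat = Dominance.L
    elif li == -1:
        cat = Dominance.R
    elif inner <= li < 1:
        cat = Dominance.BL_L
    elif -1 < li <= -inner:
        cat = Dominance.BL_R
    else:
        cat = Dominance.B
    return LateralityResult(counts, li, cat)


def classify_sessions(
    sessions: Sequence[SessionRecord],
    vlr: VlrSet,
    config: AnalysisConfig | None = None,
) -> LateralityResult:
    """Convenience: count then classify one exam's sessions."""
    return classify_dominance(count_vlr_activations(sessions, vlr), config)


def classify_cohort(
    cohort: Iterable[SessionRecord] | "object",
    vlr: VlrSet,
    config: AnalysisConfig | None = None,
) -> dict[str, LateralityResult]:
    """Classify every patient of a (curated, single-exam-per-patient) cohort.

    Returns a mapping patient_id -> LateralityResult, deterministic order.
    """
    by_patient: dict[str, list[SessionRecord]] = {}
    for rec in cohort:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    return {
        pid: classify_sessions(by_patient[pid], vlr, config)
        for pid in sorted(by_patient)
    }


def dominance_map(results: Mapping[str, LateralityResult]) -> dict[str, Dominance]:
    return {pid: res.category for pid, res in results.items()}
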