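"""Domain types for categorical speech-fMRI laterality analysis.

The unit of observation is one task *session*: a single block-design fMRI run
of one language task, visually rated into a four-level activation category
(left / right / bilateral / none) for each of ten bilateral (homotopic) ROIs.
An *exam* bundles the 1-11 sessions a patient performed across 1-4 tasks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Iterator, Mapping


class ValidationError(ValueError):
    """Raised when input records violate the cohort schema."""


class Task(str, Enum):
    """The four pediatric language tasks of the battery.

    VIT: vowel identification (visual decision), WCT: covert word-chain
    generation, BST: beep-story passive listening with gaps, SYT: synonym
    decision.
    """

    VIT = "VIT"
    WCT = "WCT"
    BST = "BST"
    SYT = "SYT"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.value


#: Canonical ordering used for deterministic output and tie-breaking.
TASK_ORDER: tuple[Task, ...] = (Task.VIT, Task.WCT, Task.BST, Task.SYT)


class Roi(str, Enum):
    """The ten homotopic regions of interest rated per session.

    CBM (cerebellum) is the single *crossed* ROI: cerebellar language
    activation is contralateral to the dominant cerebral hemisphere.
    """

    MFG = "MFG"
    IFG = "IFG"
    FOP = "FOP"
    S1M1 = "S1M1"
    A1 = "A1"
    TLA = "TLA"
    IPS = "IPS"
    ANG = "ANG"
    CBM = "CBM"
    SMA = "SMA"

    @property
    def crossed(self) -> bool:
        return self is Roi.CBM

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.value


ROI_ORDER: tuple[Roi, ...] = tuple(Roi)


class Activation(str, Enum):
    """Per-session, per-ROI categorical activation rating.

    ``NONE`` is an explicit rating (no suprathreshold activation), never an
    absent field.
    """

    LEFT = "L"
    RIGHT = "R"
    BILATERAL = "B"
    NONE = "none"

    @classmethod
    def parse(cls, token: str) -> "Activation":
        try:
            return _ACTIVATION_TOKENS[str(token).strip()]
        except KeyError:
            raise ValidationError(f"unknown activation value: {token!r}") from None

    def flipped(self) -> "Activation":
        """Swap left and right; bilateral and none are fixed points."""
        if self is Activation.LEFT:
            return Activation.RIGHT
        if self is Activation.RIGHT:
            return Activation.LEFT
        return self


_ACTIVATION_TOKENS: dict[str, Activation] = {
    "L": Activation.LEFT,
    "R": Activation.RIGHT,
    "B": Activation.BILATERAL,
    "none": Activation.NONE,
    "left": Activation.LEFT,
    "right": Activation.RIGHT,
    "bilateral": Activation.BILATERAL,
}


class Dominance(str, Enum):
    """Five-way hemispheric language dominance, plus not-classifiable."""

    L = "L"  # left-dominant, LI = +1
    BL_L = "BL_L"  # bilateral-left, 0.5 <= LI < 1
    B = "B"  # bilateral, -0.5 < LI < 0.5
    BL_R = "BL_R"  # bilateral-right, -1 < LI <= -0.5
    R = "R"  # right-dominant, LI = -1
    NC = "NC"  # not classifiable (< cutoff activations)

    def mirrored(self) -> "Dominance":
        return _DOMINANCE_MIRROR[self]


_DOMINANCE_MIRROR = {
    Dominance.L: Dominance.R,
    Dominance.R: Dominance.L,
    Dominance.BL_L: Dominance.BL_R,
    Dominance.BL_R: Dominance.BL_L,
    Dominance.B: Dominance.B,
    Dominance.NC: Dominance.NC,
}

#: Dominance categories admitted to the concordance analysis.
CONCORDANCE_DOMINANCES = frozenset({Dominance.L, Dominance.R, Dominance.B})


@dataclass(frozen=True)
class SessionRecord:
    """One task session's activation rating for all ten ROIs."""

    patient_id: str
    exam_id: str
    task: Task
    session_index: int
    activations: Mapping[Roi, Activation]

    def __post_init__(self) -> None:
        if self.session_index < 1:
            raise ValidationError(
                f"session_index must be a positive integer, got {self.session_index} "
                f"({self.key()})"
            )
        missing = [r.value for r in Roi if r not in self.activations]
        if missing:
            raise ValidationError(
                f"session {self.key()} is missing activation ratings for "
                f"{', '.join(missing)}"
            )
        extra = [k for k in self.activations if not isinstance(k, Roi)]
        if extra:
            raise ValidationError(f"session {self.key()} has unknown ROI keys: {extra}")
        object.__setattr__(self, "activations", dict(self.activations))

    def key(self) -> tuple[str, str, str, int]:
        return (self.patient_id, self.exam_id, self.task.value, self.session_index)

    @property
    def successful(self) -> bool:
        """A session is successful iff at least one ROI is activated."""
        return any(a is not Activation.NONE for a in self.activations.values())


def is_successful_session(record: SessionRecord) -> bool:
    """True iff at least one of the ten ROIs shows any activation."""
    return record.successful


def _sort_key(rec: SessionRecord):
    return (
        rec.patient_id,
        rec.exam_id,
        TASK_ORDER.index(rec.task),
        rec.session_index,
    )


@dataclass(frozen=True)
class Cohort:
    """A validated collection of session records plus provenance metadata."""

    records: tuple[SessionRecord, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        recs = tuple(sorted(self.records, key=_sort_key))
        seen: set[tuple] = set()
        for rec in recs:
            k = rec.key()
            if k in seen:
                raise ValidationError(f"duplicate session key: {k}")
            seen.add(k)
        object.__setattr__(self, "records", recs)
        object.__setattr__(self, "provenance", dict(self.provenance))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SessionRecord]:
        return iter(self.records)

    def patient_ids(self) -> list[str]:
        return sorted({r.patient_id for r in self.records})

    def sessions_of(self, patient_id: str) -> list[SessionRecord]:
        return [r for r in self.records if r.patient_id == patient_id]

    def with_provenance(self, **meta: object) -> "Cohort":
        prov = {**self.provenance, **meta}
        return Cohort(self.records, prov)


@dataclass(frozen=True)
class CurationReport:
    """What cohort curation kept and dropped, with reasons."""

    n_patients_in: int
    n_patients_out: int
    n_sessions_in: int
    n_sessions_out: int
    dropped_exams: tuple[tuple[str, str], ...]  # (patient_id, exam_id) superseded
    dropped_patients: tuple[tuple[str, str], ...]  # (patient_id, reason)

    def to_dict(self) -> dict:
        return {
            "n_patients_in": self.n_patients_in,
            "n_patients_out": self.n_patients_out,
            "n_sessions_in": self.n_sessions_in,
            "n_sessions_out": self.n_sessions_out,
            "dropped_exams": [list(x) for x in self.dropped_exams],
            "dropped_patients": [list(x) for x in self.dropped_patients],
        }


def curate_cohort(cohort: Cohort) -> tuple[Cohort, CurationReport]:
    """Apply the cohort curation rules.

    Keeps only the last exam per patient (exam ids ordered lexicographically;
    the rating protocol provides no machine-readable date) and drops patients
    whose every retained session is unsuccessful.
    """
    by_patient: dict[str, dict[str, list[SessionRecord]]] = {}
    for rec in cohort:
        by_patient.setdefault(rec.patient_id, {}).setdefault(rec.exam_id, []).append(rec)

    kept: list[SessionRecord] = []
    dropped_exams: list[tuple[str, str]] = []
    dropped_patients: list[tuple[str, str]] = []
    for pid in sorted(by_patient):
        exams = by_patient[pid]
        last = max(exams)
        for eid in sorted(exams):
            if eid != last:
                dropped_exams.append((pid, eid))
        sessions = exams[last]
        if not any(s.successful for s in sessions):
            dropped_patients.append((pid, "all sessions unsuccessful"))
            continue
        kept.extend(sessions)

    curated = Cohort(tuple(kept), {**cohort.provenance, "curated": True})
    report = CurationReport(
        n_patients_in=len(by_patient),
        n_patients_out=len(curated.patient_ids()),
        n_sessions_in=len(cohort),
        n_sessions_out=len(curated),
        dropped_exams=tuple(dropped_exams),
        dropped_patients=tuple(dropped_patients),
    )
    return curated, report


@dataclass(frozen=True)
class VlrSet:
    """A named set of validly lateralizing (task, ROI) pairs."""

    name: str
    members: frozenset[tuple[Task, Roi]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        for task, roi in self.members:
            if not isinstance(task, Task) or not isinstance(roi, Roi):
                raise ValidationError(f"invalid VLR member: {(task, roi)!r}")

    def __contains__(self, cell: tuple[Task, Roi]) -> bool:
        return cell in self.members

    def __len__(self) -> int:
        return len(self.members)

    def rois_for(self, task: Task) -> frozenset[Roi]:
        return frozenset(r for t, r in self.members if t is task)

    def union(self, cells: Iterable[tuple[Task, Roi]], name: str | None = None) -> "VlrSet":
        return VlrSet(name or self.name, self.members | frozenset(cells))

    def sorted_members(self) -> list[tuple[Task, Roi]]:
        return sorted(
            self.members,
            key=lambda c: (TASK_ORDER.index(c[0]), ROI_ORDER.index(c[1])),
        )


def _vlr(name: str, spec: dict[Task, tuple[Roi, ...]]) -> VlrSet:
    return VlrSet(name, frozenset((t, r) for t, rois in spec.items() for r in rois))


#: The 13 task-specific ROIs validated against the Wada / post-hemispherotomy
#: gold standard in the antecedent validation study.
VLR_OLD = _vlr(
    "VLR_old",
    {
        Task.VIT: (Roi.FOP, Roi.IFG, Roi.MFG),
        Task.WCT: (Roi.FOP, Roi.IFG, Roi.MFG, Roi.IPS, Roi.CBM),
        Task.BST: (Roi.IFG, Roi.MFG),
        Task.SYT: (Roi.FOP, Roi.IFG, Roi.TLA),
    },
)

#: The four cells added by the concordance re-analysis.
VLR_EXPANSION_CELLS: frozenset[tuple[Task, Roi]] = frozenset(
    {
        (Task.VIT, Roi.TLA),
        (Task.SYT, Roi.MFG),
        (Task.SYT, Roi.IPS),
        (Task.SYT, Roi.CBM),
    }
)

#: The expanded 17-member set: VLR_old plus the four new cells.
VLR_NEW = VLR_OLD.union(VLR_EXPANSION_CELLS, name="VLR_new")

#: The full 4 x 10 grid of task-specific ROIs.
ALL_CELLS: tuple[tuple[Task, Roi], ...] = tuple(
    (t, r) for t in TASK_ORDER for r in ROI_ORDER
)

#: Frequently-activated non-lateralizing cells whose absence flags an
#: unreliable session (A1 under passive listening, SMA under word generation).
INDICATOR_CELLS: frozenset[tuple[Task, Roi]] = frozenset(
    {(Task.BST, Roi.A1), (Task.WCT, Roi.SMA)}
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the classification procedure.

    min_vlr_activations: minimum VLR activation count for a safe
        classification (bilateral counts twice).
    min_vlr_sessions: minimum activated sessions for VLR discovery.
    li_inner: the |LI| boundary between the bilateral band and the
        bilateral-left / bilateral-right bands.
    """

    min_vlr_activations: int = 3
    min_vlr_sessions: int = 10
    li_inner: Fraction = Fraction(1, 2)
    vlr_set: str = "VLR_new"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_vlr_activations < 1:
            raise ValidationError("min_vlr_activations must be >= 1")
        if self.min_vlr_sessions < 1:
            raise ValidationError("min_vlr_sessions must be >= 1")
        inner = Fraction(self.li_inner)
        if not (0 < inner < 1):
            raise ValidationError("li_inner must satisfy 0 < inner < 1")
        object.__setattr__(self, "li_inner", inner)

    def resolve_vlr_set(self) -> VlrSet:
        try:
            return {"VLR_old": VLR_OLD, "VLR_new": VLR_NEW}[self.vlr_set]
        except KeyError:
            raise ValidationError(
                f"unknown vlr_set {self.vlr_set!r}; expected VLR_old or VLR_new"
            ) from None

    def replace(self, **kw) -> "AnalysisConfig":
        return dataclasses.replace(self, **kw)
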