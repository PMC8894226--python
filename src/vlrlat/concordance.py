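"""Concordance analysis, VLR discovery, expansion pipeline and indicator
ROI metrics.

A single ROI activation is *concordant* when its side agrees with the
patient's classified dominance and *discordant* otherwise. Bilateral
activation in a lateralized (L or R) patient is discordant; in a patient
with bilateral language dominance no activation is ever discordant (crossed
dominance allows single-sided activations in either hemisphere). For the
crossed cerebellum the sides are swapped before the rule is applied.

A (task, ROI) cell is *validly lateralizing* when it shows no discordant
activation AND is activated in at least ``min_vlr_sessions`` sessions of the
L/R/B subcohort.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Mapping

import pandas as pd

from .laterality import (
    LateralityResult,
    classify_cohort,
)
from .model import (
    ALL_CELLS,
    Activation,
    AnalysisConfig,
    CONCORDANCE_DOMINANCES,
    Cohort,
    Dominance,
    ROI_ORDER,
    Roi,
    TASK_ORDER,
    Task,
    VlrSet,
)


class ConcordanceLabel(str, Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"
    NOT_APPLICABLE = "not_applicable"


def classify_concordance(
    activation: Activation, roi: Roi, dominance: Dominance
) -> ConcordanceLabel:
    """Label one ROI activation against the patient's dominance."""
    if activation is Activation.NONE or dominance not in CONCORDANCE_DOMINANCES:
        return ConcordanceLabel.NOT_APPLICABLE
    if dominance is Dominance.B:
        return ConcordanceLabel.CONCORDANT
    effective = activation.flipped() if roi.crossed else activation
    expected = Activation.LEFT if dominance is Dominance.L else Activation.RIGHT
    if effective is expected:
        return ConcordanceLabel.CONCORDANT
    return ConcordanceLabel.DISCORDANT


@dataclass
class CellTally:
    """Concordance tallies for one (task, ROI) cell."""

    concordant: int = 0
    discordant: int = 0
    n_activated_sessions: int = 0
    #: stratified counts keyed by (dominance, activation side as rated)
    strata: dict[tuple[Dominance, Activation], int] = field(default_factory=dict)

    def add(self, dominance: Dominance, activation: Activation, label: ConcordanceLabel) -> None:
        if label is ConcordanceLabel.CONCORDANT:
            self.concordant += 1
        elif label is ConcordanceLabel.DISCORDANT:
            self.discordant += 1
        else:
            return
        self.n_activated_sessions += 1
        key = (dominance, activation)
        self.strata[key] = self.strata.get(key, 0) + 1


@dataclass
class ConcordanceTable:
    """Per-cell concordance tallies plus per-task session denominators.

    ``task_denominators[t]`` counts the successful sessions of task ``t``
    among included (L/R/B-classified) patients — the denominator against
    which per-cell activation proportions are read.
    """

    cells: dict[tuple[Task, Roi], CellTally]
    task_denominators: dict[Task, int]
    n_patients: int

    @property
    def n_concordant(self) -> int:
        return sum(c.concordant for c in self.cells.values())

    @property
    def n_discordant(self) -> int:
        return sum(c.discordant for c in self.cells.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for task, roi in ALL_CELLS:
            cell = self.cells[(task, roi)]
            row = {
                "task": task.value,
                "roi": roi.value,
                "n_concordant": cell.concordant,
                "n_discordant": cell.discordant,
                "n_activated_sessions": cell.n_activated_sessions,
                "task_denominator": self.task_denominators[task],
            }
            for dom in (Dominance.L, Dominance.R, Dominance.B):
                for act in (Activation.LEFT, Activation.RIGHT, Activation.BILATERAL):
                    row[f"dom_{dom.value}_act_{act.value}"] = cell.strata.get(
                        (dom, act), 0
                    )
            rows.append(row)
        return pd.DataFrame(rows)


def build_concordance_table(
    cohort: Cohort, dominance_map: Mapping[str, Dominance]
) -> ConcordanceTable:
    """Tally every non-none activation of L/R/B-classified patients.

    Patients classified bilateral-left or bilateral-right (or NC) are
    excluded. Raises on cohort patients absent from ``dominance_map``.
    """
    cells = {cell: CellTally() for cell in ALL_CELLS}
    denominators = {t: 0 for t in TASK_ORDER}
    included_patients: set[str] = set()
    for rec in cohort:
        if rec.patient_id not in dominance_map:
            raise KeyError(f"patient {rec.patient_id!r} missing from dominance map")
        dom = dominance_map[rec.patient_id]
        if dom not in CONCORDANCE_DOMINANCES:
            continue
        included_patients.add(rec.patient_id)
        if rec.successful:
            denominators[rec.task] += 1
        for roi in ROI_ORDER:
            act = rec.activations[roi]
            label = classify_concordance(act, roi, dom)
            cells[(rec.task, roi)].add(dom, act, label)
    return ConcordanceTable(cells, denominators, len(included_patients))


@dataclass(frozen=True)
class CellAudit:
    task: Task
    roi: Roi
    n_concordant: int
    n_discordant: int
    n_activated_sessions: int
    criterion1_pass: bool  # zero discordant activations
    criterion2_pass: bool  # activated in >= min_vlr_sessions sessions
    member: bool


@dataclass(frozen=True)
class VlrDiscoveryResult:
    vlr: VlrSet
    audit: tuple[CellAudit, ...]

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "task": a.task.value,
                    "roi": a.roi.value,
                    "n_concordant": a.n_concordant,
                    "n_discordant": a.n_discordant,
                    "n_activated_sessions": a.n_activated_sessions,
                    "pass_no_discordance": a.criterion1_pass,
                    "pass_min_sessions": a.criterion2_pass,
                    "member": a.member,
                }
                for a in self.audit
            ]
        )


def discover_vlr(
    table: ConcordanceTable, config: AnalysisConfig | None = None
) -> VlrDiscoveryResult:
    """Apply the two VLR inclusion criteria to all 40 grid cells."""
    config = config or AnalysisConfig()
    audits: list[CellAudit] = []
    members: set[tuple[Task, Roi]] = set()
    for task, roi in ALL_CELLS:
        cell = table.cells[(task, roi)]
        c1 = cell.discordant == 0
        c2 = cell.n_activated_sessions >= config.min_vlr_sessions
        member = c1 and c2
        if member:
            members.add((task, roi))
        audits.append(
            CellAudit(
                task,
                roi,
                cell.concordant,
                cell.discordant,
                cell.n_activated_sessions,
                c1,
                c2,
                member,
            )
        )
    return VlrDiscoveryResult(VlrSet("discovered", frozenset(members)), tuple(audits))


@dataclass(frozen=True)
class PatientComparison:
    patient_id: str
    n_old: int
    li_old: Fraction | None
    cat_old: Dominance
    n_new: int
    li_new: Fraction | None
    cat_new: Dominance

    @property
    def delta_li(self) -> Fraction | None:
        if self.li_old is None or self.li_new is None:
            return None
        return self.li_old - self.li_new


@dataclass(frozen=True)
class ExpansionReport:
    """Result of one baseline -> discovered-set reclassification pass."""

    baseline: VlrSet
    discovery: VlrDiscoveryResult
    table: ConcordanceTable
    patients: tuple[PatientComparison, ...]

    @property
    def n_classifiable_old(self) -> int:
        return sum(p.cat_old is not Dominance.NC for p in self.patients)

    @property
    def n_classifiable_new(self) -> int:
        return sum(p.cat_new is not Dominance.NC for p in self.patients)

    @property
    def newly_classifiable(self) -> tuple[str, ...]:
        return tuple(
            p.patient_id
            for p in self.patients
            if p.cat_old is Dominance.NC and p.cat_new is not Dominance.NC
        )

    def delta_li_summary(self) -> dict[str, float | int | None]:
        """Delta-LI range/median among patients with any bilaterality (old)."""
        bilat = {Dominance.BL_L, Dominance.B, Dominance.BL_R}
        deltas = [
            p.delta_li
            for p in self.patients
            if p.cat_old in bilat and p.delta_li is not None
        ]
        changed = sum(d != 0 for d in deltas)
        if not deltas:
            return {"n": 0, "n_changed": 0, "min": None, "max": None, "median": None}
        return {
            "n": len(deltas),
            "n_changed": changed,
            "min": float(min(deltas)),
            "max": float(max(deltas)),
            "median": float(statistics.median(deltas)),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "n_vlr_old": p.n_old,
                    "li_old": None if p.li_old is None else float(p.li_old),
                    "cat_old": p.cat_old.value,
                    "n_vlr_new": p.n_new,
                    "li_new": None if p.li_new is None else float(p.li_new),
                    "cat_new": p.cat_new.value,
                    "delta_li": None if p.delta_li is None else float(p.delta_li),
                }
            )
        return pd.DataFrame(rows)


def run_vlr_expansion(
    cohort: Cohort,
    baseline: VlrSet,
    config: AnalysisConfig | None = None,
    dominance_override: Mapping[str, Dominance] | None = None,
) -> ExpansionReport:
    """Full discovery pass: classify with the baseline set, restrict to the
    L/R/B subcohort, tally concordance, discover the valid set and
    reclassify every patient with it.

    ``dominance_override`` substitutes a fixed dominance map for the
    concordance stage (audit use); by default dominance is recomputed from
    the baseline set rather than taken on faith.
    """
    config = config or AnalysisConfig()
    old = classify_cohort(cohort, baseline, config)
    dom_map = (
        dict(dominance_override)
        if dominance_override is not None
        else {pid: res.category for pid, res in old.items()}
    )
    table = build_concordance_table(cohort, dom_map)
    discovery = discover_vlr(table, config)
    new = classify_cohort(cohort, discovery.vlr, config)
    patients = tuple(
        PatientComparison(
            pid,
            old[pid].n_activations,
            old[pid].li,
            old[pid].category,
            new[pid].n_activations,
            new[pid].li,
            new[pid].category,
        )
        for pid in sorted(old)
    )
    return ExpansionReport(baseline, discovery, table, patients)


@dataclass(frozen=True)
class IndicatorMetrics:
    """Activation rates of one non-VLR ROI under one task.

    Two denominators are reported side by side because both are informative:
    (a) sessions of the task activating at least one VLR cell — how reliably
    the ROI accompanies lateralizing activation; (b) all successful sessions
    of the task.
    """

    task: Task
    roi: Roi
    n_coactivated: int
    n_vlr_sessions: int
    n_activated: int
    n_successful_sessions: int

    @property
    def rate_among_vlr_sessions(self) -> float | None:
        if self.n_vlr_sessions == 0:
            return None
        return self.n_coactivated / self.n_vlr_sessions

    @property
    def rate_among_successful_sessions(self) -> float | None:
        if self.n_successful_sessions == 0:
            return None
        return self.n_activated / self.n_successful_sessions


def indicator_metrics(
    cohort: Cohort, vlr: VlrSet, task: Task
) -> tuple[IndicatorMetrics, ...]:
    """Indicator rates for every ROI that is not a VLR member for ``task``."""
    vlr_rois = vlr.rois_for(task)
    sessions = [r for r in cohort if r.task is task]
    successful = [r for r in sessions if r.successful]
    vlr_sessions = [
        r
        for r in successful
        if any(r.activations[roi] is not Activation.NONE for roi in vlr_rois)
    ]
    out = []
    for roi in ROI_ORDER:
        if roi in vlr_rois:
            continue
        n_co = sum(r.activations[roi] is not Activation.NONE for r in vlr_sessions)
        n_act = sum(r.activations[roi] is not Activation.NONE for r in successful)
        out.append(
            IndicatorMetrics(task, roi, n_co, len(vlr_sessions), n_act, len(successful))
        )
    return tuple(out)


def indicator_frame(cohort: Cohort, vlr: VlrSet) -> pd.DataFrame:
    rows = []
    for task in TASK_ORDER:
        for m in indicator_metrics(cohort, vlr, task):
            rows.append(
                {
                    "task": m.task.value,
                    "roi": m.roi.value,
                    "n_coactivated": m.n_coactivated,
                    "n_vlr_sessions": m.n_vlr_sessions,
                    "rate_among_vlr_sessions": m.rate_among_vlr_sessions,
                    "n_activated": m.n_activated,
                    "n_successful_sessions": m.n_successful_sessions,
                    "rate_among_successful_sessions": m.rate_among_successful_sessions,
                }
            )
    return pd.DataFrame(rows)
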