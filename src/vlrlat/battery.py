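"""Task-subset simulation and greedy recommendation of a measurement order.

For each of the 15 non-empty task subsets the cohort is reclassified using
only sessions of the subset's tasks, and every patient's outcome is compared
with the full-battery reference classification. Correctness is judged on
dominance *groups* — {left}, {right}, {bilateral spectrum} — so a shift
within the bilateral spectrum (e.g. B to BL_L) is not an error; because VLR
counting is monotone in the session set, a lateralized reference patient can
never flip to the opposite lateralized group, so misclassification can only
arise from bilateral-group patients yielding lateralized subset results.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .laterality import classify_cohort, classify_sessions
from .model import AnalysisConfig, Cohort, Dominance, TASK_ORDER, Task, VlrSet

#: Outcome labels per patient per subset.
CORRECT = "correct"
INCORRECT = "incorrect"
UNCLASSIFIABLE = "unclassifiable"


def dominance_group(category: Dominance) -> str | None:
    """Collapse the five-way category to {L}, {R}, {bilateral spectrum}."""
    if category is Dominance.L:
        return "L"
    if category is Dominance.R:
        return "R"
    if category in (Dominance.BL_L, Dominance.B, Dominance.BL_R):
        return "BIL"
    return None  # NC


def all_subsets() -> list[frozenset[Task]]:
    """The 15 non-empty task subsets, ordered by size then canonical order."""
    out: list[frozenset[Task]] = []
    for k in range(1, 5):
        for combo in combinations(TASK_ORDER, k):
            out.append(frozenset(combo))
    return out


def subset_label(subset: frozenset[Task]) -> str:
    return "+".join(t.value for t in TASK_ORDER if t in subset)


def _subset_sort_key(subset: frozenset[Task]) -> tuple:
    return (len(subset), tuple(TASK_ORDER.index(t) for t in TASK_ORDER if t in subset))


@dataclass(frozen=True)
class SubsetResult:
    subset: frozenset[Task]
    n_correct: int
    n_incorrect: int
    n_unclassifiable: int
    outcomes: Mapping[str, str]  # patient_id -> outcome label

    def __post_init__(self) -> None:
        object.__setattr__(self, "subset", frozenset(self.subset))
        object.__setattr__(self, "outcomes", dict(self.outcomes))

    @property
    def label(self) -> str:
        return subset_label(self.subset)


def simulate_task_subsets(
    cohort: Cohort, vlr: VlrSet, config: AnalysisConfig | None = None
) -> list[SubsetResult]:
    """Reclassify every reference-classified patient under all 15 subsets.

    The reference classification uses all sessions with the supplied VLR
    set; patients not classifiable on the full battery are excluded. The
    minimum-activation cutoff applies to subsets exactly as to full exams.
    """
    config = config or AnalysisConfig()
    reference = classify_cohort(cohort, vlr, config)
    ref_groups = {
        pid: dominance_group(res.category)
        for pid, res in reference.items()
        if res.category is not Dominance.NC
    }
    by_patient: dict[str, list] = {pid: [] for pid in ref_groups}
    for rec in cohort:
        if rec.patient_id in by_patient:
            by_patient[rec.patient_id].append(rec)

    results: list[SubsetResult] = []
    for subset in all_subsets():
        outcomes: dict[str, str] = {}
        for pid in sorted(ref_groups):
            sessions = [r for r in by_patient[pid] if r.task in subset]
            res = classify_sessions(sessions, vlr, config)
            group = dominance_group(res.category)
            if group is None:
                outcomes[pid] = UNCLASSIFIABLE
            elif group == ref_groups[pid]:
                outcomes[pid] = CORRECT
            else:
                outcomes[pid] = INCORRECT
        results.append(
            SubsetResult(
                subset,
                n_correct=sum(v == CORRECT for v in outcomes.values()),
                n_incorrect=sum(v == INCORRECT for v in outcomes.values()),
                n_unclassifiable=sum(v == UNCLASSIFIABLE for v in outcomes.values()),
                outcomes=outcomes,
            )
        )
    return results


def subsets_frame(results: Iterable[SubsetResult]) -> pd.DataFrame:
    rows = [
        {
            "subset": r.label,
            "n_tasks": len(r.subset),
            "n_correct": r.n_correct,
            "n_incorrect": r.n_incorrect,
            "n_unclassifiable": r.n_unclassifiable,
        }
        for r in sorted(results, key=lambda r: _subset_sort_key(r.subset))
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OrderRecommendation:
    """A nested chain of task prefixes, each justified by its SubsetResult."""

    order: tuple[Task, ...]
    prefix_results: tuple[SubsetResult, ...]
    tie_break_log: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "order": [t.value for t in self.order],
            "prefixes": [
                {
                    "subset": r.label,
                    "n_correct": r.n_correct,
                    "n_incorrect": r.n_incorrect,
                    "n_unclassifiable": r.n_unclassifiable,
                }
                for r in self.prefix_results
            ],
            "tie_break_log": list(self.tie_break_log),
        }


def recommend_task_order(results: Iterable[SubsetResult]) -> OrderRecommendation:
    """Greedy nested-chain ordering over the 15 subset results.

    Prefix 1 is the best singleton; prefix k the best k-subset containing
    prefix k-1. "Best" maximises correct classifications, breaking ties by
    fewest incorrect, then by the canonical task order. Every comparison is
    recorded in the tie-break log.
    """
    by_subset = {r.subset: r for r in results}
    expected = set(all_subsets())
    missing = expected - set(by_subset)
    if missing:
        raise ValueError(
            "incomplete subset results; missing: "
            + ", ".join(sorted(subset_label(s) for s in missing))
        )

    chain: frozenset[Task] = frozenset()
    order: list[Task] = []
    prefix_results: list[SubsetResult] = []
    log: list[str] = []
    for k in range(1, 5):
        candidates = sorted(
            (s for s in expected if len(s) == k and chain <= s),
            key=_subset_sort_key,
        )
        scored = [
            (-(by_subset[s].n_correct), by_subset[s].n_incorrect, _subset_sort_key(s), s)
            for s in candidates
        ]
        scored.sort()
        for neg_c, inc, _, s in scored:
            log.append(
                f"k={k}: {subset_label(s)} correct={-neg_c} incorrect={inc}"
            )
        best = scored[0][3]
        added = next(t for t in TASK_ORDER if t in best - chain)
        log.append(f"k={k}: selected {subset_label(best)} (adds {added.value})")
        order.append(added)
        prefix_results.append(by_subset[best])
        chain = best
    return OrderRecommendation(tuple(order), tuple(prefix_results), tuple(log))
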