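"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
dominance mixture over the five categories, 1-4 tasks per exam, repeated
sessions per task, dominance-dependent activation of a planted set of
validly lateralizing cells, bilaterally activating indicator-like cells,
a session-failure rate, and optional discordance noise (wrong-side
activation in lateralized patients).

A single root seed is streamed into per-patient substreams so that
increasing ``n_patients`` never reshuffles earlier patients.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .concordance import run_vlr_expansion
from .laterality import classify_cohort
from .model import (
    Activation,
    AnalysisConfig,
    CONCORDANCE_DOMINANCES,
    Cohort,
    Dominance,
    INDICATOR_CELLS,
    ROI_ORDER,
    Roi,
    SessionRecord,
    TASK_ORDER,
    Task,
    VLR_NEW,
    ValidationError,
    VlrSet,
)

#: Dominance mixture mirroring the classified share of the study cohort
#: (47 left, 18 bilateral-left, 16 bilateral, 0 bilateral-right, 6 right
#: of 87 classifiable patients).
DEFAULT_MIXTURE: dict[Dominance, float] = {
    Dominance.L: 0.54,
    Dominance.BL_L: 0.21,
    Dominance.B: 0.18,
    Dominance.BL_R: 0.00,
    Dominance.R: 0.07,
}

#: Tasks measured per exam; most exams cover three or four tasks.
DEFAULT_TASKS_PER_EXAM: dict[int, float] = {1: 0.10, 2: 0.20, 3: 0.25, 4: 0.45}

#: Sessions per measured task; mean ~2.2 so exams average ~6.6 sessions,
#: matching a 748-session / 114-exam workload.
DEFAULT_SESSIONS_PER_TASK: dict[int, float] = {1: 0.25, 2: 0.40, 3: 0.25, 4: 0.10}


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"{name} must be in [0, 1], got {p}")


def _check_dist(name: str, dist: Mapping, support=None) -> None:
    total = float(sum(dist.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"{name} probabilities must sum to 1, got {total}")
    for k, v in dist.items():
        _check_prob(f"{name}[{k}]", v)
        if support is not None and k not in support:
            raise ValidationError(f"{name} has unsupported key {k!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    All probabilities are per-session, per-cell Bernoulli rates. The
    ``planted_vlr`` set defines which cells lateralize; its activations are
    drawn on the anatomical side implied by dominance (contralateral for the
    crossed cerebellum). ``session_failure_probability`` defaults to the
    study-wide 156/748 unsuccessful-session rate.
    """

    n_patients: int = 100
    seed: int = 0
    dominance_mixture: Mapping[Dominance, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    tasks_per_exam: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TASKS_PER_EXAM)
    )
    sessions_per_task: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SESSIONS_PER_TASK)
    )
    planted_vlr: VlrSet = VLR_NEW
    vlr_activation_probability: float = 0.6
    indicator_probability: float = 0.85
    background_probability: float = 0.0
    #: probability that a lateralized patient's VLR activation lands on the
    #: wrong side (discordance noise); the study's valid cells show none.
    discordance_noise: float = 0.0
    #: probability that a lateralized patient's VLR activation is bilateral.
    bilateral_side_probability: float = 0.0
    session_failure_probability: float = 0.21
    #: side distribution (dominant, minor, bilateral) for BL_L / BL_R
    #: patients; expected LI ~ 0.58, inside the [0.5, 1) band.
    mixed_side_probabilities: tuple[float, float, float] = (0.75, 0.05, 0.20)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be non-negative")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        _check_dist("dominance_mixture", self.dominance_mixture, set(Dominance) - {Dominance.NC})
        _check_dist("tasks_per_exam", self.tasks_per_exam, {1, 2, 3, 4})
        _check_dist("sessions_per_task", self.sessions_per_task, set(range(1, 12)))
        for name in (
            "vlr_activation_probability",
            "indicator_probability",
            "background_probability",
            "discordance_noise",
            "bilateral_side_probability",
            "session_failure_probability",
        ):
            _check_prob(name, getattr(self, name))
        if abs(sum(self.mixed_side_probabilities) - 1.0) > 1e-9:
            raise ValidationError("mixed_side_probabilities must sum to 1")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth emitted alongside a synthetic cohort."""

    dominance: Mapping[str, Dominance]
    forced_failures: frozenset[tuple[str, str, Task, int]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dominance", dict(self.dominance))
        object.__setattr__(self, "forced_failures", frozenset(self.forced_failures))


def _choice(rng: np.random.Generator, dist: Mapping) -> object:
    keys = list(dist.keys())
    probs = np.asarray([float(dist[k]) for k in keys])
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _draw_functional_side(rng: np.random.Generator, dominance: Dominance, cfg: GeneratorConfig) -> Activation:
    """Side of one activation in *functional* (language) terms; the caller
    flips it for the crossed cerebellum."""
    u = rng.random()
    if dominance is Dominance.B:
        return (Activation.LEFT, Activation.RIGHT, Activation.BILATERAL)[
            int(rng.integers(3))
        ]
    if dominance in (Dominance.BL_L, Dominance.BL_R):
        p_dom, p_min, _ = cfg.mixed_side_probabilities
        major = Activation.LEFT if dominance is Dominance.BL_L else Activation.RIGHT
        if u < p_dom:
            return major
        if u < p_dom + p_min:
            return major.flipped()
        return Activation.BILATERAL
    # pure L / R
    major = Activation.LEFT if dominance is Dominance.L else Activation.RIGHT
    if u < cfg.discordance_noise:
        return major.flipped()
    if u < cfg.discordance_noise + cfg.bilateral_side_probability:
        return Activation.BILATERAL
    return major


def _emit_side(functional: Activation, roi: Roi) -> Activation:
    """Anatomical rating: the crossed cerebellum activates contralaterally."""
    return functional.flipped() if roi.crossed else functional


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _generate_patient(
    cfg: GeneratorConfig, index: int
) -> tuple[list[SessionRecord], Dominance, list[tuple[str, str, Task, int]]]:
    rng = _patient_rng(cfg.seed, index)
    pid = f"P{index:04d}"
    exam = "E1"
    dominance = _choice(rng, cfg.dominance_mixture)
    n_tasks = int(_choice(rng, cfg.tasks_per_exam))
    task_idx = sorted(rng.choice(4, size=n_tasks, replace=False).tolist())
    tasks = [TASK_ORDER[i] for i in task_idx]
    records: list[SessionRecord] = []
    failures: list[tuple[str, str, Task, int]] = []
    for task in tasks:
        n_sessions = int(_choice(rng, cfg.sessions_per_task))
        for s in range(1, n_sessions + 1):
            failed = rng.random() < cfg.session_failure_probability
            activations: dict[Roi, Activation] = {}
            for roi in ROI_ORDER:
                cell = (task, roi)
                act = Activation.NONE
                if not failed:
                    if cell in cfg.planted_vlr:
                        if rng.random() < cfg.vlr_activation_probability:
                            act = _emit_side(
                                _draw_functional_side(rng, dominance, cfg), roi
                            )
                    elif cell in INDICATOR_CELLS:
                        if rng.random() < cfg.indicator_probability:
                            act = Activation.BILATERAL
                    elif cfg.background_probability > 0:
                        if rng.random() < cfg.background_probability:
                            act = Activation.BILATERAL
                activations[roi] = act
            if failed:
                failures.append((pid, exam, task, s))
            records.append(SessionRecord(pid, exam, task, s, activations))
    return records, dominance, failures


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a reproducible synthetic cohort and its ground truth."""
    all_records: list[SessionRecord] = []
    dominance: dict[str, Dominance] = {}
    failures: list[tuple[str, str, Task, int]] = []
    for i in range(config.n_patients):
        recs, dom, fails = _generate_patient(config, i)
        all_records.extend(recs)
        dominance[f"P{i:04d}"] = dom
        failures.extend(fails)
    cohort = Cohort(
        tuple(all_records),
        {"generator": "vlrlat.synthetic", "seed": config.seed, "n_patients": config.n_patients},
    )
    return cohort, GroundTruth(dominance, frozenset(failures))


def config_to_dict(cfg: GeneratorConfig) -> dict:
    """Serialize a GeneratorConfig to plain YAML/JSON-ready types."""
    return {
        "n_patients": cfg.n_patients,
        "seed": cfg.seed,
        "dominance_mixture": {d.value: float(p) for d, p in cfg.dominance_mixture.items()},
        "tasks_per_exam": {int(k): float(v) for k, v in cfg.tasks_per_exam.items()},
        "sessions_per_task": {int(k): float(v) for k, v in cfg.sessions_per_task.items()},
        "planted_vlr": {
            "name": cfg.planted_vlr.name,
            "members": [f"{t.value}:{r.value}" for t, r in cfg.planted_vlr.sorted_members()],
        },
        "vlr_activation_probability": cfg.vlr_activation_probability,
        "indicator_probability": cfg.indicator_probability,
        "background_probability": cfg.background_probability,
        "discordance_noise": cfg.discordance_noise,
        "bilateral_side_probability": cfg.bilateral_side_probability,
        "session_failure_probability": cfg.session_failure_probability,
        "mixed_side_probabilities": list(cfg.mixed_side_probabilities),
    }


def config_from_dict(data: Mapping) -> GeneratorConfig:
    """Inverse of :func:`config_to_dict`; omitted keys take defaults."""
    from .io import parse_vlr_member  # local import to avoid a cycle

    kw: dict = dict(data)
    if "dominance_mixture" in kw:
        kw["dominance_mixture"] = {
            Dominance(k): float(v) for k, v in kw["dominance_mixture"].items()
        }
    for field_name in ("tasks_per_exam", "sessions_per_task"):
        if field_name in kw:
            kw[field_name] = {int(k): float(v) for k, v in kw[field_name].items()}
    if "planted_vlr" in kw:
        spec = kw["planted_vlr"]
        kw["planted_vlr"] = VlrSet(
            str(spec.get("name", "planted")),
            frozenset(parse_vlr_member(m) for m in spec["members"]),
        )
    if "mixed_side_probabilities" in kw:
        kw["mixed_side_probabilities"] = tuple(float(x) for x in kw["mixed_side_probabilities"])
    return GeneratorConfig(**kw)


def _concordant_side(dominance: Dominance, roi: Roi) -> Activation:
    """An anatomical side guaranteed concordant with ``dominance``."""
    if dominance is Dominance.B:
        return Activation.LEFT  # any side is concordant for bilateral patients
    functional = Activation.LEFT if dominance is Dominance.L else Activation.RIGHT
    return _emit_side(functional, roi)


def _blank_activations() -> dict[Roi, Activation]:
    return {r: Activation.NONE for r in ROI_ORDER}


def plant_expansion_scenario(
    config: GeneratorConfig,
    extra_cells: frozenset[tuple[Task, Roi]] | set[tuple[Task, Roi]],
    k_newly_classifiable: int,
    analysis: AnalysisConfig | None = None,
    baseline: VlrSet | None = None,
) -> tuple[Cohort, GroundTruth]:
    """Construct a cohort in which expanding the baseline VLR set by
    ``extra_cells`` makes exactly ``k_newly_classifiable`` patients
    classifiable.

    The last ``k`` patients are replaced by deterministic records holding
    one activation short of the classification cutoff under the baseline
    set, plus two concordant activations in the first extra cell. Every
    planted cell is guaranteed to meet both discovery criteria: discordance
    noise is forced to zero and, where a cell falls short of the
    minimum-session criterion, concordant single-cell "booster" sessions
    are appended to classified patients.
    """
    analysis = analysis or AnalysisConfig()
    baseline = baseline or analysis.resolve_vlr_set()
    extra = frozenset(extra_cells)
    if not extra:
        raise ValidationError("extra_cells must be non-empty")
    if extra & baseline.members:
        raise ValidationError("extra_cells must be disjoint from the baseline set")
    k = int(k_newly_classifiable)
    if k < 0 or k > config.n_patients:
        raise ValidationError(
            f"k_newly_classifiable={k} infeasible for n_patients={config.n_patients}"
        )

    planted = baseline.union(extra, name=f"{baseline.name}+planted")
    gen_cfg = config.replace(
        planted_vlr=planted,
        discordance_noise=0.0,
        bilateral_side_probability=0.0,
        background_probability=0.0,
    )
    cohort, truth = generate_cohort(gen_cfg)
    dominance = dict(truth.dominance)

    designated = [f"P{i:04d}" for i in range(config.n_patients - k, config.n_patients)]
    records = [r for r in cohort if r.patient_id not in set(designated)]

    # Deterministic near-threshold patients: m = cutoff-1 baseline activations
    # (one per session of the first baseline cell's task) plus two activations
    # of the first extra cell, all concordant-left.
    tb, rb = baseline.sorted_members()[0]
    te, re = sorted(extra, key=lambda c: (TASK_ORDER.index(c[0]), ROI_ORDER.index(c[1])))[0]
    m = analysis.min_vlr_activations - 1
    for pid in designated:
        dominance[pid] = Dominance.L
        idx = {t: 0 for t in TASK_ORDER}
        for _ in range(m):
            idx[tb] += 1
            acts = _blank_activations()
            acts[rb] = _concordant_side(Dominance.L, rb)
            records.append(SessionRecord(pid, "E1", tb, idx[tb], acts))
        for _ in range(2):
            idx[te] += 1
            acts = _blank_activations()
            acts[re] = _concordant_side(Dominance.L, re)
            records.append(SessionRecord(pid, "E1", te, idx[te], acts))

    cohort = Cohort(tuple(records), dict(cohort.provenance))

    # Non-designated patients below the baseline cutoff must stay below it
    # under any discoverable superset: strip every activation outside the
    # baseline cells. Patients classified L or R can carry a wrong-side
    # draw in a non-baseline planted cell (a mixed-dominance truth hiding
    # behind an all-left baseline draw), which would block discovery of
    # that cell; rewrite such activations to the concordant side.
    old = classify_cohort(cohort, baseline, analysis)
    fixed: list[SessionRecord] = []
    for rec in cohort:
        pid = rec.patient_id
        cat = old[pid].category
        acts = dict(rec.activations)
        touched = False
        if pid not in set(designated) and cat is Dominance.NC:
            for roi in ROI_ORDER:
                if (rec.task, roi) not in baseline.members and acts[roi] is not Activation.NONE:
                    acts[roi] = Activation.NONE
                    touched = True
        elif cat in (Dominance.L, Dominance.R):
            for (t, r) in extra:
                if t is rec.task and acts[r] is not Activation.NONE:
                    good = _concordant_side(cat, r)
                    if acts[r] is not good:
                        acts[r] = good
                        touched = True
        if touched:
            fixed.append(SessionRecord(pid, rec.exam_id, rec.task, rec.session_index, acts))
        else:
            fixed.append(rec)
    cohort = Cohort(tuple(fixed), dict(cohort.provenance))

    # Boost every planted cell to the minimum-session criterion using
    # concordant single-cell sessions on baseline-classified patients.
    old = classify_cohort(cohort, baseline, analysis)
    # Anchor boosters on lateralized patients only: a concordant activation
    # leaves LI pinned at +-1, so their classification cannot drift.
    eligible = [
        pid
        for pid in sorted(old)
        if old[pid].category in (Dominance.L, Dominance.R)
        and pid not in set(designated)
    ]
    if not eligible:
        raise ValidationError(
            "infeasible scenario: no classified patients available to anchor "
            "the planted cells; increase n_patients"
        )
    counts = {cell: 0 for cell in planted.members}
    for rec in cohort:
        if old[rec.patient_id].category in CONCORDANCE_DOMINANCES:
            for (t, r) in planted.members:
                if t is rec.task and rec.activations[r] is not Activation.NONE:
                    counts[(t, r)] += 1
    boosters: list[SessionRecord] = []
    next_index: dict[tuple[str, Task], int] = {}
    for rec in cohort:
        key = (rec.patient_id, rec.task)
        next_index[key] = max(next_index.get(key, 0), rec.session_index)
    cursor = 0
    for cell in sorted(planted.members, key=lambda c: (TASK_ORDER.index(c[0]), ROI_ORDER.index(c[1]))):
        t, r = cell
        while counts[cell] < analysis.min_vlr_sessions:
            pid = eligible[cursor % len(eligible)]
            cursor += 1
            key = (pid, t)
            next_index[key] = next_index.get(key, 0) + 1
            acts = _blank_activations()
            acts[r] = _concordant_side(old[pid].category, r)
            boosters.append(SessionRecord(pid, "E1", t, next_index[key], acts))
            counts[cell] += 1
    if boosters:
        cohort = Cohort(tuple(cohort.records) + tuple(boosters), dict(cohort.provenance))

    truth = GroundTruth(dominance, truth.forced_failures)

    # Post-condition check: the expansion pipeline must report exactly k
    # newly classifiable patients and recover every planted cell.
    report = run_vlr_expansion(cohort, baseline, analysis)
    if set(report.newly_classifiable) != set(designated):
        raise RuntimeError(
            "planted expansion scenario failed its post-condition: newly "
            f"classifiable {report.newly_classifiable} != designated {designated}"
        )
    if not planted.members <= report.discovery.vlr.members:
        missing = planted.members - report.discovery.vlr.members
        raise RuntimeError(
            f"planted cells not recovered by discovery: {sorted(missing)}"
        )
    return cohort, truth
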