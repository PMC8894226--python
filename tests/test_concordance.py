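"""Concordance labelling, table tallies, VLR discovery and indicators."""

import pytest
from hypothesis import given, strategies as st

from vlrlat import (
    ALL_CELLS,
    Activation,
    AnalysisConfig,
    ConcordanceLabel,
    Dominance,
    GeneratorConfig,
    Roi,
    Task,
    VLR_EXPANSION_CELLS,
    VLR_NEW,
    VLR_OLD,
    build_concordance_table,
    classify_concordance,
    discover_vlr,
    generate_cohort,
    indicator_metrics,
    run_vlr_expansion,
)
from vlrlat.concordance import CellTally, ConcordanceTable
from vlrlat.model import Cohort

from conftest import make_record, mirror_cohort, random_cohort


class TestClassifyConcordance:
    @pytest.mark.parametrize(
        "act, roi, dom, label",
        [
            (Activation.BILATERAL, Roi.IFG, Dominance.L, ConcordanceLabel.DISCORDANT),
            (Activation.BILATERAL, Roi.IFG, Dominance.R, ConcordanceLabel.DISCORDANT),
            (Activation.LEFT, Roi.IFG, Dominance.L, ConcordanceLabel.CONCORDANT),
            (Activation.RIGHT, Roi.IFG, Dominance.L, ConcordanceLabel.DISCORDANT),
            (Activation.LEFT, Roi.IFG, Dominance.B, ConcordanceLabel.CONCORDANT),
            (Activation.RIGHT, Roi.IFG, Dominance.B, ConcordanceLabel.CONCORDANT),
            (Activation.BILATERAL, Roi.IFG, Dominance.B, ConcordanceLabel.CONCORDANT),
            # crossed cerebellum: right activation indicates left dominance
            (Activation.RIGHT, Roi.CBM, Dominance.L, ConcordanceLabel.CONCORDANT),
            (Activation.LEFT, Roi.CBM, Dominance.L, ConcordanceLabel.DISCORDANT),
            (Activation.LEFT, Roi.CBM, Dominance.R, ConcordanceLabel.CONCORDANT),
            (Activation.BILATERAL, Roi.CBM, Dominance.L, ConcordanceLabel.DISCORDANT),
            (Activation.NONE, Roi.IFG, Dominance.L, ConcordanceLabel.NOT_APPLICABLE),
            (Activation.LEFT, Roi.IFG, Dominance.BL_L, ConcordanceLabel.NOT_APPLICABLE),
            (Activation.LEFT, Roi.IFG, Dominance.NC, ConcordanceLabel.NOT_APPLICABLE),
        ],
    )
    def test_rule_table(self, act, roi, dom, label):
        assert classify_concordance(act, roi, dom) is label

    @given(
        act=st.sampled_from([Activation.LEFT, Activation.RIGHT, Activation.BILATERAL]),
        roi=st.sampled_from(list(Roi)),
    )
    def test_bilateral_dominance_never_discordant(self, act, roi):
        assert classify_concordance(act, roi, Dominance.B) is ConcordanceLabel.CONCORDANT

    @given(
        act=st.sampled_from(list(Activation)),
        roi=st.sampled_from(list(Roi)),
        dom=st.sampled_from([Dominance.L, Dominance.R, Dominance.B]),
    )
    def test_mirror_invariance(self, act, roi, dom):
        assert classify_concordance(act, roi, dom) is classify_concordance(
            act.flipped(), roi, dom.mirrored()
        )


def naive_table(cohort, dom_map):
    """Independent per-activation recount of the concordance tallies."""
    conc = {cell: 0 for cell in ALL_CELLS}
    disc = {cell: 0 for cell in ALL_CELLS}
    denom = {t: 0 for t in Task}
    for rec in cohort:
        dom = dom_map[rec.patient_id]
        if dom not in (Dominance.L, Dominance.R, Dominance.B):
            continue
        if any(a != Activation.NONE for a in rec.activations.values()):
            denom[rec.task] += 1
        for roi, act in rec.activations.items():
            if act == Activation.NONE:
                continue
            if dom == Dominance.B:
                conc[(rec.task, roi)] += 1
                continue
            side = act
            if roi == Roi.CBM and side != Activation.BILATERAL:
                side = side.flipped()
            good = Activation.LEFT if dom == Dominance.L else Activation.RIGHT
            if side == good:
                conc[(rec.task, roi)] += 1
            else:
                disc[(rec.task, roi)] += 1
    return conc, disc, denom


class TestConcordanceTable:
    def test_empty_cohort_all_zero(self):
        table = build_concordance_table(Cohort(()), {})
        assert table.n_concordant == 0 and table.n_discordant == 0
        assert all(v == 0 for v in table.task_denominators.values())

    def test_direct_rule_application(self):
        cohort = Cohort((make_record("P1", task=Task.BST, IFG="L", A1="B"),))
        table = build_concordance_table(cohort, {"P1": Dominance.L})
        assert table.cells[(Task.BST, Roi.IFG)].concordant == 1
        assert table.cells[(Task.BST, Roi.A1)].discordant == 1
        assert table.task_denominators[Task.BST] == 1

    def test_excludes_mixed_dominance_patients(self):
        cohort = Cohort((make_record("P1", task=Task.VIT, IFG="L"),))
        table = build_concordance_table(cohort, {"P1": Dominance.BL_L})
        assert table.n_concordant == 0 and table.n_patients == 0

    def test_unknown_patient_errors(self):
        cohort = Cohort((make_record("P1", IFG="L"),))
        with pytest.raises(KeyError):
            build_concordance_table(cohort, {})

    @given(seed=st.integers(0, 5_000))
    def test_matches_naive_per_activation_loop(self, seed):
        cohort = random_cohort(seed=seed, n_patients=6)
        doms = [Dominance.L, Dominance.R, Dominance.B, Dominance.BL_L, Dominance.NC]
        dom_map = {pid: doms[i % len(doms)] for i, pid in enumerate(cohort.patient_ids())}
        table = build_concordance_table(cohort, dom_map)
        conc, disc, denom = naive_table(cohort, dom_map)
        for cell in ALL_CELLS:
            assert table.cells[cell].concordant == conc[cell]
            assert table.cells[cell].discordant == disc[cell]
            assert (
                table.cells[cell].n_activated_sessions == conc[cell] + disc[cell]
            )
        for t in Task:
            assert table.task_denominators[t] == denom[t]

    @given(seed=st.integers(0, 5_000))
    def test_tallies_mirror_invariant(self, seed):
        cohort = random_cohort(seed=seed, n_patients=5)
        dom_map = {
            pid: [Dominance.L, Dominance.R, Dominance.B][i % 3]
            for i, pid in enumerate(cohort.patient_ids())
        }
        mirrored_map = {pid: d.mirrored() for pid, d in dom_map.items()}
        fwd = build_concordance_table(cohort, dom_map)
        rev = build_concordance_table(mirror_cohort(cohort), mirrored_map)
        for cell in ALL_CELLS:
            assert fwd.cells[cell].concordant == rev.cells[cell].concordant
            assert fwd.cells[cell].discordant == rev.cells[cell].discordant


def _table_with(cells: dict) -> ConcordanceTable:
    full = {cell: CellTally() for cell in ALL_CELLS}
    for cell, (conc, disc) in cells.items():
        full[cell] = CellTally(conc, disc, conc + disc, {})
    return ConcordanceTable(full, {t: 0 for t in Task}, 0)


class TestDiscoverVlr:
    def test_one_discordant_activation_excludes(self):
        table = _table_with({(Task.VIT, Roi.TLA): (12, 1)})
        result = discover_vlr(table)
        assert (Task.VIT, Roi.TLA) not in result.vlr
        audit = {(a.task, a.roi): a for a in result.audit}[(Task.VIT, Roi.TLA)]
        assert not audit.criterion1_pass and audit.criterion2_pass

    def test_nine_sessions_fails_threshold(self):
        table = _table_with({(Task.VIT, Roi.TLA): (9, 0)})
        result = discover_vlr(table)
        audit = {(a.task, a.roi): a for a in result.audit}[(Task.VIT, Roi.TLA)]
        assert audit.criterion1_pass and not audit.criterion2_pass
        assert (Task.VIT, Roi.TLA) not in result.vlr

    def test_both_criteria_admit(self):
        table = _table_with({(Task.VIT, Roi.TLA): (10, 0)})
        assert (Task.VIT, Roi.TLA) in discover_vlr(table).vlr

    def test_audit_covers_all_forty_cells(self):
        result = discover_vlr(_table_with({}))
        assert len(result.audit) == 40

    @given(threshold=st.integers(1, 30), seed=st.integers(0, 2_000))
    def test_monotone_in_session_threshold(self, threshold, seed):
        cohort = random_cohort(seed=seed, n_patients=6)
        dom_map = {
            pid: [Dominance.L, Dominance.B, Dominance.R][i % 3]
            for i, pid in enumerate(cohort.patient_ids())
        }
        table = build_concordance_table(cohort, dom_map)
        lo = discover_vlr(table, AnalysisConfig(min_vlr_sessions=threshold))
        hi = discover_vlr(table, AnalysisConfig(min_vlr_sessions=threshold + 1))
        assert hi.vlr.members <= lo.vlr.members

    def test_planted_set_recovered_exactly_on_noise_free_cohort(self):
        cfg = GeneratorConfig(n_patients=80, seed=42, discordance_noise=0.0)
        cohort, truth = generate_cohort(cfg)
        report = run_vlr_expansion(cohort, VLR_OLD)
        assert report.discovery.vlr.members == VLR_NEW.members
        for cell in VLR_NEW.members:
            assert report.table.cells[cell].discordant == 0


class TestExpansion:
    def test_fixed_point_when_discovered_equals_baseline(self):
        cfg = GeneratorConfig(n_patients=60, seed=5, planted_vlr=VLR_OLD)
        cohort, _ = generate_cohort(cfg)
        report = run_vlr_expansion(cohort, VLR_OLD)
        assert report.discovery.vlr.members == VLR_OLD.members
        for p in report.patients:
            assert p.cat_old is p.cat_new and p.n_old == p.n_new
            assert p.delta_li in (0, None)
        assert report.delta_li_summary()["n_changed"] == 0

    def test_patient_classifiable_only_under_expanded_set(self):
        """Two baseline activations plus two in a newly valid cell cross
        the cutoff only once the discovered set includes that cell."""
        records = [
            make_record("PX", task=Task.VIT, session_index=1, FOP="L", TLA="L"),
            make_record("PX", task=Task.VIT, session_index=2, TLA="L"),
            make_record("PX", task=Task.WCT, session_index=1, FOP="L"),
        ]
        anchors = []
        for i in range(12):
            anchors.append(
                make_record(f"PA{i:02d}", task=Task.VIT, session_index=1,
                            FOP="L", IFG="L", MFG="L", TLA="L")
            )
        cohort = Cohort(tuple(records + anchors))
        report = run_vlr_expansion(cohort, VLR_OLD)
        assert (Task.VIT, Roi.TLA) in report.discovery.vlr
        assert report.newly_classifiable == ("PX",)

    def test_dominance_override_is_respected(self):
        cohort = Cohort((make_record("P1", task=Task.VIT, IFG="L"),))
        report = run_vlr_expansion(
            cohort, VLR_OLD, dominance_override={"P1": Dominance.R}
        )
        assert report.table.cells[(Task.VIT, Roi.IFG)].discordant == 1


def naive_indicator(cohort, vlr, task, roi):
    succ = [
        r for r in cohort
        if r.task == task and any(a != Activation.NONE for a in r.activations.values())
    ]
    vlr_sessions = [
        r for r in succ
        if any(r.activations[x] != Activation.NONE for x in vlr.rois_for(task))
    ]
    co = sum(r.activations[roi] != Activation.NONE for r in vlr_sessions)
    act = sum(r.activations[roi] != Activation.NONE for r in succ)
    return co, len(vlr_sessions), act, len(succ)


class TestIndicators:
    def test_saturated_coactivation_rate(self):
        records = [
            make_record(f"P{i}", task=Task.BST, IFG="L", A1="B") for i in range(5)
        ]
        cohort = Cohort(tuple(records))
        metrics = {m.roi: m for m in indicator_metrics(cohort, VLR_NEW, Task.BST)}
        assert metrics[Roi.A1].rate_among_vlr_sessions == 1.0
        assert metrics[Roi.A1].n_coactivated == 5

    def test_no_successful_sessions_yields_undefined_rates(self):
        cohort = Cohort((make_record("P1", task=Task.BST),))
        for m in indicator_metrics(cohort, VLR_NEW, Task.BST):
            assert m.rate_among_vlr_sessions is None
            assert m.rate_among_successful_sessions is None

    def test_vlr_members_excluded_from_metrics(self):
        cohort = Cohort((make_record("P1", task=Task.BST, IFG="L"),))
        rois = {m.roi for m in indicator_metrics(cohort, VLR_NEW, Task.BST)}
        assert rois == set(Roi) - VLR_NEW.rois_for(Task.BST)

    @given(seed=st.integers(0, 5_000))
    def test_matches_naive_recount(self, seed):
        cohort = random_cohort(seed=seed, n_patients=5)
        for task in (Task.BST, Task.WCT):
            for m in indicator_metrics(cohort, VLR_NEW, task):
                expected = naive_indicator(cohort, VLR_NEW, task, m.roi)
                assert (
                    m.n_coactivated,
                    m.n_vlr_sessions,
                    m.n_activated,
                    m.n_successful_sessions,
                ) == expected
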