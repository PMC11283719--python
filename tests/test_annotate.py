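"""Taxonomy voting, AMG stats, Fisher test, recruitment, core/flexible OGs."""

import numpy as np
import pytest
from scipy.stats import fisher_exact

from virobead import annotate as an
from virobead.clustering import ProteinCluster
from virobead.community import ParameterError


LIN = ("realm", "kingdom", "phylum", "class", "famX", "genX")


class TestVoteTaxonomy:
    def test_hit_fraction_gate_is_strict(self):
        call = an.vote_taxonomy("g", 10, [LIN] * 2)
        assert call.method == "none" and call.lineage == ()
        # 3/10 = 0.3 is still not > 0.3
        assert an.vote_taxonomy("g", 10, [LIN] * 3).method == "none"
        assert an.vote_taxonomy("g", 10, [LIN] * 4).method == "vote"

    def test_majority_per_rank_with_stop(self):
        fam_x = ("r", "k", "p", "c", "famX", "gen1")
        hits = [fam_x, fam_x, ("r", "k", "p", "c", "famX", "gen2"),
                ("r", "k", "p", "c", "famX", "gen3"),
                ("r", "k", "p", "c", "famY", "gen4"),
                ("r", "k", "p", "c", "famY", "gen5")]
        call = an.vote_taxonomy("g", 10, hits)
        # 4/6 famX > 0.5 assigns family; genus splits 2/1/1/... -> no majority
        assert call.lineage[-1] == "famX"
        assert call.support[-1] == pytest.approx(4 / 6)

    def test_unanimous_full_lineage(self):
        call = an.vote_taxonomy("g", 10, [LIN] * 9)
        assert call.lineage == LIN
        assert all(s == 1.0 for s in call.support)

    def test_agreeing_hit_never_truncates(self):
        # voting monotonicity: adding a hit matching the current consensus
        # cannot shorten the assigned lineage
        hits = [LIN] * 5 + [("realm", "kingdom", "phylum", "class", "famY", "genY")]
        before = an.vote_taxonomy("g", 10, hits)
        after = an.vote_taxonomy("g", 10, hits + [LIN])
        assert len(after.lineage) >= len(before.lineage)


class TestMarkerTaxonomy:
    def test_conflict_truncates_to_agreement(self):
        hits = [
            (("r", "k", "p", "ordA", "fam1"), 80.0, 1e-10),
            (("r", "k", "p", "ordA", "fam2"), 90.0, 1e-10),
        ]
        call = an.marker_taxonomy("g", hits)
        assert call.lineage == ("r", "k", "p", "ordA")

    def test_single_marker_full_lineage(self):
        call = an.marker_taxonomy("g", [(LIN, 50.0, 1e-9)])
        assert call.lineage == LIN and call.method == "marker"

    def test_score_minimum_inclusive(self):
        below = an.marker_taxonomy("g", [(LIN, 39.0, 1e-9)])
        at = an.marker_taxonomy("g", [(LIN, 40.0, 1e-9)])
        assert below.method == "none"
        assert at.method == "marker"


class TestIdentifyAMGs:
    def test_score_gate_and_truth_recovery(self):
        from types import SimpleNamespace
        from virobead.community import GeneAnnotation

        genes = [
            GeneAnnotation(f"g{i}", i * 100, i * 100 + 99 - (99 % 3) + 3 * 0, "+",
                           f"OG{i}", "AMG", "energy", score)
            for i, score in enumerate([1, 2, 3, 4, 5], start=1)
        ]
        genome = SimpleNamespace(genome_id="v1", genes=genes)
        records = an.identify_amgs([genome])
        assert len(records) == 3
        assert {r.aux_score for r in records} == {1, 2, 3}


class TestFisher:
    def test_degenerate_margin(self):
        res = an.fisher_exact_2x2([[0, 10], [0, 10]])
        assert res["p_value"] == 1.0 and res["degenerate"]

    def test_diagonal_table(self):
        res = an.fisher_exact_2x2([[5, 0], [0, 5]])
        assert res["p_value"] == pytest.approx(2 / 252, abs=1e-6)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            t = rng.integers(0, 15, size=4)
            table = [[int(t[0]), int(t[1])], [int(t[2]), int(t[3])]]
            if any(
                x == 0 for x in (t[0] + t[1], t[2] + t[3], t[0] + t[2], t[1] + t[3])
            ):
                continue
            mine = an.fisher_exact_2x2(table)["p_value"]
            _, ref = fisher_exact(table, alternative="two-sided")
            assert mine == pytest.approx(ref, abs=1e-9)

    def test_transpose_invariance(self):
        table = [[3, 7], [9, 2]]
        t_table = [[3, 9], [7, 2]]
        assert an.fisher_exact_2x2(table)["p_value"] == pytest.approx(
            an.fisher_exact_2x2(t_table)["p_value"], abs=1e-12
        )

    def test_amg_sharing_table_construction(self):
        pcs = (
            [ProteinCluster(f"PC{i}", [("a", "x")], is_amg_pc=True, n_vcs_touched=2) for i in range(5)]
            + [ProteinCluster(f"PCn{i}", [("a", "x")], is_amg_pc=False, n_vcs_touched=1) for i in range(5)]
        )
        res = an.amg_sharing_test(pcs)
        assert res["table"] == [[5, 0], [0, 5]]
        assert res["p_value"] == pytest.approx(2 / 252, abs=1e-6)
        assert res["multi_vc_pc_fraction"] == 0.5


class TestAbundanceAndRecruitment:
    def test_reads_per_base(self):
        assert an.reads_per_base(0, 1000) == 0.0
        assert an.reads_per_base(1000, 30_000) == pytest.approx(0.03333, abs=1e-5)
        assert an.reads_per_base(2000, 30_000) == 2 * an.reads_per_base(1000, 30_000)
        with pytest.raises(ParameterError):
            an.reads_per_base(10, 0)

    def test_clonal_reads_concentrate_at_100(self):
        ids = np.full(200, 100.0)
        curve = an.recruitment_curve(ids, np.full(200, 95.0), np.full(200, 1e-20))
        assert curve.n_reads == 200
        assert curve.identity[np.argmax(curve.percentage)] == pytest.approx(100.0)

    def test_query_coverage_strictly_over_80(self):
        ids = np.array([99.0, 98.0])
        curve = an.recruitment_curve(
            ids, np.array([80.0, 80.1]), np.array([1e-10, 1e-10])
        )
        assert curve.n_reads == 1

    def test_filters_are_monotone(self):
        rng = np.random.default_rng(9)
        ids = rng.uniform(55, 100, 500)
        qc = rng.uniform(70, 100, 500)
        ev = 10.0 ** rng.uniform(-30, -3, 500)
        base = an.recruitment_curve(ids, qc, ev).n_reads
        assert an.recruitment_curve(ids, qc, ev, id_min=70).n_reads <= base
        assert an.recruitment_curve(ids, qc, ev, qcov_min=90).n_reads <= base
        assert an.recruitment_curve(ids, qc, ev, evalue_max=1e-20).n_reads <= base

    def test_curve_integrates_to_100(self):
        rng = np.random.default_rng(10)
        ids = rng.normal(97, 1.5, 400).clip(50, 100)
        curve = an.recruitment_curve(ids, np.full(400, 99.0), np.full(400, 1e-10))
        area = np.trapezoid(curve.percentage, curve.identity)
        assert area == pytest.approx(100.0, rel=0.02)

    def test_microdiverse_population_is_wider(self):
        rng = np.random.default_rng(11)
        # micro-diverse: reads from two strain populations at 95-100% identity
        micro = np.concatenate(
            [rng.normal(95.5, 0.5, 300), rng.normal(99.5, 0.3, 300)]
        ).clip(50, 100)
        clonal = rng.normal(99.8, 0.1, 600).clip(50, 100)
        qcv = np.full(600, 95.0)
        ev = np.full(600, 1e-15)
        iqr_micro = an.curve_iqr(an.recruitment_curve(micro, qcv, ev))
        iqr_clonal = an.curve_iqr(an.recruitment_curve(clonal, qcv, ev))
        assert iqr_micro - iqr_clonal >= 3.0


class TestOGMatrix:
    def test_identical_members_all_core(self):
        genes = [("g1", "OG1"), ("g2", "OG2")]
        m = an.build_og_matrix({"a": genes, "b": genes})
        assert m.core == {"OG1", "OG2"} and not m.flexible

    def test_core_flexible_partition(self, strain_group):
        _, cassettes, strains = strain_group
        members = {
            s.genome_id: [(g.gene_id, g.og_label) for g in s.genes] for s in strains
        }
        m = an.build_og_matrix(members)
        assert m.core | m.flexible == set(m.og_ids)
        assert not (m.core & m.flexible)
        cassette_ogs = {c.og_label for c in cassettes}
        planted = cassette_ogs & set(m.og_ids)
        assert planted <= m.flexible
        backbone = set(m.og_ids) - cassette_ogs
        assert backbone <= m.core

    def test_removing_member_only_promotes_to_core(self):
        members = {
            "a": [("g1", "OG1"), ("g2", "OG2")],
            "b": [("g3", "OG1")],
            "c": [("g4", "OG1"), ("g5", "OG3")],
        }
        full = an.build_og_matrix(members)
        reduced = an.build_og_matrix({k: members[k] for k in ("a", "c")})
        for og in reduced.og_ids:
            if og in full.core:
                assert og in reduced.core

    def test_needs_two_members(self):
        with pytest.raises(ParameterError):
            an.build_og_matrix({"a": [("g", "OG1")]})


class TestDetectInsertions:
    def test_single_cassette_with_flanks(self):
        members = {
            "s1": [("a", "OG1"), ("m", "MT1"), ("b", "OG2"), ("c", "OG3")],
            "s2": [("a", "OG1"), ("b", "OG2"), ("c", "OG3")],
        }
        m = an.build_og_matrix(members)
        events = an.detect_insertions(members, m)
        assert len(events) == 1
        ev = events[0]
        assert ev.genome_id == "s1"
        assert ev.og_run == ("MT1",)
        assert (ev.left_flank, ev.right_flank) == ("OG1", "OG2")
        assert not ev.partial_flank

    def test_no_cassettes_no_events(self):
        members = {"s1": [("a", "OG1")], "s2": [("b", "OG1")]}
        m = an.build_og_matrix(members)
        assert an.detect_insertions(members, m) == []

    def test_planted_cassettes_recovered_with_flanks(self, strain_group):
        parent, cassettes, strains = strain_group
        members = {
            s.genome_id: [(g.gene_id, g.og_label) for g in s.genes] for s in strains
        }
        m = an.build_og_matrix(members)
        events = an.detect_insertions(members, m)
        order = [g.og_label for g in sorted(parent.genes, key=lambda g: g.start)]
        cassette_ogs = {c.og_label for c in cassettes}
        n_planted = n_correct = 0
        for s in strains:
            genes = sorted(s.genes, key=lambda g: g.start)
            for i, g in enumerate(genes):
                if g.og_label in cassette_ogs:
                    n_planted += 1
                    left, right = genes[i - 1].og_label, genes[i + 1].og_label
                    if any(
                        e.genome_id == s.genome_id
                        and g.og_label in e.og_run
                        and e.left_flank == left
                        and e.right_flank == right
                        for e in events
                    ):
                        n_correct += 1
        assert n_planted > 0
        assert n_correct / n_planted >= 0.95
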