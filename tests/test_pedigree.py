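"""Duo/trio/FS calling, the conditional SD scan, grandparent tests,
direction inference and network export."""

import numpy as np
import pandas as pd
import pytest

import grapekin as gk
from grapekin.simulate import AV, GP, HS, UNREL


def _rep(truth, name, samples):
    s = truth.stand_in(name, samples)
    assert s is not None
    return s


class TestPoDuos:
    def test_recovers_exactly_the_true_po_set(self, chain):
        truth_po = chain.scenario.truth.po_pairs(among=chain.panel_parentage.samples)
        assert chain.found_po_pairs() == truth_po

    def test_k0_histogram_has_bimodal_gap(self, chain):
        truth_po = chain.scenario.truth.po_pairs(among=chain.panel_parentage.samples)
        po_k0, other_k0 = [], []
        for r in chain.ibd.itertuples():
            (po_k0 if frozenset((r.id1, r.id2)) in truth_po else other_k0).append(r.k0)
        assert max(po_k0) < 0.03 < min(other_k0)

    def test_po_duos_confirmed_by_low_duo_errors(self, chain):
        for e in chain.duos:
            assert e.duo_errors <= 5  # single digits at panel scale

    def test_zero_threshold_gives_no_edges(self, chain):
        duos, _ = gk.find_po_duos(
            chain.panel_parentage, k0_max=0.0, pruned_panel=chain.pruned
        )
        assert duos == []


class TestTrios:
    def test_recovers_exactly_the_true_trios(self, chain):
        assert chain.found_trios() == chain.scenario.truth.trios(
            among=chain.panel_parentage.samples
        )

    def test_accepted_trio_has_minimal_errors_for_its_offspring(self, chain):
        """No rejected trio of the same offspring has fewer errors."""
        by_off = {}
        for t in chain.trios_tested:
            by_off.setdefault(t.offspring, []).append(t)
        accepted = chain.found_trios()
        for t in chain.trios_accepted:
            for other in by_off[t.offspring]:
                key = (other.offspring, frozenset((other.parent1, other.parent2)))
                if key not in accepted:
                    assert other.mendelian_errors >= t.mendelian_errors

    def test_single_partner_individuals_not_tested(self, chain):
        partner_counts = {}
        for e in chain.duos:
            partner_counts[e.id1] = partner_counts.get(e.id1, 0) + 1
            partner_counts[e.id2] = partner_counts.get(e.id2, 0) + 1
        tested_offspring = {t.offspring for t in chain.trios_tested}
        for ind, n in partner_counts.items():
            if n < 2:
                assert ind not in tested_offspring


class TestFullSibs:
    def test_no_false_positives_at_conservative_threshold(self, chain):
        """k2 > 0.3 may miss true FS but must never flag non-FS."""
        truth_fs = chain.scenario.truth.fs_pairs(among=chain.panel_parentage.samples)
        edges = gk.find_fullsibs(chain.ibd, chain.duos, 0.3)
        assert {e.pair for e in edges} <= truth_fs

    def test_fs_separate_from_second_degree_by_k2(self, chain):
        """FS k2 concentrates near 0.25, second-degree k2 near 0."""
        truth = chain.scenario.truth
        samples = chain.panel_parentage.samples
        truth_fs = truth.fs_pairs(among=samples)
        fs_k2, sd_k2 = [], []
        for r in chain.ibd.itertuples():
            rel = truth.relationship(r.id1, r.id2)
            if frozenset((r.id1, r.id2)) in truth_fs:
                fs_k2.append(r.k2)
            elif rel in (HS, GP, AV):
                sd_k2.append(r.k2)
        assert min(fs_k2) > 0.15 > max(sd_k2)

    def test_detects_fs_at_simulation_calibrated_threshold(self, chain):
        truth_fs = chain.scenario.truth.fs_pairs(among=chain.panel_parentage.samples)
        edges = gk.find_fullsibs(chain.ibd, chain.duos, 0.15)
        assert {e.pair for e in edges} == truth_fs


class TestSDScan:
    def test_true_missing_parent_carries_every_obligate_allele(self, clean_scenario):
        """At eps = 0 the missing parent itself scores f_obs = 1."""
        panel = clean_scenario.clean_full  # includes the hidden parent
        res = gk.sd_scan(panel, ("F03", "HSA1"), ("F03", "HSA1"), ["MP1"])
        (r,) = res
        assert r.f_obs == 1.0 and r.accepted

    def test_half_sib_scores_half_excess(self, clean_scenario):
        panel = clean_scenario.clean_full
        (r,) = gk.sd_scan(panel, ("F03", "HSA1"), ("F03", "HSA1"), ["HSA2"])
        # inherits each obligate allele with prob 1/2; background fills the rest
        expected = 0.5 + 0.5 * r.f_exp
        assert r.f_obs == pytest.approx(expected, abs=0.05)
        assert r.accepted

    def test_unrelated_candidate_sits_at_carrier_background(self, clean_scenario):
        """Against the true frequencies, an unrelated candidate's carrier
        fraction matches the HWE expectation.  (Panel-estimated frequencies
        include the conditioning individuals and their lineage, inflating
        f_exp slightly — a conservative bias that only suppresses
        candidates.)"""
        panel = clean_scenario.clean_full
        for cand in ("F37", "F38", "F39", "F40"):
            (r,) = gk.sd_scan(
                panel, ("F03", "HSA1"), ("F03", "HSA1"), [cand],
                freqs=clean_scenario.freqs,
            )
            assert r.f_obs == pytest.approx(r.f_exp, abs=0.05)
            assert abs(r.z) < 4 and not r.accepted

    def test_direction_must_order_the_pair(self, clean_scenario):
        with pytest.raises(ValueError):
            gk.sd_scan(
                clean_scenario.clean_full, ("F03", "HSA1"), ("F03", "F04"), ["F40"]
            )

    def test_wrong_direction_of_true_duo_finds_fewer_candidates(self, recovery_runs):
        """Scanning a parent->child duo with the child as assumed parent
        yields systematically fewer accepted SD candidates, whenever the
        missing parent has genotyped relatives (asserted over all seeds)."""
        for run in recovery_runs:
            truth = run.scenario.truth
            samples = run.panel_parentage.samples
            for off_base, par_base in [("HSA1", "F03"), ("HSB1", "F33")]:
                off = _rep(truth, off_base, samples)
                par = _rep(truth, par_base, samples)
                fwd = run.sd_counts[(par, off)]
                rev = run.sd_counts[(off, par)]
                assert fwd >= 2 and rev < fwd


class TestGrandparents:
    def test_true_pair_is_exactly_compatible_without_error(self, clean_scenario):
        panel = clean_scenario.clean_full
        t = gk.test_grandparents(panel, ("F03", "HSA1"), ("F03", "HSA1"), "F01", "F02")
        assert t.incompatibilities == 0
        assert t.n_informative > 100

    def test_unrelated_pair_rate_matches_hwe_closed_form(self, clean_scenario):
        """Neither of two unrelated candidates carries the obligate allele
        at ~ E[q^4]-style rates over the informative markers."""
        panel = clean_scenario.clean_full
        freqs = clean_scenario.freqs
        pd_ = panel.dosages[panel.sample_index("F03")]
        od = panel.dosages[panel.sample_index("HSA1")]
        het = od == 1
        aa, bb = (pd_ == 0) & het, (pd_ == 2) & het
        p = np.where(aa, freqs, 1 - freqs)[aa | bb]  # obligate-allele frequency
        expect = float(((1 - p) ** 4).mean())
        t = gk.test_grandparents(panel, ("F03", "HSA1"), ("F03", "HSA1"), "F39", "F40")
        assert t.rate == pytest.approx(expect, abs=0.05)

    def test_half_true_pair_rate_is_intermediate(self, clean_scenario):
        panel = clean_scenario.clean_full
        true_unrel = gk.test_grandparents(
            panel, ("F03", "HSA1"), ("F03", "HSA1"), "F01", "F40"
        )
        unrel = gk.test_grandparents(
            panel, ("F03", "HSA1"), ("F03", "HSA1"), "F39", "F40"
        )
        assert 0 < true_unrel.rate < unrel.rate

    def test_true_pair_beats_permutation_background(self, chain):
        truth = chain.scenario.truth
        samples = chain.panel_parentage.samples
        off, g1, g2 = (_rep(truth, n, samples) for n in ("HSA1", "F01", "F02"))
        pair = ("F03", off)
        t = gk.test_grandparents(chain.panel_parentage, pair, pair, g1, g2)
        bg = gk.grandparent_background(
            chain.panel_parentage, pair, pair, n_permutations=100, rng=11,
            exclude={g1, g2},
        )
        assert t.rate < bg.min()


class TestDirectionInference:
    def test_trio_rule_directs_both_parental_edges(self, chain):
        directed = {
            e["direction"] for e in chain.graph.edges() if e["evidence"] == "trio"
        }
        for t in chain.trios_accepted:
            assert f"{t.parent1}->{t.offspring}" in directed
            assert f"{t.parent2}->{t.offspring}" in directed

    def test_fs_rule_directs_hidden_parent_founder(self, chain):
        """VIS has a genotyped full sib with no PO edges, so the FS rule
        marks VIS as parent of all three of its children."""
        fs_edges = gk.find_fullsibs(chain.ibd, chain.duos, 0.15)
        graph = gk.infer_directions(
            chain.duos, chain.trios_accepted, fs_edges, chain.sd_counts
        )
        vis_edges = [
            e for e in graph.edges()
            if "VIS" in (e["id1"], e["id2"]) and e["relation"] == "PO"
        ]
        assert len(vis_edges) == 3
        for e in vis_edges:
            assert e["direction"].startswith("VIS->")
            assert e["evidence"] == "fs-rule"

    def test_no_direction_contradicts_truth(self, recovery_runs):
        for run in recovery_runs:
            truth = run.scenario.truth
            for e in run.graph.edges():
                if e["relation"] != "PO" or not e["direction"]:
                    continue
                parent, child = e["direction"].split("->")
                assert truth._resolve(parent) in truth.parent_set(child), e

    def test_duo_without_evidence_stays_undirected(self):
        duos = [gk.RelationshipEdge("a", "b", "PO", k0=0.0)]
        graph = gk.infer_directions(duos, [], [], {})
        (edge,) = graph.edges()
        assert edge["direction"] == ""


class TestKinshipNeighbors:
    def test_excludes_classified_and_ranks_by_kinship(self, chain):
        ibd = chain.ibd
        truth = chain.scenario.truth
        samples = chain.panel_parentage.samples
        u1 = "U1"
        classified = {e.pair for e in chain.duos}
        out = gk.kinship_neighbors(ibd, u1, phi_min=0.10, classified=classified)
        listed = set(out["individual"])
        # PO partners are excluded even though their kinship is highest
        assert not any(frozenset((u1, o)) in classified for o in listed)
        # grandparents (phi = 0.125) make the list
        assert _rep(truth, "F07", samples) in listed
        assert list(out["kinship"]) == sorted(out["kinship"], reverse=True)

    def test_unrelated_absent(self, chain):
        out = gk.kinship_neighbors(chain.ibd, "U1", phi_min=0.10)
        truth = chain.scenario.truth
        for other in out["individual"]:
            assert truth.relationship("U1", other) != UNREL


class TestExport:
    def test_empty_graph_documents(self, tmp_path):
        g = gk.PedigreeGraph()
        for fmt, name in [("edge_tsv", "e.tsv"), ("graphml", "g.graphml"), ("dot", "g.dot")]:
            gk.export_network(g, tmp_path / name, fmt)
            assert (tmp_path / name).exists()
        assert gk.read_edge_tsv(tmp_path / "e.tsv").graph.number_of_edges() == 0

    def test_edge_tsv_round_trip_is_lossless(self, chain, tmp_path):
        gk.export_network(chain.graph, tmp_path / "edges.tsv", "edge_tsv")
        back = gk.read_edge_tsv(tmp_path / "edges.tsv")
        a = sorted(map(str, chain.graph.edges()))
        b = sorted(map(str, back.edges()))
        assert a == b

    def test_trio_encoded_as_two_directed_edges_sharing_id(self, chain, tmp_path):
        gk.export_network(chain.graph, tmp_path / "edges.tsv", "edge_tsv")
        df = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
        with_trio = df[df["trio_id"].notna() & (df["trio_id"] != "")]
        counts = with_trio.groupby("trio_id").size()
        assert (counts == 2).all()
        assert (with_trio["direction"].str.contains("->")).all()

    def test_dot_contains_directed_and_undirected_edges(self, chain, tmp_path):
        gk.export_network(chain.graph, tmp_path / "g.dot", "dot")
        text = (tmp_path / "g.dot").read_text()
        assert "digraph" in text and "dir=none" in text
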