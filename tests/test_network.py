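"""Multilayer network construction: contingency strata, link screening,
filtering, normalization, summary statistics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from comotraj.network import (
    BuilderConfig,
    MultilayerNetwork,
    build_contingency,
    build_network,
    filter_nodes,
    interlayer_links,
    intralayer_links,
    network_summary,
    normalize_weights,
)
from comotraj.records import EVENT_COLUMNS


def events_frame(rows):
    """rows: (patient_id, code, age_group, year) for male patients."""
    return pd.DataFrame(
        [(pid, "male", code, g, y) for pid, code, g, y in rows],
        columns=EVENT_COLUMNS,
    )


def stratum_events(counts, layer=3, year=2003, start=0):
    """Build one window's worth of events realizing a 2x2 table."""
    a, b, c, d = counts
    rows, k = [], start
    for _ in range(a):
        rows += [(f"P{k:04d}", "I10", layer, year), (f"P{k:04d}", "E66", layer, year)]
        k += 1
    for _ in range(b):
        rows += [(f"P{k:04d}", "I10", layer, year)]
        k += 1
    for _ in range(c):
        rows += [(f"P{k:04d}", "E66", layer, year)]
        k += 1
    for _ in range(d):
        rows += [(f"P{k:04d}", "J18", layer, year)]
        k += 1
    return rows, k


class TestContingency:
    def test_cells_partition_the_stratum_denominator(self):
        rows, _ = stratum_events((10, 5, 3, 2))
        strata = build_contingency(events_frame(rows), ("I10", "E66"), 3,
                                   "male")
        assert len(strata) == 1
        s = strata[0]
        assert (s.a, s.b, s.c, s.d) == (10, 5, 3, 2)
        assert s.n == 20
        assert not s.used  # d = 2 is below the min-cell rule

    def test_small_cell_marks_stratum_unused(self):
        rows, _ = stratum_events((4, 10, 10, 10))
        strata = build_contingency(events_frame(rows), ("I10", "E66"), 3,
                                   "male")
        assert not strata[0].used

    def test_windows_are_separate_strata(self):
        rows1, k = stratum_events((10, 5, 5, 5), year=2003)
        rows2, _ = stratum_events((20, 5, 5, 5), year=2005, start=k)
        strata = build_contingency(events_frame(rows1 + rows2),
                                   ("I10", "E66"), 3, "male")
        assert [s.a for s in strata] == [10, 20]
        assert [s.stratum_id[0] for s in strata] == [0, 1]

    def test_patient_split_across_windows(self):
        # i in window 0 and j in window 1: b in the first table, c in the
        # second
        rows = [("P1", "I10", 3, 2003), ("P1", "E66", 3, 2005),
                ("P2", "J18", 3, 2003), ("P2", "J18", 3, 2005)]
        strata = build_contingency(events_frame(rows), ("I10", "E66"), 3,
                                   "male")
        assert (strata[0].b, strata[0].c) == (1, 0)
        assert (strata[1].b, strata[1].c) == (0, 1)

    def test_identical_pair_rejected(self):
        with pytest.raises(ValueError):
            build_contingency(events_frame([]), ("I10", "I10"), 3, "male")


class TestIntralayerLinks:
    def _strong_pair_events(self):
        rows = []
        k = 0
        for year in (2003, 2005, 2007, 2009, 2011, 2013):
            r, k = stratum_events((30, 10, 10, 50), year=year, start=k)
            rows += r
        return events_frame(rows)

    def test_associated_pair_emits_both_directions(self):
        edges, audit = intralayer_links(self._strong_pair_events())
        pair_edges = [e for e in edges
                      if {e[0][0], e[1][0]} == {"I10", "E66"}]
        assert len(pair_edges) == 2
        directions = {(e[0][0], e[1][0]) for e in pair_edges}
        assert directions == {("I10", "E66"), ("E66", "I10")}
        row = audit[audit.emitted].iloc[0]
        assert row["rr_ij"] > 1.5 and row["p_value"] < 0.05

    def test_below_rr_threshold_no_edge(self):
        # RR approx 1.2: strongly significant is irrelevant
        rows = []
        k = 0
        for year in (2003, 2005):
            r, k = stratum_events((60, 40, 50, 50), year=year, start=k)
            rows += r
        edges, audit = intralayer_links(events_frame(rows))
        assert not [e for e in edges if {e[0][0], e[1][0]} == {"I10", "E66"}]

    def test_insignificant_pair_no_edge(self):
        rows, _ = stratum_events((8, 5, 5, 8))
        edges, audit = intralayer_links(events_frame(rows))
        row = audit[(audit.code_i == "E66") & (audit.code_j == "I10")].iloc[0]
        assert not row["emitted"]

    def test_skipped_pairs_reported(self):
        rows, _ = stratum_events((2, 2, 2, 2))
        edges, audit = intralayer_links(events_frame(rows))
        assert edges == []
        assert (audit["n_strata_used"] == 0).all()


class TestInterlayerLinks:
    def test_weight_is_conditional_risk_ratio(self):
        rows = []
        # 10 exposed (i at layer 3 in T1); 7 of them get j at layer 4 in
        # T2; 10 unexposed controls with j-rate 2/10
        for k in range(10):
            rows.append((f"E{k}", "I10", 3, 2004))
            rows.append((f"E{k}", "J18", 4, 2010))  # observed in beta, T2
            if k < 7:
                rows.append((f"E{k}", "N18", 4, 2010))
        for k in range(10):
            rows.append((f"C{k}", "J18", 4, 2010))
            if k < 2:
                rows.append((f"C{k}", "N18", 4, 2010))
        edges, audit = interlayer_links(events_frame(rows))
        row = audit[(audit.code_i == "I10") & (audit.code_j == "N18")].iloc[0]
        # P(j|i) = 0.7, P(j) = 9/20
        assert row["weight"] == pytest.approx(0.7 / 0.45)
        assert row["emitted"]

    def test_too_few_exposed_no_edge(self):
        rows = []
        for k in range(4):
            rows.append((f"E{k}", "I10", 3, 2004))
            rows.append((f"E{k}", "N18", 4, 2010))
        for k in range(20):
            rows.append((f"C{k}", "J18", 4, 2010))
        edges, audit = interlayer_links(events_frame(rows))
        assert audit.empty or not audit[
            (audit.code_i == "I10") & (audit.code_j == "N18")]["emitted"].any()

    def test_persistence_same_code_allowed(self):
        rows = []
        for k in range(10):
            rows.append((f"E{k}", "I10", 3, 2004))
            rows.append((f"E{k}", "I10", 4, 2010))
        for k in range(30):
            rows.append((f"C{k}", "J18", 4, 2010))
        edges, audit = interlayer_links(events_frame(rows))
        assert any(e[0][0] == e[1][0] == "I10" for e in edges)

    def test_layers_strictly_forward(self):
        rows = [(f"E{k}", "I10", 4, 2004) for k in range(10)]
        rows += [(f"E{k}", "N18", 3, 2010) for k in range(10)]
        edges, _ = interlayer_links(events_frame(rows))
        assert all(u[1] < v[1] for u, v, _ in edges)


def toy_network(edges, cfg=None):
    g = nx.DiGraph()
    for u, v, kind, w in edges:
        g.add_edge(u, v, type=kind, raw_weight=w)
    return MultilayerNetwork(g, "male", cfg or BuilderConfig())


class TestFilterNormalize:
    def test_isolated_node_removed_every_mode(self):
        for mode in ("intralayer_only", "in_and_out", "both_stages"):
            net = toy_network([(("A00", 1), ("B00", 1), "intra", 2.0),
                               (("B00", 1), ("A00", 1), "intra", 2.0)])
            net.graph.add_node(("C00", 2))
            out = filter_nodes(net, mode)
            assert ("C00", 2) not in out.nodes

    def test_interlayer_only_node_removed_by_intralayer_filter(self):
        net = toy_network([(("A00", 1), ("B00", 1), "intra", 2.0),
                           (("B00", 1), ("A00", 1), "intra", 2.0),
                           (("C00", 1), ("A00", 2), "inter", 3.0)])
        out = filter_nodes(net, "intralayer_only")
        assert ("C00", 1) not in out.nodes

    def test_in_and_out_iterates_to_fixed_point(self):
        # chain where removing the tail exposes the next node
        net = toy_network([
            (("A00", 1), ("B00", 1), "intra", 2.0),
            (("B00", 1), ("A00", 1), "intra", 2.0),
            (("A00", 1), ("C00", 2), "inter", 3.0),
            (("C00", 2), ("D00", 3), "inter", 3.0),
        ])
        out = filter_nodes(net, "in_and_out")
        assert out.nodes == {("A00", 1), ("B00", 1)}

    def test_bidirectional_intralayer_node_survives(self):
        net = toy_network([(("A00", 1), ("B00", 1), "intra", 2.0),
                           (("B00", 1), ("A00", 1), "intra", 2.0)])
        assert filter_nodes(net, "both_stages").nodes == {("A00", 1),
                                                          ("B00", 1)}

    def test_empty_result_raises(self):
        net = toy_network([(("C00", 1), ("A00", 2), "inter", 3.0)])
        with pytest.raises(ValueError):
            filter_nodes(net, "both_stages")

    def test_normalization_per_target_and_type(self):
        net = toy_network([
            (("A00", 1), ("C00", 1), "intra", 2.0),
            (("B00", 1), ("C00", 1), "intra", 6.0),
            (("D00", 1), ("C00", 2), "inter", 3.0),
            (("A00", 1), ("C00", 2), "inter", 9.0),
        ])
        out = normalize_weights(net)
        g = out.graph
        assert g[("A00", 1)][("C00", 1)]["norm_weight"] == pytest.approx(0.25)
        assert g[("B00", 1)][("C00", 1)]["norm_weight"] == pytest.approx(0.75)
        assert g[("D00", 1)][("C00", 2)]["norm_weight"] == pytest.approx(0.25)
        assert g[("A00", 1)][("C00", 2)]["norm_weight"] == pytest.approx(0.75)

    def test_single_incoming_link_normalizes_to_one(self):
        net = toy_network([(("A00", 1), ("B00", 1), "intra", 7.3)])
        out = normalize_weights(net)
        assert out.graph[("A00", 1)][("B00", 1)]["norm_weight"] == 1.0

    def test_conservation_on_built_network(self):
        # end-to-end: incoming normalized weights sum to 1 per type
        from comotraj.records import apply_washout, to_events
        from comotraj.simulate import simulate_cohort, study_config

        cfg = study_config(n_patients=4000, seed=9, male_fraction=1.0)
        stays, _ = simulate_cohort(cfg)
        _, kept = apply_washout(stays)
        net, _ = build_network(to_events(kept), BuilderConfig(), "male")
        g = net.graph
        for node in g.nodes:
            for kind in ("intra", "inter"):
                s = sum(d["norm_weight"] for _, _, d in
                        g.in_edges(node, data=True) if d["type"] == kind)
                assert s == 0 or abs(s - 1.0) < 1e-9


class TestSummary:
    def test_ring_density(self):
        edges = []
        for k in range(8):
            u = (f"A{k:02d}", 1)
            v = (f"A{(k + 1) % 8:02d}", 1)
            edges.append((u, v, "intra", 1.0))
            edges.append((v, u, "intra", 1.0))
        net = normalize_weights(toy_network(edges))
        summary, per_layer = network_summary(net)
        assert summary["n_nodes"] == 8
        assert summary["density"] == pytest.approx(16 / (8 * 7))
        assert per_layer.iloc[0]["n_nodes"] == 8

    def test_two_clique_modularity(self):
        edges = []
        for base in ("A", "B"):
            for i in range(4):
                for j in range(4):
                    if i != j:
                        edges.append(((f"{base}{i:02d}", 1),
                                      (f"{base}{j:02d}", 1), "intra", 1.0))
        edges.append((("A00", 1), ("B00", 1), "intra", 1.0))
        edges.append((("B00", 1), ("A00", 1), "intra", 1.0))
        net = normalize_weights(toy_network(edges))
        summary, _ = network_summary(net)
        assert summary["modularity"] > 0.3

    def test_graphml_round_trip(self, tmp_path):
        net = normalize_weights(toy_network(
            [(("A00", 1), ("B00", 1), "intra", 2.0),
             (("B00", 1), ("A00", 1), "intra", 3.0),
             (("A00", 1), ("C00", 2), "inter", 1.8)]))
        path = tmp_path / "net.graphml"
        net.to_graphml(path)
        back = MultilayerNetwork.from_graphml(path)
        assert back.nodes == net.nodes
        assert len(back.intralayer_links) == 2
        assert back.sex == "male"

    def test_build_determinism(self):
        from comotraj.records import apply_washout, to_events
        from comotraj.simulate import simulate_cohort, study_config

        cfg = study_config(n_patients=3000, seed=2, male_fraction=1.0)
        stays, _ = simulate_cohort(cfg)
        _, kept = apply_washout(stays)
        ev = to_events(kept)
        net1, _ = build_network(ev, BuilderConfig(), "male")
        net2, _ = build_network(ev, BuilderConfig(), "male")
        assert net1.edge_list().equals(net2.edge_list())
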