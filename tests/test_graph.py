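"""Trajectory graph composition, counting and ranking."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from trajscan.graph import (
    build_graph,
    compose_trajectories,
    count_all_trajectories,
    count_trajectory,
    export_dot,
    export_graphml,
    mask_count,
    rank_trajectories,
)
from trajscan.params import StudyParams
from conftest import panel_from_day_offsets


def results_frame(rows):
    """rows: (e1, e2, rr, n_pair, directional)."""
    return pd.DataFrame(
        [
            {"e1": a, "e2": b, "rr": rr, "n_pair": n,
             "significant_assoc": True, "significant_direction": d}
            for a, b, rr, n, d in rows
        ]
    )


class TestBuildGraph:
    def test_shared_concept_merges_nodes(self, three_event_panel):
        res = results_frame([(1, 2, 2.0, 1, True), (2, 3, 3.0, 1, True)])
        g = build_graph(res, three_event_panel)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
        assert g.edges[1, 2]["rr"] == 2.0
        assert g.nodes[1]["patient_count"] == 1

    def test_no_directional_pairs_empty_graph(self, three_event_panel):
        res = results_frame([(1, 2, 2.0, 1, False)])
        g = build_graph(res, three_event_panel)
        assert g.number_of_nodes() == 0

    def test_associated_but_not_directional_excluded(self, three_event_panel):
        res = results_frame([(1, 2, 2.0, 1, True), (1, 3, 2.0, 1, False)])
        g = build_graph(res, three_event_panel)
        assert list(g.edges) == [(1, 2)]

    def test_min_edge_count_display_filter(self, three_event_panel):
        res = results_frame([(1, 2, 2.0, 5, True), (2, 3, 3.0, 50, True)])
        g = build_graph(res, three_event_panel, min_edge_count=10)
        assert list(g.edges) == [(2, 3)]


class TestComposeTrajectories:
    def test_chain_produces_all_subpaths(self):
        g = nx.DiGraph([(1, 2), (2, 3)])
        assert compose_trajectories(g, 5) == [(1, 2), (1, 2, 3), (2, 3)]

    def test_two_cycle_never_repeats_a_concept(self):
        g = nx.DiGraph([(1, 2), (2, 1)])
        assert compose_trajectories(g, 3) == [(1, 2), (2, 1)]

    def test_empty_graph(self):
        assert compose_trajectories(nx.DiGraph(), 4) == []

    def test_terminates_on_dense_cyclic_graph(self):
        g = nx.complete_graph(6, create_using=nx.DiGraph)
        paths = compose_trajectories(g, 4)
        assert all(len(set(p)) == len(p) for p in paths)
        assert max(len(p) for p in paths) == 4

    def test_enumeration_is_lexicographic(self):
        g = nx.DiGraph([(3, 1), (3, 2), (1, 2)])
        paths = compose_trajectories(g, 3)
        assert paths == sorted(paths)


class TestCountTrajectory:
    params = StudyParams(min_gap_days=1, max_gap_days=365)

    def test_intermediate_event_allowed(self):
        panel = panel_from_day_offsets({0: {1: 0, 9: 5, 2: 10, 3: 30}})
        assert count_trajectory([1, 2, 3], panel, self.params) == 1

    def test_wrong_order_not_counted(self):
        panel = panel_from_day_offsets({0: {1: 0, 3: 10, 2: 20}})
        assert count_trajectory([1, 2, 3], panel, self.params) == 0

    def test_adjacent_gap_above_max_not_counted(self):
        panel = panel_from_day_offsets({0: {1: 0, 2: 400, 3: 410}})
        assert count_trajectory([1, 2, 3], panel, self.params) == 0

    def test_too_short_trajectory_rejected(self):
        panel = panel_from_day_offsets({0: {1: 0}})
        with pytest.raises(ValueError):
            count_trajectory([1], panel, self.params)


def brute_force_trajectory_count(concepts, panel, params):
    """Literal per-unit scan, independent of the vectorized implementation."""
    n = 0
    for seq in panel.sequences().values():
        dates = {c: d for c, d in seq}
        if not all(c in dates for c in concepts):
            continue
        ok = True
        for a, b in zip(concepts, concepts[1:]):
            gap = dates[b] - dates[a]
            if not (params.min_gap_days <= gap <= params.gap_upper):
                ok = False
                break
        if ok:
            n += 1
    return n


@pytest.fixture(scope="module")
def random_panel():
    rng = np.random.default_rng(23)
    day_map = {}
    for u in range(50):
        present = rng.choice(range(1, 7), size=rng.integers(0, 6), replace=False)
        day_map[u] = {
            int(c): int(d)
            for c, d in zip(present, rng.choice(2000, len(present), replace=False))
        }
    return panel_from_day_offsets(day_map)


class TestCountingProperties:

    def test_matches_brute_force_on_small_data(self, random_panel):
        params = StudyParams(min_gap_days=1, max_gap_days=500)
        for k in (2, 3, 4):
            for concepts in itertools.permutations(range(1, 7), k):
                assert count_trajectory(concepts, random_panel, params) == \
                    brute_force_trajectory_count(concepts, random_panel, params), concepts

    def test_anti_monotonicity(self, random_panel):
        params = StudyParams(min_gap_days=1, max_gap_days=500)
        for concepts in itertools.permutations(range(1, 7), 3):
            full = count_trajectory(concepts, random_panel, params)
            for sub in (concepts[:2], concepts[1:]):
                assert full <= count_trajectory(sub, random_panel, params)

    def test_counted_trajectories_close_over_graph_edges(self, random_panel):
        params = StudyParams(min_gap_days=1, max_gap_days=500,
                             min_pair_count=1, min_pair_prevalence=None)
        g = nx.DiGraph([(1, 2), (2, 3), (1, 3)])
        for n in g.nodes:
            g.nodes[n]["patient_count"] = random_panel.patient_count(n)
        df = count_all_trajectories(g, random_panel, params, include_unrealized=True)
        for t in df["trajectory"]:
            for a, b in zip(t, t[1:]):
                assert g.has_edge(a, b)


class TestRankTrajectories:
    def test_sorted_by_count_then_lexicographic(self):
        df = pd.DataFrame(
            {"trajectory": [(1, 2), (1, 3), (2, 3)],
             "length": [2, 2, 2],
             "n_patients": [50, 70, 50]}
        )
        out = rank_trajectories(df)
        assert out["trajectory"].tolist() == [(1, 3), (1, 2), (2, 3)]

    def test_prefix_filter(self):
        df = pd.DataFrame(
            {"trajectory": [(1, 2), (1, 2, 3), (2, 3)],
             "length": [2, 3, 2],
             "n_patients": [5, 3, 9]}
        )
        out = rank_trajectories(df, prefix=(1, 2))
        assert out["trajectory"].tolist() == [(1, 2), (1, 2, 3)]


class TestExports:
    def test_mask_count(self):
        assert mask_count(19, 20) == "<20"
        assert mask_count(20, 20) == "20"
        assert mask_count(0, 20) == "0"

    def test_graphml_round_trip(self, tmp_path, three_event_panel):
        res = results_frame([(1, 2, 2.5, 30, True)])
        g = build_graph(res, three_event_panel)
        path = tmp_path / "g.graphml"
        export_graphml(g, path)
        g2 = nx.read_graphml(path)
        assert g2.number_of_edges() == 1
        (_, _, attrs), = g2.edges(data=True)
        assert attrs["rr"] == pytest.approx(2.5)

    def test_dot_export_contains_rr_labels(self, tmp_path, three_event_panel):
        res = results_frame([(1, 2, 2.5, 30, True)])
        g = build_graph(res, three_event_panel)
        path = tmp_path / "g.dot"
        export_dot(g, path)
        text = path.read_text()
        assert "digraph" in text and "RR=2.50" in text
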