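"""Shared-16S genome graph: construction, components, cliques,
ANI classification, sharing statistics and certificates."""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from strep16s.ani import AniConfig, AniResult, classify_pair
from strep16s.genomes import GenomeProfile
from strep16s.network import (
    ComponentAniClass,
    build_graph,
    classify_component,
    clique_test,
    component_report,
    components,
    count_summary,
    sharing_certificate,
    variant_sharing_stats,
)


def _profiles(variant_sets, labels=None):
    return [
        GenomeProfile(f"G{i}", species_label=(labels or {}).get(i, f"sp{i}"), copies=list(vs))
        for i, vs in enumerate(variant_sets)
    ]


def _results(spec):
    out = {}
    for pair, (ident, cov) in spec.items():
        res = AniResult(tuple(sorted(pair)), ident, cov)
        classify_pair(res)
        out[tuple(sorted(pair))] = res
    return out


class TestGraph:
    def test_single_shared_variant_edge(self):
        profs = _profiles([["v1", "v2"], ["v1"]])
        g = build_graph(profs)
        assert g.has_edge("G0", "G1") and g["G0"]["G1"]["weight"] == 1

    def test_disjoint_variants_no_edge(self):
        g = build_graph(_profiles([["v1"], ["v2"]]))
        assert g.number_of_edges() == 0

    def test_edge_weight_counts_distinct_shared_variants(self):
        profs = _profiles([["v1", "v2", "v2"], ["v1", "v2", "v3"]])
        g = build_graph(profs)
        assert g["G0"]["G1"]["weight"] == 2

    def test_no_self_edges(self):
        g = build_graph(_profiles([["v1", "v1"]]))
        assert g.number_of_edges() == 0

    def test_planted_adjacency_recovered(self, cohort, retained_profiles):
        g = build_graph(retained_profiles)
        truth_sets = {
            row.accession: set()
            for row in cohort.truth.genomes.itertuples(index=False)
            if row.fate == "retained"
        }
        for row in cohort.truth.variant_incidence.itertuples(index=False):
            truth_sets[row.accession].add(row.variant_key)
        for a, b in combinations(sorted(truth_sets), 2):
            assert g.has_edge(a, b) == bool(truth_sets[a] & truth_sets[b])


class TestComponents:
    def test_edgeless_graph_all_singletons(self):
        comps = components(build_graph(_profiles([["v1"], ["v2"], ["v3"], ["v4"], ["v5"]])))
        assert len(comps) == 5 and all(c.is_singleton for c in comps)

    def test_path_is_single_component(self):
        comps = components(build_graph(_profiles([["v1"], ["v1", "v2"], ["v2"]])))
        assert len(comps) == 1 and comps[0].size == 3

    @pytest.mark.parametrize("trial", range(10))
    def test_random_graphs_match_bfs_oracle(self, trial):
        rng = np.random.default_rng(200 + trial)
        n = int(rng.integers(3, 13))
        variant_pool = [f"v{k}" for k in range(6)]
        sets = [
            list(rng.choice(variant_pool, size=int(rng.integers(1, 4)), replace=False))
            for _ in range(n)
        ]
        profs = _profiles(sets)
        graph = build_graph(profs)
        got = sorted(sorted(c.members) for c in components(graph))
        # oracle: BFS reachability on the shared-variant relation
        adj = {
            p.accession: {
                q.accession
                for q in profs
                if q.accession != p.accession and set(p.copies) & set(q.copies)
            }
            for p in profs
        }
        seen, want = set(), []
        for p in profs:
            if p.accession in seen:
                continue
            comp, frontier = {p.accession}, [p.accession]
            while frontier:
                nxt = [m for f in frontier for m in adj[f] if m not in comp]
                comp.update(nxt)
                frontier = nxt
            seen |= comp
            want.append(sorted(comp))
        assert got == sorted(want)


class TestClique:
    def test_triangle_true_path_false(self):
        tri = components(build_graph(_profiles([["v1"], ["v1"], ["v1"]])))[0]
        g_tri = build_graph(_profiles([["v1"], ["v1"], ["v1"]]))
        assert clique_test(tri, g_tri)
        path_profiles = _profiles([["v1"], ["v1", "v2"], ["v2"]])
        g_path = build_graph(path_profiles)
        path = components(g_path)[0]
        assert not clique_test(path, g_path)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_exhaustive_pair_oracle(self, trial):
        rng = np.random.default_rng(300 + trial)
        sets = [
            list(rng.choice([f"v{k}" for k in range(5)], size=int(rng.integers(1, 3)), replace=False))
            for _ in range(int(rng.integers(3, 10)))
        ]
        profs = _profiles(sets)
        graph = build_graph(profs)
        for comp in components(graph):
            if comp.is_singleton:
                continue
            want = all(
                graph.has_edge(a, b) for a, b in combinations(comp.members, 2)
            )
            assert clique_test(comp, graph) == want


class TestClassifyComponent:
    def _component(self, n=3):
        profs = _profiles([["v1"]] * n)
        graph = build_graph(profs)
        return components(graph)[0]

    def test_all_same_species(self):
        comp = self._component()
        spec = {(f"G{i}", f"G{j}"): (98.0, 90.0) for i in range(3) for j in range(i + 1, 3)}
        assert classify_component(comp, _results(spec)) is ComponentAniClass.SINGLE_SPECIES

    def test_one_low_identity_pair(self):
        spec = {("G0", "G1"): (93.0, 80.0), ("G0", "G2"): (97.0, 85.0), ("G1", "G2"): (98.0, 82.0)}
        assert classify_component(self._component(), _results(spec)) is ComponentAniClass.MULTI_SPECIES_SINGLE_GENUS

    def test_low_coverage_dominates(self):
        spec = {("G0", "G1"): (93.0, 80.0), ("G0", "G2"): (99.0, 40.0), ("G1", "G2"): (98.0, 82.0)}
        assert classify_component(self._component(), _results(spec)) is ComponentAniClass.MULTI_GENUS

    def test_missing_pair_is_error(self):
        with pytest.raises(KeyError):
            classify_component(self._component(), {})

    def test_order_invariance(self):
        spec = {("G0", "G1"): (93.0, 80.0), ("G0", "G2"): (97.0, 85.0), ("G1", "G2"): (98.0, 82.0)}
        comp = self._component()
        first = classify_component(comp, _results(spec))
        comp.members = list(reversed(comp.members))
        assert classify_component(comp, _results(spec)) == first


class TestReportsAndStats:
    def test_variant_sharing_records(self):
        profs = _profiles(
            [["v1"], ["v1", "v2"], ["v1"], ["v1"], ["v1"]],
            labels={0: "spA", 1: "spA", 2: "spB", 3: "spB", 4: "spB"},
        )
        stats = variant_sharing_stats(profs)
        row_v1 = stats[stats.n_genomes == 5].iloc[0]
        assert row_v1.n_species_labels == 2
        # conservation: total incidences equal the sum over variants
        assert stats.n_genomes.sum() == sum(len(set(p.copies)) for p in profs)

    def test_component_report_rows(self):
        profs = _profiles([["v1"], ["v1"]], labels={0: "spA", 1: "spA"})
        graph = build_graph(profs)
        comps = components(graph)
        clique_test(comps[0], graph)
        classify_component(comps[0], _results({("G0", "G1"): (98.0, 90.0)}))
        comp_df, pair_df = component_report(comps, profs)
        assert comp_df.loc[0, "n_species_labels"] == 1
        assert comp_df.loc[0, "ani_class"] == "single_species"
        assert len(pair_df) == 1 and bool(pair_df.loc[0, "same_species"])

    def test_empty_component_list(self):
        comp_df, pair_df = component_report([], [])
        assert comp_df.empty and pair_df.empty

    def test_certificate_verifies(self, cohort, retained_profiles):
        graph = build_graph(retained_profiles)
        by_acc = {p.accession: p for p in retained_profiles}
        for comp in components(graph):
            tree = sharing_certificate(comp, retained_profiles)
            assert len(tree) == (0 if comp.is_singleton else comp.size - 1)
            seen = {comp.members[0]}
            for a, b, witness in tree:
                assert witness in by_acc[a].variant_set
                assert witness in by_acc[b].variant_set
                seen.update((a, b))
            assert seen == set(comp.members)

    def test_count_summary_conservation(self, retained_profiles):
        graph = build_graph(retained_profiles)
        comps = components(graph)
        summary = count_summary(comps)
        assert summary["n_genomes"] == len(retained_profiles)
        sizes = [c.size for c in comps]
        assert summary["n_singletons"] + sum(s for s in sizes if s > 1) == len(retained_profiles)
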