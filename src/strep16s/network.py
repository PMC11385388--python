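"""The shared-identical-16S genome network and its ANI classification.

Genomes are nodes; two genomes are joined by an edge when they share at
least one byte-identical full-length 16S variant, the edge weight being
the number of shared distinct variants.  If 16S mapped one-to-one onto
species, every connected component would be a clique of conspecific
genomes; departures from that - non-clique components, components whose
members fail the species or even the genus ANI thresholds - are the
phenomena this module quantifies.

Component-level ANI classes (checked over all member pairs):

* ``multi_genus``                - any pair below the genus coverage threshold,
* ``multi_species_single_genus`` - otherwise, any pair below the species
  identity threshold,
* ``single_species``             - every pair passes both thresholds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations

import networkx as nx
import pandas as pd

from .ani import AniConfig, AniRelation, AniResult, classify_pair
from .genomes import GenomeProfile


class ComponentAniClass(str, Enum):
    SINGLE_SPECIES = "single_species"
    MULTI_SPECIES_SINGLE_GENUS = "multi_species_single_genus"
    MULTI_GENUS = "multi_genus"


@dataclass
class CongruenceComponent:
    members: list[str]
    is_singleton: bool
    is_clique: bool | None = None
    n_distinct_species_labels: int | None = None
    ani_class: ComponentAniClass | None = None
    pairwise: dict[tuple[str, str], AniResult] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


def build_graph(profiles: list[GenomeProfile]) -> nx.Graph:
    """Shared-variant graph over retained genome profiles.

    Undirected, no self-edges; edge weight = number of shared distinct
    variant strings.  Every profile becomes a node even if isolated.
    """
    graph = nx.Graph()
    for prof in profiles:
        graph.add_node(prof.accession, species_label=prof.species_label)
    variant_sets = {p.accession: p.variant_set for p in profiles}
    by_variant: dict[str, list[str]] = {}
    for acc, variants in variant_sets.items():
        for v in variants:
            by_variant.setdefault(v, []).append(acc)
    for accs in by_variant.values():
        for a, b in combinations(sorted(accs), 2):
            if graph.has_edge(a, b):
                graph[a][b]["weight"] += 1
            else:
                graph.add_edge(a, b, weight=1)
    return graph


def components(graph: nx.Graph) -> list[CongruenceComponent]:
    """Connected components, sorted by (descending size, smallest member)."""
    comps = [
        CongruenceComponent(members=sorted(c), is_singleton=len(c) == 1)
        for c in nx.connected_components(graph)
    ]
    comps.sort(key=lambda c: (-c.size, c.members[0]))
    return comps


def clique_test(component: CongruenceComponent, graph: nx.Graph) -> bool:
    """True iff every member pair is directly joined by an edge."""
    members = component.members
    ok = all(graph.has_edge(a, b) for a, b in combinations(members, 2))
    component.is_clique = ok
    return ok


def classify_component(
    component: CongruenceComponent,
    ani_results: dict[tuple[str, str], AniResult],
    config: AniConfig | None = None,
) -> ComponentAniClass:
    """ANI class of a component from its within-component pairwise results.

    All member pairs must be present in ``ani_results`` (keys are sorted
    accession pairs); a missing pair is an error.  Precedence follows
    the threshold nesting: genus failures dominate species failures.
    """
    cfg = config or AniConfig()
    relations = []
    for a, b in combinations(component.members, 2):
        key = (a, b) if a <= b else (b, a)
        if key not in ani_results:
            raise KeyError(f"missing ANI result for pair {key}")
        res = ani_results[key]
        if res.relation is None:
            classify_pair(res, cfg)
        relations.append(res.relation)
        component.pairwise[key] = res
    if any(r is AniRelation.DIFF_GENUS for r in relations):
        cls = ComponentAniClass.MULTI_GENUS
    elif any(r is AniRelation.SAME_GENUS_DIFF_SPECIES for r in relations):
        cls = ComponentAniClass.MULTI_SPECIES_SINGLE_GENUS
    else:
        cls = ComponentAniClass.SINGLE_SPECIES
    component.ani_class = cls
    return cls


def component_report(
    comps: list[CongruenceComponent],
    profiles: list[GenomeProfile],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-component summary table and long-format pairwise ANI table."""
    labels = {p.accession: p.species_label for p in profiles}
    comp_rows, pair_rows = [], []
    for i, comp in enumerate(comps):
        species = {labels.get(m, "") for m in comp.members} - {""}
        comp.n_distinct_species_labels = len(species)
        idents = [r.identity for r in comp.pairwise.values() if r.identity is not None]
        covs = [r.coverage for r in comp.pairwise.values()]
        comp_rows.append(
            {
                "component": i,
                "size": comp.size,
                "is_singleton": comp.is_singleton,
                "is_clique": comp.is_clique,
                "n_species_labels": comp.n_distinct_species_labels,
                "ani_class": comp.ani_class.value if comp.ani_class else None,
                "min_identity": min(idents) if idents else None,
                "max_identity": max(idents) if idents else None,
                "min_coverage": min(covs) if covs else None,
                "max_coverage": max(covs) if covs else None,
            }
        )
        for (a, b), res in sorted(comp.pairwise.items()):
            pair_rows.append(
                {
                    "component": i,
                    "n_species_labels": len(species),
                    "genome_a": a,
                    "genome_b": b,
                    "identity": res.identity,
                    "coverage": res.coverage,
                    "same_species": res.relation is AniRelation.SAME_SPECIES,
                    "same_genus": res.relation is not AniRelation.DIFF_GENUS,
                }
            )
    return pd.DataFrame(comp_rows), pd.DataFrame(pair_rows)


def variant_sharing_stats(profiles: list[GenomeProfile]) -> pd.DataFrame:
    """One row per distinct variant: carrier genomes and species labels."""
    carriers: dict[str, list[str]] = {}
    for prof in profiles:
        for v in prof.variant_set:
            carriers.setdefault(v, []).append(prof.accession)
    labels = {p.accession: p.species_label for p in profiles}
    rows = []
    for i, (variant, accs) in enumerate(sorted(carriers.items())):
        species = {labels[a] for a in accs if labels.get(a)}
        rows.append(
            {
                "variant_index": i,
                "n_genomes": len(accs),
                "n_species_labels": len(species),
                "genomes": ";".join(sorted(accs)),
            }
        )
    return pd.DataFrame(rows)


def sharing_certificate(
    component: CongruenceComponent, profiles: list[GenomeProfile]
) -> list[tuple[str, str, str]]:
    """Spanning-tree witness that a component is connected through shared
    variants: (genome_a, genome_b, witness_variant) triples, one per tree
    edge, each witness present in both endpoint genomes."""
    variant_sets = {p.accession: p.variant_set for p in profiles if p.accession in component.members}
    tree: list[tuple[str, str, str]] = []
    if component.is_singleton:
        return tree
    root = component.members[0]
    seen = {root}
    frontier = [root]
    while frontier:
        nxt = []
        for node in frontier:
            for other in component.members:
                if other in seen:
                    continue
                shared = variant_sets[node] & variant_sets[other]
                if shared:
                    tree.append((node, other, min(shared)))
                    seen.add(other)
                    nxt.append(other)
        frontier = nxt
    if len(seen) != len(component.members):
        raise ValueError("component is not connected through shared variants")
    return tree


def count_summary(comps: list[CongruenceComponent]) -> dict:
    """Headline counts: components, singletons, non-cliques, ANI classes."""
    by_class = Counter(c.ani_class for c in comps if c.ani_class is not None)
    return {
        "n_genomes": sum(c.size for c in comps),
        "n_components": len(comps),
        "n_singletons": sum(c.is_singleton for c in comps),
        "n_non_clique": sum(
            1 for c in comps if not c.is_singleton and c.is_clique is False
        ),
        "n_single_species": by_class.get(ComponentAniClass.SINGLE_SPECIES, 0),
        "n_multi_species_single_genus": by_class.get(ComponentAniClass.MULTI_SPECIES_SINGLE_GENUS, 0),
        "n_multi_genus": by_class.get(ComponentAniClass.MULTI_GENUS, 0),
    }


def export_edge_list(graph: nx.Graph, path) -> None:
    rows = [
        {"genome_a": a, "genome_b": b, "weight": d["weight"]}
        for a, b, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["genome_a", "genome_b", "weight"]).to_csv(path, sep="\t", index=False)
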