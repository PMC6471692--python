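"""Differential topology between two condition networks.

Mirrors the pairwise comparisons usually done interactively with DyNet-style
tools: a union "reference" network labels every node and edge as common or
condition-specific; shortest-path length distributions summarize global
connectivity; and a per-node rewiring score (Dn-score) quantifies how much
each shared node's neighbourhood changed between conditions. For two states
the score reduces to 0.25 times the size of the symmetric difference of the
node's incident edge sets (each differing edge contributes the population
variance of its 0/1 presence indicator across the two states).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .network_build import ConditionGraph


@dataclass(frozen=True)
class PathLengthDistribution:
    """Histogram of finite directed shortest-path lengths (>= 1)."""

    histogram: dict[int, int]
    reachable_pairs: int
    modal_length: int | None

    def __post_init__(self):
        if sum(self.histogram.values()) != self.reachable_pairs:
            raise ValueError("histogram counts must sum to reachable pairs")


@dataclass
class ReferenceNetwork:
    """Union of two condition graphs with per-node/per-edge membership."""

    node_kind: str
    label_a: str
    label_b: str
    graph: nx.DiGraph  # nodes/edges carry a "membership" attribute
    node_membership: dict[str, str]
    edge_membership: dict[tuple[str, str], str]

    def membership_counts(self, which: str = "nodes") -> dict[str, int]:
        src = self.node_membership if which == "nodes" else self.edge_membership
        counts = Counter(src.values())
        return {k: counts.get(k, 0) for k in ("both", "A_only", "B_only")}


@dataclass(frozen=True)
class RewiringReport:
    """Dn-scores for nodes present in both conditions, ranked descending."""

    scores: dict[str, float]  # dn_raw
    degree_corrected: dict[str, float]
    union_degree: dict[str, int]
    ranking: list[str]


def shortest_path_distribution(cg: ConditionGraph) -> PathLengthDistribution:
    """All-pairs directed BFS; counts ordered reachable pairs per length.

    Unreachable pairs are excluded (not treated as infinite); the modal
    length breaks ties toward the smaller length.
    """
    hist: Counter[int] = Counter()
    for _, lengths in nx.all_pairs_shortest_path_length(cg.graph):
        for dist in lengths.values():
            if dist >= 1:
                hist[dist] += 1
    total = sum(hist.values())
    modal = min(
        hist, key=lambda length: (-hist[length], length)
    ) if hist else None
    return PathLengthDistribution(
        histogram=dict(sorted(hist.items())), reachable_pairs=total, modal_length=modal
    )


def merge_reference(ga: ConditionGraph, gb: ConditionGraph) -> ReferenceNetwork:
    """Union reference network with common / A-only / B-only labels."""
    if ga.node_kind != gb.node_kind:
        raise ValueError(
            f"cannot merge graphs of different node kinds: {ga.node_kind} vs {gb.node_kind}"
        )

    def member(in_a: bool, in_b: bool) -> str:
        if in_a and in_b:
            return "both"
        return "A_only" if in_a else "B_only"

    union = nx.DiGraph()
    node_membership = {}
    for n in set(ga.graph.nodes) | set(gb.graph.nodes):
        m = member(n in ga.graph, n in gb.graph)
        node_membership[n] = m
        union.add_node(n, membership=m)
    edge_membership = {}
    for e in set(ga.graph.edges) | set(gb.graph.edges):
        m = member(e in ga.graph.edges, e in gb.graph.edges)
        edge_membership[e] = m
        union.add_edge(*e, membership=m)
    return ReferenceNetwork(
        node_kind=ga.node_kind,
        label_a=ga.condition_label or "A",
        label_b=gb.condition_label or "B",
        graph=union,
        node_membership=node_membership,
        edge_membership=edge_membership,
    )


def rewiring_scores(ref: ReferenceNetwork) -> RewiringReport:
    """Per-node rewiring (Dn) scores over the union reference network.

    For each node present in both states, pool its incident union edges (in
    and out); an edge present in exactly one state contributes 0.25 (the
    population variance of its presence indicator over two states), an edge
    present in both contributes 0. dn_degree_corrected divides by the union
    degree. Ranking: dn_raw descending, ties by node id.
    """
    scores, corrected, degrees = {}, {}, {}
    for n, membership in ref.node_membership.items():
        if membership != "both":
            continue
        incident = list(ref.graph.in_edges(n)) + list(ref.graph.out_edges(n))
        dn = sum(
            0.25 for e in incident if ref.edge_membership[e] != "both"
        )
        deg = len(incident)
        scores[n] = dn
        degrees[n] = deg
        corrected[n] = dn / deg if deg else 0.0
    ranking = sorted(scores, key=lambda n: (-scores[n], n))
    return RewiringReport(
        scores=scores, degree_corrected=corrected, union_degree=degrees, ranking=ranking
    )


def top_rewired(report: RewiringReport, k: int) -> list[tuple[str, float]]:
    """First k nodes by Dn-score (ties broken lexicographically by id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [(n, report.scores[n]) for n in report.ranking[:k]]


def comparison_report(
    ga: ConditionGraph, gb: ConditionGraph, top_k: int = 20
) -> dict:
    """JSON-ready summary: membership counts, top rewired nodes, histograms."""
    ref = merge_reference(ga, gb)
    rew = rewiring_scores(ref)
    dist_a = shortest_path_distribution(ga)
    dist_b = shortest_path_distribution(gb)
    return {
        "node_kind": ref.node_kind,
        "labels": {"A": ref.label_a, "B": ref.label_b},
        "node_membership_counts": ref.membership_counts("nodes"),
        "edge_membership_counts": ref.membership_counts("edges"),
        "nodes_A_only": sorted(
            n for n, m in ref.node_membership.items() if m == "A_only"
        ),
        "nodes_B_only": sorted(
            n for n, m in ref.node_membership.items() if m == "B_only"
        ),
        "top_rewired": [
            {
                "node": n,
                "dn_raw": score,
                "dn_degree_corrected": rew.degree_corrected[n],
                "union_degree": rew.union_degree[n],
            }
            for n, score in top_rewired(rew, top_k)
        ],
        "path_length_histograms": {
            ref.label_a: {str(k): v for k, v in dist_a.histogram.items()},
            ref.label_b: {str(k): v for k, v in dist_b.histogram.items()},
        },
        "modal_path_lengths": {
            ref.label_a: dist_a.modal_length,
            ref.label_b: dist_b.modal_length,
        },
    }


def write_reference_graphml(ref: ReferenceNetwork, report: RewiringReport, path) -> None:
    g = nx.DiGraph()
    for n in sorted(ref.graph.nodes):
        g.add_node(n, membership=ref.node_membership[n])
        if n in report.scores:
            g.nodes[n]["dn_raw"] = report.scores[n]
            g.nodes[n]["dn_degree_corrected"] = report.degree_corrected[n]
    for u, v in ref.graph.edges:
        g.add_edge(u, v, membership=ref.edge_membership[(u, v)])
    g.graph["node_kind"] = ref.node_kind
    nx.write_graphml(g, path)
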