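"""Condition-specific directed graphs from flux solutions.

A fitted flux vector induces a reaction-level directed graph: active
reactions are nodes, and an edge runs from the reaction producing a
metabolite to the reaction consuming it, after forcing each reversible
reaction's orientation to the sign of its fitted flux. Ubiquitous currency
metabolites (ATP, H2O, NADH, ...) are excluded so that edges trace actual
substrate flow rather than cofactor recycling. A gene-level graph replaces
each reaction by the genes in its GPR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .flux_fit import FluxSolution
from .gem_io import MetabolicModel

logger = logging.getLogger("fluxweaver")

ZERO_TOL = 1e-6

#: Default currency (recurring) metabolites, matched by compartment-stripped
#: base name. Configurable; this list is a pragmatic default, not a claim
#: about any particular published model.
DEFAULT_CURRENCY = (
    "H2O", "CO2", "O2", "ATP", "ADP", "AMP", "Pi", "PPi",
    "NADH", "NAD+", "NADPH", "NADP+", "FADH2", "FAD", "H+", "CoA",
)


@dataclass
class ConditionGraph:
    """A directed condition network at reaction or gene resolution."""

    node_kind: str  # "reaction" | "gene"
    graph: nx.DiGraph
    condition_label: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def shared_metabolites(self, u: str, v: str) -> list[str]:
        return list(self.graph.edges[u, v].get("shared_metabolites", []))


def _base_name(met_id: str, name: str, compartment: str) -> set[str]:
    """Candidate currency-matching names for a metabolite."""
    cands = {met_id, name}
    if compartment:
        for suffix in (f"_{compartment}", f"[{compartment}]"):
            if met_id.endswith(suffix):
                cands.add(met_id[: -len(suffix)])
            if name.endswith(suffix):
                cands.add(name[: -len(suffix)])
    return {c.lower() for c in cands if c}


def currency_metabolite_ids(model: MetabolicModel, currency_names) -> set[str]:
    """Resolve currency base names to model metabolite ids (any compartment)."""
    wanted = {str(c).lower() for c in currency_names}
    out = set()
    matched = set()
    for m in model.metabolites:
        hits = _base_name(m.id, m.name, m.compartment) & wanted
        if hits:
            out.add(m.id)
            matched |= hits
    unmatched = wanted - matched
    if unmatched:
        logger.warning("currency names not found in model: %s", sorted(unmatched))
    return out


def orient_active(
    model: MetabolicModel, solution: FluxSolution, zero_tol: float = ZERO_TOL
) -> dict[str, dict[str, float]]:
    """Effective stoichiometry of active reactions under fitted flux signs.

    Reactions with |v| <= zero_tol are dropped; a negative flux flips the
    reaction's products and reagents (all coefficients change sign).
    """
    oriented = {}
    for r in model.reactions:
        v = solution.fluxes[r.id]
        if abs(v) <= zero_tol:
            continue
        sign = 1.0 if v > 0 else -1.0
        oriented[r.id] = {mid: sign * c for mid, c in r.stoichiometry.items()}
    return oriented


def build_reaction_graph(
    model: MetabolicModel,
    solution: FluxSolution,
    currency=DEFAULT_CURRENCY,
    zero_tol: float = ZERO_TOL,
) -> ConditionGraph:
    """Directed reaction graph: producer -> consumer per shared metabolite.

    Nodes are all active reactions (isolated ones included); for every
    internal non-currency metabolite, an edge connects each producing
    reaction to each consuming reaction under the effective orientation.
    Parallel edges over several metabolites merge into one edge carrying the
    full shared-metabolite list.
    """
    currency_ids = currency_metabolite_ids(model, currency)
    boundary = {m.id for m in model.metabolites if m.is_boundary}
    oriented = orient_active(model, solution, zero_tol)

    g = nx.DiGraph()
    g.add_nodes_from(oriented)
    for rid in oriented:
        g.nodes[rid]["flux"] = solution.fluxes[rid]
    mets = [
        m.id
        for m in model.metabolites
        if m.id not in currency_ids and m.id not in boundary
    ]
    for mid in mets:
        producers = [r for r, st in oriented.items() if st.get(mid, 0.0) > 0]
        consumers = [r for r, st in oriented.items() if st.get(mid, 0.0) < 0]
        for p in producers:
            for c in consumers:
                if p == c:
                    continue
                if g.has_edge(p, c):
                    g.edges[p, c]["shared_metabolites"].append(mid)
                else:
                    g.add_edge(p, c, shared_metabolites=[mid])
    return ConditionGraph(
        node_kind="reaction",
        graph=g,
        condition_label=solution.condition_label,
        provenance={
            "constraint_label": solution.constraint_label,
            "zero_tol": zero_tol,
            "currency": sorted(currency_ids),
        },
    )


def build_gene_graph(
    model: MetabolicModel,
    solution: FluxSolution,
    currency=DEFAULT_CURRENCY,
    zero_tol: float = ZERO_TOL,
) -> ConditionGraph:
    """Directed gene graph: genes of producing vs consuming reactions.

    Every reaction-graph edge a->b expands to gene edges g->h for all genes g
    regulating a and h regulating b (self-edges excluded); reactions without
    a GPR contribute neither nodes nor bridges.
    """
    rxn_graph = build_reaction_graph(model, solution, currency, zero_tol)
    gene_sets = {r.id: sorted(r.genes()) for r in model.reactions}

    g = nx.DiGraph()
    for rid in rxn_graph.nodes:
        g.add_nodes_from(gene_sets.get(rid, ()))
    for a, b in rxn_graph.edges:
        shared = rxn_graph.shared_metabolites(a, b)
        for ga in gene_sets.get(a, ()):
            for gb in gene_sets.get(b, ()):
                if ga == gb:
                    continue
                if g.has_edge(ga, gb):
                    cur = g.edges[ga, gb]["shared_metabolites"]
                    g.edges[ga, gb]["shared_metabolites"] = sorted(set(cur) | set(shared))
                else:
                    g.add_edge(ga, gb, shared_metabolites=sorted(set(shared)))
    return ConditionGraph(
        node_kind="gene",
        graph=g,
        condition_label=solution.condition_label,
        provenance=dict(rxn_graph.provenance),
    )


# ---------------------------------------------------------------------------
# Graph I/O
# ---------------------------------------------------------------------------

def write_edge_list(cg: ConditionGraph, path) -> None:
    """TSV edge list: source, target, shared metabolites semicolon-joined."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tshared_metabolites\n")
        for u, v in sorted(cg.graph.edges):
            shared = ";".join(cg.shared_metabolites(u, v))
            fh.write(f"{u}\t{v}\t{shared}\n")


def write_node_table(cg: ConditionGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tkind\tflux\tcondition\n")
        for n in sorted(cg.graph.nodes):
            flux = cg.graph.nodes[n].get("flux", "")
            flux_s = repr(float(flux)) if flux != "" else ""
            fh.write(f"{n}\t{cg.node_kind}\t{flux_s}\t{cg.condition_label}\n")


def write_graphml(cg: ConditionGraph, path) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(sorted(cg.graph.nodes))
    for n, attrs in cg.graph.nodes(data=True):
        for k, val in attrs.items():
            g.nodes[n][k] = val
    for u, v, attrs in cg.graph.edges(data=True):
        g.add_edge(u, v, shared_metabolites=";".join(attrs.get("shared_metabolites", [])))
    g.graph["node_kind"] = cg.node_kind
    g.graph["condition_label"] = cg.condition_label
    nx.write_graphml(g, path)


def read_graphml(path) -> ConditionGraph:
    g = nx.read_graphml(path)
    dg = nx.DiGraph()
    dg.add_nodes_from(g.nodes(data=True))
    for u, v, attrs in g.edges(data=True):
        shared = attrs.get("shared_metabolites", "")
        dg.add_edge(u, v, shared_metabolites=[s for s in shared.split(";") if s])
    return ConditionGraph(
        node_kind=g.graph.get("node_kind", "reaction"),
        graph=dg,
        condition_label=g.graph.get("condition_label", ""),
    )
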