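"""Synthetic metabolic models, fluxes and expression profiles for testing.

Real runs of this pipeline require a genome-scale model and clinical exchange
fluxes; everything here generates desk-scale stand-ins with a known ground
truth so that each stage (and the whole pipeline) can be verified: a small
hand-specified network with an exactly balanced flux vector, seeded random
toy networks built from superposed source-to-sink path flows (so S v = 0
holds by construction), expression profiles derived from a flux vector with
controlled multiplicative noise, and two-condition pairs with planted
reaction knockouts for differential-topology recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .expression import ExpressionProfile, GeneRecord, SD_FLOOR
from .flux_fit import FluxSolution, InfeasibleModelError
from .gem_io import (
    DEFAULT_BOUND,
    GprTree,
    MetaboliteRef,
    MetabolicModel,
    ReactionRef,
    parse_gpr,
)

#: currency metabolites of the hand fixture
FIXTURE_CURRENCY = ("ATP", "ADP")


def fixture_model() -> MetabolicModel:
    """Hand-specified 7-reaction toy network with an exactly balanced flux.

    Internal metabolites A-D plus an ATP/ADP currency couple; a clamped
    uptake (R_in, at most 10), a branched interior (R2/R3) reconverging
    through a reversible bridge (R4), a sink (R5) and an ATP-regenerating
    reaction with no gene. Ground truth: see :func:`fixture_true_fluxes`.
    """
    mets = tuple(
        MetaboliteRef(mid, name=mid, compartment="c")
        for mid in ("A", "B", "C", "D", "ATP", "ADP")
    )
    def rxn(rid, stoich, lb, ub, gpr=None):
        return ReactionRef(
            id=rid, name=rid, stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, reversible=lb < 0,
            gpr=parse_gpr(gpr) if gpr else None,
        )
    reactions = (
        rxn("R_in", {"A": 1.0}, 0.0, 10.0),
        rxn("R1", {"A": -1.0, "ATP": -1.0, "B": 1.0, "ADP": 1.0}, 0.0, DEFAULT_BOUND, "G1"),
        rxn("R2", {"B": -1.0, "C": 1.0}, 0.0, DEFAULT_BOUND, "G2 or G3"),
        rxn("R3", {"B": -1.0, "D": 1.0}, 0.0, DEFAULT_BOUND, "G4"),
        rxn("R4", {"C": -1.0, "D": 1.0}, -DEFAULT_BOUND, DEFAULT_BOUND, "G5"),
        rxn("R5", {"D": -1.0}, 0.0, DEFAULT_BOUND, "G6 and G7"),
        rxn("R_atp", {"ADP": -1.0, "ATP": 1.0}, 0.0, DEFAULT_BOUND),
    )
    return MetabolicModel(id="toy_fixture", metabolites=mets, reactions=reactions)


def fixture_true_fluxes() -> dict[str, float]:
    """Balanced ground-truth fluxes of the fixture (S v = 0 exactly)."""
    return {"R_in": 10.0, "R1": 10.0, "R2": 6.0, "R3": 4.0, "R4": 6.0,
            "R5": 10.0, "R_atp": 10.0}


def solution_from_fluxes(
    model: MetabolicModel, fluxes: dict[str, float], condition_label: str = ""
) -> FluxSolution:
    """Wrap a known flux vector as a FluxSolution (for graph building)."""
    return FluxSolution(
        model=model,
        fluxes=dict(fluxes),
        throughputs={rid: abs(v) for rid, v in fluxes.items()},
        objective=0.0,
        rho=float("nan"),
        rho_trajectory=[],
        iterations=0,
        converged=True,
        condition_label=condition_label,
    )


# ---------------------------------------------------------------------------
# Random toy networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyGemSpec:
    """Shape parameters of a random toy network."""

    n_internal_metabolites: int = 8
    n_reactions: int = 20
    reversible_fraction: float = 0.2
    n_currency: int = 1  # currency couples (each adds 2 metabolites + recharge)
    gpr_complexity: int = 1  # max genes per reaction
    exchange_count: int = 2  # 1 uptake + (count-1) sinks
    seed: int = 0

    def __post_init__(self):
        if self.exchange_count < 2:
            raise ValueError("need at least one uptake and one sink exchange")
        if self.n_internal_metabolites < 2:
            raise ValueError("need at least 2 internal metabolites")
        if not 0 <= self.reversible_fraction <= 1:
            raise ValueError("reversible_fraction must be in [0, 1]")
        if self.gpr_complexity < 1:
            raise ValueError("gpr_complexity must be >= 1")
        min_rxns = self.exchange_count + (self.n_internal_metabolites - 1) + self.n_currency
        if self.n_reactions < min_rxns:
            raise ValueError(
                f"n_reactions={self.n_reactions} too small; this shape needs >= {min_rxns}"
            )


@dataclass(frozen=True)
class ToyGem:
    model: MetabolicModel
    v_true: dict[str, float]
    uptake_id: str
    sink_ids: tuple[str, ...]
    currency_ids: tuple[str, ...]


def make_toy_gem(spec: ToyGemSpec) -> ToyGem:
    """Random connected toy network with an exactly balanced ground truth.

    Built as a backbone chain from an uptake to a terminal sink, plus random
    forward branch reactions and currency-coupled reactions with a recharge
    loop. The ground-truth flux superposes one random positive source-to-sink
    path flow per internal edge, so every reaction is active and S v = 0
    holds to machine precision. The same seed reproduces the model exactly.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_internal_metabolites
    mets = [MetaboliteRef(f"M{i}", name=f"M{i}", compartment="c") for i in range(k)]

    # internal edges: backbone chain plus random forward branches
    n_internal = spec.n_reactions - spec.exchange_count - spec.n_currency
    edges: list[tuple[int, int]] = [(i, i + 1) for i in range(k - 1)]
    existing = set(edges)
    attempts = 0
    while len(edges) < n_internal and attempts < 10000:
        attempts += 1
        i = int(rng.integers(0, k - 1))
        j = int(rng.integers(i + 1, k))
        if (i, j) in existing:
            continue
        existing.add((i, j))
        edges.append((i, j))
    if len(edges) < n_internal:
        raise ValueError(
            "cannot place the requested number of internal reactions; "
            "increase n_internal_metabolites or reduce n_reactions"
        )

    # sinks: terminal metabolite always; extras on random metabolites
    sink_mets = [k - 1]
    for _ in range(spec.exchange_count - 2):
        sink_mets.append(int(rng.integers(1, k)))

    # ground truth: one random path flow per internal edge
    succ: dict[int, list[int]] = {}
    for i, j in edges:
        succ.setdefault(i, []).append(j)
    flux: dict[tuple[int, int], float] = {e: 0.0 for e in edges}
    sink_flow = {m: 0.0 for m in set(sink_mets)}
    sink_set = set(sink_mets)

    def backbone_path(a: int, b: int) -> list[tuple[int, int]]:
        return [(i, i + 1) for i in range(a, b)]

    total_in = 0.0
    for (i, j) in edges:
        f = float(rng.uniform(1.0, 3.0))
        path = backbone_path(0, i) + [(i, j)]
        # continue from j to the nearest sink metabolite (terminal works always)
        end = j
        if end not in sink_set:
            path += backbone_path(j, k - 1)
            end = k - 1
        for e in path:
            flux[e] += f
        sink_flow[end] += f
        total_in += f

    reactions: list[ReactionRef] = []
    v_true: dict[str, float] = {}

    uptake_id = "EX_up"
    reactions.append(ReactionRef(
        id=uptake_id, name=uptake_id, stoichiometry={"M0": 1.0},
        # integer cap just above the routed total: serializes exactly in SBML
        lower_bound=0.0, upper_bound=float(math.ceil(total_in)),
    ))
    v_true[uptake_id] = total_in

    for s_i, met in enumerate(sorted(sink_flow)):
        rid = f"EX_sink{s_i}"
        reactions.append(ReactionRef(
            id=rid, name=rid, stoichiometry={f"M{met}": -1.0},
            lower_bound=0.0, upper_bound=DEFAULT_BOUND,
        ))
        v_true[rid] = sink_flow[met]

    n_rev = int(math.floor(spec.reversible_fraction * len(edges)))
    rev_idx = set(rng.choice(len(edges), size=n_rev, replace=False).tolist()) if n_rev else set()

    gene_counter = 0
    def make_gpr(rng) -> GprTree | None:
        nonlocal gene_counter
        if spec.gpr_complexity == 1:
            n_genes, shape = 1, "leaf"
        else:
            n_genes = int(rng.integers(1, spec.gpr_complexity + 1))
            shape = "leaf" if n_genes == 1 else ("and" if rng.random() < 0.5 else "or")
        leaves = []
        for _ in range(n_genes):
            leaves.append(GprTree("leaf", gene=f"G{gene_counter:03d}"))
            gene_counter += 1
        if shape == "leaf":
            return leaves[0]
        return GprTree(shape, children=tuple(leaves))

    internal_ids = []
    for idx, (i, j) in enumerate(edges):
        rid = f"R{idx:03d}"
        internal_ids.append(rid)
        lb = -DEFAULT_BOUND if idx in rev_idx else 0.0
        reactions.append(ReactionRef(
            id=rid, name=rid, stoichiometry={f"M{i}": -1.0, f"M{j}": 1.0},
            lower_bound=lb, upper_bound=DEFAULT_BOUND, reversible=lb < 0,
            gpr=make_gpr(rng),
        ))
        v_true[rid] = flux[(i, j)]

    currency_ids: list[str] = []
    for p in range(spec.n_currency):
        hi, lo = f"CUR{p}hi", f"CUR{p}lo"  # charged / discharged couple
        currency_ids += [hi, lo]
        mets.append(MetaboliteRef(hi, name=hi, compartment="c"))
        mets.append(MetaboliteRef(lo, name=lo, compartment="c"))
        n_coupled = int(rng.integers(1, min(3, len(internal_ids)) + 1))
        coupled = rng.choice(len(internal_ids), size=n_coupled, replace=False)
        recharge_flux = 0.0
        for ci in sorted(coupled.tolist()):
            rid = internal_ids[ci]
            pos = next(i for i, r in enumerate(reactions) if r.id == rid)
            r = reactions[pos]
            st = dict(r.stoichiometry)
            st[hi] = st.get(hi, 0.0) - 1.0
            st[lo] = st.get(lo, 0.0) + 1.0
            reactions[pos] = ReactionRef(
                id=r.id, name=r.name, stoichiometry=st,
                lower_bound=r.lower_bound, upper_bound=r.upper_bound,
                reversible=r.reversible, gpr=r.gpr,
            )
            recharge_flux += v_true[rid]
        rid = f"R_regen{p}"
        reactions.append(ReactionRef(
            id=rid, name=rid, stoichiometry={lo: -1.0, hi: 1.0},
            lower_bound=0.0, upper_bound=DEFAULT_BOUND,
        ))
        v_true[rid] = recharge_flux

    model = MetabolicModel(
        id=f"toy_gem_seed{spec.seed}", metabolites=tuple(mets), reactions=tuple(reactions)
    )
    S, _, rxn_ids = model.stoichiometric_matrix()
    resid = float(np.max(np.abs(S @ np.array([v_true[r] for r in rxn_ids]))))
    if resid > 1e-10:
        raise AssertionError(f"generated ground truth violates mass balance ({resid:.2e})")
    return ToyGem(
        model=model,
        v_true=v_true,
        uptake_id=uptake_id,
        sink_ids=tuple(r.id for r in reactions if r.id.startswith("EX_sink")),
        currency_ids=tuple(currency_ids),
    )


# ---------------------------------------------------------------------------
# Expression from flux
# ---------------------------------------------------------------------------

def _assign_leaves(node: GprTree, target: float, assigned: dict[str, float]) -> None:
    """Greedy leaf assignment so the default policy evaluates to target."""
    if node.op == "leaf":
        assigned.setdefault(node.gene, target)
        return
    if node.op == "and":
        for c in node.children:
            _assign_leaves(c, target, assigned)
        return
    # OR: already-assigned children count toward the sum, remainder is split
    def value_of(c: GprTree) -> float | None:
        if c.op == "leaf":
            return assigned.get(c.gene)
        return None

    fixed = [value_of(c) for c in node.children]
    known = sum(v for v in fixed if v is not None)
    free = [c for c, v in zip(node.children, fixed) if v is None]
    if not free:
        return
    share = max(0.0, target - known) / len(free)
    for c in free:
        _assign_leaves(c, share, assigned)


def make_expression_from_flux(
    model: MetabolicModel,
    v_true: dict[str, float],
    noise_sd_frac: float = 0.0,
    seed: int = 0,
    condition_label: str = "synthetic",
) -> ExpressionProfile:
    """Gene expression whose GPR evaluation reproduces the flux magnitudes.

    Each reaction's GPR is solved greedily leaf-by-leaf so that the default
    policy (AND=min, OR=sum) evaluates to |v_true| for that reaction (exact
    when genes are private to one reaction). Means are then perturbed with
    multiplicative gaussian noise of sd = noise_sd_frac * mean; the profile's
    sd field records that noise sd (floored).
    """
    if noise_sd_frac < 0:
        raise ValueError("noise_sd_frac must be >= 0")
    rng = np.random.default_rng(seed)
    assigned: dict[str, float] = {}
    for r in model.reactions:
        if r.gpr is None:
            continue
        _assign_leaves(r.gpr, abs(v_true.get(r.id, 0.0)), assigned)
    records = {}
    for gene in sorted(assigned):
        mean = assigned[gene]
        sd = noise_sd_frac * mean
        noisy = mean + rng.normal(0.0, sd) if sd > 0 else mean
        records[gene] = GeneRecord(gene, max(noisy, 0.0), max(sd, SD_FLOOR))
    return ExpressionProfile(condition_label=condition_label, records=records)


# ---------------------------------------------------------------------------
# Two-condition pairs with planted differences
# ---------------------------------------------------------------------------

def rebalance_knockout(
    model: MetabolicModel,
    v_true: dict[str, float],
    knockout_reactions,
) -> dict[str, float]:
    """Reroute a balanced flux around knocked-out reactions.

    Exchanges keep their ground-truth values (so the network stays driven),
    knocked-out reactions are forced to zero, and the remaining fluxes move
    as little as possible in L1 from the original ground truth. Raises if a
    knockout cuts the network (no balanced rerouting exists).
    """
    knockout = set(knockout_reactions)
    unknown = knockout - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"unknown knockout reactions {sorted(unknown)}")
    S, _, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    exchanges = {
        r.id for r in model.reactions
        if all(c > 0 for c in r.stoichiometry.values())
        or all(c < 0 for c in r.stoichiometry.values())
    }
    bounds = []
    for r in model.reactions:
        if r.id in knockout:
            bounds.append((0.0, 0.0))
        elif r.id in exchanges:
            v = v_true[r.id]
            bounds.append((v, v))
        else:
            bounds.append((r.lower_bound, r.upper_bound))
    v0 = np.array([v_true[r] for r in rxn_ids])
    # minimize sum |v - v0| via v - e+ + e- = v0
    import scipy.sparse as sp

    I = sp.identity(n, format="csr")
    A_eq = sp.vstack([
        sp.hstack([sp.csr_matrix(S), sp.csr_matrix((S.shape[0], 2 * n))]),
        sp.hstack([I, -I, I]),
    ]).tocsr()
    b_eq = np.concatenate([np.zeros(S.shape[0]), v0])
    c = np.concatenate([np.zeros(n), np.ones(2 * n)])
    lp_bounds = bounds + [(0.0, None)] * (2 * n)
    res = scipy.optimize.linprog(
        c, A_eq=A_eq, b_eq=b_eq, bounds=lp_bounds, method="highs"
    )
    if not res.success:
        raise InfeasibleModelError(
            f"knockout {sorted(knockout)} admits no balanced rerouting: {res.message}"
        )
    return {rid: float(res.x[i]) for i, rid in enumerate(rxn_ids)}


def make_condition_pair(
    model: MetabolicModel,
    v_true: dict[str, float],
    knockout_reactions=(),
    scale_b: float = 1.0,
    seed: int = 0,
    noise_sd_frac: float = 0.0,
    currency=(),
) -> tuple[ExpressionProfile, ExpressionProfile, dict]:
    """Two expression profiles with planted knockouts and a global scale.

    Condition A reflects the ground truth; condition B reflects the
    knockout-rerouted flux scaled by ``scale_b``, with the knocked-out
    reactions' genes set to zero expression (the loss must propagate through
    the flux fit, not through model edits). Returns the profiles plus the
    expected differential signature: A-only nodes and the neighbours expected
    to score as rewired in the reaction graph.
    """
    from .network_build import build_reaction_graph

    knockout = sorted(set(knockout_reactions))
    v_b = rebalance_knockout(model, v_true, knockout) if knockout else dict(v_true)
    v_b = {rid: scale_b * v for rid, v in v_b.items()}

    prof_a = make_expression_from_flux(
        model, v_true, noise_sd_frac, seed=seed, condition_label="A"
    )
    prof_b = make_expression_from_flux(
        model, v_b, noise_sd_frac, seed=seed + 1, condition_label="B"
    )
    ko_genes = set()
    for rid in knockout:
        ko_genes |= model.reaction(rid).genes()
    if ko_genes:
        records = dict(prof_b.records)
        for g in ko_genes:
            if g in records:
                records[g] = GeneRecord(g, 0.0, SD_FLOOR)
        prof_b = ExpressionProfile(condition_label="B", records=records)

    graph_a = build_reaction_graph(
        model, solution_from_fluxes(model, v_true, "A"), currency=currency
    )
    graph_b_nodes = {rid for rid, v in v_b.items() if abs(v) > 1e-6}
    a_only = sorted(
        n for n in graph_a.nodes
        if n not in graph_b_nodes and abs(v_true.get(n, 0.0)) > 1e-6
    )
    expected_rewired = sorted({
        nbr
        for node in a_only
        for nbr in set(graph_a.graph.predecessors(node)) | set(graph_a.graph.successors(node))
        if nbr not in a_only
    })
    expected = {
        "knockout_reactions": knockout,
        "scale_b": scale_b,
        "a_only_nodes": a_only,
        "expected_rewired": expected_rewired,
        "v_true_a": dict(v_true),
        "v_true_b": v_b,
    }
    return prof_a, prof_b, expected
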