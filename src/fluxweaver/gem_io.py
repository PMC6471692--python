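"""Reading and writing genome-scale metabolic models and flux tables.

Models are held in a small frozen representation (:class:`MetabolicModel`)
that carries exactly what the downstream fitting and graph-building stages
need: signed stoichiometry, flux bounds, reversibility, and gene-protein-
reaction (GPR) boolean rules. SBML parsing is delegated to cobrapy/libsbml;
GPR strings are parsed here into an explicit boolean tree so that the
expression-mapping policies can walk them.
"""

from __future__ import annotations

import gzip
import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("fluxweaver")

#: Flux bound applied when a reaction declares none, in umol 100g^-1 min^-1.
DEFAULT_BOUND = 1000.0


# ---------------------------------------------------------------------------
# GPR boolean trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GprTree:
    """Boolean gene association: a gene leaf, or an AND/OR over children.

    ``op`` is one of ``"leaf"``, ``"and"``, ``"or"``. Leaves carry ``gene``;
    AND/OR nodes carry a non-empty tuple of ``children``.
    """

    op: str
    gene: str | None = None
    children: tuple["GprTree", ...] = ()

    def __post_init__(self):
        if self.op == "leaf":
            if not self.gene:
                raise ValueError("leaf GPR node requires a gene symbol")
        elif self.op in ("and", "or"):
            if not self.children:
                raise ValueError(f"{self.op!r} GPR node requires children")
        else:
            raise ValueError(f"unknown GPR node op {self.op!r}")

    def genes(self) -> set[str]:
        """All gene symbols appearing in the tree."""
        if self.op == "leaf":
            return {self.gene}
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        """Serialize with explicit parentheses around OR inside AND."""
        if self.op == "leaf":
            return self.gene
        if self.op == "and":
            parts = [
                f"({c.to_string()})" if c.op == "or" else c.to_string()
                for c in self.children
            ]
            return " and ".join(parts)
        return " or ".join(c.to_string() for c in self.children)


class GprSyntaxError(ValueError):
    """Raised on malformed GPR strings; carries the token position."""


def _tokenize_gpr(rule: str) -> list[tuple[str, str, int]]:
    tokens = []
    i, n = 0, len(rule)
    while i < n:
        ch = rule[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append(("paren", ch, i))
            i += 1
            continue
        j = i
        while j < n and not rule[j].isspace() and rule[j] not in "()":
            j += 1
        word = rule[i:j]
        low = word.lower()
        if low == "and":
            tokens.append(("and", word, i))
        elif low == "or":
            tokens.append(("or", word, i))
        else:
            tokens.append(("gene", word, i))
        i = j
    return tokens


def parse_gpr(rule: str) -> GprTree | None:
    """Parse a GPR string into a :class:`GprTree`.

    AND binds tighter than OR; parentheses override. An empty/blank rule
    returns ``None`` (no gene association). Raises :class:`GprSyntaxError`
    with the offending position on malformed input.
    """
    tokens = _tokenize_gpr(rule or "")
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def expect_factor() -> GprTree:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GprSyntaxError(f"unexpected end of GPR rule {rule!r}")
        kind, word, at = tok
        if kind == "paren" and word == "(":
            pos += 1
            node = expr()
            tok = peek()
            if tok is None or tok[1] != ")":
                raise GprSyntaxError(
                    f"unbalanced parenthesis in GPR rule {rule!r} (opened at {at})"
                )
            pos += 1
            return node
        if kind == "gene":
            pos += 1
            return GprTree("leaf", gene=word)
        raise GprSyntaxError(
            f"unexpected token {word!r} at position {at} in GPR rule {rule!r}"
        )

    def combine(op: str, parts: list[GprTree]) -> GprTree:
        # flatten nested same-operator nodes so parsing is canonical
        if len(parts) == 1:
            return parts[0]
        flat: list[GprTree] = []
        for p in parts:
            if p.op == op:
                flat.extend(p.children)
            else:
                flat.append(p)
        return GprTree(op, children=tuple(flat))

    def term() -> GprTree:
        nonlocal pos
        parts = [expect_factor()]
        while peek() is not None and peek()[0] == "and":
            pos += 1
            parts.append(expect_factor())
        return combine("and", parts)

    def expr() -> GprTree:
        nonlocal pos
        parts = [term()]
        while peek() is not None and peek()[0] == "or":
            pos += 1
            parts.append(term())
        return combine("or", parts)

    tree = expr()
    if pos != len(tokens):
        kind, word, at = tokens[pos]
        raise GprSyntaxError(
            f"unexpected token {word!r} at position {at} in GPR rule {rule!r}"
        )
    return tree


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaboliteRef:
    id: str
    name: str = ""
    compartment: str = ""
    is_boundary: bool = False


@dataclass(frozen=True)
class ReactionRef:
    id: str
    name: str = ""
    #: signed stoichiometric coefficients keyed by metabolite id
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    reversible: bool = False
    gpr: GprTree | None = None

    def genes(self) -> set[str]:
        return self.gpr.genes() if self.gpr is not None else set()


@dataclass(frozen=True)
class MetabolicModel:
    """A metabolic network: metabolites, reactions with bounds and GPRs.

    Column j of :meth:`stoichiometric_matrix` is reaction j; row i is
    internal (non-boundary) metabolite i. Reversibility is normalized to
    ``lower_bound < 0`` so that orientation logic depends only on achievable
    flux signs.
    """

    id: str
    metabolites: tuple[MetaboliteRef, ...]
    reactions: tuple[ReactionRef, ...]

    def __post_init__(self):
        met_ids = {m.id for m in self.metabolites}
        if len(met_ids) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        seen = set()
        for r in self.reactions:
            if r.id in seen:
                raise ValueError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            missing = set(r.stoichiometry) - met_ids
            if missing:
                raise ValueError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )
            if r.lower_bound > r.upper_bound:
                raise ValueError(
                    f"reaction {r.id!r} has lower_bound > upper_bound"
                )
            if r.reversible != (r.lower_bound < 0):
                raise ValueError(
                    f"reaction {r.id!r}: reversible flag inconsistent with bounds"
                )

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes()
        return out

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> ReactionRef:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.is_boundary]

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S over internal metabolites: returns (S, met_ids, rxn_ids)."""
        met_ids = self.internal_metabolite_ids()
        idx = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoichiometry.items():
                i = idx.get(mid)
                if i is not None:
                    S[i, j] = coef
        return S, met_ids, self.reaction_ids

    def with_bounds(self, new_bounds: dict[str, tuple[float, float]]) -> "MetabolicModel":
        """Copy with selected reactions' bounds replaced (and reversibility renormalized)."""
        rxns = []
        for r in self.reactions:
            if r.id in new_bounds:
                lo, hi = new_bounds[r.id]
                rxns.append(replace(r, lower_bound=lo, upper_bound=hi, reversible=lo < 0))
            else:
                rxns.append(r)
        return replace(self, reactions=tuple(rxns))


def normalize_reversibility(
    rid: str, lb: float, ub: float
) -> tuple[float, float, bool]:
    if lb > ub:
        raise ValueError(f"reaction {rid!r}: lower bound {lb} > upper bound {ub}")
    return lb, ub, lb < 0


# ---------------------------------------------------------------------------
# SBML input
# ---------------------------------------------------------------------------

class SBMLParseError(ValueError):
    pass


def _clip(sid: str, prefix: str) -> str:
    """Mirror cobrapy's SBML id convention (R_/M_/G_ prefixes are clipped)."""
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _libsbml_metadata(path: str) -> tuple[set[str], list[str], dict[str, bool], set[str]]:
    """Boundary species, reaction order, reversible attrs, and explicit-bound ids.

    Reads the raw SBML to recover information cobrapy normalizes away: which
    species are boundary-condition species, the declared reaction list (so
    auto-added exchanges can be dropped), the SBML ``reversible`` attribute,
    and which reactions declare any explicit bound (fbc or kinetic-law).
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLParseError(
            f"invalid SBML in {path}: {err.getMessage().strip()} (line {err.getLine()})"
        )
    model = doc.getModel()
    if model is None:
        raise SBMLParseError(f"no <model> element found in {path}")
    boundary = {
        _clip(s.getId(), "M_")
        for s in model.getListOfSpecies()
        if s.getBoundaryCondition()
    }
    rxn_ids, reversible, has_bounds = [], {}, set()
    for rxn in model.getListOfReactions():
        rid = _clip(rxn.getId(), "R_")
        rxn_ids.append(rid)
        reversible[rid] = bool(rxn.getReversible())
        fbc = rxn.getPlugin("fbc")
        if fbc is not None and (fbc.isSetLowerFluxBound() or fbc.isSetUpperFluxBound()):
            has_bounds.add(rid)
        kl = rxn.getKineticLaw()
        if kl is not None:
            for pname in ("LOWER_BOUND", "UPPER_BOUND"):
                if kl.getParameter(pname) is not None:
                    has_bounds.add(rid)
    return boundary, rxn_ids, reversible, has_bounds


def read_sbml_model(path, default_bound: float = DEFAULT_BOUND) -> MetabolicModel:
    """Read an SBML L2/L3 (+FBC) model, optionally gzip-compressed.

    Bounds come from FBC parameters or kinetic-law defaults when present;
    reactions declaring neither get ``[0, default_bound]`` if irreversible in
    the SBML and ``[-default_bound, default_bound]`` if reversible. After
    reading, ``reversible`` is normalized to ``lower_bound < 0``.
    """
    import cobra.io

    path = str(path)
    cobra_log = logging.getLogger("cobra")
    level = cobra_log.level
    cobra_log.setLevel(logging.ERROR)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmodel = cobra.io.read_sbml_model(path)
    except Exception as exc:  # cobra raises various I/O and parse errors
        raise SBMLParseError(f"cannot parse SBML file {path}: {exc}") from exc
    finally:
        cobra_log.setLevel(level)
    boundary, rxn_order, sbml_reversible, has_bounds = _libsbml_metadata(path)

    mets = tuple(
        MetaboliteRef(
            id=m.id,
            name=m.name or m.id,
            compartment=m.compartment or "",
            is_boundary=m.id in boundary,
        )
        for m in cmodel.metabolites
    )
    declared = set(rxn_order)
    crxns = {r.id: r for r in cmodel.reactions if r.id in declared}
    reactions = []
    for rid in rxn_order:
        cr = crxns.get(rid)
        if cr is None:
            continue
        if rid in has_bounds:
            lb, ub = float(cr.lower_bound), float(cr.upper_bound)
        else:
            ub = default_bound
            lb = -default_bound if sbml_reversible.get(rid, False) else 0.0
        lb, ub, rev = normalize_reversibility(rid, lb, ub)
        try:
            gpr = parse_gpr(cr.gene_reaction_rule)
        except GprSyntaxError as exc:
            raise GprSyntaxError(f"reaction {rid!r}: {exc}") from exc
        reactions.append(
            ReactionRef(
                id=rid,
                name=cr.name or rid,
                stoichiometry={m.id: float(c) for m, c in cr.metabolites.items()},
                lower_bound=lb,
                upper_bound=ub,
                reversible=rev,
                gpr=gpr,
            )
        )
    return MetabolicModel(id=cmodel.id or "model", metabolites=mets, reactions=tuple(reactions))


def write_sbml_model(model: MetabolicModel, path) -> None:
    """Serialize a :class:`MetabolicModel` to SBML L3+FBC via cobrapy."""
    import cobra
    import cobra.io

    cmodel = cobra.Model(model.id)
    cmets = {}
    for m in model.metabolites:
        cm = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        cmets[m.id] = cm
    cmodel.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name)
        crxns.append(cr)
    cmodel.add_reactions(crxns)
    for r, cr in zip(model.reactions, crxns):
        cr.add_metabolites({cmets[mid]: c for mid, c in r.stoichiometry.items()})
        cr.bounds = (r.lower_bound, r.upper_bound)
        if r.gpr is not None:
            cr.gene_reaction_rule = r.gpr.to_string()
    cobra_log = logging.getLogger("cobra")
    level = cobra_log.level
    cobra_log.setLevel(logging.ERROR)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cobra.io.write_sbml_model(cmodel, str(path))
    finally:
        cobra_log.setLevel(level)


# ---------------------------------------------------------------------------
# Flux tables
# ---------------------------------------------------------------------------

FLUX_TABLE_COLUMNS = [
    "reaction_id", "flux", "lower_bound", "upper_bound", "data_value", "in_objective",
]


def write_flux_table(solution, path) -> None:
    """Write a flux solution as TSV in model reaction order.

    Columns: reaction_id, flux, lower_bound, upper_bound, data_value (the
    expression-derived target, empty where absent) and in_objective (whether
    the reaction carried data and entered the fit objective).
    """
    model = solution.model
    rows = []
    for r in model.reactions:
        d = solution.data_values.get(r.id)
        rows.append(
            {
                "reaction_id": r.id,
                "flux": repr(float(solution.fluxes[r.id])),
                "lower_bound": repr(float(r.lower_bound)),
                "upper_bound": repr(float(r.upper_bound)),
                "data_value": "" if d is None else repr(float(d)),
                "in_objective": str(d is not None).lower(),
            }
        )
    df = pd.DataFrame(rows, columns=FLUX_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_flux_table(path) -> pd.DataFrame:
    """Read a flux TSV back; fluxes round-trip bit-exactly (repr serialization)."""
    df = pd.read_csv(path, sep="\t", dtype={"reaction_id": str})
    missing = set(FLUX_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"flux table {path} missing columns {sorted(missing)}")
    return df
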