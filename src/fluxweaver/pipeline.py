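"""End-to-end orchestration: fit fluxes per condition and time point, build
condition graphs, and run the differential comparisons, from one config.

Output layout: ``out/<condition>_<timepoint>/`` holds per-run artifacts (flux
table, run record, graphs); ``out/compare_<timepoint>/`` holds differential
artifacts (comparison report, flux-change report, reference GraphML). A
manifest JSON lists every artifact with its SHA-256 hash plus the rho
trajectories, so identical inputs are checkable to the byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import gem_io
from .expression import map_to_reactions, read_expression_table
from .flux_fit import (
    FitOptions,
    FluxConstraintSet,
    apply_flux_constraints,
    classify_flux_changes,
    fit_fluxes,
)
from .network_build import (
    DEFAULT_CURRENCY,
    build_gene_graph,
    build_reaction_graph,
    write_edge_list,
    write_graphml,
    write_node_table,
)
from .network_compare import (
    comparison_report,
    merge_reference,
    rewiring_scores,
    write_reference_graphml,
)

logger = logging.getLogger("fluxweaver")


@dataclass(frozen=True)
class RunConfig:
    """Inputs and options for a full pipeline run."""

    model_path: str
    #: condition label -> expression table path
    expression_paths: dict[str, str]
    #: time-point label -> {reaction_id: [lower, upper]}
    constraint_sets: dict[str, dict[str, tuple[float, float]]]
    out_dir: str
    currency: tuple[str, ...] = DEFAULT_CURRENCY
    fit_options: FitOptions = field(default_factory=FitOptions)
    graph_kinds: tuple[str, ...] = ("reaction", "gene")
    gpr_policy: str = "min_sum"
    top_k: int = 20
    fc_threshold: float = 2.0
    zero_tol: float = 1e-6

    def __post_init__(self):
        if len(set(self.expression_paths)) != len(self.expression_paths):
            raise ValueError("condition labels must be unique")
        for kind in self.graph_kinds:
            if kind not in ("reaction", "gene"):
                raise ValueError(f"unknown graph kind {kind!r}")


def load_config(path) -> RunConfig:
    """Load a YAML run config (paths resolved relative to the config file)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def resolve(p):
        p = Path(p)
        return str(p if p.is_absolute() else base / p)

    fit_raw = raw.get("fit_options", {})
    constraint_sets = {
        label: {rid: (float(lo), float(hi)) for rid, (lo, hi) in entries.items()}
        for label, entries in raw.get("constraint_sets", {}).items()
    }
    currency = raw.get("currency")
    if isinstance(currency, str):
        currency = yaml.safe_load(Path(resolve(currency)).read_text())
    return RunConfig(
        model_path=resolve(raw["model"]),
        expression_paths={k: resolve(v) for k, v in raw["expression"].items()},
        constraint_sets=constraint_sets,
        out_dir=resolve(raw.get("out_dir", "out")),
        currency=tuple(currency) if currency else DEFAULT_CURRENCY,
        fit_options=FitOptions(**fit_raw),
        graph_kinds=tuple(raw.get("graph_kinds", ("reaction", "gene"))),
        gpr_policy=raw.get("gpr_policy", "min_sum"),
        top_k=int(raw.get("top_k", 20)),
        fc_threshold=float(raw.get("fc_threshold", 2.0)),
        zero_tol=float(raw.get("zero_tol", 1e-6)),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_safe(x):
    if isinstance(x, float) and math.isnan(x):
        return None
    return x


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_all(config: RunConfig) -> dict:
    """Run fit -> graphs -> compare for every condition and time point.

    Returns (and writes) the manifest: every artifact path with its hash,
    the per-run rho trajectories, and any stage warnings. Deterministic:
    rerunning on identical inputs reproduces every output byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"artifacts": {}, "runs": {}, "comparisons": {}}

    stage = "read_model"
    try:
        model = gem_io.read_sbml_model(config.model_path)
        profiles = {
            label: read_expression_table(p, condition_label=label)
            for label, p in config.expression_paths.items()
        }

        solutions: dict[tuple[str, str], object] = {}
        graphs: dict[tuple[str, str, str], object] = {}
        for tp_label, entries in config.constraint_sets.items():
            cset = FluxConstraintSet(tp_label, dict(entries))
            clamped = apply_flux_constraints(model, cset)
            for cond, profile in profiles.items():
                stage = f"fit[{cond},{tp_label}]"
                data = map_to_reactions(clamped, profile, policy=config.gpr_policy)
                sol = fit_fluxes(
                    clamped, data, config.fit_options, constraint_label=tp_label
                )
                solutions[(cond, tp_label)] = sol
                run_dir = out / f"{cond}_{tp_label}"
                run_dir.mkdir(exist_ok=True)
                flux_path = run_dir / "flux.tsv"
                gem_io.write_flux_table(sol, flux_path)
                record = {
                    "condition": cond,
                    "constraint_set": tp_label,
                    "objective": sol.objective,
                    "rho": _json_safe(sol.rho),
                    "rho_trajectory": [_json_safe(r) for r in sol.rho_trajectory],
                    "iterations": sol.iterations,
                    "converged": sol.converged,
                }
                _dump_json(record, run_dir / "run_record.json")
                manifest["runs"][f"{cond}_{tp_label}"] = record

                stage = f"graphs[{cond},{tp_label}]"
                for kind in config.graph_kinds:
                    build = build_reaction_graph if kind == "reaction" else build_gene_graph
                    cg = build(clamped, sol, currency=config.currency, zero_tol=config.zero_tol)
                    graphs[(cond, tp_label, kind)] = cg
                    write_graphml(cg, run_dir / f"{kind}_graph.graphml")
                    write_edge_list(cg, run_dir / f"{kind}_edges.tsv")
                    write_node_table(cg, run_dir / f"{kind}_nodes.tsv")

        conditions = list(config.expression_paths)
        for tp_label in config.constraint_sets:
            stage = f"compare[{tp_label}]"
            if len(conditions) != 2:
                logger.warning(
                    "comparison needs exactly 2 conditions, got %d; skipping", len(conditions)
                )
                break
            ca, cb = conditions
            cmp_dir = out / f"compare_{tp_label}"
            cmp_dir.mkdir(exist_ok=True)
            reports = {}
            for kind in config.graph_kinds:
                ga = graphs[(ca, tp_label, kind)]
                gb = graphs[(cb, tp_label, kind)]
                report = comparison_report(ga, gb, top_k=config.top_k)
                reports[kind] = report
                ref = merge_reference(ga, gb)
                write_reference_graphml(
                    ref, rewiring_scores(ref), cmp_dir / f"reference_{kind}.graphml"
                )
            _dump_json(reports, cmp_dir / "comparison.json")
            fc = classify_flux_changes(
                solutions[(ca, tp_label)],
                solutions[(cb, tp_label)],
                fc_threshold=config.fc_threshold,
                active_tol=config.fit_options.active_tol,
            )
            fc_report = {
                "labels": {"A": ca, "B": cb},
                "counts": fc.counts,
                "opposite_direction": sorted(
                    rid for rid, rec in fc.records.items() if rec.opposite_direction
                ),
            }
            _dump_json(fc_report, cmp_dir / "flux_changes.json")
            manifest["comparisons"][tp_label] = {
                "node_membership_counts": {
                    kind: reports[kind]["node_membership_counts"] for kind in reports
                },
                "flux_change_counts": fc.counts,
            }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _dump_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage} failed: {exc}") from exc

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["artifacts"][str(p.relative_to(out))] = _sha256(p)
    manifest["wall_time_s"] = round(time.time() - t0, 3)
    _dump_json({k: v for k, v in manifest.items() if k != "wall_time_s"}, out / "manifest.json")
    return manifest


def planted_recovery_trial(
    seed: int,
    n_reactions: int = 24,
    noise_sd_frac: float = 0.05,
    fit_options: FitOptions | None = None,
) -> dict:
    """One end-to-end knockout-recovery experiment on a random toy network.

    Generates a seeded toy model with ground-truth fluxes, plants a reaction
    knockout (expressed as zeroed gene expression in condition B), fits both
    conditions, builds reaction graphs, and checks how many of the planted
    condition-A-only nodes and expected rewired neighbours the differential
    comparison recovers. Returns the per-trial tallies.
    """
    import numpy as np

    from .flux_fit import InfeasibleModelError
    from .network_compare import merge_reference, rewiring_scores
    from .synthetic_data import ToyGemSpec, make_condition_pair, make_toy_gem

    toy = make_toy_gem(ToyGemSpec(n_reactions=n_reactions, seed=seed))
    rng = np.random.default_rng(seed + 10007)
    candidates = [r.id for r in toy.model.reactions if r.gpr is not None]
    rng.shuffle(candidates)
    pair = None
    for ko in candidates:
        try:
            pa, pb, expected = make_condition_pair(
                toy.model, toy.v_true, [ko], seed=seed,
                noise_sd_frac=noise_sd_frac, currency=toy.currency_ids,
            )
        except InfeasibleModelError:
            continue
        if expected["a_only_nodes"]:
            pair = (pa, pb, expected)
            break
    if pair is None:
        raise RuntimeError(f"no reroutable knockout found for seed {seed}")
    pa, pb, expected = pair

    opts = fit_options or FitOptions()
    sols = {}
    for prof in (pa, pb):
        data = map_to_reactions(toy.model, prof)
        sols[prof.condition_label] = fit_fluxes(toy.model, data, opts)
    ga = build_reaction_graph(toy.model, sols["A"], currency=toy.currency_ids)
    gb = build_reaction_graph(toy.model, sols["B"], currency=toy.currency_ids)
    ref = merge_reference(ga, gb)
    rew = rewiring_scores(ref)
    planted = expected["a_only_nodes"]
    rewired = expected["expected_rewired"]
    return {
        "knockout": expected["knockout_reactions"],
        "planted_nodes": planted,
        "found_nodes": [n for n in planted if ref.node_membership.get(n) == "A_only"],
        "expected_rewired": rewired,
        "found_rewired": [n for n in rewired if rew.scores.get(n, 0.0) >= 0.25],
    }
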