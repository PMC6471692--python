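"""Group-level expression summaries and their mapping onto reactions.

Each condition (e.g. lean vs obese) is summarized as a per-gene mean and
standard deviation over the group's samples. Those summaries are pushed
through each reaction's GPR rule to produce a per-reaction expression level
``d`` (the fit target) and a weight ``w`` (reciprocal dispersion), so that
precisely measured genes pull harder on the flux fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gem_io import GprTree, MetabolicModel

logger = logging.getLogger("fluxweaver")

#: smallest SD used when forming weights, in expression units
SD_FLOOR = 1e-6

GPR_POLICIES = ("min_sum", "min_max", "min_mean")


@dataclass(frozen=True)
class GeneRecord:
    gene: str
    mean: float
    sd: float


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-gene mean/SD summary for one condition group."""

    condition_label: str
    records: dict[str, GeneRecord]

    def __post_init__(self):
        for g, rec in self.records.items():
            if not math.isfinite(rec.mean):
                raise ValueError(f"gene {g!r}: non-finite mean")
            if rec.sd < 0 or not math.isfinite(rec.sd):
                raise ValueError(f"gene {g!r}: sd must be finite and >= 0")

    @property
    def genes(self) -> set[str]:
        return set(self.records)


@dataclass(frozen=True)
class ReactionRecord:
    reaction_id: str
    d: float = 0.0
    sd: float = 0.0
    w: float = 0.0
    has_data: bool = False


@dataclass(frozen=True)
class ReactionData:
    """Expression-derived per-reaction data values and weights."""

    condition_label: str
    records: dict[str, ReactionRecord]

    def data_reactions(self) -> list[str]:
        return [rid for rid, rec in self.records.items() if rec.has_data]


def read_expression_table(path, condition_label: str | None = None) -> ExpressionProfile:
    """Read a TSV/CSV with columns gene, mean, sd into a profile.

    Duplicate gene rows are collapsed by averaging both mean and sd (with a
    logged warning). Negative means are clamped to zero, negative sds are a
    validation error.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = {"gene", "mean", "sd"} - set(df.columns)
    if missing:
        raise ValueError(f"expression table {path} missing columns {sorted(missing)}")
    if (df["sd"] < 0).any():
        bad = df.loc[df["sd"] < 0, "gene"].tolist()
        raise ValueError(f"negative sd for genes {bad}")
    dup = df["gene"].duplicated()
    if dup.any():
        logger.warning(
            "expression table %s: %d duplicate gene rows collapsed by averaging",
            path, int(dup.sum()),
        )
        df = df.groupby("gene", as_index=False)[["mean", "sd"]].mean()
    records = {}
    for row in df.itertuples(index=False):
        mean = float(row.mean)
        if mean < 0:
            logger.warning("gene %s: negative mean %.4g clamped to 0", row.gene, mean)
            mean = 0.0
        records[str(row.gene)] = GeneRecord(str(row.gene), mean, float(row.sd))
    label = condition_label or str(path)
    return ExpressionProfile(condition_label=label, records=records)


def write_expression_table(profile: ExpressionProfile, path) -> None:
    rows = [
        {"gene": g, "mean": repr(rec.mean), "sd": repr(rec.sd)}
        for g, rec in sorted(profile.records.items())
    ]
    pd.DataFrame(rows, columns=["gene", "mean", "sd"]).to_csv(path, sep="\t", index=False)


def summarize_group(
    sample_values: pd.DataFrame, group_mask, condition_label: str = "group"
) -> ExpressionProfile:
    """Arithmetic mean and sample SD (n-1) per gene over the masked samples.

    ``sample_values`` is genes x samples; ``group_mask`` selects columns.
    Groups of fewer than two samples are rejected (SD undefined).
    """
    mask = np.asarray(group_mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("group must contain at least 2 samples to define an SD")
    sub = sample_values.loc[:, mask]
    means = sub.mean(axis=1)
    sds = sub.std(axis=1, ddof=1)
    records = {
        str(g): GeneRecord(str(g), float(means[g]), float(sds[g]))
        for g in sample_values.index
    }
    return ExpressionProfile(condition_label=condition_label, records=records)


def _evaluate_gpr(
    node: GprTree, profile: ExpressionProfile, policy: str
) -> tuple[float, float] | None:
    """Evaluate (value, sd) for a GPR node; None where undefined.

    AND takes the minimum of its children (complex limited by the scarcest
    subunit), propagating the SD of the child attaining the minimum; an AND
    with any unmeasured child is undefined. OR combines isoenzyme branches by
    sum (default), max, or mean; unmeasured branches are dropped, and the SD
    combines as root-sum-of-squares (for max: the winning branch's sd).
    """
    if node.op == "leaf":
        rec = profile.records.get(node.gene)
        if rec is None:
            return None
        return max(rec.mean, 0.0), rec.sd
    vals = [_evaluate_gpr(c, profile, policy) for c in node.children]
    if node.op == "and":
        if any(v is None for v in vals):
            return None
        return min(vals, key=lambda t: t[0])
    vals = [v for v in vals if v is not None]
    if not vals:
        return None
    if policy == "min_sum":
        return sum(v for v, _ in vals), math.sqrt(sum(s * s for _, s in vals))
    if policy == "min_max":
        return max(vals, key=lambda t: t[0])
    if policy == "min_mean":
        k = len(vals)
        return (sum(v for v, _ in vals) / k,
                math.sqrt(sum(s * s for _, s in vals)) / k)
    raise ValueError(f"unknown GPR policy {policy!r}; choose from {GPR_POLICIES}")


def map_to_reactions(
    model: MetabolicModel,
    profile: ExpressionProfile,
    policy: str = "min_sum",
    sd_floor: float = SD_FLOOR,
) -> ReactionData:
    """Push per-gene expression through GPR rules to per-reaction data.

    Reactions with no GPR, or whose GPR cannot be evaluated from the measured
    genes, get ``has_data=False``. Weights are ``1/max(sd, sd_floor)``.
    """
    if not (model.genes & profile.genes):
        logger.warning(
            "no overlap between model genes and profile %s; all reactions unmeasured",
            profile.condition_label,
        )
    records = {}
    for r in model.reactions:
        out = None
        if r.gpr is not None:
            out = _evaluate_gpr(r.gpr, profile, policy)
        if out is None:
            records[r.id] = ReactionRecord(r.id)
        else:
            d, sd = out
            records[r.id] = ReactionRecord(
                r.id, d=d, sd=sd, w=1.0 / max(sd, sd_floor), has_data=True
            )
    return ReactionData(condition_label=profile.condition_label, records=records)


def write_reaction_data(data: ReactionData, path) -> None:
    rows = [
        {
            "reaction_id": rid,
            "d": repr(rec.d),
            "sd": repr(rec.sd),
            "w": repr(rec.w),
            "has_data": str(rec.has_data).lower(),
        }
        for rid, rec in data.records.items()
    ]
    pd.DataFrame(rows, columns=["reaction_id", "d", "sd", "w", "has_data"]).to_csv(
        path, sep="\t", index=False
    )
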