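"""Data-driven steady-state flux fitting (objective-free simulation).

Instead of maximizing a biomass objective as in flux balance analysis, the
fit finds a steady-state flux distribution whose activity pattern agrees as
closely as possible with expression-derived reaction data. The realization is
a weighted L1 fit: reversible reactions are split into non-negative forward/
backward components, the per-reaction throughput ``t = v+ + v-`` is matched
to the (scaled) expression value ``d`` under mass balance and bounds, and the
data scale is re-estimated between solves until the rank correlation between
fluxes and expression stops improving. Among LP optima a deterministic second
stage picks the parsimonious (minimum total throughput) or least-squares
solution.

All fluxes are in umol 100g^-1 min^-1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from scipy.stats import pearsonr, spearmanr

from .expression import ReactionData
from .gem_io import MetabolicModel

logger = logging.getLogger("fluxweaver")


@dataclass(frozen=True)
class FitOptions:
    """Tunables for the iterative weighted L1 flux fit."""

    rho_tol: float = 1e-4
    max_iter: int = 25
    steady_tol: float = 1e-6
    lp_tol: float = 1e-9
    active_tol: float = 1e-6
    tiebreak: str = "throughput"  # or "least_squares"
    correlation: str = "spearman"  # or "pearson"
    #: "none": expression data are taken as already on the flux scale and the
    #: iterative rescale adapts any magnitude mismatch; "median_range": a
    #: one-off pre-scale matches the median data value to the median of the
    #: data reactions' achievable flux-range midpoints, which makes the fit
    #: exactly invariant to a global rescaling of the data.
    data_scaling: str = "none"

    def __post_init__(self):
        for name in ("rho_tol", "steady_tol", "lp_tol", "active_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tiebreak not in ("throughput", "least_squares"):
            raise ValueError(f"unknown tiebreak {self.tiebreak!r}")
        if self.correlation not in ("spearman", "pearson"):
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.data_scaling not in ("none", "median_range"):
            raise ValueError(f"unknown data_scaling {self.data_scaling!r}")


@dataclass(frozen=True)
class FluxConstraintSet:
    """Measured exchange-flux clamps for one time point (e.g. tp4/tp5)."""

    label: str
    entries: dict[str, tuple[float, float]]

    def __post_init__(self):
        for rid, (lo, hi) in self.entries.items():
            if lo > hi:
                raise ValueError(f"constraint on {rid!r}: lower {lo} > upper {hi}")


@dataclass
class FluxSolution:
    """A fitted steady-state flux vector plus fit provenance."""

    model: MetabolicModel
    fluxes: dict[str, float]
    throughputs: dict[str, float]
    objective: float
    rho: float
    rho_trajectory: list[float]
    iterations: int
    converged: bool
    constraint_label: str = ""
    condition_label: str = ""
    data_values: dict[str, float] = field(default_factory=dict)

    def flux_vector(self) -> np.ndarray:
        return np.array([self.fluxes[r.id] for r in self.model.reactions])

    def steady_state_residual(self) -> float:
        S, _, _ = self.model.stoichiometric_matrix()
        if S.size == 0:
            return 0.0
        return float(np.max(np.abs(S @ self.flux_vector())))


class InfeasibleModelError(RuntimeError):
    pass


def apply_flux_constraints(
    model: MetabolicModel, constraints: FluxConstraintSet
) -> MetabolicModel:
    """Return a copy of the model with measured reactions' bounds clamped."""
    known = set(model.reaction_ids)
    unknown = sorted(set(constraints.entries) - known)
    if unknown:
        raise KeyError(f"constraint set {constraints.label!r} references unknown reactions {unknown}")
    return model.with_bounds(dict(constraints.entries))


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

def _split_bounds(lb: float, ub: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Bounds for the forward/backward components of v = v+ - v-."""
    return (max(0.0, lb), max(0.0, ub)), (max(0.0, -ub), max(0.0, -lb))


def feasible_flux_range(model: MetabolicModel, rid: str) -> tuple[float, float]:
    """Achievable net-flux range of one reaction under S v = 0 and bounds."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    j = rxn_ids.index(rid)
    n = len(rxn_ids)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    A_eq = S if S.shape[0] else None
    b_eq = np.zeros(S.shape[0]) if S.shape[0] else None
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(n)
        c[j] = sign
        res = scipy.optimize.linprog(
            c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs"
        )
        if not res.success:
            raise InfeasibleModelError(f"flux range of {rid!r}: {res.message}")
        out.append(float(res.x[j]))
    vmin, vmax = min(out), max(out)
    return vmin, vmax


def _throughput_midpoint(vmin: float, vmax: float) -> float:
    """Midpoint of the achievable single-direction throughput range."""
    t_hi = max(abs(vmin), abs(vmax))
    t_lo = 0.0 if vmin <= 0.0 <= vmax else min(abs(vmin), abs(vmax))
    return 0.5 * (t_lo + t_hi)


def _initial_scale(model: MetabolicModel, data: ReactionData, data_ids: list[str]) -> float:
    mids = [_throughput_midpoint(*feasible_flux_range(model, rid)) for rid in data_ids]
    d_med = float(np.median([data.records[rid].d for rid in data_ids]))
    m_med = float(np.median(mids))
    if d_med <= 0 or m_med <= 0:
        return 1.0
    return m_med / d_med


class _SplitLP:
    """Weighted L1 fit LP over split fluxes [v+, v-, r]."""

    def __init__(self, model: MetabolicModel, data: ReactionData):
        self.model = model
        self.n = len(model.reactions)
        S, _, _ = model.stoichiometric_matrix()
        self.S = S
        self.data_ids = [rid for rid in model.reaction_ids if data.records[rid].has_data]
        self.data_idx = np.array(
            [model.reaction_ids.index(rid) for rid in self.data_ids], dtype=int
        )
        self.w = np.array([data.records[rid].w for rid in self.data_ids])
        self.d = np.array([data.records[rid].d for rid in self.data_ids])
        self.m = len(self.data_ids)

        lo, hi = [], []
        for r in model.reactions:
            (plo, phi), (mlo, mhi) = _split_bounds(r.lower_bound, r.upper_bound)
            lo.append((plo, mlo))
            hi.append((phi, mhi))
        self.plus_bounds = [(l[0], h[0]) for l, h in zip(lo, hi)]
        self.minus_bounds = [(l[1], h[1]) for l, h in zip(lo, hi)]

        n, m = self.n, self.m
        # mass balance: S v+ - S v- = 0
        if S.shape[0]:
            self.A_eq = sp.hstack(
                [sp.csr_matrix(S), -sp.csr_matrix(S), sp.csr_matrix((S.shape[0], m))]
            ).tocsr()
            self.b_eq = np.zeros(S.shape[0])
        else:
            self.A_eq = None
            self.b_eq = None
        # residual constraints: t_j - r_j <= dhat_j ; -t_j - r_j <= -dhat_j
        T = sp.lil_matrix((m, 2 * n + m))
        for k, j in enumerate(self.data_idx):
            T[k, j] = 1.0
            T[k, n + j] = 1.0
        T = T.tocsr()
        R = sp.hstack([sp.csr_matrix((m, 2 * n)), sp.identity(m, format="csr")])
        self.A_resid = sp.vstack([T - R, -T - R]).tocsr()
        self.T = T

    def bounds(self):
        return (
            self.plus_bounds
            + self.minus_bounds
            + [(0.0, None)] * self.m
        )

    def solve(self, dhat: np.ndarray, extra_ub=None, objective=None):
        n, m = self.n, self.m
        c = np.zeros(2 * n + m) if objective is None else objective
        if objective is None:
            c[2 * n:] = self.w
        A_ub = self.A_resid
        b_ub = np.concatenate([dhat, -dhat])
        if extra_ub is not None:
            A_extra, b_extra = extra_ub
            A_ub = sp.vstack([A_ub, A_extra]).tocsr()
            b_ub = np.concatenate([b_ub, b_extra])
        res = scipy.optimize.linprog(
            c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=self.A_eq,
            b_eq=self.b_eq,
            bounds=self.bounds(),
            method="highs",
        )
        if not res.success:
            raise InfeasibleModelError(_diagnose_infeasibility(self.model, res))
        return res

    def throughput(self, x: np.ndarray) -> np.ndarray:
        n = self.n
        return x[:n] + x[n:2 * n]

    def net_flux(self, x: np.ndarray) -> np.ndarray:
        n = self.n
        return x[:n] - x[n:2 * n]


def _diagnose_infeasibility(model: MetabolicModel, res) -> str:
    msg = f"flux fit LP failed: {res.message}"
    # cheap check for directly conflicting bound pairs on a shared metabolite
    for r in model.reactions:
        if r.lower_bound > r.upper_bound:
            return msg + f" (reaction {r.id!r} has lower > upper bound)"
    return msg


def flux_correlation(
    throughputs, data_values, method: str = "spearman"
) -> float:
    """Rank (or Pearson) correlation between flux throughput and expression.

    Requires at least three data-carrying reactions; ties get average ranks.
    """
    t = np.asarray(throughputs, dtype=float)
    d = np.asarray(data_values, dtype=float)
    if t.size < 3:
        raise ValueError("correlation undefined for fewer than 3 data-carrying reactions")
    if np.allclose(t, t[0]) or np.allclose(d, d[0]):
        return 0.0
    if method == "pearson":
        return float(pearsonr(t, d).statistic)
    return float(spearmanr(t, d).statistic)


def fit_fluxes(
    model: MetabolicModel,
    data: ReactionData,
    opts: FitOptions = FitOptions(),
    constraint_label: str = "",
) -> FluxSolution:
    """Fit a steady-state flux distribution to expression-derived data.

    Iterates weighted L1 solves with a rescaling of the data vector between
    rounds (a weighted least-squares match of the data scale to the current
    throughputs), stopping when the flux-expression correlation stabilizes.
    A lexicographic second stage resolves degenerate optima.
    """
    lp = _SplitLP(model, data)
    if lp.m == 0:
        raise ValueError("no data-carrying reactions; nothing to fit")

    s = _initial_scale(model, data, lp.data_ids) if opts.data_scaling == "median_range" else 1.0
    dhat = lp.d * s

    rho_traj: list[float] = []
    res = None
    converged = False
    def snap(t):
        # quantize away LP solver noise so genuine ties rank as ties
        return np.round(t / opts.active_tol) * opts.active_tol

    for it in range(1, opts.max_iter + 1):
        res = lp.solve(dhat)
        t = lp.throughput(res.x)[lp.data_idx]
        if lp.m < 3:
            # correlation (and hence the convergence signal) is undefined:
            # the single weighted L1 solve is the answer
            rho_traj.append(float("nan"))
            converged = True
            break
        rho = flux_correlation(snap(t), lp.d, opts.correlation)
        rho_traj.append(rho)
        if len(rho_traj) >= 2 and abs(rho_traj[-1] - rho_traj[-2]) < opts.rho_tol:
            converged = True
            break
        denom = float(np.sum(lp.w * dhat**2))
        if denom <= 0:
            break
        alpha = float(np.sum(lp.w * t * dhat)) / denom
        if alpha <= 0:
            break
        dhat = dhat * alpha

    objective = float(res.fun)
    x = _tiebreak_stage(lp, dhat, objective, res.x, opts)

    v = lp.net_flux(x)
    t_all = lp.throughput(x)
    two_way = np.minimum(x[: lp.n], x[lp.n: 2 * lp.n])
    if np.any(two_way > opts.active_tol):
        worst = model.reaction_ids[int(np.argmax(two_way))]
        logger.warning(
            "residual two-way flux above tolerance on %s (%.3g)", worst, float(two_way.max())
        )
    t_data = t_all[lp.data_idx]
    rho_final = (
        flux_correlation(snap(t_data), lp.d, opts.correlation) if lp.m >= 3 else float("nan")
    )
    sol = FluxSolution(
        model=model,
        fluxes={rid: float(v[j]) for j, rid in enumerate(model.reaction_ids)},
        throughputs={rid: float(t_all[j]) for j, rid in enumerate(model.reaction_ids)},
        objective=objective,
        rho=rho_final,
        rho_trajectory=rho_traj,
        iterations=len(rho_traj),
        converged=converged,
        constraint_label=constraint_label,
        condition_label=data.condition_label,
        data_values={rid: float(data.records[rid].d) for rid in lp.data_ids},
    )
    resid = sol.steady_state_residual()
    if resid > opts.steady_tol:
        raise InfeasibleModelError(
            f"steady-state residual {resid:.3g} exceeds tolerance {opts.steady_tol:.3g}"
        )
    return sol


def _tiebreak_stage(lp: _SplitLP, dhat, objective, x0, opts: FitOptions) -> np.ndarray:
    """Pick a deterministic point on the optimal face of the final LP."""
    n, m = lp.n, lp.m
    slack = opts.lp_tol * max(1.0, abs(objective))
    # cap the weighted L1 objective at its optimum
    cap_row = sp.csr_matrix(
        (lp.w, (np.zeros(m, dtype=int), np.arange(2 * n, 2 * n + m))),
        shape=(1, 2 * n + m),
    )
    cap = (cap_row, np.array([objective + slack]))
    if opts.tiebreak == "throughput":
        c = np.zeros(2 * n + m)
        c[: 2 * n] = 1.0
        res = lp.solve(dhat, extra_ub=cap, objective=c)
        return res.x

    # least-squares tiebreak: minimize sum_data (t_j - dhat_j)^2 on the
    # optimal face; solved with SLSQP from the LP vertex (small models only).
    T = lp.T.toarray()
    A_eq = lp.A_eq.toarray() if lp.A_eq is not None else np.zeros((0, 2 * n + m))
    w = lp.w

    def fun(x):
        resid = T @ x - dhat
        return float(resid @ resid)

    def jac(x):
        return 2.0 * T.T @ (T @ x - dhat)

    cons = [
        {"type": "eq", "fun": lambda x: A_eq @ x, "jac": lambda x: A_eq},
        {
            "type": "ineq",
            "fun": lambda x: (objective + slack + 1e-9) - w @ np.abs(T @ x - dhat),
        },
    ]
    bounds = [(lo, hi if hi is not None else np.inf) for lo, hi in lp.bounds()]
    res = scipy.optimize.minimize(
        fun, x0, jac=jac, bounds=bounds, constraints=cons, method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    x = res.x if res.success else x0
    # keep feasibility: fall back to the LP vertex if SLSQP drifted off S v = 0
    if A_eq.size and np.max(np.abs(A_eq @ x)) > opts.steady_tol:
        return x0
    return x


# ---------------------------------------------------------------------------
# Differential flux classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluxChangeRecord:
    reaction_id: str
    v_a: float
    v_b: float
    opposite_direction: bool
    log2_ratio: float | None
    category: str  # lower_in_B | higher_in_B | unchanged | inactive


@dataclass(frozen=True)
class FluxComparison:
    records: dict[str, FluxChangeRecord]
    counts: dict[str, int]
    label_a: str = "A"
    label_b: str = "B"


def classify_flux_changes(
    sol_a: FluxSolution,
    sol_b: FluxSolution,
    fc_threshold: float = 2.0,
    active_tol: float = 1e-6,
) -> FluxComparison:
    """Per-reaction comparison of two conditions' fluxes.

    Flags reversible reactions running in opposite directions, and classifies
    active reactions by the log2 ratio of flux magnitudes (B over A) against
    a fold-change threshold. Reactions inactive in either condition are
    "inactive".
    """
    ids_a, ids_b = set(sol_a.fluxes), set(sol_b.fluxes)
    if ids_a != ids_b:
        raise ValueError("flux solutions are defined on different reaction sets")
    log_thr = math.log2(fc_threshold)
    records = {}
    counts = {"lower_in_B": 0, "higher_in_B": 0, "unchanged": 0, "inactive": 0}
    for rid in sol_a.model.reaction_ids:
        va, vb = sol_a.fluxes[rid], sol_b.fluxes[rid]
        both_active = abs(va) > active_tol and abs(vb) > active_tol
        opposite = both_active and (math.copysign(1, va) * math.copysign(1, vb) < 0)
        if both_active:
            lr = math.log2(abs(vb) / abs(va))
            if lr <= -log_thr:
                cat = "lower_in_B"
            elif lr >= log_thr:
                cat = "higher_in_B"
            else:
                cat = "unchanged"
        else:
            lr = None
            cat = "inactive"
        counts[cat] += 1
        records[rid] = FluxChangeRecord(rid, va, vb, opposite, lr, cat)
    return FluxComparison(
        records=records,
        counts=counts,
        label_a=sol_a.condition_label,
        label_b=sol_b.condition_label,
    )
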