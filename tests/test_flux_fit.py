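import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from fluxweaver import (
    FitOptions,
    FluxConstraintSet,
    apply_flux_constraints,
    classify_flux_changes,
    fit_fluxes,
    fixture_model,
    flux_correlation,
    make_expression_from_flux,
    make_toy_gem,
    map_to_reactions,
    solution_from_fluxes,
)
from fluxweaver.flux_fit import InfeasibleModelError, feasible_flux_range
from fluxweaver.synthetic_data import ToyGemSpec
from conftest import two_sink_profile


def _grid_search_objective(da, db, w=1.0, step=0.01):
    """Brute-force oracle for the two-sink toy: v(Ra) in [0,10], v(Rb)=10-v(Ra)."""
    grid = np.arange(0.0, 10.0 + step, step)
    obj = w * np.abs(grid - da) + w * np.abs((10.0 - grid) - db)
    return float(obj.min())


class TestApplyConstraints:
    def test_clamp_replaces_bounds(self, toy_model):
        clamped = apply_flux_constraints(
            toy_model, FluxConstraintSet("tp4", {"R_in": (10.0, 10.0)})
        )
        assert clamped.reaction("R_in").lower_bound == 10.0
        assert clamped.reaction("R_in").upper_bound == 10.0
        assert clamped.reaction("R1").upper_bound == toy_model.reaction("R1").upper_bound

    def test_empty_set_is_identity(self, toy_model):
        assert apply_flux_constraints(toy_model, FluxConstraintSet("tp", {})) == toy_model

    def test_mean_pm_sd_interval_set_verbatim(self, toy_model):
        mean, sd = 7.0, 2.5
        clamped = apply_flux_constraints(
            toy_model, FluxConstraintSet("tp", {"R_in": (mean - sd, mean + sd)})
        )
        assert clamped.reaction("R_in").lower_bound == 4.5
        assert clamped.reaction("R_in").upper_bound == 9.5

    def test_unknown_reaction_listed(self, toy_model):
        with pytest.raises(KeyError, match="nope"):
            apply_flux_constraints(toy_model, FluxConstraintSet("tp", {"nope": (0, 1)}))

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            FluxConstraintSet("tp", {"R_in": (5.0, 1.0)})


class TestFitTwoSinkToy:
    def test_unequal_data_fits_exactly(self, lp_toy):
        data = map_to_reactions(lp_toy, two_sink_profile(8.0, 2.0))
        sol = fit_fluxes(lp_toy, data)
        assert sol.objective == pytest.approx(0.0, abs=1e-6)
        assert sol.fluxes["Ra"] == pytest.approx(8.0, abs=1e-3)
        assert sol.fluxes["Rb"] == pytest.approx(2.0, abs=1e-3)

    def test_equal_data_degenerate_least_squares_tiebreak(self, lp_toy):
        data = map_to_reactions(lp_toy, two_sink_profile(8.0, 8.0))
        sol = fit_fluxes(lp_toy, data, FitOptions(tiebreak="least_squares"))
        assert sol.objective == pytest.approx(6.0, abs=1e-6)
        assert sol.fluxes["Ra"] == pytest.approx(5.0, abs=1e-3)
        assert sol.fluxes["Rb"] == pytest.approx(5.0, abs=1e-3)

    @pytest.mark.parametrize("da,db", [(8.0, 2.0), (8.0, 8.0), (3.0, 12.0), (0.0, 25.0)])
    def test_lp_objective_matches_grid_oracle(self, lp_toy, da, db):
        data = map_to_reactions(lp_toy, two_sink_profile(da, db))
        sol = fit_fluxes(lp_toy, data)
        assert sol.objective == pytest.approx(_grid_search_objective(da, db), abs=1e-3)


class TestFitFixture:
    def test_noise_free_perfect_fit(self, toy_model, fitted_solution, v_true):
        assert fitted_solution.objective == pytest.approx(0.0, abs=1e-6)
        assert fitted_solution.rho == 1.0
        for rid, v in v_true.items():
            assert fitted_solution.fluxes[rid] == pytest.approx(v, abs=1e-6)

    def test_steady_state_and_bounds(self, fitted_solution):
        assert fitted_solution.steady_state_residual() <= 1e-6
        for r in fitted_solution.model.reactions:
            v = fitted_solution.fluxes[r.id]
            assert r.lower_bound - 1e-9 <= v <= r.upper_bound + 1e-9

    def test_rho_trajectory_non_decreasing(self, fitted_solution):
        traj = fitted_solution.rho_trajectory
        for prev, cur in zip(traj, traj[1:]):
            assert cur >= prev - 1e-4

    def test_no_data_raises(self, toy_model):
        from fluxweaver.expression import ExpressionProfile

        empty = ExpressionProfile("x", {})
        data = map_to_reactions(toy_model, empty)
        with pytest.raises(ValueError, match="no data-carrying"):
            fit_fluxes(toy_model, data)

    def test_infeasible_bounds_reported(self, toy_model):
        clamped = apply_flux_constraints(
            toy_model, FluxConstraintSet("bad", {"R_in": (5.0, 5.0), "R5": (8.0, 9.0)})
        )
        data = map_to_reactions(
            clamped, make_expression_from_flux(clamped, {r.id: 1.0 for r in clamped.reactions})
        )
        with pytest.raises(InfeasibleModelError):
            fit_fluxes(clamped, data)

    def test_scaling_invariance_under_median_range(self, toy_model, v_true):
        from fluxweaver.expression import ExpressionProfile, GeneRecord

        prof = make_expression_from_flux(toy_model, v_true, 0.0, seed=0)
        scaled = ExpressionProfile("x", {
            g: GeneRecord(g, 137.0 * r.mean, r.sd) for g, r in prof.records.items()
        })
        opts = FitOptions(data_scaling="median_range")
        sol1 = fit_fluxes(toy_model, map_to_reactions(toy_model, prof), opts)
        sol2 = fit_fluxes(toy_model, map_to_reactions(toy_model, scaled), opts)
        for rid in sol1.fluxes:
            assert sol2.fluxes[rid] == pytest.approx(sol1.fluxes[rid], abs=1e-6)


class TestFitRandomToys:
    @pytest.mark.parametrize("seed", range(10))
    def test_steady_state_and_bounds_hold(self, seed):
        toy = make_toy_gem(ToyGemSpec(n_reactions=20, seed=seed))
        prof = make_expression_from_flux(toy.model, toy.v_true, 0.05, seed=seed)
        sol = fit_fluxes(toy.model, map_to_reactions(toy.model, prof))
        assert sol.steady_state_residual() <= 1e-6
        for r in toy.model.reactions:
            assert r.lower_bound - 1e-6 <= sol.fluxes[r.id] <= r.upper_bound + 1e-6

    def test_parameter_recovery_noise_free(self):
        # measured over the data-carrying reactions: unmeasured exchanges are
        # only determined up to alternative optima
        toy = make_toy_gem(ToyGemSpec(n_reactions=25, seed=3))
        prof = make_expression_from_flux(toy.model, toy.v_true, 0.0, seed=0)
        data = map_to_reactions(toy.model, prof)
        ids = data.data_reactions()
        sol = fit_fluxes(toy.model, data)
        rho = spearmanr([sol.throughputs[r] for r in ids],
                        [abs(toy.v_true[r]) for r in ids]).statistic
        assert rho >= 0.99

    def test_parameter_recovery_ten_percent_noise(self):
        toy = make_toy_gem(ToyGemSpec(n_reactions=25, seed=3))
        rhos = []
        for seed in range(20):
            prof = make_expression_from_flux(toy.model, toy.v_true, 0.10, seed=seed)
            data = map_to_reactions(toy.model, prof)
            ids = data.data_reactions()
            truth = [abs(toy.v_true[r]) for r in ids]
            sol = fit_fluxes(toy.model, data)
            rhos.append(spearmanr([sol.throughputs[r] for r in ids], truth).statistic)
        assert float(np.mean(rhos)) >= 0.9


class TestFluxCorrelation:
    @pytest.mark.parametrize("t,d,expected", [
        ((1, 2, 3), (10, 20, 30), 1.0),
        ((1, 2, 3), (30, 20, 10), -1.0),
        ((1, 2, 3), (20, 10, 30), 0.5),
    ])
    def test_spearman_values(self, t, d, expected):
        assert flux_correlation(t, d) == pytest.approx(expected)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            flux_correlation((1, 2), (1, 2))

    def test_pearson_option(self):
        assert flux_correlation((1, 2, 4), (2, 4, 8), method="pearson") == pytest.approx(1.0)


class TestClassifyFluxChanges:
    def _solutions(self, toy_model, va, vb):
        return (solution_from_fluxes(toy_model, va, "lean"),
                solution_from_fluxes(toy_model, vb, "obese"))

    def test_fold_change_categories(self, toy_model, v_true):
        vb = dict(v_true)
        vb["R2"] = v_true["R2"] / 4      # log2 ratio -2 -> lower
        vb["R3"] = v_true["R3"] * 4      # +2 -> higher
        vb["R5"] = v_true["R5"]          # 0 -> unchanged
        vb["R_atp"] = 0.0                # inactive
        sa, sb = self._solutions(toy_model, v_true, vb)
        cmp = classify_flux_changes(sa, sb, fc_threshold=2.0)
        assert cmp.records["R2"].category == "lower_in_B"
        assert cmp.records["R2"].log2_ratio == pytest.approx(-2.0)
        assert cmp.records["R3"].category == "higher_in_B"
        assert cmp.records["R5"].category == "unchanged"
        assert cmp.records["R_atp"].category == "inactive"
        assert sum(cmp.counts.values()) == len(toy_model.reactions)

    def test_opposite_direction_flag(self, toy_model, v_true):
        vb = dict(v_true)
        vb["R4"] = -2.0
        sa, sb = self._solutions(toy_model, v_true, vb)
        cmp = classify_flux_changes(sa, sb)
        flagged = [rid for rid, rec in cmp.records.items() if rec.opposite_direction]
        assert flagged == ["R4"]

    def test_mismatched_reaction_sets_rejected(self, toy_model, v_true, lp_toy):
        sa = solution_from_fluxes(toy_model, v_true)
        sb = solution_from_fluxes(lp_toy, {"R_in": 10.0, "Ra": 5.0, "Rb": 5.0})
        with pytest.raises(ValueError, match="different reaction sets"):
            classify_flux_changes(sa, sb)


def test_feasible_flux_range_on_fixture(toy_model):
    assert feasible_flux_range(toy_model, "R_in") == pytest.approx((0.0, 10.0))
    # R4's net flux is pinned to R2's by the balance of metabolite C
    assert feasible_flux_range(toy_model, "R4") == pytest.approx((0.0, 10.0))
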