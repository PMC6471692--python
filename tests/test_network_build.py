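import networkx as nx
import pytest

from fluxweaver import (
    build_gene_graph,
    build_reaction_graph,
    make_toy_gem,
    orient_active,
    read_graphml,
    solution_from_fluxes,
    write_graphml,
)
from fluxweaver.network_build import currency_metabolite_ids, write_edge_list
from fluxweaver.synthetic_data import ToyGemSpec
from conftest import FIXTURE_CURRENCY

EXPECTED_RXN_EDGES = {
    ("R_in", "R1"), ("R1", "R2"), ("R1", "R3"),
    ("R2", "R4"), ("R3", "R5"), ("R4", "R5"),
}
EXPECTED_GENE_EDGES = {
    ("G1", "G2"), ("G1", "G3"), ("G1", "G4"),
    ("G2", "G5"), ("G3", "G5"),
    ("G4", "G6"), ("G4", "G7"), ("G5", "G6"), ("G5", "G7"),
}


class TestOrientActive:
    def test_ground_truth_all_active_forward(self, toy_model, truth_solution):
        oriented = orient_active(toy_model, truth_solution)
        assert set(oriented) == set(toy_model.reaction_ids)
        assert oriented["R4"] == {"C": -1.0, "D": 1.0}

    def test_negative_flux_flips_orientation(self, toy_model, v_true):
        flipped = dict(v_true)
        flipped["R4"] = -6.0
        sol = solution_from_fluxes(toy_model, flipped)
        assert orient_active(toy_model, sol)["R4"] == {"C": 1.0, "D": -1.0}

    def test_zero_flux_reaction_dropped(self, toy_model, v_true):
        v = dict(v_true)
        v["R3"] = 0.0
        sol = solution_from_fluxes(toy_model, v)
        assert "R3" not in orient_active(toy_model, sol)


class TestReactionGraph:
    def test_fixture_graph_matches_hand_derivation(self, toy_model, truth_solution):
        g = build_reaction_graph(toy_model, truth_solution, currency=FIXTURE_CURRENCY)
        assert g.nodes == {"R_in", "R1", "R2", "R3", "R4", "R5", "R_atp"}
        assert g.edges == EXPECTED_RXN_EDGES
        # R_atp stays as an isolated node
        assert g.graph.degree("R_atp") == 0

    def test_edge_annotates_shared_metabolite(self, toy_model, truth_solution):
        g = build_reaction_graph(toy_model, truth_solution, currency=FIXTURE_CURRENCY)
        assert g.shared_metabolites("R1", "R2") == ["B"]

    def test_empty_currency_adds_cofactor_edges(self, toy_model, truth_solution):
        g = build_reaction_graph(toy_model, truth_solution, currency=())
        assert ("R_atp", "R1") in g.edges
        assert ("R1", "R_atp") in g.edges
        assert g.edges > EXPECTED_RXN_EDGES

    def test_all_zero_flux_gives_empty_graph(self, toy_model):
        sol = solution_from_fluxes(toy_model, {r.id: 0.0 for r in toy_model.reactions})
        g = build_reaction_graph(toy_model, sol, currency=FIXTURE_CURRENCY)
        assert g.nodes == set() and g.edges == set()

    def test_no_self_edges_and_edge_soundness(self, toy_model, truth_solution):
        g = build_reaction_graph(toy_model, truth_solution, currency=FIXTURE_CURRENCY)
        oriented = orient_active(toy_model, truth_solution)
        currency = currency_metabolite_ids(toy_model, FIXTURE_CURRENCY)
        for a, b in g.edges:
            assert a != b
            assert any(
                oriented[a].get(m, 0) > 0 and oriented[b].get(m, 0) < 0
                for m in g.shared_metabolites(a, b)
                if m not in currency
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_currency_removal_monotonicity(self, seed):
        toy = make_toy_gem(ToyGemSpec(n_reactions=22, n_currency=2, seed=seed))
        sol = solution_from_fluxes(toy.model, toy.v_true)
        g_full = build_reaction_graph(toy.model, sol, currency=toy.currency_ids)
        g_less = build_reaction_graph(toy.model, sol, currency=toy.currency_ids[:2])
        assert g_less.edges >= g_full.edges
        g_none = build_reaction_graph(toy.model, sol, currency=())
        assert g_none.edges >= g_less.edges

    def test_unknown_currency_names_warned_and_ignored(self, toy_model, truth_solution, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="fluxweaver"):
            g = build_reaction_graph(
                toy_model, truth_solution, currency=("ATP", "ADP", "NOT_A_MET")
            )
        assert g.edges == EXPECTED_RXN_EDGES
        assert any("not found" in r.message for r in caplog.records)

    def test_compartment_suffix_matching(self):
        from fluxweaver.gem_io import MetaboliteRef, MetabolicModel, ReactionRef

        model = MetabolicModel("m", (
            MetaboliteRef("ATP_c", compartment="c"),
            MetaboliteRef("atp_m", compartment="m"),
            MetaboliteRef("B_c", compartment="c"),
        ), ())
        assert currency_metabolite_ids(model, ("ATP",)) == {"ATP_c", "atp_m"}


class TestGeneGraph:
    def test_fixture_gene_graph_matches_hand_expansion(self, toy_model, truth_solution):
        g = build_gene_graph(toy_model, truth_solution, currency=FIXTURE_CURRENCY)
        assert g.nodes == {f"G{i}" for i in range(1, 8)}
        assert g.edges == EXPECTED_GENE_EDGES

    def test_shared_gene_never_self_edges(self):
        from fluxweaver.gem_io import MetaboliteRef, MetabolicModel, ReactionRef, parse_gpr

        model = MetabolicModel("m", (MetaboliteRef("A"), MetaboliteRef("B")), (
            ReactionRef("Rin", stoichiometry={"A": 1.0}, upper_bound=10),
            ReactionRef("Ra", stoichiometry={"A": -1.0, "B": 1.0}, upper_bound=10,
                        gpr=parse_gpr("Gx")),
            ReactionRef("Rb", stoichiometry={"B": -1.0}, upper_bound=10,
                        gpr=parse_gpr("Gx")),
        ))
        sol = solution_from_fluxes(model, {"Rin": 1.0, "Ra": 1.0, "Rb": 1.0})
        g = build_gene_graph(model, sol, currency=())
        assert g.nodes == {"Gx"}
        assert g.edges == set()

    def test_model_without_gprs_gives_empty_gene_graph(self, lp_toy):
        from dataclasses import replace

        stripped = replace(lp_toy, reactions=tuple(
            replace(r, gpr=None) for r in lp_toy.reactions
        ))
        sol = solution_from_fluxes(stripped, {"R_in": 10.0, "Ra": 5.0, "Rb": 5.0})
        g = build_gene_graph(stripped, sol, currency=())
        assert g.nodes == set() and g.edges == set()

    @pytest.mark.parametrize("seed", range(3))
    def test_gene_edge_count_bounded_by_gpr_product(self, seed):
        toy = make_toy_gem(ToyGemSpec(n_reactions=22, gpr_complexity=3, seed=seed))
        sol = solution_from_fluxes(toy.model, toy.v_true)
        rg = build_reaction_graph(toy.model, sol, currency=toy.currency_ids)
        gg = build_gene_graph(toy.model, sol, currency=toy.currency_ids)
        bound = sum(
            len(toy.model.reaction(a).genes()) * len(toy.model.reaction(b).genes())
            for a, b in rg.edges
        )
        assert gg.graph.number_of_edges() <= bound


class TestGraphIO:
    def test_graphml_round_trip(self, toy_model, truth_solution, tmp_path):
        g = build_reaction_graph(toy_model, truth_solution, currency=FIXTURE_CURRENCY)
        path = tmp_path / "g.graphml"
        write_graphml(g, path)
        g2 = read_graphml(path)
        assert g2.nodes == g.nodes
        assert g2.edges == g.edges
        assert g2.shared_metabolites("R1", "R2") == ["B"]
        assert g2.node_kind == "reaction"

    def test_edge_list_tsv(self, toy_model, truth_solution, tmp_path):
        g = build_reaction_graph(toy_model, truth_solution, currency=FIXTURE_CURRENCY)
        path = tmp_path / "edges.tsv"
        write_edge_list(g, path)
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "source\ttarget\tshared_metabolites"
        assert len(lines) == 1 + len(g.edges)
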