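import pytest

from fluxweaver import (
    FitOptions,
    MetabolicModel,
    MetaboliteRef,
    ReactionRef,
    fit_fluxes,
    fixture_model,
    fixture_true_fluxes,
    make_expression_from_flux,
    map_to_reactions,
    parse_gpr,
    solution_from_fluxes,
)
from fluxweaver.expression import ExpressionProfile, GeneRecord

FIXTURE_CURRENCY = ("ATP", "ADP")


@pytest.fixture(scope="session")
def toy_model():
    return fixture_model()


@pytest.fixture(scope="session")
def v_true():
    return fixture_true_fluxes()


@pytest.fixture(scope="session")
def truth_solution(toy_model, v_true):
    """Ground-truth fluxes wrapped as a solution (graph-building input)."""
    return solution_from_fluxes(toy_model, v_true, condition_label="lean")


@pytest.fixture(scope="session")
def fitted_solution(toy_model, v_true):
    """Noise-free one-gene-per-branch fit on the hand fixture."""
    profile = make_expression_from_flux(toy_model, v_true, 0.0, seed=0)
    data = map_to_reactions(toy_model, profile)
    return fit_fluxes(toy_model, data)


def two_sink_model():
    """One metabolite, clamped uptake of 10, two competing sinks with genes.

    The only freedom is how the 10 units split between Ra and Rb, which makes
    every optimum checkable by a 1-D grid search.
    """
    mets = (MetaboliteRef("A", compartment="c"),)
    rxns = (
        ReactionRef("R_in", stoichiometry={"A": 1.0}, lower_bound=10.0, upper_bound=10.0),
        ReactionRef("Ra", stoichiometry={"A": -1.0}, lower_bound=0.0, upper_bound=1000.0,
                    gpr=parse_gpr("Ga")),
        ReactionRef("Rb", stoichiometry={"A": -1.0}, lower_bound=0.0, upper_bound=1000.0,
                    gpr=parse_gpr("Gb")),
    )
    return MetabolicModel("two_sink", mets, rxns)


def two_sink_profile(da: float, db: float) -> ExpressionProfile:
    return ExpressionProfile(
        "toy", {"Ga": GeneRecord("Ga", da, 1.0), "Gb": GeneRecord("Gb", db, 1.0)}
    )


@pytest.fixture()
def lp_toy():
    return two_sink_model()
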