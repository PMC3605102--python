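import pytest

from examo.expression import call_reactions
from examo.fixtures import toy_network
from examo.imat import ImatProblem
from examo.model import MetabolicModel, Reaction
from examo.preprocess import open_exchanges, trim_dead_ends


@pytest.fixture(scope="session")
def toy():
    """The raw ten-reaction toy network and its gene-expression calls."""
    return toy_network()


@pytest.fixture(scope="session")
def toy_opened(toy):
    """Toy network after exchange opening and dead-end trimming."""
    model, calls = toy
    return trim_dead_ends(open_exchanges(model)), calls


@pytest.fixture(scope="session")
def toy_problem(toy_opened):
    model, calls = toy_opened
    return ImatProblem(model, call_reactions(model, calls), eps=1.0)


@pytest.fixture
def chain_model():
    """Linear pathway: uptake -> A -> B -> biomass, with one side branch."""
    return MetabolicModel(
        [
            Reaction("EX_in", {"A": 1.0}, 0.0, 1000.0),
            Reaction("v1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("v2", {"B": -1.0, "C": 1.0}, 0.0, 1000.0),
            Reaction("branch", {"B": -1.0, "D": 1.0}, 0.0, 1000.0),
            Reaction("EX_D", {"D": -1.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"C": -1.0}, 0.0, 1000.0, is_biomass=True),
        ],
        id="chain",
    )


def to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (test-only oracle path)."""
    import cobra

    cm = cobra.Model(model.id or "model")
    mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c")
            for m in model.metabolites}
    rxns = []
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id, lower_bound=rxn.lb, upper_bound=rxn.ub)
        cr.add_metabolites({mets[mid]: coeff for mid, coeff in rxn.stoich.items()})
        rule = rxn.gpr.to_string()
        if rule:
            cr.gene_reaction_rule = rule.replace("AND", "and").replace("OR", "or")
        rxns.append(cr)
    cm.add_reactions(rxns)
    biomass = model.biomass
    if biomass is not None:
        cm.objective = biomass.id
    return cm
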