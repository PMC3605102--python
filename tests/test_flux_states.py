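"""Min-total-flux states and FBA gene essentiality."""

import numpy as np
import pytest

from examo.flux_states import (
    MinFluxProblem,
    essentiality_metrics,
    fba_max_biomass,
    minimize_total_flux,
    predict_essential_genes,
    single_gene_deletion,
)
from examo.lp import InfeasibleProblem, solve_flux_lp
from examo.model import MetabolicModel, Reaction, parse_gpr, stoichiometric_matrix

from conftest import to_cobra


def _chain(k: int, bound: float = 1000.0) -> MetabolicModel:
    """uptake -> M1 -> ... -> M_{k-1} -> biomass, k reactions in total."""
    rxns = [Reaction("u", {"M1": 1.0}, 0.0, bound)]
    for i in range(1, k - 1):
        rxns.append(Reaction(f"c{i}", {f"M{i}": -1.0, f"M{i+1}": 1.0}, 0.0, bound))
    rxns.append(Reaction("BIOMASS", {f"M{k-1}": -1.0}, 0.0, bound, is_biomass=True))
    return MetabolicModel(rxns)


@pytest.mark.parametrize("k", [2, 4, 7])
def test_chain_total_flux_closed_form(k):
    """Unit-stoichiometry chain with every reaction forced: total = k * eps."""
    model = _chain(k)
    state = minimize_total_flux(MinFluxProblem(model, set(model.reaction_ids), eps=1.0))
    assert state.total_flux == pytest.approx(k * 1.0, abs=1e-6)
    for v in state.fluxes.values():
        assert v == pytest.approx(1.0, abs=1e-6)


def test_state_invariants(toy_opened):
    model, _ = toy_opened
    state = minimize_total_flux(MinFluxProblem(model, {"r2", "r6"}, eps=1.0))
    v = np.array([state.fluxes[r.id] for r in model.reactions])
    S = stoichiometric_matrix(model)
    assert np.abs(S @ v).max() <= 1e-6 * max(1.0, np.abs(v).max())
    for rid in ("r2", "r6"):
        assert abs(state.fluxes[rid]) >= 1.0 - 1e-6
    assert state.total_flux == pytest.approx(np.abs(v).sum(), abs=1e-6)


def test_hfr_only_biomass_matches_lp_oracle():
    """With no reversible forced reactions the MILP equals a plain LP with
    the biomass lower bound fixed at eps."""
    model = _chain(5)
    state = minimize_total_flux(MinFluxProblem(model, set(), eps=1.0))
    lp = solve_flux_lp(
        model,
        {rid: 1.0 for rid in model.reaction_ids},  # all irreversible: |v| = v
        sense="min",
        extra_bounds={"BIOMASS": (1.0, 1000.0)},
    )
    assert state.total_flux == pytest.approx(lp.objective, abs=1e-6)


def test_reversible_forced_reaction_picks_one_direction(toy_opened):
    model, _ = toy_opened  # exchanges are open, so r2 is reversible
    state = minimize_total_flux(MinFluxProblem(model, {"r2"}, eps=1.0))
    assert abs(state.fluxes["r2"]) >= 1.0 - 1e-6
    assert state.directions["r2"] in (+1, -1)


def test_total_flux_monotone_in_forced_set(toy_opened):
    model, _ = toy_opened
    with_r5 = minimize_total_flux(MinFluxProblem(model, {"r2", "r5", "r6"}))
    without = minimize_total_flux(MinFluxProblem(model, {"r2", "r6"}))
    assert without.total_flux <= with_r5.total_flux + 1e-9


def test_infeasible_forced_set_names_conflict():
    model = MetabolicModel(
        [
            Reaction("EX_A", {"A": 1.0}, 0.0, 1000.0),
            Reaction("fwd", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("dead", {"C": -1.0, "D": 1.0}, 0.0, 1000.0),  # C unproducible
            Reaction("BIOMASS", {"B": -1.0}, 0.0, 1000.0, is_biomass=True),
        ]
    )
    with pytest.raises(InfeasibleProblem, match="dead"):
        minimize_total_flux(MinFluxProblem(model, {"fwd", "dead"}))


# --------------------------------------------------------------------------
# FBA and essentiality
# --------------------------------------------------------------------------


def test_fba_bound_limited_chain():
    assert fba_max_biomass(_chain(3)) == pytest.approx(1000.0)


def test_fba_unproducible_substrate_gives_zero():
    model = MetabolicModel(
        [
            Reaction("EX_A", {"A": 1.0}, -1000.0, 1000.0),
            Reaction("BIOMASS", {"Z": -1.0}, 0.0, 1000.0, is_biomass=True),
        ]
    )
    assert fba_max_biomass(model) == pytest.approx(0.0, abs=1e-9)


def test_fba_toy_grows(toy_opened):
    model, _ = toy_opened
    assert fba_max_biomass(model) > 1.0


def _gpr_chain() -> MetabolicModel:
    return MetabolicModel(
        [
            Reaction("u", {"A": 1.0}, 0.0, 1000.0),
            Reaction("iso", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, gpr=parse_gpr("g1 OR g2")),
            Reaction("cplx", {"B": -1.0, "C": 1.0}, 0.0, 1000.0, gpr=parse_gpr("g3 AND g4")),
            Reaction("BIOMASS", {"C": -1.0}, 0.0, 1000.0, is_biomass=True),
        ]
    )


def test_isoenzyme_rescues_deletion():
    growth, essential = single_gene_deletion(_gpr_chain(), "g1")
    assert growth > 0 and not essential


def test_complex_subunit_loss_is_lethal():
    growth, essential = single_gene_deletion(_gpr_chain(), "g4")
    assert growth == pytest.approx(0.0, abs=1e-9) and essential


def test_single_path_gene_essential():
    model = MetabolicModel(
        [
            Reaction("u", {"A": 1.0}, 0.0, 1000.0),
            Reaction("only", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, gpr=parse_gpr("g")),
            Reaction("BIOMASS", {"B": -1.0}, 0.0, 1000.0, is_biomass=True),
        ]
    )
    assert predict_essential_genes(model) == {"g"}


def test_unknown_gene_errors():
    with pytest.raises(ValueError, match="not in model"):
        single_gene_deletion(_gpr_chain(), "nope")


def test_gene_deletion_matches_cobra():
    """Independent oracle: cobra's single_gene_deletion on the same model."""
    from cobra.flux_analysis import single_gene_deletion as cobra_sgd

    model = _gpr_chain()
    ref = cobra_sgd(to_cobra(model))
    ref_growth = {next(iter(ids)): growth for ids, growth in
                  zip(ref["ids"], ref["growth"])}
    for gene in sorted(model.genes):
        ours, _ = single_gene_deletion(model, gene)
        assert ours == pytest.approx(ref_growth[gene], abs=1e-6), gene


def test_essentiality_metrics_counts():
    report = essentiality_metrics(
        predicted={"a", "b", "c"},
        observed={"a", "d"},
        universe={"a", "b", "c", "d", "e"},
    )
    assert (report.tp, report.fp, report.fn) == (1, 2, 1)
    assert report.sensitivity == pytest.approx(0.5)
    assert report.ppv == pytest.approx(1 / 3)
    assert report.classes == {"a": "tp", "b": "fp", "c": "fp", "d": "fn", "e": "tn"}


def test_essentiality_metrics_perfect_prediction():
    report = essentiality_metrics({"a", "b"}, {"a", "b"}, {"a", "b", "c"})
    assert report.sensitivity == 1.0 and report.ppv == 1.0


def test_essentiality_metrics_exclusion_and_undefined():
    report = essentiality_metrics(
        predicted={"a", "x"}, observed={"x"}, universe={"a", "x", "y"}, excluded={"x"}
    )
    assert report.classes["x"] == "excluded"
    assert report.sensitivity is None  # tp + fn = 0 once x is excluded
    assert report.ppv == 0.0


def test_heg_baseline_uses_same_metrics():
    """Highly expressed genes as essentiality predictors need no extra code."""
    universe = {f"g{i}" for i in range(10)}
    heg = {"g0", "g1"}  # top-fraction genes
    observed = {"g1", "g5"}
    report = essentiality_metrics(heg, observed, universe)
    assert (report.tp, report.fp, report.fn) == (1, 1, 1)
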