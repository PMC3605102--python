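"""Model container, GPR parsing and reaction-list CSV round-trips."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from examo.model import (
    GprParseError,
    GprRule,
    MetabolicModel,
    ModelFormatError,
    Reaction,
    parse_gpr,
    read_model_csv,
    stoichiometric_matrix,
    write_model_csv,
)

# --------------------------------------------------------------------------
# GPR parsing
# --------------------------------------------------------------------------


def _truth_table(rule_text: str, genes: list[str]):
    """Direct Boolean evaluation of the rule string, independent of the parser."""
    table = []
    for bits in itertools.product([False, True], repeat=len(genes)):
        env = dict(zip(genes, bits))
        expr = rule_text
        for g, val in env.items():
            expr = expr.replace(g, str(val))
        expr = expr.replace("AND", "and").replace("OR", "or")
        table.append(eval(expr))  # noqa: S307 - controlled test input
    return table


@pytest.mark.parametrize(
    "text,genes",
    [
        ("(g1 AND g2) OR (g3 AND g4)", ["g1", "g2", "g3", "g4"]),
        ("g1 OR (g2 AND (g3 OR g4))", ["g1", "g2", "g3", "g4"]),
        ("g1 AND g2 OR g3", ["g1", "g2", "g3"]),  # AND binds tighter
        ("g1", ["g1"]),
        ("((g1))", ["g1"]),
        ("g1 and g2 or g3", ["g1", "g2", "g3"]),  # keywords case-insensitive
    ],
)
def test_parse_gpr_matches_truth_table(text, genes):
    rule = parse_gpr(text)
    assert rule.genes() == frozenset(genes)
    expected = _truth_table(text, genes)
    got = [
        rule.evaluate({g: v for g, v in zip(genes, bits)})
        for bits in itertools.product([False, True], repeat=len(genes))
    ]
    assert got == expected


def test_parse_gpr_round_trip_preserves_semantics():
    text = "g1 OR (g2 AND (g3 OR g4))"
    rule = parse_gpr(text)
    reparsed = parse_gpr(rule.to_string())
    genes = sorted(rule.genes())
    for bits in itertools.product([False, True], repeat=len(genes)):
        env = dict(zip(genes, bits))
        assert rule.evaluate(env) == reparsed.evaluate(env)


def test_parse_gpr_isoenzyme_complex_structure():
    rule = parse_gpr("(g1 AND g2) OR (g3 AND g4)")
    assert rule.op == "or"
    assert all(child.op == "and" for child in rule.children)


def test_parse_gpr_empty_means_no_association():
    assert parse_gpr("").is_empty
    assert parse_gpr(None).is_empty
    assert parse_gpr("   ").is_empty
    assert parse_gpr("").evaluate({}) is True  # no genes required


@pytest.mark.parametrize("bad", ["(g1 AND g2", "g1 OR", "AND g1", "g1 g2", "g1 )"])
def test_parse_gpr_errors_name_position(bad):
    with pytest.raises(GprParseError) as exc:
        parse_gpr(bad)
    assert "position" in str(exc.value)


@st.composite
def gpr_trees(draw, depth=0):
    genes = ["g1", "g2", "g3", "g4"]
    if depth >= 2 or draw(st.booleans()):
        return GprRule.gene(draw(st.sampled_from(genes)))
    op = draw(st.sampled_from(["and", "or"]))
    n = draw(st.integers(2, 3))
    return GprRule(op, tuple(draw(gpr_trees(depth=depth + 1)) for _ in range(n)))


@settings(max_examples=60, derandomize=True)
@given(gpr_trees())
def test_gpr_serialization_round_trips_truth_table(rule):
    reparsed = parse_gpr(rule.to_string())
    genes = sorted(rule.genes())
    for bits in itertools.product([False, True], repeat=len(genes)):
        env = dict(zip(genes, bits))
        assert rule.evaluate(env) == reparsed.evaluate(env)


# --------------------------------------------------------------------------
# Model invariants and the stoichiometric matrix
# --------------------------------------------------------------------------


def test_model_rejects_duplicate_reaction_ids():
    r = Reaction("r1", {"A": -1.0, "B": 1.0})
    with pytest.raises(ValueError, match="duplicate"):
        MetabolicModel([r, r])


def test_model_rejects_two_biomass_reactions():
    with pytest.raises(ValueError, match="biomass"):
        MetabolicModel(
            [
                Reaction("r1", {"A": -1.0}, is_biomass=True),
                Reaction("r2", {"B": -1.0}, is_biomass=True),
            ]
        )


def test_reaction_invariants():
    with pytest.raises(ValueError):
        Reaction("r", {})
    with pytest.raises(ValueError):
        Reaction("r", {"A": 1.0}, lb=1.0, ub=-1.0)


def test_gene_set_is_union_of_gpr_leaves(toy):
    model, _ = toy
    assert model.genes == frozenset({"g2", "g3a", "g3b", "g5", "g6", "g7a", "g7b"})


def test_single_conversion_column():
    model = MetabolicModel([Reaction("r", {"A": -1.0, "B": 1.0})])
    S = stoichiometric_matrix(model)
    order = [m.id for m in model.metabolites]
    col = {mid: S[i, 0] for i, mid in enumerate(order)}
    assert col == {"A": -1.0, "B": 1.0}


def test_toy_matrix_shape_and_nonzeros(toy):
    model, _ = toy
    S = stoichiometric_matrix(model)
    assert S.shape == (5, 10)
    expected_nnz = sum(len(r.stoich) for r in model.reactions)
    assert np.count_nonzero(S) == expected_nnz


def test_toy_carbon_balance(toy):
    """Every internal reaction conserves carbon (2C + 3C -> 5C accounting)."""
    model, _ = toy
    carbons = {"A2[c]": 2, "B3[c]": 3, "C2[c]": 2, "D3[c]": 3, "E5[c]": 5}
    for rxn in model.reactions:
        if rxn.is_exchange:
            continue
        balance = sum(coeff * carbons[mid] for mid, coeff in rxn.stoich.items())
        assert balance == pytest.approx(0.0, abs=1e-12), rxn.id


def test_exchange_detection(toy):
    model, _ = toy
    assert {r.id for r in model.exchanges} == {"r1", "r2", "r6"}


# --------------------------------------------------------------------------
# CSV round-trip
# --------------------------------------------------------------------------


def test_csv_linear_chain(tmp_path):
    path = tmp_path / "chain.csv"
    path.write_text(
        "id,name,stoichiometry,gpr,lb,ub\n"
        "u,uptake,-> A[c],,0,1000\n"
        "c1,step one,A[c] -> B[c],g1,0,1000\n"
        "s,secretion,B[c] ->,,0,1000\n"
    )
    model = read_model_csv(path)
    internal = [m.id for m in model.metabolites]
    assert sorted(internal) == ["A[c]", "B[c]"]
    assert model.reaction("c1").stoich == {"A[c]": -1.0, "B[c]": 1.0}
    uptake = model.reaction("u")
    assert uptake.is_exchange and uptake.stoich == {"A[c]": 1.0}
    assert uptake.gpr.is_empty


def test_csv_round_trip_toy(tmp_path, toy):
    model, _ = toy
    path = tmp_path / "toy.csv"
    write_model_csv(model, path)
    back = read_model_csv(path)
    assert back.reaction_ids == model.reaction_ids
    np.testing.assert_allclose(
        stoichiometric_matrix(back), stoichiometric_matrix(model), atol=1e-9
    )
    for rxn in model.reactions:
        got = back.reaction(rxn.id)
        assert (got.lb, got.ub) == (rxn.lb, rxn.ub)
        assert got.is_biomass == rxn.is_biomass
        genes = sorted(rxn.gpr.genes())
        for bits in itertools.product([False, True], repeat=len(genes)):
            env = dict(zip(genes, bits))
            assert got.gpr.evaluate(env) == rxn.gpr.evaluate(env)


def test_csv_arrow_conventions(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text(
        "id,name,stoichiometry,gpr,lb,ub\n"
        "fwd,,A -> B,,,\n"
        "rev,,B <=> C,,,\n"
    )
    model = read_model_csv(path)
    assert model.reaction("fwd").lb == 0.0
    assert model.reaction("rev").lb < 0


@pytest.mark.parametrize(
    "row,match",
    [
        ("r1,,A >> B,,0,1", "arrow"),
        ("r1,,x A -> B,,0,1", "stoichiometry|coefficient|arrow"),
        ("r1,,A -> B,,zero,1", "non-numeric"),
    ],
)
def test_csv_format_errors_carry_row_number(tmp_path, row, match):
    path = tmp_path / "bad.csv"
    path.write_text("id,name,stoichiometry,gpr,lb,ub\n" + row + "\n")
    with pytest.raises(ModelFormatError, match="2"):
        read_model_csv(path)


def test_csv_duplicate_reaction_id(tmp_path):
    path = tmp_path / "dup.csv"
    path.write_text(
        "id,name,stoichiometry,gpr,lb,ub\nr1,,A -> B,,0,1\nr1,,B -> C,,0,1\n"
    )
    with pytest.raises(ModelFormatError, match="duplicate"):
        read_model_csv(path)


def test_csv_fractional_coefficients(tmp_path):
    path = tmp_path / "frac.csv"
    path.write_text("id,name,stoichiometry,gpr,lb,ub\nr,,2 A + 0.5 B -> C,,0,10\n")
    model = read_model_csv(path)
    assert model.reaction("r").stoich == {"A": -2.0, "B": -0.5, "C": 1.0}
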