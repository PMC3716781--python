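"""SBML-subset codec, MathML, programme construction, conservation."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st
from lxml import etree

from biofacets.facet_schema import Annotation, FacetAddress
from biofacets.sbml_io import (
    ModelError,
    OdeModel,
    Reaction,
    Species,
    UnsupportedFeatureError,
    build_programme,
    check_model,
    conserved_total_residual,
    expand_expr,
    expr_from_mathml,
    mathml_from_expr,
    parse_arith,
    read_sbml,
    write_sbml,
)

# ---------------------------------------------------------------------------
# Expression grammar and MathML codec
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("bad", ["sin(x)", "x**0.5", "exp(k1*t)", "Max(x, y)"])
def test_parse_arith_rejects_nonarithmetic(bad):
    with pytest.raises(UnsupportedFeatureError):
        parse_arith(bad)


_symbols = st.sampled_from([sympy.Symbol(s) for s in ("x", "y", "k1", "k6", "CT")])
_leaves = st.one_of(
    _symbols,
    st.integers(min_value=-9, max_value=9).map(sympy.Integer),
    st.floats(min_value=0.01, max_value=100, allow_nan=False).map(
        lambda v: sympy.Float(round(v, 4))),
)


def _combine(children):
    return st.one_of(
        st.tuples(children, children).map(lambda ab: ab[0] + ab[1]),
        st.tuples(children, children).map(lambda ab: ab[0] * ab[1]),
        st.tuples(children, children).map(lambda ab: ab[0] - ab[1]),
        st.tuples(children, _symbols).map(lambda ab: ab[0] / ab[1]),
        st.tuples(_symbols, st.integers(min_value=1, max_value=3)).map(
            lambda ab: ab[0] ** ab[1]),
    )


_exprs = st.recursive(_leaves, _combine, max_leaves=8)


@given(expr=_exprs)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_mathml_round_trip_preserves_expression(expr):
    restored = expr_from_mathml(mathml_from_expr(expr))
    diff = sympy.simplify(restored - expr)
    if diff == 0:
        return
    # float literals can leave simplification residue; check numerically
    rng = np.random.default_rng(1)
    for _ in range(5):
        subs = {s: float(rng.uniform(0.5, 2.0)) for s in expr.free_symbols}
        a = complex(expr.subs(subs))
        b = complex(restored.subs(subs))
        assert abs(a - b) <= 1e-9 * (1 + abs(a))


def test_mathml_rejects_unsupported_elements():
    math = etree.fromstring(
        b'<math xmlns="http://www.w3.org/1998/Math/MathML">'
        b'<apply><sin/><ci>x</ci></apply></math>')
    with pytest.raises(UnsupportedFeatureError):
        expr_from_mathml(math)


# ---------------------------------------------------------------------------
# Programme construction
# ---------------------------------------------------------------------------


def _tiny_model():
    model = OdeModel(id="tiny")
    model.species = [Species("M", initial_amount=1.0), Species("C2"), Species("YP")]
    model.parameters = {"k6": 0.5}
    model.reactions = [Reaction("dissociation", parse_arith("k6*M"),
                                reactants=[("M", 1)],
                                products=[("C2", 1), ("YP", 1)])]
    return model


def test_single_dissociation_reaction_rhs():
    prog = build_programme(_tiny_model())
    k6, M = sympy.symbols("k6 M")
    assert sympy.simplify(prog.rhs["M"] + k6 * M) == 0
    assert sympy.simplify(prog.rhs["C2"] - k6 * M) == 0
    assert sympy.simplify(prog.rhs["YP"] - k6 * M) == 0


def test_empty_network_gives_zero_rhs():
    model = OdeModel(id="empty")
    model.species = [Species("A"), Species("B")]
    prog = build_programme(model)
    assert all(r == 0 for r in prog.rhs.values())


def test_constant_species_excluded_from_state(model1_bundle):
    prog = build_programme(model1_bundle.model)
    assert prog.state_symbols == ["C2", "CP", "pM", "M", "Y", "YP"]


def test_model1_programme_matches_printed_rate_equations(model1_bundle):
    """The reaction-derived ODEs must equal the six rate equations exactly.

    The expected right-hand sides are written out independently here,
    straight from the rate-equation form of the model, and compared
    symbolically after expanding the algebraic definitions.
    """
    C2, CP, pM, M, Y, YP, AP, aa = sympy.symbols("C2 CP pM M Y YP AP aa")
    k1, k2, k3, k4, k4p, k5, k6, k7, k8, k9 = sympy.symbols(
        "k1 k2 k3 k4 k4p k5 k6 k7 k8 k9")
    CT = C2 + CP + pM + M
    F = k4p + k4 * (M / CT) ** 2
    expected = {
        "C2": k6 * M - k8 * AP * C2 + k9 * CP,
        "CP": -k3 * CP * Y + k8 * AP * C2 - k9 * CP,
        "pM": k3 * CP * Y - pM * F + k5 * AP * M,
        "M": pM * F - k5 * AP * M - k6 * M,
        "Y": k1 * aa - k2 * Y - k3 * CP * Y,
        "YP": k6 * M - k7 * YP,
    }
    model = model1_bundle.model
    prog = build_programme(model)
    for state, rhs in expected.items():
        derived = expand_expr(model, prog.rhs[state])
        assert sympy.simplify(derived - rhs) == 0, state


def test_programme_linearity_under_reaction_addition():
    """Adding a reaction adds exactly its stoichiometry-weighted law."""
    rng = np.random.default_rng(42)
    species = ["A", "B", "C", "D"]
    for _ in range(10):
        model = OdeModel(id="rand")
        model.species = [Species(s) for s in species]
        model.parameters = {"k": float(rng.uniform(0.1, 2))}
        n = rng.integers(1, 4)
        reactions = []
        for i in range(n + 1):
            subs = rng.choice(species, size=2, replace=False)
            law = parse_arith(f"k*{subs[0]}")
            reactions.append(Reaction(
                f"r{i}", law,
                reactants=[(str(subs[0]), int(rng.integers(1, 3)))],
                products=[(str(subs[1]), int(rng.integers(1, 3)))]))
        model.reactions = reactions[:-1]
        before = build_programme(model).rhs
        extra = reactions[-1]
        model.reactions = reactions
        after = build_programme(model).rhs
        for s in species:
            delta = sympy.Integer(0)
            for sid, stoich in extra.reactants:
                if sid == s:
                    delta -= stoich * extra.kinetic_law
            for sid, stoich in extra.products:
                if sid == s:
                    delta += stoich * extra.kinetic_law
            assert sympy.simplify(after[s] - before[s] - delta) == 0


# ---------------------------------------------------------------------------
# Conserved totals
# ---------------------------------------------------------------------------


def test_total_cdc2_is_conserved_at_random_states(model1_bundle):
    model = model1_bundle.model
    prog = build_programme(model)
    rng = np.random.default_rng(7)
    for _ in range(1000):
        state = {s: float(v) for s, v in zip(
            ["C2", "CP", "pM", "M", "Y", "YP", "AP", "aa"],
            rng.uniform(0.01, 2.0, 8))}
        params = {k: float(v) for k, v in zip(
            ["k1", "k2", "k3", "k4", "k4p", "k5", "k6", "k7", "k8", "k9"],
            rng.uniform(0.01, 5.0, 10))}
        residual = conserved_total_residual(
            model, prog, ["C2", "CP", "pM", "M"], {**state, **params})
        assert abs(residual) < 1e-12


def test_single_member_residual_is_that_species_rate():
    model = OdeModel(id="decay")
    model.species = [Species("X", initial_amount=1.0)]
    model.parameters = {"k": 0.7}
    model.reactions = [Reaction("deg", parse_arith("k*X"), reactants=[("X", 1)])]
    prog = build_programme(model)
    residual = conserved_total_residual(model, prog, ["X"], {"X": 2.0, "k": 0.7})
    assert residual == pytest.approx(-0.7 * 2.0)


def test_residual_unknown_member_errors(model1_bundle):
    prog = build_programme(model1_bundle.model)
    with pytest.raises(KeyError):
        conserved_total_residual(model1_bundle.model, prog, ["nope"], {})


# ---------------------------------------------------------------------------
# Model invariants
# ---------------------------------------------------------------------------


def test_undeclared_symbol_in_kinetic_law_is_named():
    model = OdeModel(id="bad")
    model.species = [Species("A")]
    model.reactions = [Reaction("r", parse_arith("kX*A"), reactants=[("A", 1)])]
    with pytest.raises(ModelError, match="kX"):
        check_model(model)


def test_cyclic_algebraic_definitions_rejected():
    model = OdeModel(id="cyclic")
    model.species = [Species("A")]
    model.algebraic = {"p": parse_arith("q + A"), "q": parse_arith("p * 2")}
    with pytest.raises(ModelError, match="cyclic"):
        check_model(model)


# ---------------------------------------------------------------------------
# Read / write round-trips
# ---------------------------------------------------------------------------


def _rhs_agree(model_a, model_b, seed=0):
    prog_a = build_programme(model_a)
    prog_b = build_programme(model_b)
    assert prog_a.state_symbols == prog_b.state_symbols
    rng = np.random.default_rng(seed)
    names = sorted({s.name for rhs in prog_a.rhs.values()
                    for s in expand_expr(model_a, rhs).free_symbols}
                   | {s.name for rhs in prog_b.rhs.values()
                      for s in expand_expr(model_b, rhs).free_symbols})
    for _ in range(20):
        subs = {sympy.Symbol(n): float(rng.uniform(0.1, 2)) for n in names}
        for state in prog_a.state_symbols:
            va = float(expand_expr(model_a, prog_a.rhs[state]).subs(subs))
            vb = float(expand_expr(model_b, prog_b.rhs[state]).subs(subs))
            assert va == pytest.approx(vb, rel=1e-12, abs=1e-12)


def test_model1_round_trip(model1_bundle):
    model = model1_bundle.model
    document = write_sbml(model)
    restored, record = read_sbml(document)
    assert [s.id for s in restored.species] == [s.id for s in model.species]
    assert restored.parameters == model.parameters
    assert {r.id for r in restored.reactions} == {r.id for r in model.reactions}
    # boundary marking survives
    assert restored.get_species("AP").constant
    assert restored.get_species("aa").constant
    _rhs_agree(model, restored)
    # harvested extrinsic slots carry the printed cross-references
    objects = record.slots[FacetAddress("structure", 2, "extrinsic", "objects")]
    assert Annotation("uniprot", "P04551", qualifier="is") in objects.annotations


def test_empty_model_round_trip():
    model = OdeModel(id="nothing")
    restored, _ = read_sbml(write_sbml(model))
    assert restored.id == "nothing"
    assert restored.species == [] and restored.reactions == []


def test_randomized_model_round_trips():
    rng = np.random.default_rng(11)
    for trial in range(8):
        model = OdeModel(id=f"rand{trial}")
        n_species = int(rng.integers(1, 5))
        names = [f"S{i}" for i in range(n_species)]
        model.species = [
            Species(n, initial_amount=float(rng.uniform(0, 2)),
                    constant=bool(rng.random() < 0.2))
            for n in names
        ]
        model.parameters = {"ka": float(rng.uniform(0.1, 2)), "kb": None}
        if rng.random() < 0.5:
            model.algebraic = {"tot": parse_arith("+".join(names))}
        for i in range(int(rng.integers(0, 3))):
            a, b = rng.choice(names, size=2, replace=True)
            model.reactions.append(Reaction(
                f"r{i}", parse_arith(f"ka*{a}"),
                reactants=[(str(a), 1)], products=[(str(b), 2)]))
        restored, _ = read_sbml(write_sbml(model))
        assert [s.id for s in restored.species] == names
        assert restored.parameters == model.parameters
        assert set(restored.algebraic) == set(model.algebraic)
        _rhs_agree(model, restored, seed=trial)


def test_unsupported_constructs_are_reported():
    document = (
        '<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" '
        'version="4"><model id="m"><listOfEvents/></model></sbml>')
    with pytest.raises(UnsupportedFeatureError, match="listOfEvents"):
        read_sbml(document)


def test_rate_rules_are_unsupported():
    document = (
        '<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" '
        'version="4"><model id="m"><listOfRules><rateRule variable="x"/>'
        "</listOfRules></model></sbml>")
    with pytest.raises(UnsupportedFeatureError, match="rateRule"):
        read_sbml(document)


def test_empty_namespace_annotation_refused():
    model = OdeModel(id="m")
    ann = Annotation("x", "y")
    object.__setattr__(ann, "namespace", "")  # bypass constructor guard
    model.annotations = [ann]
    with pytest.raises(Exception):
        write_sbml(model)
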