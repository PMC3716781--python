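"""SBML-subset I/O and ODE programme construction.

Reads and writes the core of SBML Level 2 Version 4 — species, global
parameters, assignment rules, reactions with content-MathML kinetic laws,
and MIRIAM-style RDF annotations — and derives the model's *programme*:
the system of ODEs obtained by summing, for every non-boundary species,
the stoichiometry-weighted kinetic laws of the reactions it takes part in.

Kinetic-law expressions are deliberately restricted to the arithmetic
fragment the supported models need (+, -, *, /, integer powers over
species, parameters and algebraic definitions); anything beyond that
raises :class:`UnsupportedFeatureError` instead of being silently
misread.  Expressions are held as :mod:`sympy` expressions throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import sympy
from lxml import etree

from .facet_schema import (
    Annotation,
    FacetAddress,
    FacetRecord,
    format_url,
    parse_identifier,
)

__all__ = [
    "SbmlError",
    "ModelError",
    "UnsupportedFeatureError",
    "Species",
    "Reaction",
    "OdeModel",
    "Programme",
    "parse_arith",
    "mathml_from_expr",
    "expr_from_mathml",
    "check_model",
    "expand_expr",
    "build_programme",
    "conserved_total_residual",
    "read_sbml",
    "write_sbml",
]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"

_SUPPORTED_LISTS = {
    "listOfCompartments", "listOfSpecies", "listOfParameters",
    "listOfRules", "listOfReactions",
}


class SbmlError(ValueError):
    pass


class ModelError(SbmlError):
    """A structural defect: undeclared symbols, cyclic definitions, duplicates."""


class UnsupportedFeatureError(SbmlError):
    """A construct outside the supported SBML/MathML subset."""


# ---------------------------------------------------------------------------
# Expressions
# ---------------------------------------------------------------------------

def parse_arith(text: str) -> sympy.Expr:
    """Parse an arithmetic expression restricted to + - * / and integer powers."""
    try:
        expr = sympy.sympify(text, rational=False, evaluate=True)
    except (sympy.SympifyError, SyntaxError, TypeError) as exc:
        raise SbmlError(f"cannot parse expression {text!r}: {exc}") from exc
    _check_arith(expr, text)
    return expr


def _check_arith(expr: sympy.Expr, origin: str) -> None:
    for node in sympy.preorder_traversal(expr):
        if isinstance(node, (sympy.Symbol, sympy.Integer, sympy.Float, sympy.Rational)):
            continue
        if isinstance(node, (sympy.Add, sympy.Mul)):
            continue
        if isinstance(node, sympy.Pow):
            if not node.exp.is_Integer:
                raise UnsupportedFeatureError(
                    f"non-integer power {node} in {origin!r}")
            continue
        raise UnsupportedFeatureError(
            f"unsupported operation {type(node).__name__} in {origin!r}")


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


def mathml_from_expr(expr: sympy.Expr) -> etree._Element:
    """Emit content MathML for the restricted arithmetic fragment."""
    math = etree.Element(_q(MATHML_NS, "math"))
    math.append(_mathml_node(sympy.sympify(expr)))
    return math


def _apply(op: str, *children: etree._Element) -> etree._Element:
    el = etree.Element(_q(MATHML_NS, "apply"))
    el.append(etree.Element(_q(MATHML_NS, op)))
    for c in children:
        el.append(c)
    return el


def _cn(value) -> etree._Element:
    el = etree.Element(_q(MATHML_NS, "cn"))
    if isinstance(value, sympy.Integer) or isinstance(value, int):
        el.set("type", "integer")
        el.text = str(int(value))
    else:
        el.text = repr(float(value))
    return el


def _ci(name: str) -> etree._Element:
    el = etree.Element(_q(MATHML_NS, "ci"))
    el.text = f" {name} "
    return el


def _mathml_node(expr: sympy.Expr) -> etree._Element:
    if isinstance(expr, sympy.Symbol):
        return _ci(expr.name)
    if isinstance(expr, sympy.Integer):
        return _cn(expr)
    if isinstance(expr, sympy.Rational):
        return _apply("divide", _cn(expr.p), _cn(expr.q))
    if isinstance(expr, sympy.Float):
        return _cn(expr)
    if isinstance(expr, sympy.Add):
        return _apply("plus", *[_mathml_node(a) for a in expr.args])
    if isinstance(expr, sympy.Mul):
        return _apply("times", *[_mathml_node(a) for a in expr.args])
    if isinstance(expr, sympy.Pow):
        if not expr.exp.is_Integer:
            raise UnsupportedFeatureError(f"non-integer power {expr}")
        n = int(expr.exp)
        if n < 0:
            return _apply("divide", _cn(1), _mathml_node(expr.base ** (-n)))
        return _apply("power", _mathml_node(expr.base), _cn(n))
    raise UnsupportedFeatureError(f"cannot serialize expression node {expr!r}")


_MATHML_OPS = {"plus", "minus", "times", "divide", "power"}


def expr_from_mathml(math: etree._Element) -> sympy.Expr:
    """Parse the content-MathML fragment back into a sympy expression."""
    children = [c for c in math if isinstance(c.tag, str)]
    if len(children) != 1:
        raise UnsupportedFeatureError("math element must have exactly one child")
    return _expr_node(children[0])


def _expr_node(el: etree._Element) -> sympy.Expr:
    tag = etree.QName(el).localname
    if tag == "ci":
        return sympy.Symbol((el.text or "").strip())
    if tag == "cn":
        text = (el.text or "").strip()
        if el.get("type", "real") == "integer":
            return sympy.Integer(int(text))
        return sympy.Float(text)
    if tag == "apply":
        children = [c for c in el if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = [_expr_node(c) for c in children[1:]]
        if op not in _MATHML_OPS:
            raise UnsupportedFeatureError(f"unsupported MathML operator <{op}>")
        if op == "plus":
            return sympy.Add(*args)
        if op == "times":
            return sympy.Mul(*args)
        if op == "minus":
            if len(args) == 1:
                return -args[0]
            if len(args) == 2:
                return args[0] - args[1]
            raise UnsupportedFeatureError("minus takes one or two arguments")
        if op == "divide":
            if len(args) != 2:
                raise UnsupportedFeatureError("divide takes two arguments")
            return args[0] / args[1]
        if op == "power":
            base, exp = args
            if not sympy.sympify(exp).is_Integer:
                raise UnsupportedFeatureError(f"non-integer power exponent {exp}")
            return base ** exp
    raise UnsupportedFeatureError(f"unsupported MathML element <{tag}>")


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class Species:
    id: str
    name: Optional[str] = None
    initial_amount: float = 0.0
    constant: bool = False  # boundary species: amount never changes
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.initial_amount < 0:
            raise ModelError(f"species {self.id}: negative initialAmount")


@dataclass
class Reaction:
    id: str
    kinetic_law: sympy.Expr
    reactants: list[tuple[str, int]] = field(default_factory=list)
    products: list[tuple[str, int]] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    name: Optional[str] = None
    annotations: list[Annotation] = field(default_factory=list)


@dataclass
class OdeModel:
    """A reaction-network model with its symbol tables.

    ``parameters`` maps parameter symbols to a value or ``None`` (unset);
    ``algebraic`` holds assignment-rule definitions (e.g. conserved totals
    and rate functions) which must be acyclic.  The independent variable
    is time in the declared ``time_units``.
    """

    id: str
    name: Optional[str] = None
    species: list[Species] = field(default_factory=list)
    parameters: dict[str, Optional[float]] = field(default_factory=dict)
    algebraic: dict[str, sympy.Expr] = field(default_factory=dict)
    reactions: list[Reaction] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)
    time_units: str = "minute"
    amount_units: str = "dimensionless"

    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(f"unknown species {sid!r}")


@dataclass
class Programme:
    """The derived ODE system: an ordered state and one rhs expression per state."""

    state_symbols: list[str]
    rhs: dict[str, sympy.Expr]


# ---------------------------------------------------------------------------
# Model checking and programme construction
# ---------------------------------------------------------------------------

def _algebraic_order(model: OdeModel) -> list[str]:
    """Topological order of algebraic definitions; raises on cycles."""
    deps = {
        name: {s.name for s in expr.free_symbols if s.name in model.algebraic}
        for name, expr in model.algebraic.items()
    }
    order: list[str] = []
    placed: set[str] = set()
    while len(order) < len(deps):
        progress = [n for n in deps if n not in placed and deps[n] <= placed]
        if not progress:
            cyclic = sorted(set(deps) - placed)
            raise ModelError(f"cyclic algebraic definitions among {cyclic}")
        for n in sorted(progress):
            order.append(n)
            placed.add(n)
    return order


def check_model(model: OdeModel) -> None:
    """Enforce the model invariants (unique ids, declared symbols, acyclicity)."""
    sids = model.species_ids()
    if len(set(sids)) != len(sids):
        raise ModelError("duplicate species ids")
    declared = set(sids) | set(model.parameters) | set(model.algebraic)
    overlap = set(sids) & set(model.parameters)
    if overlap:
        raise ModelError(f"symbols declared as both species and parameter: {sorted(overlap)}")
    _algebraic_order(model)
    for name, expr in model.algebraic.items():
        for s in expr.free_symbols:
            if s.name not in declared:
                raise ModelError(
                    f"algebraic definition {name} references undeclared symbol {s.name}")
    for rxn in model.reactions:
        for sid, _ in rxn.reactants + rxn.products:
            if sid not in sids:
                raise ModelError(f"reaction {rxn.id} references unknown species {sid}")
        for sid in rxn.modifiers:
            if sid not in sids:
                raise ModelError(f"reaction {rxn.id} modifier {sid} is not a species")
        for s in rxn.kinetic_law.free_symbols:
            if s.name not in declared:
                raise ModelError(
                    f"kinetic law of {rxn.id} references undeclared symbol {s.name}")
        _check_arith(rxn.kinetic_law, f"kinetic law of {rxn.id}")


def expand_expr(model: OdeModel, expr: sympy.Expr) -> sympy.Expr:
    """Substitute algebraic definitions (in dependency order) into *expr*."""
    order = _algebraic_order(model)
    # substitute later definitions first so earlier ones resolve transitively
    for name in reversed(order):
        expr = expr.subs(sympy.Symbol(name), model.algebraic[name])
    return expr


def build_programme(model: OdeModel) -> Programme:
    """Derive the ODE system from the reaction network.

    For each non-constant species *s*,
    ``d[s]/dt = sum over reactions of (net stoichiometry of s) * kinetic law``.
    Constant (boundary) species are excluded from the state.
    """
    check_model(model)
    state = [s.id for s in model.species if not s.constant]
    rhs: dict[str, sympy.Expr] = {sid: sympy.Integer(0) for sid in state}
    for rxn in model.reactions:
        for sid, stoich in rxn.reactants:
            if sid in rhs:
                rhs[sid] = rhs[sid] - stoich * rxn.kinetic_law
        for sid, stoich in rxn.products:
            if sid in rhs:
                rhs[sid] = rhs[sid] + stoich * rxn.kinetic_law
    return Programme(state_symbols=state, rhs=rhs)


def conserved_total_residual(
    model: OdeModel,
    prog: Programme,
    members: Iterable[str],
    state: Mapping[str, float],
) -> float:
    """Instantaneous drift of a candidate conserved total.

    Returns ``sum over members of rhs`` evaluated at *state* (which must
    also assign constant species and parameters).  An identically zero
    residual over random states certifies a conserved moiety such as
    total cdc2.
    """
    members = list(members)
    unknown = [m for m in members if m not in prog.rhs]
    if unknown:
        raise KeyError(f"not state symbols: {unknown}")
    total = sympy.Add(*[prog.rhs[m] for m in members])
    total = expand_expr(model, total)
    subs = {sympy.Symbol(k): v for k, v in state.items()}
    for name, value in model.parameters.items():
        if value is not None and sympy.Symbol(name) not in subs:
            subs[sympy.Symbol(name)] = value
    for sp in model.species:
        if sp.constant and sympy.Symbol(sp.id) not in subs:
            subs[sympy.Symbol(sp.id)] = sp.initial_amount
    value = total.subs(subs)
    if value.free_symbols:
        raise ModelError(f"residual still contains symbols {value.free_symbols}")
    return float(value)


# ---------------------------------------------------------------------------
# RDF annotation helpers
# ---------------------------------------------------------------------------

def _read_annotations(parent: etree._Element) -> list[Annotation]:
    out: list[Annotation] = []
    ann = parent.find(_q(SBML_NS, "annotation"))
    if ann is None:
        return out
    for desc in ann.iter(_q(RDF_NS, "Description")):
        for child in desc:
            if not isinstance(child.tag, str):
                continue
            qname = etree.QName(child)
            if qname.namespace != BQBIOL_NS:
                continue
            qualifier = qname.localname
            for li in child.iter(_q(RDF_NS, "li")):
                resource = li.get(_q(RDF_NS, "resource"))
                if resource:
                    parsed = parse_identifier(resource)
                    out.append(Annotation(parsed.namespace, parsed.identifier,
                                          qualifier=qualifier))
    return out


def _write_annotations(parent: etree._Element, about: str,
                       annotations: list[Annotation]) -> None:
    if not annotations:
        return
    for ann in annotations:
        if not ann.namespace:
            raise SbmlError("refusing to serialize annotation with empty namespace")
    el = etree.SubElement(parent, _q(SBML_NS, "annotation"))
    rdf = etree.SubElement(el, _q(RDF_NS, "RDF"),
                           nsmap={"rdf": RDF_NS, "bqbiol": BQBIOL_NS})
    desc = etree.SubElement(rdf, _q(RDF_NS, "Description"))
    desc.set(_q(RDF_NS, "about"), f"#{about}")
    by_qualifier: dict[str, list[Annotation]] = {}
    for ann in annotations:
        by_qualifier.setdefault(ann.qualifier or "is", []).append(ann)
    for qualifier, anns in sorted(by_qualifier.items()):
        q_el = etree.SubElement(desc, _q(BQBIOL_NS, qualifier))
        bag = etree.SubElement(q_el, _q(RDF_NS, "Bag"))
        for ann in anns:
            li = etree.SubElement(bag, _q(RDF_NS, "li"))
            li.set(_q(RDF_NS, "resource"), format_url(ann))


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_sbml(document: str | bytes) -> tuple[OdeModel, FacetRecord]:
    """Parse an SBML-subset document into a model and a partial facet record.

    Species populate the intrinsic entity slots, reactions the intrinsic
    relation/programme slots, parameter and initial values the intrinsic
    instantiation slots; RDF annotations are harvested into the matching
    extrinsic slots (model-level -> biological system, species ->
    biological objects, reactions -> biological interactions).
    Constructs outside the subset raise :class:`UnsupportedFeatureError`.
    """
    if isinstance(document, str):
        document = document.encode()
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise SbmlError(f"not well-formed XML: {exc}") from exc
    if etree.QName(root).localname != "sbml" or etree.QName(root).namespace != SBML_NS:
        raise UnsupportedFeatureError(
            "document is not SBML Level 2 Version 4 (unexpected root element)")
    model_el = root.find(_q(SBML_NS, "model"))
    if model_el is None:
        raise SbmlError("sbml element contains no model")

    unsupported = []
    for child in model_el:
        if not isinstance(child.tag, str):
            continue
        tag = etree.QName(child).localname
        if tag not in _SUPPORTED_LISTS | {"annotation", "notes"}:
            unsupported.append(tag)
    rules_el = model_el.find(_q(SBML_NS, "listOfRules"))
    if rules_el is not None:
        for rule in rules_el:
            if isinstance(rule.tag, str) and \
                    etree.QName(rule).localname != "assignmentRule":
                unsupported.append(etree.QName(rule).localname)
    if unsupported:
        raise UnsupportedFeatureError(
            f"unsupported SBML constructs: {sorted(set(unsupported))}")

    model = OdeModel(id=model_el.get("id") or "model", name=model_el.get("name"))
    model.annotations = _read_annotations(model_el)

    species_list = model_el.find(_q(SBML_NS, "listOfSpecies"))
    if species_list is not None:
        for sp_el in species_list.findall(_q(SBML_NS, "species")):
            constant = (sp_el.get("boundaryCondition") == "true"
                        or sp_el.get("constant") == "true")
            model.species.append(Species(
                id=sp_el.get("id"),
                name=sp_el.get("name"),
                initial_amount=float(sp_el.get("initialAmount", "0")),
                constant=constant,
                annotations=_read_annotations(sp_el),
            ))

    params_list = model_el.find(_q(SBML_NS, "listOfParameters"))
    if params_list is not None:
        for p_el in params_list.findall(_q(SBML_NS, "parameter")):
            value = p_el.get("value")
            model.parameters[p_el.get("id")] = None if value is None else float(value)

    if rules_el is not None:
        for rule in rules_el.findall(_q(SBML_NS, "assignmentRule")):
            math = rule.find(_q(MATHML_NS, "math"))
            if math is None:
                raise SbmlError(f"assignmentRule for {rule.get('variable')} has no math")
            model.algebraic[rule.get("variable")] = expr_from_mathml(math)
    # algebraic targets are declared as parameters in SBML; drop the shadow entry
    for name in model.algebraic:
        model.parameters.pop(name, None)

    reactions_list = model_el.find(_q(SBML_NS, "listOfReactions"))
    if reactions_list is not None:
        for r_el in reactions_list.findall(_q(SBML_NS, "reaction")):
            kl = r_el.find(_q(SBML_NS, "kineticLaw"))
            if kl is None or kl.find(_q(MATHML_NS, "math")) is None:
                raise SbmlError(f"reaction {r_el.get('id')} has no kineticLaw math")
            if kl.find(_q(SBML_NS, "listOfParameters")) is not None:
                raise UnsupportedFeatureError(
                    f"reaction {r_el.get('id')}: local kineticLaw parameters "
                    "are outside the supported subset (declare them globally)")

            def _refs(tag: str) -> list[tuple[str, int]]:
                lst = r_el.find(_q(SBML_NS, tag))
                if lst is None:
                    return []
                return [
                    (ref.get("species"), int(float(ref.get("stoichiometry", "1"))))
                    for ref in lst.findall(_q(SBML_NS, "speciesReference"))
                ]

            modifiers = []
            mod_list = r_el.find(_q(SBML_NS, "listOfModifiers"))
            if mod_list is not None:
                modifiers = [m.get("species") for m in
                             mod_list.findall(_q(SBML_NS, "modifierSpeciesReference"))]
            model.reactions.append(Reaction(
                id=r_el.get("id"),
                name=r_el.get("name"),
                kinetic_law=expr_from_mathml(kl.find(_q(MATHML_NS, "math"))),
                reactants=_refs("listOfReactants"),
                products=_refs("listOfProducts"),
                modifiers=modifiers,
                annotations=_read_annotations(r_el),
            ))

    check_model(model)
    record = harvest_record(model)
    return model, record


def harvest_record(model: OdeModel) -> FacetRecord:
    """Build the partial facet record derivable from the encoded model alone."""
    record = FacetRecord(model_id=model.id)
    record.fill(FacetAddress("structure", 1, "intrinsic", "formal_system"),
                text=f"coupled ODE system derived from the reaction network "
                     f"of model {model.id!r}")
    record.fill(FacetAddress("structure", 2, "intrinsic", "entities"),
                text="species: " + ", ".join(model.species_ids()))
    record.fill(FacetAddress("structure", 2, "intrinsic", "attributes"),
                text="amount of each species as a continuous state variable")
    if model.reactions:
        record.fill(FacetAddress("structure", 3, "intrinsic", "relations"),
                    text="reactions: " + ", ".join(r.id for r in model.reactions))
        record.fill(FacetAddress("structure", 3, "intrinsic", "programme"),
                    text="ODEs summing stoichiometry-weighted kinetic laws "
                         "per species")
    set_params = {k: v for k, v in model.parameters.items() if v is not None}
    if set_params:
        record.fill(FacetAddress("function", 2, "intrinsic", "instantiation"),
                    text="parameter values: " + ", ".join(
                        f"{k}={v:g}" for k, v in sorted(set_params.items())))
    record.fill(FacetAddress("function", 2, "intrinsic", "initial_values"),
                text="initial amounts: " + ", ".join(
                    f"{s.id}={s.initial_amount:g}" for s in model.species))
    if model.annotations:
        record.fill(FacetAddress("structure", 1, "extrinsic", "biological_system"),
                    annotations=model.annotations)
    for sp in model.species:
        if sp.annotations:
            record.fill(FacetAddress("structure", 2, "extrinsic", "objects"),
                        annotations=sp.annotations)
    for rxn in model.reactions:
        if rxn.annotations:
            record.fill(FacetAddress("structure", 3, "extrinsic", "interactions"),
                        annotations=rxn.annotations)
    return record


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_sbml(model: OdeModel, record: Optional[FacetRecord] = None) -> bytes:
    """Serialize the model (annotations included) as an SBML L2V4 document.

    ``read_sbml(write_sbml(m))`` reproduces the model and its harvested
    record slots on the supported subset.  The *record* argument is
    accepted for interface symmetry; annotations are carried on the model
    object itself.
    """
    check_model(model)
    nsmap = {None: SBML_NS, "math": MATHML_NS}
    root = etree.Element(_q(SBML_NS, "sbml"), nsmap=nsmap)
    root.set("level", "2")
    root.set("version", "4")
    model_el = etree.SubElement(root, _q(SBML_NS, "model"))
    model_el.set("id", model.id)
    if model.name:
        model_el.set("name", model.name)
    _write_annotations(model_el, model.id, model.annotations)

    comp_list = etree.SubElement(model_el, _q(SBML_NS, "listOfCompartments"))
    comp = etree.SubElement(comp_list, _q(SBML_NS, "compartment"))
    comp.set("id", "cell")
    comp.set("size", "1")

    if model.species:
        sp_list = etree.SubElement(model_el, _q(SBML_NS, "listOfSpecies"))
        for sp in model.species:
            el = etree.SubElement(sp_list, _q(SBML_NS, "species"))
            el.set("id", sp.id)
            if sp.name:
                el.set("name", sp.name)
            el.set("compartment", "cell")
            el.set("initialAmount", repr(sp.initial_amount))
            if sp.constant:
                el.set("boundaryCondition", "true")
                el.set("constant", "true")
            _write_annotations(el, sp.id, sp.annotations)

    if model.parameters or model.algebraic:
        p_list = etree.SubElement(model_el, _q(SBML_NS, "listOfParameters"))
        for name in sorted(model.parameters):
            el = etree.SubElement(p_list, _q(SBML_NS, "parameter"))
            el.set("id", name)
            value = model.parameters[name]
            if value is not None:
                el.set("value", repr(value))
        # assignment-rule targets must be declared, and as non-constant
        for name in model.algebraic:
            el = etree.SubElement(p_list, _q(SBML_NS, "parameter"))
            el.set("id", name)
            el.set("constant", "false")

    if model.algebraic:
        rules_el = etree.SubElement(model_el, _q(SBML_NS, "listOfRules"))
        for name in _algebraic_order(model):
            rule = etree.SubElement(rules_el, _q(SBML_NS, "assignmentRule"))
            rule.set("variable", name)
            rule.append(mathml_from_expr(model.algebraic[name]))

    if model.reactions:
        r_list = etree.SubElement(model_el, _q(SBML_NS, "listOfReactions"))
        for rxn in model.reactions:
            el = etree.SubElement(r_list, _q(SBML_NS, "reaction"))
            el.set("id", rxn.id)
            if rxn.name:
                el.set("name", rxn.name)
            el.set("reversible", "false")
            _write_annotations(el, rxn.id, rxn.annotations)
            if rxn.reactants:
                lst = etree.SubElement(el, _q(SBML_NS, "listOfReactants"))
                for sid, stoich in rxn.reactants:
                    ref = etree.SubElement(lst, _q(SBML_NS, "speciesReference"))
                    ref.set("species", sid)
                    ref.set("stoichiometry", str(stoich))
            if rxn.products:
                lst = etree.SubElement(el, _q(SBML_NS, "listOfProducts"))
                for sid, stoich in rxn.products:
                    ref = etree.SubElement(lst, _q(SBML_NS, "speciesReference"))
                    ref.set("species", sid)
                    ref.set("stoichiometry", str(stoich))
            if rxn.modifiers:
                lst = etree.SubElement(el, _q(SBML_NS, "listOfModifiers"))
                for sid in rxn.modifiers:
                    ref = etree.SubElement(lst, _q(SBML_NS, "modifierSpeciesReference"))
                    ref.set("species", sid)
            kl = etree.SubElement(el, _q(SBML_NS, "kineticLaw"))
            kl.append(mathml_from_expr(rxn.kinetic_law))

    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)
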