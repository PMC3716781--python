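"""Reference fixtures: the two MPF cell-cycle models and their facet records.

Model 1 is the six-ODE description of maturation promoting factor (MPF)
formation and activation: cdc2 (``C2``), phosphorylated cdc2 (``CP``),
inactive MPF (``pM``), active MPF (``M``), cyclin (``Y``) and
phosphorylated cyclin (``YP``), with ATP (written ``AP`` since ``~P`` is
not a legal SBML id) and amino acids (``aa``) held constant.  It is
constructed reaction-wise — the sparse reaction set below is the unique
decomposition whose derived programme reproduces the printed rate
equations — with the activation step governed by the autocatalytic rate
function ``F(M) = k4' + k4 (M/CT)^2`` over the conserved total cdc2
``CT = C2 + CP + pM + M``.

Model 2 is its two-variable abstraction in the relative concentrations
``u = M/CT`` and ``v = (Y + pM + M)/CT``, with ``alpha = k4'/k4`` and the
lumped cyclin synthesis rate ``ks = k1[aa]/[CT]`` exposed as a single
parameter.

The source publication's parameter table is not reproduced here; all
concrete parameter points are produced by :func:`find_regime_parameters`,
a seeded random search that returns a point classifying to a requested
dynamics regime under the default protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dynamics_classifier import (
    EXCITABLE_SWITCH,
    LIMIT_CYCLE_OSCILLATION,
    STABLE_FIXED_POINT,
    TEDDY_HOPF,
    TEDDY_STABLE_FIXED_POINT,
    ClassificationProtocol,
    DymlDocument,
    DymlStatement,
    DynamicsClass,
    classify,
)
from .facet_schema import (
    AccessRef,
    Annotation,
    FacetAddress,
    FacetRecord,
    GlobalMeta,
    ModelRelationRef,
    StructuredRef,
    TaxonomyFragment,
)
from .sbml_io import OdeModel, Reaction, Species, check_model, harvest_record, parse_arith
from .sim_engine import Instantiation, SimulationSetup, SolverFailure, instantiate

__all__ = [
    "FixtureBundle",
    "SearchSpec",
    "MODEL1_SEARCH_SPEC",
    "MODEL2_SEARCH_SPEC",
    "tyson_model1",
    "tyson_model2",
    "find_regime_parameters",
    "populate_dynamics",
    "taxonomy_fragment",
]


@dataclass
class FixtureBundle:
    model: OdeModel
    record: FacetRecord
    sedml: Optional[SimulationSetup] = None
    dyml: Optional[DymlDocument] = None
    regime_points: dict[str, Instantiation] = field(default_factory=dict)


@dataclass
class SearchSpec:
    """Bounds and fixed values for the regime-parameter search."""

    bounds: dict[str, tuple[float, float]]
    fixed: dict[str, float] = field(default_factory=dict)
    initial_values: dict[str, float] = field(default_factory=dict)
    budget: int = 200
    log_scale: bool = True
    #: variable perturbed by the excitability probe (cyclin accumulation is
    #: the physiological trigger)
    perturb_symbol: Optional[str] = None


#: The documented unfilled extrinsic aspects of the fixture records: the
#: source publication gives no biological initial state, no experimental
#: settings or result calculation, and no concrete measurements or results.
DOCUMENTED_GAPS = frozenset({
    "F2:extrinsic:initial_state",
    "F3:extrinsic:experimental_settings",
    "F3:extrinsic:result_calculation",
    "B2:extrinsic:measurements",
    "B2:extrinsic:key",
    "B3:extrinsic:results",
})


# ---------------------------------------------------------------------------
# Model 1
# ---------------------------------------------------------------------------

def _model1_ode_model() -> OdeModel:
    model = OdeModel(
        id="tyson_model1",
        name="MPF formation/activation cell-cycle model (six ODEs)",
        annotations=[Annotation("obo.go", "GO:0000278"),
                     Annotation("taxonomy", "7625"),
                     Annotation("taxonomy", "33511"),
                     Annotation("taxonomy", "6072")],
    )
    model.species = [
        Species("C2", name="cdc2k",
                annotations=[Annotation("uniprot", "P04551"),
                             Annotation("biomodels.sbo", "SBO:0000252")]),
        Species("CP", name="cdc2k-P"),
        Species("pM", name="preMPF (inactive)"),
        Species("M", name="active MPF"),
        Species("Y", name="cyclin"),
        Species("YP", name="cyclin-P"),
        Species("AP", name="~P (adenosine triphosphate)", initial_amount=1.0,
                constant=True),
        Species("aa", name="amino acids", initial_amount=1.0, constant=True),
    ]
    model.parameters = {k: None for k in
                        ("k1", "k2", "k3", "k4", "k4p", "k5", "k6", "k7", "k8", "k9")}
    model.algebraic = {
        "CT": parse_arith("C2 + CP + pM + M"),
        "YT": parse_arith("Y + YP + pM + M"),
        "F_M": parse_arith("k4p + k4*(M/CT)**2"),
    }
    model.reactions = [
        Reaction("R_synthesis", parse_arith("k1*aa"),
                 reactants=[("aa", 1)], products=[("Y", 1)],
                 name="cyclin synthesis"),
        Reaction("R_degradation", parse_arith("k2*Y"),
                 reactants=[("Y", 1)], name="cyclin degradation"),
        Reaction("R_association", parse_arith("k3*CP*Y"),
                 reactants=[("CP", 1), ("Y", 1)], products=[("pM", 1)],
                 name="cyclin cdc2k-P association"),
        Reaction("R_activation", parse_arith("pM*F_M"),
                 reactants=[("pM", 1)], products=[("M", 1)], modifiers=["M"],
                 name="preMPF activation (autocatalytic)"),
        Reaction("R_inactivation", parse_arith("k5*AP*M"),
                 reactants=[("M", 1)], products=[("pM", 1)], modifiers=["AP"],
                 name="MPF inactivation"),
        Reaction("R_dissociation", parse_arith("k6*M"),
                 reactants=[("M", 1)], products=[("C2", 1), ("YP", 1)],
                 name="cyclin cdc2k dissociation",
                 annotations=[Annotation("biomodels.sbo", "SBO:0000180"),
                              Annotation("reactome", "REACT_6308")]),
        Reaction("R_yp_degradation", parse_arith("k7*YP"),
                 reactants=[("YP", 1)], name="cyclin-P degradation"),
        Reaction("R_phosphorylation", parse_arith("k8*AP*C2"),
                 reactants=[("C2", 1)], products=[("CP", 1)], modifiers=["AP"],
                 name="cdc2k phosphorylation"),
        Reaction("R_dephosphorylation", parse_arith("k9*CP"),
                 reactants=[("CP", 1)], products=[("C2", 1)],
                 name="cdc2k dephosphorylation"),
    ]
    # fixture initial state: all cdc2 phosphorylated, no cyclin yet; CT = 1
    model.get_species("CP").initial_amount = 1.0
    check_model(model)
    return model


def _fill_common_extras(record: FacetRecord, sedml_ref: str) -> None:
    """Fill the record aspects shared by both fixtures beyond the harvest."""
    A = FacetAddress
    record.fill(A("structure", 1, "intrinsic", "formalism"),
                text="coupled ODEs over continuous state variables in time t "
                     "(minutes); deterministic, non-spatial",
                annotations=[Annotation("biomodels.sbo", "SBO:0000293")])
    record.fill(A("structure", 1, "extrinsic", "biological_system"),
                text="MPF formation and activation controlling major cell-cycle "
                     "events (frog, sea urchin, fission yeast)",
                annotations=[Annotation("obo.go", "GO:0000278")])
    record.fill(A("structure", 1, "extrinsic", "conceptual_level"),
                text="pools of molecular entities; no spatial effects (high copy "
                     "numbers, fast diffusion)")
    record.fill(A("structure", 2, "extrinsic", "quantities"),
                text="molar concentration of each substance",
                annotations=[Annotation("biomodels.sbo", "SBO:0000472")])
    record.fill(A("structure", 3, "extrinsic", "mechanisms"),
                text="mass-action kinetics for all steps except the "
                     "autocatalytic activation",
                annotations=[Annotation("biomodels.sbo", "SBO:0000012")])
    record.fill(A("function", 1, "intrinsic", "intended_use"),
                text="generation of time series through numerical integration; "
                     "reported observables are relative MPF and total cyclin")
    record.fill(A("function", 1, "intrinsic", "constraints"),
                text="total cdc2 CT is constant; cyclin degradation is slow "
                     "against association (k2 << k3*CT)")
    record.fill(A("function", 1, "extrinsic", "questions"),
                text="can one mechanism account for metaphase arrest, rapid "
                     "embryonic division cycles and growth-controlled cycles?")
    record.fill(A("function", 1, "extrinsic", "assumptions"),
                text="cdc2 is synthesised at a constant rate in growing cells, "
                     "supporting CT = const")
    record.fill(A("function", 2, "intrinsic", "instantiation"),
                text="rate constants k1..k9 and k4' assigned per simulation "
                     "experiment; regime points via seeded search")
    record.fill(A("function", 2, "extrinsic", "boundary_conditions"),
                text="conditions of early embryonic cells; no experimental "
                     "kinetic data available",
                annotations=[Annotation("cl", "CL:0000007")])
    record.fill(A("function", 3, "intrinsic", "setup"),
                text="uniform time course 0-100 min, step 0.001 min",
                annotations=[Annotation("kisao", "KISAO_0000280")],
                structured=[StructuredRef("simulation_setup", sedml_ref)])
    record.fill(A("function", 3, "intrinsic", "post_processing"),
                text="normalise amounts of M and of total cyclin YT by the "
                     "conserved total CT")
    record.fill(A("behaviour", 1, "intrinsic", "dynamics"),
                text="stable steady state, spontaneous limit-cycle oscillation, "
                     "excitable switch — depending on the parameter setting",
                annotations=[TEDDY_STABLE_FIXED_POINT])
    record.fill(A("behaviour", 1, "intrinsic", "diversification"),
                text="supercritical Hopf bifurcation between steady state and "
                     "oscillation as k4 and k6 vary",
                annotations=[TEDDY_HOPF])
    record.fill(A("behaviour", 1, "extrinsic", "phenomena"),
                text="metaphase arrest in unfertilised eggs (steady state); rapid "
                     "division cycles in early embryos (oscillation); "
                     "growth-controlled cycles (excitable switch)",
                annotations=[Annotation("obo.go", "GO:0007050")])
    record.fill(A("behaviour", 1, "extrinsic", "variability"),
                text="different modes of operation observed in different "
                     "developmental stages")
    record.fill(A("behaviour", 2, "intrinsic", "raw_data"),
                text="series of amount values for each entity from time-course "
                     "simulation")
    record.fill(A("behaviour", 2, "intrinsic", "index"),
                text="modelling time t in minutes")
    record.fill(A("behaviour", 3, "intrinsic", "outcome"),
                text="plots of M/CT and YT/CT against time under different "
                     "settings; regime regions in the (k4, k6) plane")
    record.fill(A("behaviour", 3, "intrinsic", "characteristics"),
                text="relative steady-state amount of M; period of the oscillation")
    record.fill(A("behaviour", 3, "extrinsic", "observables"),
                text="period of division cycles; maximal and minimal relative "
                     "concentrations")


def tyson_model1() -> FixtureBundle:
    """Model 1 (six ODEs), its facet record and the reference time-course setup."""
    model = _model1_ode_model()
    record = harvest_record(model)
    _fill_common_extras(record, sedml_ref="tyson_model1_timecourse")
    record.slot(FacetAddress("structure", 2, "extrinsic", "objects")).text = \
        "C2 is the cyclin-dependent kinase 1 protein; Y is cyclin; pM/M are the " \
        "inactive/active cyclin-cdc2 dimer"
    record.slot(FacetAddress("structure", 3, "extrinsic", "interactions")).text = \
        "R_dissociation is the cyclin cdc2k dissociation step"
    record.meta = GlobalMeta(
        publication_id="1831270",
        authors=["John J. Tyson"],
        date="1991-08",
        access=[AccessRef("http://identifiers.org/biomodels.db/BIOMD0000000005",
                          format="SBML L2V4")],
        relations=[ModelRelationRef("tyson_model2", "abstraction",
                                    note="tyson_model2 is a two-variable "
                                         "abstraction of this model")],
    )
    sedml = SimulationSetup(
        t_start=0.0, t_end=100.0, step=0.001,
        algorithm=Annotation("kisao", "KISAO_0000280"),
        postprocess={"M_over_CT": "M/CT", "YT_over_CT": "YT/CT"},
    )
    return FixtureBundle(model=model, record=record, sedml=sedml)


# ---------------------------------------------------------------------------
# Model 2
# ---------------------------------------------------------------------------

def _model2_ode_model() -> OdeModel:
    model = OdeModel(
        id="tyson_model2",
        name="two-variable MPF abstraction",
        annotations=[Annotation("obo.go", "GO:0000278")],
    )
    model.species = [
        Species("u", name="relative active MPF, u = M/CT"),
        Species("v", name="relative total cyclin pool, v = (Y + pM + M)/CT"),
    ]
    # ks is the lumped synthesis rate k1[aa]/[CT]
    model.parameters = {"k4": None, "k4p": None, "k6": None, "ks": None}
    model.algebraic = {"alpha": parse_arith("k4p/k4")}
    # the two rate equations are represented as independent production /
    # consumption steps so each species' derivative matches its equation
    model.reactions = [
        Reaction("R_u_activation", parse_arith("k4*(v - u)*(alpha + u**2)"),
                 products=[("u", 1)], modifiers=["v"],
                 name="autocatalytic MPF activation (relative)"),
        Reaction("R_u_loss", parse_arith("k6*u"),
                 reactants=[("u", 1)], name="MPF dissociation (relative)"),
        Reaction("R_v_synthesis", parse_arith("ks"),
                 products=[("v", 1)], name="lumped cyclin synthesis"),
        Reaction("R_v_loss", parse_arith("k6*u"),
                 reactants=[("v", 1)], modifiers=["u"],
                 name="cyclin pool consumption by dissociation"),
    ]
    check_model(model)
    return model


def tyson_model2() -> FixtureBundle:
    """Model 2 (two-variable abstraction) and its facet record."""
    model = _model2_ode_model()
    record = harvest_record(model)
    _fill_common_extras(record, sedml_ref="tyson_model2_timecourse")
    record.slot(FacetAddress("structure", 2, "extrinsic", "objects")).text = \
        "u and v have no direct biological counterpart; their meaning derives " \
        "from the defining relations u = M/CT and v = (Y + pM + M)/CT"
    record.slot(FacetAddress("structure", 3, "extrinsic", "interactions")).text = \
        "lumped interactions; the reaction-level reading of the abstraction is " \
        "not one-to-one with the protein-protein network"
    record.meta = GlobalMeta(
        publication_id="1831270",
        authors=["John J. Tyson"],
        date="1991-08",
        access=[AccessRef("http://identifiers.org/biomodels.db/BIOMD0000000006",
                          format="SBML L2V4")],
        relations=[
            ModelRelationRef("tyson_model1", "abstraction",
                             note="this model is an abstraction of tyson_model1"),
            ModelRelationRef("Brusselator", "modified_version_of",
                             note="a modified version of the Brusselator"),
        ],
    )
    sedml = SimulationSetup(
        t_start=0.0, t_end=100.0, step=0.01,
        algorithm=Annotation("kisao", "KISAO_0000280"),
        postprocess={"u": "u", "v": "v"},
    )
    return FixtureBundle(model=model, record=record, sedml=sedml)


# ---------------------------------------------------------------------------
# Regime-parameter search
# ---------------------------------------------------------------------------

MODEL2_SEARCH_SPEC = SearchSpec(
    bounds={"k4": (10.0, 3000.0), "k4p": (1e-3, 3.0),
            "k6": (0.05, 5.0), "ks": (0.005, 0.1)},
    initial_values={"u": 0.0, "v": 0.0},
    budget=200,
    perturb_symbol="v",
)

#: Model 1 search: the fast steps (association, phosphorylation cycle) are
#: held at package-chosen rates so the slow (k4, k6, synthesis) subsystem
#: explores the same regimes as the two-variable abstraction.
MODEL1_SEARCH_SPEC = SearchSpec(
    bounds={"k1": (0.005, 0.1), "k4": (10.0, 3000.0),
            "k4p": (1e-3, 3.0), "k6": (0.05, 5.0)},
    fixed={"k2": 0.0, "k3": 300.0, "k5": 0.0, "k7": 0.6, "k8": 200.0, "k9": 2.0},
    initial_values={"C2": 0.0, "CP": 1.0, "pM": 0.0, "M": 0.0, "Y": 0.0, "YP": 0.0},
    budget=400,
    perturb_symbol="Y",
)


class RegimeNotFound(RuntimeError):
    pass


def find_regime_parameters(
    model: OdeModel,
    target_label: str,
    spec: Optional[SearchSpec] = None,
    seed: int = 1,
    protocol: Optional[ClassificationProtocol] = None,
) -> Instantiation:
    """Seeded random search for a parameter point classifying as *target_label*.

    Draws log-uniformly (by default) from the spec bounds, classifies each
    draw under the default protocol, and returns the first hit.
    Deterministic given the seed; raises :class:`RegimeNotFound` listing
    the classes encountered if the budget is exhausted.
    """
    if spec is None:
        spec = MODEL2_SEARCH_SPEC if model.id == "tyson_model2" else MODEL1_SEARCH_SPEC
    protocol = protocol or ClassificationProtocol(perturb_symbol=spec.perturb_symbol)
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    names = sorted(spec.bounds)
    for _ in range(spec.budget):
        draw = {}
        for name in names:
            lo, hi = spec.bounds[name]
            if spec.log_scale and lo > 0:
                draw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                draw[name] = float(rng.uniform(lo, hi))
        draw.update(spec.fixed)
        inst = Instantiation(parameter_values=draw,
                             initial_values=dict(spec.initial_values))
        try:
            cls, _ = classify(instantiate(model, inst), protocol)
        except SolverFailure:
            seen.add("solver_failure")
            continue
        seen.add(cls.label)
        if cls.label == target_label:
            return inst
    raise RegimeNotFound(
        f"no {target_label!r} point within budget {spec.budget}; "
        f"classes encountered: {sorted(seen)}")


def populate_dynamics(
    bundle: FixtureBundle,
    seed: int = 1,
    labels: tuple[str, ...] = (STABLE_FIXED_POINT, LIMIT_CYCLE_OSCILLATION,
                               EXCITABLE_SWITCH),
    spec: Optional[SearchSpec] = None,
    protocol: Optional[ClassificationProtocol] = None,
) -> FixtureBundle:
    """Fill ``bundle.regime_points`` (and a DYML document) by seeded search.

    The DYML statements assert, for each found regime point, that the
    dynamics class is constant over a tight box around the point in
    (k4, k6) — only those two parameters are allowed to vary, all others
    are fixed at the point's values.
    """
    for label in labels:
        if label not in bundle.regime_points:
            bundle.regime_points[label] = find_regime_parameters(
                bundle.model, label, spec=spec, seed=seed, protocol=protocol)
    statements = []
    for label, inst in sorted(bundle.regime_points.items()):
        constraints: dict[str, tuple[float, float] | float] = {}
        for sym, value in sorted(inst.parameter_values.items()):
            if sym in ("k4", "k6"):
                constraints[sym] = (value / 1.02, value * 1.02)
            else:
                constraints[sym] = value
        statements.append(DymlStatement(
            constraints=constraints,
            asserted=DynamicsClass.of(label),
            note=f"seeded regime point for {label} (seed {seed})"))
    bundle.dyml = DymlDocument(model_ref=bundle.model.id, statements=statements)
    return bundle


# ---------------------------------------------------------------------------
# Taxonomy fragment
# ---------------------------------------------------------------------------

def taxonomy_fragment() -> TaxonomyFragment:
    """Lineage fragment for the organisms the models address.

    Sea urchin (7625) and frog are siblings under Deuterostomia (33511),
    itself under Eumetazoa (6072).  The frog node carries a label-only id
    (no numeric accession is packaged); a real NCBI taxon id would
    replace it.
    """
    return TaxonomyFragment(
        nodes={
            "7625": "sea urchin",
            "frog": "frog",
            "33511": "Deuterostomia",
            "6072": "Eumetazoa",
        },
        parent={"7625": "33511", "frog": "33511", "33511": "6072"},
    )
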