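"""Execution of the functional facets: instantiation, time courses, post-processing.

A model becomes simulable only once fully instantiated — every parameter
assigned and every state given a non-negative initial value.  A
:class:`SimulationSetup` describes the experiment itself: a uniform
time-course grid in minutes, the algorithm annotation (a KiSAO term,
recorded as metadata), optional instantaneous state perturbations, and
named post-processing expressions that turn raw per-species series into
the outcome series (e.g. amounts normalised by the conserved total).

Integration uses a stiff-capable solver (LSODA) with tight tolerances;
the output grid is produced by dense evaluation, decoupled from the
solver's internal steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import sympy
from lxml import etree
from scipy.integrate import solve_ivp

from .facet_schema import Annotation
from .sbml_io import (
    OdeModel,
    Programme,
    UnsupportedFeatureError,
    build_programme,
    expand_expr,
    parse_arith,
)

__all__ = [
    "Instantiation",
    "Perturbation",
    "SimulationSetup",
    "Trajectory",
    "SimInstance",
    "SolverFailure",
    "instantiate",
    "run_timecourse",
    "postprocess",
    "trajectory_to_table",
    "read_sedml_lite",
    "write_sedml_lite",
]

DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-9
NEGATIVITY_TOLERANCE = 1e-9


class SolverFailure(RuntimeError):
    def __init__(self, message: str, last_good_time: Optional[float] = None):
        super().__init__(message)
        self.last_good_time = last_good_time


@dataclass
class Instantiation:
    """Concrete parameter values and initial state values (the F2 content)."""

    parameter_values: dict[str, float] = field(default_factory=dict)
    initial_values: dict[str, float] = field(default_factory=dict)

    def override(self, **params: float) -> "Instantiation":
        merged = dict(self.parameter_values)
        merged.update(params)
        return Instantiation(merged, dict(self.initial_values))


@dataclass(frozen=True)
class Perturbation:
    time: float
    symbol: str
    delta: float


@dataclass
class SimulationSetup:
    t_start: float
    t_end: float
    step: float
    algorithm: Optional[Annotation] = None
    perturbations: list[Perturbation] = field(default_factory=list)
    postprocess: dict[str, str] = field(default_factory=dict)  # name -> expression
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")
        if not self.step > 0:
            raise ValueError("step must be positive")
        if self.step > self.t_end - self.t_start:
            raise ValueError("step exceeds the simulation horizon")
        for p in self.perturbations:
            if not (self.t_start <= p.time <= self.t_end):
                raise ValueError(f"perturbation at t={p.time} outside the horizon")

    def grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.step))
        return self.t_start + self.step * np.arange(n + 1)


@dataclass
class Trajectory:
    """Raw simulation data (time-indexed state matrix) plus outcome series."""

    raw: pd.DataFrame  # index: time grid; columns: state symbols
    outcome: pd.DataFrame  # index: time grid; columns: post-processed names

    @property
    def index(self) -> np.ndarray:
        return self.raw.index.to_numpy()


class SimInstance:
    """A closed (fully instantiated) system ready for numerical integration."""

    def __init__(self, model: OdeModel, programme: Programme,
                 instantiation: Instantiation):
        self.model = model
        self.programme = programme
        self.instantiation = instantiation
        self.state_symbols = list(programme.state_symbols)
        subs = {sympy.Symbol(k): float(v)
                for k, v in instantiation.parameter_values.items()}
        for sp in model.species:
            if sp.constant:
                subs[sympy.Symbol(sp.id)] = float(
                    instantiation.initial_values.get(sp.id, sp.initial_amount))
        exprs = []
        for sid in self.state_symbols:
            expr = expand_expr(model, programme.rhs[sid]).subs(subs)
            remaining = {s.name for s in expr.free_symbols} - set(self.state_symbols)
            if remaining:
                raise ValueError(
                    f"rhs of {sid} still contains unset symbols {sorted(remaining)}")
            exprs.append(expr)
        self._rhs_exprs = exprs
        syms = [sympy.Symbol(s) for s in self.state_symbols]
        self._f = sympy.lambdify(syms, exprs, modules="numpy")
        self._jac_exprs = sympy.Matrix(exprs).jacobian(sympy.Matrix(syms))
        self._jac = sympy.lambdify(syms, self._jac_exprs, modules="numpy")

    def rhs(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(self._f(*y), dtype=float)

    def jacobian(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(self._jac(*y), dtype=float)

    def initial_state(self) -> np.ndarray:
        return np.array(
            [self.instantiation.initial_values[s] for s in self.state_symbols],
            dtype=float)


def instantiate(model: OdeModel, inst: Instantiation) -> SimInstance:
    """Close the model over an instantiation, rejecting partial ones."""
    programme = build_programme(model)
    unset = [name for name, value in model.parameters.items()
             if value is None and name not in inst.parameter_values]
    if unset:
        raise ValueError(f"unset parameters: {sorted(unset)}")
    merged_params = {name: value for name, value in model.parameters.items()
                     if value is not None}
    merged_params.update(inst.parameter_values)
    initials = dict(inst.initial_values)
    for sid in programme.state_symbols:
        if sid not in initials:
            initials[sid] = model.get_species(sid).initial_amount
    negative = {k: v for k, v in initials.items() if v < 0}
    if negative:
        raise ValueError(f"negative initial values: {negative}")
    return SimInstance(model, programme,
                       Instantiation(merged_params, initials))


def _integrate_segment(instance: SimInstance, t0: float, t1: float, y0: np.ndarray,
                       t_eval: np.ndarray, rtol: float, atol: float):
    sol = solve_ivp(
        lambda t, y: instance.rhs(y), (t0, t1), y0,
        method="LSODA", jac=lambda t, y: instance.jacobian(y),
        t_eval=t_eval if len(t_eval) else None,
        rtol=rtol, atol=atol, dense_output=False,
    )
    if not sol.success:
        last = float(sol.t[-1]) if len(sol.t) else t0
        raise SolverFailure(f"integration failed: {sol.message}", last_good_time=last)
    return sol


def run_timecourse(instance: SimInstance, setup: SimulationSetup) -> Trajectory:
    """Integrate over the uniform grid, applying perturbations as state jumps."""
    grid = setup.grid()
    y = instance.initial_state()
    rows = np.empty((len(grid), len(instance.state_symbols)))
    computed = np.zeros(len(grid), dtype=bool)
    # zero-delta perturbations are exact no-ops: they must not even split
    # the integration (a solver restart would change the step sequence)
    jumps = [p for p in setup.perturbations if p.delta != 0.0]
    segment_edges = [setup.t_start] + sorted(
        {p.time for p in jumps
         if setup.t_start < p.time < setup.t_end}) + [setup.t_end]
    # perturbations exactly at t_start apply before integration
    for p in jumps:
        if p.time == setup.t_start:
            y[instance.state_symbols.index(p.symbol)] += p.delta
    if grid[0] == setup.t_start:
        rows[0] = y
        computed[0] = True
    for t0, t1 in zip(segment_edges[:-1], segment_edges[1:]):
        mask = (grid > t0) & (grid <= t1) & ~computed
        t_eval = grid[mask]
        need_endpoint = len(t_eval) == 0 or t_eval[-1] != t1
        eval_times = np.append(t_eval, t1) if need_endpoint else t_eval
        sol = _integrate_segment(instance, t0, t1, y, eval_times,
                                 setup.rtol, setup.atol)
        values = sol.y.T
        if need_endpoint:
            rows[mask] = values[:-1]
            y = values[-1].copy()
        else:
            rows[mask] = values
            y = values[-1].copy()
        computed |= mask
        for p in jumps:
            if p.time == t1 and t1 != setup.t_end:
                y[instance.state_symbols.index(p.symbol)] += p.delta
    if not computed.all():  # pragma: no cover - grid always inside horizon
        raise SolverFailure("output grid not fully covered")
    if rows.min() < -NEGATIVITY_TOLERANCE:
        worst = rows.min()
        raise SolverFailure(
            f"state went negative ({worst:.3e}); mass-action dynamics should stay "
            "non-negative — tighten tolerances")
    if not np.isfinite(rows).all():
        raise SolverFailure("non-finite values in trajectory")
    raw = pd.DataFrame(rows, index=pd.Index(grid, name="time"),
                       columns=instance.state_symbols)
    traj = Trajectory(raw=raw, outcome=pd.DataFrame(index=raw.index))
    if setup.postprocess:
        traj = postprocess(traj, instance.model, setup.postprocess,
                           parameter_values=instance.instantiation.parameter_values,
                           constant_values={
                               sp.id: instance.instantiation.initial_values.get(
                                   sp.id, sp.initial_amount)
                               for sp in instance.model.species if sp.constant})
    return traj


def postprocess(
    traj: Trajectory,
    model: OdeModel,
    expressions: Mapping[str, str],
    parameter_values: Optional[Mapping[str, float]] = None,
    constant_values: Optional[Mapping[str, float]] = None,
) -> Trajectory:
    """Evaluate named outcome expressions pointwise over the raw series.

    Expressions may reference state symbols, algebraic definitions (e.g.
    the conserved total ``CT``), parameters and constant species.  The raw
    data is left untouched.
    """
    columns = {}
    state_syms = [sympy.Symbol(c) for c in traj.raw.columns]
    subs = {}
    for name, value in (parameter_values or {}).items():
        subs[sympy.Symbol(name)] = float(value)
    for name, value in (constant_values or {}).items():
        subs[sympy.Symbol(name)] = float(value)
    for name, value in model.parameters.items():
        if value is not None:
            subs.setdefault(sympy.Symbol(name), float(value))
    for name, text in expressions.items():
        expr = expand_expr(model, parse_arith(text)).subs(subs)
        unknown = {s.name for s in expr.free_symbols} - set(traj.raw.columns)
        if unknown:
            raise ValueError(
                f"outcome expression {name!r} references unknown symbols "
                f"{sorted(unknown)}")
        f = sympy.lambdify(state_syms, expr, modules="numpy")
        values = f(*[traj.raw[c].to_numpy() for c in traj.raw.columns])
        columns[name] = np.broadcast_to(np.asarray(values, dtype=float),
                                        (len(traj.raw),)).copy()
    outcome = pd.DataFrame(columns, index=traj.raw.index)
    return Trajectory(raw=traj.raw, outcome=outcome)


def trajectory_to_table(traj: Trajectory) -> str:
    """Tab-delimited export with a header row; time is the first column."""
    df = pd.concat([traj.raw, traj.outcome], axis=1)
    return df.to_csv(sep="\t", index=True, float_format="%.10g")


# ---------------------------------------------------------------------------
# SED-ML-lite
# ---------------------------------------------------------------------------

SEDML_LITE_NS = "https://biofacets.dev/ns/sedml-lite"
SEDML_LITE_VERSION = "1"


def write_sedml_lite(setup: SimulationSetup,
                     overrides: Optional[Instantiation] = None) -> bytes:
    """Serialize a uniform-time-course description (subset-marked, not SED-ML)."""
    if setup.algorithm is None:
        raise ValueError("setup must carry an algorithm annotation")
    root = etree.Element("sedmlLite", nsmap={None: SEDML_LITE_NS})
    root.set("version", SEDML_LITE_VERSION)
    sim = etree.SubElement(root, f"{{{SEDML_LITE_NS}}}uniformTimeCourse")
    sim.set("start", repr(setup.t_start))
    sim.set("end", repr(setup.t_end))
    sim.set("step", repr(setup.step))
    alg = etree.SubElement(sim, f"{{{SEDML_LITE_NS}}}algorithm")
    alg.set("kisaoID", setup.algorithm.identifier)
    overrides = overrides or Instantiation()
    if overrides.parameter_values or overrides.initial_values:
        changes = etree.SubElement(root, f"{{{SEDML_LITE_NS}}}listOfChanges")
        for name in sorted(overrides.parameter_values):
            el = etree.SubElement(changes, f"{{{SEDML_LITE_NS}}}changeParameter")
            el.set("target", name)
            el.set("value", repr(overrides.parameter_values[name]))
        for name in sorted(overrides.initial_values):
            el = etree.SubElement(changes, f"{{{SEDML_LITE_NS}}}changeInitial")
            el.set("target", name)
            el.set("value", repr(overrides.initial_values[name]))
    if setup.perturbations:
        pl = etree.SubElement(root, f"{{{SEDML_LITE_NS}}}listOfPerturbations")
        for p in setup.perturbations:
            el = etree.SubElement(pl, f"{{{SEDML_LITE_NS}}}perturbation")
            el.set("time", repr(p.time))
            el.set("target", p.symbol)
            el.set("delta", repr(p.delta))
    if setup.postprocess:
        dg = etree.SubElement(root, f"{{{SEDML_LITE_NS}}}listOfDataGenerators")
        for name, expression in setup.postprocess.items():
            el = etree.SubElement(dg, f"{{{SEDML_LITE_NS}}}dataGenerator")
            el.set("id", name)
            el.set("math", expression)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def read_sedml_lite(document: str | bytes) -> tuple[SimulationSetup, Instantiation]:
    if isinstance(document, str):
        document = document.encode()
    root = etree.fromstring(document)
    if etree.QName(root).localname != "sedmlLite" \
            or etree.QName(root).namespace != SEDML_LITE_NS:
        raise UnsupportedFeatureError(
            "not a sedmlLite document (this reader handles the subset format only)")
    if root.get("version") != SEDML_LITE_VERSION:
        raise UnsupportedFeatureError(
            f"unsupported sedmlLite version {root.get('version')!r}")
    sims = [c for c in root if isinstance(c.tag, str)
            and etree.QName(c).localname not in
            {"listOfChanges", "listOfPerturbations", "listOfDataGenerators"}]
    if len(sims) != 1 or etree.QName(sims[0]).localname != "uniformTimeCourse":
        kinds = [etree.QName(s).localname for s in sims]
        raise UnsupportedFeatureError(
            f"expected exactly one uniformTimeCourse simulation, got {kinds}")
    sim = sims[0]
    alg = sim.find(f"{{{SEDML_LITE_NS}}}algorithm")
    if alg is None or not alg.get("kisaoID"):
        raise ValueError("uniformTimeCourse lacks an algorithm element with kisaoID")
    perturbations = []
    pl = root.find(f"{{{SEDML_LITE_NS}}}listOfPerturbations")
    if pl is not None:
        perturbations = [
            Perturbation(float(p.get("time")), p.get("target"), float(p.get("delta")))
            for p in pl.findall(f"{{{SEDML_LITE_NS}}}perturbation")
        ]
    post = {}
    dg = root.find(f"{{{SEDML_LITE_NS}}}listOfDataGenerators")
    if dg is not None:
        for el in dg.findall(f"{{{SEDML_LITE_NS}}}dataGenerator"):
            post[el.get("id")] = el.get("math")
    setup = SimulationSetup(
        t_start=float(sim.get("start")),
        t_end=float(sim.get("end")),
        step=float(sim.get("step")),
        algorithm=Annotation("kisao", alg.get("kisaoID")),
        perturbations=perturbations,
        postprocess=post,
    )
    overrides = Instantiation()
    changes = root.find(f"{{{SEDML_LITE_NS}}}listOfChanges")
    if changes is not None:
        for el in changes.findall(f"{{{SEDML_LITE_NS}}}changeParameter"):
            overrides.parameter_values[el.get("target")] = float(el.get("value"))
        for el in changes.findall(f"{{{SEDML_LITE_NS}}}changeInitial"):
            overrides.initial_values[el.get("target")] = float(el.get("value"))
    return setup, overrides
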