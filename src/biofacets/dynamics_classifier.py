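"""Qualitative dynamics: classification, regime maps, bifurcation boundaries, DYML.

The behavioural meaning of a kinetic model is a qualitative description
of what its simulations do.  For the supported model family three
regimes matter: a stable fixed point (labelled with the TEDDY term for
"Stable Fixed Point"), a spontaneous limit-cycle oscillation, and an
excitable switch — a stable steady state from which a suprathreshold
perturbation triggers a large excursion before return.

Classification is purely simulation-based and deterministic given the
(instance, protocol) pair.  A closed-form linearization check
(:func:`jacobian_class_at_fixed_point`) is provided as an independent
oracle: wherever the classifier reports a stable fixed point, the
eigenvalues of the Jacobian at the detected steady state must all have
negative real part.  Fixed-point/oscillation boundaries of a
two-parameter regime scan are refined by bisection on the leading
eigenvalue real part of the continued equilibrium; a crossing through
zero is a Hopf bifurcation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import yaml
from scipy.optimize import root
from scipy.signal import find_peaks
from scipy.stats import qmc

from .facet_schema import Annotation
from .sbml_io import OdeModel
from .sim_engine import (
    Instantiation,
    SimInstance,
    SimulationSetup,
    SolverFailure,
    instantiate,
    run_timecourse,
)

__all__ = [
    "STABLE_FIXED_POINT",
    "LIMIT_CYCLE_OSCILLATION",
    "EXCITABLE_SWITCH",
    "UNCLASSIFIED",
    "TEDDY_STABLE_FIXED_POINT",
    "TEDDY_HOPF",
    "DynamicsClass",
    "Characteristics",
    "ClassificationProtocol",
    "RegimeMap",
    "BifurcationPoint",
    "DymlStatement",
    "DymlDocument",
    "DymlVerdict",
    "classify",
    "find_equilibrium",
    "jacobian_class_at_fixed_point",
    "scan",
    "locate_bifurcation",
    "check_dyml",
    "dyml_to_yaml",
    "dyml_from_yaml",
]

STABLE_FIXED_POINT = "stable_fixed_point"
LIMIT_CYCLE_OSCILLATION = "limit_cycle_oscillation"
EXCITABLE_SWITCH = "excitable_switch"
UNCLASSIFIED = "unclassified"

LABELS = (STABLE_FIXED_POINT, LIMIT_CYCLE_OSCILLATION, EXCITABLE_SWITCH, UNCLASSIFIED)

TEDDY_STABLE_FIXED_POINT = Annotation("teddy", "TEDDY_0000113")
TEDDY_HOPF = Annotation("teddy", "TEDDY_0000074")


@dataclass(frozen=True)
class DynamicsClass:
    label: str
    teddy: Optional[Annotation] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown dynamics label {self.label!r}")

    @classmethod
    def of(cls, label: str) -> "DynamicsClass":
        teddy = TEDDY_STABLE_FIXED_POINT if label == STABLE_FIXED_POINT else None
        return cls(label, teddy)


@dataclass
class Characteristics:
    """B3 characteristics: steady states, period, per-state extrema, excursions."""

    steady_state_values: Optional[dict[str, float]] = None
    period: Optional[float] = None
    amplitude_extrema: Optional[dict[str, tuple[float, float]]] = None
    excursion_magnitude: Optional[float] = None
    diagnostic: Optional[str] = None


@dataclass
class ClassificationProtocol:
    """All knobs of the classification procedure, pinned so runs are reproducible.

    Times are minutes.  The transient fraction of the horizon is
    discarded before any test.  A fixed point requires relative
    post-transient variation below ``tol_fp`` in every state; an
    oscillation requires at least ``min_peaks`` successive peaks with a
    period coefficient of variation below ``period_cv_tol`` and a
    stationary peak amplitude; a detected fixed point is probed for
    excitability by perturbing ``perturb_symbol`` (default: the last
    state variable, the slow accumulating one in the supported models)
    upward by ``perturbation_rel`` of its steady-state value — an
    excursion at least ``excitability_ratio`` times the perturbation
    that returns to the fixed point marks an excitable switch.
    """

    horizon: float = 600.0
    n_points: int = 6000
    transient_fraction: float = 0.5
    tol_fp: float = 1e-6
    min_peaks: int = 5
    period_cv_tol: float = 0.01
    amplitude_tol: float = 0.05
    decay_ratio: float = 0.8
    excitability_ratio: float = 10.0
    perturbation_rel: float = 0.05
    perturb_symbol: Optional[str] = None
    rtol: float = 1e-9
    atol: float = 1e-9
    #: if the verdict is still open after one horizon, continue from the
    #: endpoint with a doubled horizon this many times before giving up
    max_extensions: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.transient_fraction < 1:
            raise ValueError("transient_fraction must lie in (0, 1)")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")


def _simulate(instance: SimInstance, protocol: ClassificationProtocol,
              horizon: float):
    # keep the output step at its base-horizon density even when the
    # horizon has been extended, so narrow relaxation spikes stay resolved
    step = protocol.horizon / protocol.n_points
    setup = SimulationSetup(
        t_start=0.0, t_end=horizon, step=step,
        rtol=protocol.rtol, atol=protocol.atol,
    )
    traj = run_timecourse(instance, setup)
    t = traj.index
    y = traj.raw.to_numpy()
    cut = int(len(t) * protocol.transient_fraction)
    return t[cut:], y[cut:]


def _relative_variation(window: np.ndarray) -> np.ndarray:
    hi = window.max(axis=0)
    lo = window.min(axis=0)
    scale = np.maximum(np.maximum(np.abs(hi), np.abs(lo)), 1e-12)
    return (hi - lo) / scale


def find_equilibrium(instance: SimInstance, guess: np.ndarray,
                     resid_tol: float = 1e-9) -> np.ndarray:
    """Newton-polish an approximate equilibrium; raises if no convergence.

    Acceptance is by residual, not by the optimizer's own success flag
    (the hybr stop criterion can report stalling at machine precision).
    """
    sol = root(lambda y: instance.rhs(y), guess,
               jac=lambda y: instance.jacobian(y), method="hybr")
    residual = float(np.abs(instance.rhs(sol.x)).max())
    if residual > resid_tol:
        raise SolverFailure(
            f"equilibrium search failed (max |rhs| = {residual:.3e}): {sol.message}")
    return sol.x


def _is_attracting(instance: SimInstance, equilibrium: np.ndarray,
                   protocol: ClassificationProtocol) -> bool:
    """Simulation-based stability check of an equilibrium.

    Nudge every state by a tiny relative amount and integrate; the
    equilibrium is attracting iff the deviation never grows by more than
    an order of magnitude.  (An unstable focus inside a relaxation limit
    cycle fails this immediately.)
    """
    scale = max(float(np.abs(equilibrium).max()), 1e-9)
    eps = 1e-4 * scale
    y0 = equilibrium + eps
    probe = SimInstance(instance.model, instance.programme,
                        Instantiation(dict(instance.instantiation.parameter_values),
                                      dict(zip(instance.state_symbols, y0))))
    setup = SimulationSetup(0.0, protocol.horizon / 4,
                            step=protocol.horizon / (4 * 200),
                            rtol=protocol.rtol, atol=protocol.atol)
    try:
        traj = run_timecourse(probe, setup)
    except SolverFailure:
        return False
    deviation = np.abs(traj.raw.to_numpy() - equilibrium[None, :]).max(axis=1)
    return float(deviation.max()) < 10.0 * eps * len(instance.state_symbols)


def _excitability_probe(
    instance: SimInstance,
    equilibrium: np.ndarray,
    protocol: ClassificationProtocol,
) -> tuple[bool, float]:
    """Perturb the settled state and measure the excursion before return."""
    symbols = instance.state_symbols
    sym = protocol.perturb_symbol or symbols[-1]
    idx = symbols.index(sym)
    scale = max(float(equilibrium[idx]), float(np.max(np.abs(equilibrium))), 1e-9)
    delta = protocol.perturbation_rel * scale
    y0 = equilibrium.copy()
    y0[idx] += delta
    probe = SimInstance(instance.model, instance.programme,
                        Instantiation(dict(instance.instantiation.parameter_values),
                                      dict(zip(symbols, y0))))
    setup = SimulationSetup(0.0, protocol.horizon / 2,
                            step=protocol.horizon / (2 * protocol.n_points),
                            rtol=protocol.rtol, atol=protocol.atol)
    traj = run_timecourse(probe, setup)
    deviation = np.abs(traj.raw.to_numpy() - equilibrium[None, :]).max(axis=1)
    excursion = float(deviation.max())
    returned = deviation[-1] < delta
    return (returned and excursion >= protocol.excitability_ratio * delta), excursion


def classify(
    instance: SimInstance,
    protocol: Optional[ClassificationProtocol] = None,
) -> tuple[DynamicsClass, Characteristics]:
    """Classify the dynamics of a closed model instance.

    Deterministic given (instance, protocol).  Solver failures propagate.
    If one horizon leaves the verdict open (e.g. the trajectory is still
    ramping toward a distant attractor), the run is continued from its
    endpoint with a doubled horizon up to ``protocol.max_extensions``
    times.
    """
    protocol = protocol or ClassificationProtocol()
    current = instance
    horizon = protocol.horizon
    for _ in range(protocol.max_extensions + 1):
        cls, ch, y_end = _classify_once(current, protocol, horizon)
        if cls.label != UNCLASSIFIED:
            return cls, ch
        current = SimInstance(
            instance.model, instance.programme,
            Instantiation(dict(instance.instantiation.parameter_values),
                          dict(zip(instance.state_symbols, map(float, y_end)))))
        horizon *= 2
    return cls, ch


def _classify_once(
    instance: SimInstance,
    protocol: ClassificationProtocol,
    horizon: float,
) -> tuple[DynamicsClass, Characteristics, np.ndarray]:
    t, window = _simulate(instance, protocol, horizon)
    symbols = instance.state_symbols
    variation = _relative_variation(window)

    if np.all(variation < protocol.tol_fp):
        equilibrium = find_equilibrium(instance, window[-1])
        return (*_fixed_point_or_excitable(instance, equilibrium, protocol),
                window[-1])

    # peak analysis, trying states in order of decreasing relative variation:
    # the slow variable of a relaxation oscillator gives smooth, reliably
    # sampled peaks where the fast variable's narrow spikes may not
    order = np.argsort(variation)[::-1]
    last_diag = None
    decaying_span = None
    for dom in order:
        signal = window[:, int(dom)]
        span = signal.max() - signal.min()
        if span <= 0:
            continue
        peaks, _ = find_peaks(signal, prominence=0.1 * span)
        if len(peaks) < protocol.min_peaks:
            continue
        # judge the trailing peaks only: early peaks may still ride the
        # wind-up transient toward the attractor
        tail_peaks = peaks[-(protocol.min_peaks + 1):]
        times = t[tail_peaks]
        intervals = np.diff(times)
        cv = intervals.std() / intervals.mean()
        if cv >= protocol.period_cv_tol:
            last_diag = f"period CV {cv:.3f} above tolerance"
            continue
        baseline = signal.min()
        amp_first = signal[tail_peaks[0]] - baseline
        amp_last = signal[tail_peaks[-1]] - baseline
        ratio = amp_last / amp_first if amp_first > 0 else np.inf
        if abs(ratio - 1.0) <= protocol.amplitude_tol:
            period = float(intervals.mean())
            tail = t >= t[-1] - 3 * period
            extrema = {
                s: (float(window[tail, i].min()), float(window[tail, i].max()))
                for i, s in enumerate(symbols)
            }
            return (DynamicsClass.of(LIMIT_CYCLE_OSCILLATION),
                    Characteristics(period=period, amplitude_extrema=extrema),
                    window[-1])
        full_ratio = ((signal[peaks[-1]] - baseline)
                      / max(signal[peaks[0]] - baseline, 1e-300))
        if full_ratio < protocol.decay_ratio:
            decaying_span = span
        last_diag = (f"peak amplitude ratio {ratio:.3f} "
                     "neither stationary nor decayed")
    if decaying_span is not None:
        # regularly spaced but decaying peaks: a damped spiral into a
        # fixed point that the variation test alone has not settled yet
        try:
            equilibrium = find_equilibrium(instance, window[-1])
        except SolverFailure:
            equilibrium = None
        if equilibrium is not None \
                and np.abs(equilibrium - window[-1]).max() < max(decaying_span, 1e-9) \
                and _is_attracting(instance, equilibrium, protocol):
            return (*_fixed_point_or_excitable(instance, equilibrium, protocol),
                    window[-1])
    if last_diag is not None:
        return (DynamicsClass.of(UNCLASSIFIED),
                Characteristics(diagnostic=last_diag),
                window[-1])
    # no sustained oscillation: a trajectory still contracting toward an
    # equilibrium (variation shrinking across the post-transient window)
    # is accepted as a fixed point once Newton lands next to its endpoint
    half = len(window) // 2
    v_first = _relative_variation(window[:half])
    v_last = _relative_variation(window[half:])
    if np.all(v_last < 0.25 * v_first + protocol.tol_fp):
        try:
            equilibrium = find_equilibrium(instance, window[-1])
        except SolverFailure:
            equilibrium = None
        if equilibrium is not None:
            scale = max(float(np.abs(equilibrium).max()),
                        float(np.abs(window).max()), 1e-9)
            if np.abs(equilibrium - window[-1]).max() < 0.05 * scale \
                    and _is_attracting(instance, equilibrium, protocol):
                return (*_fixed_point_or_excitable(instance, equilibrium, protocol),
                        window[-1])
    return (DynamicsClass.of(UNCLASSIFIED),
            Characteristics(diagnostic="no fixed point and no sustained oscillation "
                                       "within the protocol horizon"),
            window[-1])


def _fixed_point_or_excitable(instance, equilibrium, protocol):
    steady = dict(zip(instance.state_symbols, map(float, equilibrium)))
    excitable, excursion = _excitability_probe(instance, equilibrium, protocol)
    if excitable:
        return (DynamicsClass.of(EXCITABLE_SWITCH),
                Characteristics(steady_state_values=steady,
                                excursion_magnitude=excursion))
    return (DynamicsClass.of(STABLE_FIXED_POINT),
            Characteristics(steady_state_values=steady))


# ---------------------------------------------------------------------------
# Jacobian oracle
# ---------------------------------------------------------------------------

@dataclass
class StabilityVerdict:
    eigenvalues: np.ndarray
    verdict: str  # "stable" | "unstable" | "marginal"

    @property
    def max_real_part(self) -> float:
        return float(self.eigenvalues.real.max())


def jacobian_class_at_fixed_point(
    instance: SimInstance,
    point: np.ndarray | dict[str, float],
    rhs_tol: float = 1e-6,
    marginal_tol: float = 1e-9,
) -> StabilityVerdict:
    """Sign pattern of the eigenvalue real parts of the linearization at *point*.

    *point* must be an (approximate) equilibrium; otherwise an error is
    raised rather than returning a meaningless verdict.
    """
    if isinstance(point, dict):
        point = np.array([point[s] for s in instance.state_symbols], dtype=float)
    residual = np.abs(instance.rhs(point)).max()
    if residual > rhs_tol:
        raise ValueError(
            f"point is not an equilibrium (max |rhs| = {residual:.3e} > {rhs_tol:g})")
    eig = np.linalg.eigvals(instance.jacobian(point))
    max_re = eig.real.max()
    if max_re < -marginal_tol:
        verdict = "stable"
    elif max_re > marginal_tol:
        verdict = "unstable"
    else:
        verdict = "marginal"
    return StabilityVerdict(eigenvalues=eig, verdict=verdict)


# ---------------------------------------------------------------------------
# Two-parameter regime scans
# ---------------------------------------------------------------------------

@dataclass
class RegimeMap:
    axis1: tuple[str, np.ndarray]
    axis2: tuple[str, np.ndarray]
    cells: list[list[DynamicsClass]]  # indexed [i][j] over axis1 x axis2
    characteristics: list[list[Characteristics]]
    base: Instantiation

    def labels(self) -> set[str]:
        return {c.label for row in self.cells for c in row}

    def boundary_edges(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        """Pairs of adjacent grid cells whose labels differ."""
        edges = []
        n1, n2 = len(self.axis1[1]), len(self.axis2[1])
        for i in range(n1):
            for j in range(n2):
                if i + 1 < n1 and self.cells[i][j].label != self.cells[i + 1][j].label:
                    edges.append(((i, j), (i + 1, j)))
                if j + 1 < n2 and self.cells[i][j].label != self.cells[i][j + 1].label:
                    edges.append(((i, j), (i, j + 1)))
        return edges

    def to_table(self) -> str:
        sym1, vals1 = self.axis1
        sym2, vals2 = self.axis2
        lines = ["\t".join([f"{sym1}\\{sym2}"] + [f"{v:.6g}" for v in vals2])]
        for i, v1 in enumerate(vals1):
            lines.append("\t".join([f"{v1:.6g}"] +
                                   [self.cells[i][j].label for j in range(len(vals2))]))
        return "\n".join(lines) + "\n"


def scan(
    model: OdeModel,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    base: Instantiation,
    protocol: Optional[ClassificationProtocol] = None,
) -> RegimeMap:
    """Classify the dynamics on a 2-parameter grid.

    A solver failure in one cell marks that cell unclassified (with the
    diagnostic attached) and the scan continues.
    """
    protocol = protocol or ClassificationProtocol()
    sym1, vals1 = axis1
    sym2, vals2 = axis2
    if sym1 not in model.parameters or sym2 not in model.parameters:
        raise KeyError(f"scan axes must be model parameters: {sym1}, {sym2}")
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    cells: list[list[DynamicsClass]] = []
    chars: list[list[Characteristics]] = []
    for v1 in vals1:
        row_c: list[DynamicsClass] = []
        row_x: list[Characteristics] = []
        for v2 in vals2:
            inst = base.override(**{sym1: float(v1), sym2: float(v2)})
            try:
                instance = instantiate(model, inst)
                cls, ch = classify(instance, protocol)
            except SolverFailure as exc:
                cls = DynamicsClass.of(UNCLASSIFIED)
                ch = Characteristics(diagnostic=f"solver failure: {exc}")
            row_c.append(cls)
            row_x.append(ch)
        cells.append(row_c)
        chars.append(row_x)
    return RegimeMap(axis1=(sym1, vals1), axis2=(sym2, vals2),
                     cells=cells, characteristics=chars, base=base)


# ---------------------------------------------------------------------------
# Bifurcation boundary refinement
# ---------------------------------------------------------------------------

@dataclass
class BifurcationPoint:
    edge: tuple[tuple[int, int], tuple[int, int]]
    label: str  # "hopf" | "unknown"
    teddy: Optional[Annotation]
    parameters: Optional[dict[str, float]] = None
    max_real_part: Optional[float] = None
    diagnostic: Optional[str] = None


def _interp_params(p_lo: dict[str, float], p_hi: dict[str, float],
                   theta: float) -> dict[str, float]:
    out = {}
    for k in p_lo:
        a, b = p_lo[k], p_hi[k]
        if a > 0 and b > 0:
            out[k] = float(np.exp((1 - theta) * np.log(a) + theta * np.log(b)))
        else:
            out[k] = float((1 - theta) * a + theta * b)
    return out


def locate_bifurcation(
    rmap: RegimeMap,
    instance_factory: Callable[[dict[str, float]], SimInstance],
    eig_tol: float = 1e-6,
    max_iter: int = 120,
) -> list[BifurcationPoint]:
    """Refine the fixed-point/oscillation boundaries of a regime map.

    Along each such edge the tracked equilibrium is continued by Newton
    from the stable side and the parameter segment is bisected until the
    leading eigenvalue real part crosses zero within *eig_tol*; the
    crossing is a Hopf bifurcation and carries the corresponding TEDDY
    annotation.  Any other label pair (and any edge where the equilibrium
    branch is lost) is reported as ``unknown``.
    """
    out: list[BifurcationPoint] = []
    sym1, vals1 = rmap.axis1
    sym2, vals2 = rmap.axis2

    def cell_params(ij: tuple[int, int]) -> dict[str, float]:
        i, j = ij
        return {sym1: float(vals1[i]), sym2: float(vals2[j])}

    for edge in rmap.boundary_edges():
        (i1, j1), (i2, j2) = edge
        pair = {rmap.cells[i1][j1].label, rmap.cells[i2][j2].label}
        if pair != {STABLE_FIXED_POINT, LIMIT_CYCLE_OSCILLATION}:
            out.append(BifurcationPoint(edge, "unknown", None,
                                        diagnostic=f"labels {sorted(pair)}"))
            continue
        if rmap.cells[i1][j1].label == STABLE_FIXED_POINT:
            stable_ij, other_ij = (i1, j1), (i2, j2)
        else:
            stable_ij, other_ij = (i2, j2), (i1, j1)
        p_stable = cell_params(stable_ij)
        p_other = cell_params(other_ij)
        steady = rmap.characteristics[stable_ij[0]][stable_ij[1]].steady_state_values
        try:
            instance = instance_factory(p_stable)
            guess = np.array([steady[s] for s in instance.state_symbols])
            eq = find_equilibrium(instance, guess)

            def max_re(theta: float, eq_guess: np.ndarray):
                inst = instance_factory(_interp_params(p_stable, p_other, theta))
                eq_t = find_equilibrium(inst, eq_guess)
                eigs = np.linalg.eigvals(inst.jacobian(eq_t))
                return float(eigs.real.max()), eq_t

            lo, hi = 0.0, 1.0
            f_lo, eq = max_re(lo, eq)
            f_hi, eq_hi = max_re(hi, eq)
            if f_lo >= 0 or f_hi <= 0:
                out.append(BifurcationPoint(
                    edge, "unknown", None,
                    diagnostic=f"no eigenvalue sign change along edge "
                               f"({f_lo:.3e} .. {f_hi:.3e})"))
                continue
            f_mid, theta = f_lo, 0.0
            for _ in range(max_iter):
                theta = 0.5 * (lo + hi)
                f_mid, eq = max_re(theta, eq)
                if abs(f_mid) < eig_tol:
                    break
                if f_mid < 0:
                    lo = theta
                else:
                    hi = theta
            if abs(f_mid) >= eig_tol:
                out.append(BifurcationPoint(
                    edge, "unknown", None,
                    diagnostic=f"bisection stalled at |Re lambda|={abs(f_mid):.2e}"))
                continue
            out.append(BifurcationPoint(
                edge, "hopf", TEDDY_HOPF,
                parameters=_interp_params(p_stable, p_other, theta),
                max_real_part=f_mid))
        except (SolverFailure, ValueError) as exc:
            out.append(BifurcationPoint(edge, "unknown", None,
                                        diagnostic=f"equilibrium tracking lost: {exc}"))
    return out


# ---------------------------------------------------------------------------
# DYML: declarative dynamics assertions
# ---------------------------------------------------------------------------

DYML_VERSION = 1


@dataclass
class DymlStatement:
    """Parameter constraints (closed intervals or fixed values) + asserted class."""

    constraints: dict[str, tuple[float, float] | float]
    asserted: DynamicsClass
    note: Optional[str] = None

    def __post_init__(self) -> None:
        for sym, c in self.constraints.items():
            if isinstance(c, tuple):
                lo, hi = c
                if not lo <= hi:
                    raise ValueError(f"empty interval for {sym}: [{lo}, {hi}]")


@dataclass
class DymlDocument:
    model_ref: str
    statements: list[DymlStatement] = field(default_factory=list)


@dataclass
class DymlVerdict:
    statement: DymlStatement
    passed: bool
    n_samples: int
    counterexamples: list[tuple[dict[str, float], str]] = field(default_factory=list)
    warning: Optional[str] = None


def check_dyml(
    doc: DymlDocument,
    model: OdeModel,
    base: Instantiation,
    protocol: Optional[ClassificationProtocol] = None,
    n_samples: int = 16,
    seed: int = 0,
) -> list[DymlVerdict]:
    """Check each statement by seeded Latin-hypercube sampling of its region.

    A statement passes iff every sampled parameter point classifies to the
    asserted dynamics class; failures carry the counterexample points.
    """
    protocol = protocol or ClassificationProtocol()
    verdicts = []
    for stmt in doc.statements:
        for sym in stmt.constraints:
            if sym not in model.parameters:
                raise KeyError(f"constrained symbol {sym!r} is not a model parameter")
        fixed = {s: c for s, c in stmt.constraints.items() if not isinstance(c, tuple)}
        boxes = {s: c for s, c in stmt.constraints.items() if isinstance(c, tuple)}
        degenerate = {s: (lo, hi) for s, (lo, hi) in boxes.items() if lo == hi}
        for s, (lo, _) in degenerate.items():
            fixed[s] = lo
            del boxes[s]
        if boxes:
            sampler = qmc.LatinHypercube(d=len(boxes), seed=seed)
            unit = sampler.random(n=n_samples)
            names = sorted(boxes)
            lows = np.array([boxes[s][0] for s in names])
            highs = np.array([boxes[s][1] for s in names])
            points = qmc.scale(unit, lows, highs)
        else:
            names = []
            points = np.zeros((1, 0))
        counterexamples = []
        n_run = 0
        for row in points:
            overrides = dict(fixed)
            overrides.update({s: float(v) for s, v in zip(names, row)})
            instance = instantiate(model, base.override(**overrides))
            cls, _ = classify(instance, protocol)
            n_run += 1
            if cls.label != stmt.asserted.label:
                counterexamples.append((overrides, cls.label))
        verdicts.append(DymlVerdict(
            statement=stmt,
            passed=not counterexamples,
            n_samples=n_run,
            counterexamples=counterexamples,
        ))
    return verdicts


def dyml_to_yaml(doc: DymlDocument) -> str:
    def _constraint(c):
        if isinstance(c, tuple):
            return [float(c[0]), float(c[1])]
        return float(c)

    payload = {
        "dyml_version": DYML_VERSION,
        "model": doc.model_ref,
        "statements": [
            {
                "constraints": {s: _constraint(c)
                                for s, c in sorted(stmt.constraints.items())},
                "dynamics": stmt.asserted.label,
                **({"note": stmt.note} if stmt.note else {}),
            }
            for stmt in doc.statements
        ],
    }
    return yaml.safe_dump(payload, sort_keys=True, allow_unicode=True)


def dyml_from_yaml(text: str) -> DymlDocument:
    payload = yaml.safe_load(text)
    if not isinstance(payload, dict) or "dyml_version" not in payload:
        raise ValueError("not a DYML document (missing dyml_version header)")
    if payload["dyml_version"] != DYML_VERSION:
        raise ValueError(f"unsupported DYML version {payload['dyml_version']}")
    statements = []
    for s in payload.get("statements", []):
        constraints: dict[str, tuple[float, float] | float] = {}
        for sym, c in s.get("constraints", {}).items():
            if isinstance(c, list):
                constraints[sym] = (float(c[0]), float(c[1]))
            else:
                constraints[sym] = float(c)
        statements.append(DymlStatement(
            constraints=constraints,
            asserted=DynamicsClass.of(s["dynamics"]),
            note=s.get("note"),
        ))
    return DymlDocument(model_ref=payload["model"], statements=statements)
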