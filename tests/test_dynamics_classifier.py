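"""Qualitative dynamics classification, Jacobian oracle, scans, DYML."""

import numpy as np
import pytest

from biofacets.dynamics_classifier import (
    EXCITABLE_SWITCH,
    LIMIT_CYCLE_OSCILLATION,
    STABLE_FIXED_POINT,
    TEDDY_STABLE_FIXED_POINT,
    ClassificationProtocol,
    DymlDocument,
    DymlStatement,
    DynamicsClass,
    check_dyml,
    classify,
    dyml_from_yaml,
    dyml_to_yaml,
    find_equilibrium,
    jacobian_class_at_fixed_point,
    locate_bifurcation,
    scan,
)
from biofacets.sbml_io import OdeModel, Reaction, Species, parse_arith
from biofacets.sim_engine import Instantiation, SimulationSetup, instantiate, run_timecourse


def _relaxation_model():
    """dx/dt = 2 - x: a single globally stable fixed point at x = 2."""
    model = OdeModel(id="relax")
    model.species = [Species("x", initial_amount=0.0)]
    model.reactions = [Reaction("r", parse_arith("2 - x"), products=[("x", 1)],
                                modifiers=["x"])]
    return model


def _saddle_model():
    """dx/dt = x, dy/dt = -y: a saddle at the origin."""
    model = OdeModel(id="saddle")
    model.species = [Species("x"), Species("y")]
    model.reactions = [
        Reaction("grow", parse_arith("x"), products=[("x", 1)], modifiers=["x"]),
        Reaction("shrink", parse_arith("y"), reactants=[("y", 1)]),
    ]
    return model


def test_classify_finds_closed_form_fixed_point():
    instance = instantiate(_relaxation_model(), Instantiation())
    cls, ch = classify(instance, ClassificationProtocol(horizon=60.0, n_points=600))
    assert cls.label == STABLE_FIXED_POINT
    assert cls.teddy == TEDDY_STABLE_FIXED_POINT
    assert ch.steady_state_values["x"] == pytest.approx(2.0, abs=1e-8)


def test_jacobian_oracle_trivial_cases():
    decay = instantiate(_relaxation_model(), Instantiation())
    verdict = jacobian_class_at_fixed_point(decay, np.array([2.0]))
    assert verdict.verdict == "stable"
    assert verdict.max_real_part == pytest.approx(-1.0)

    saddle = instantiate(_saddle_model(), Instantiation())
    verdict = jacobian_class_at_fixed_point(saddle, np.array([0.0, 0.0]))
    assert verdict.verdict == "unstable"
    signs = sorted(np.sign(verdict.eigenvalues.real))
    assert signs == [-1.0, 1.0]


def test_jacobian_oracle_rejects_non_equilibria():
    decay = instantiate(_relaxation_model(), Instantiation())
    with pytest.raises(ValueError, match="not an equilibrium"):
        jacobian_class_at_fixed_point(decay, np.array([0.5]))


def test_classify_oscillation_with_autocorrelation_oracle(
        model2_bundle, model2_regime_points, protocol_v):
    """Peak-interval period must agree with an autocorrelation estimate."""
    inst = model2_regime_points[LIMIT_CYCLE_OSCILLATION]
    instance = instantiate(model2_bundle.model, inst)
    cls, ch = classify(instance, protocol_v)
    assert cls.label == LIMIT_CYCLE_OSCILLATION
    assert ch.period is not None and ch.period > 0
    lo, hi = ch.amplitude_extrema["u"]
    assert lo <= hi

    # independent estimate: lag of the first autocorrelation maximum of u
    traj = run_timecourse(instance, SimulationSetup(0.0, 600.0, 0.05))
    u = traj.raw["u"].to_numpy()[len(traj.raw) // 2:]
    u = u - u.mean()
    ac = np.correlate(u, u, mode="full")[u.size - 1:]
    min_lag = int(0.5 * ch.period / 0.05)
    max_lag = int(1.5 * ch.period / 0.05)
    lag = min_lag + int(np.argmax(ac[min_lag:max_lag]))
    ac_period = lag * 0.05
    assert abs(ac_period - ch.period) / ch.period < 0.02


def test_classify_excitable_switch(model2_bundle, model2_regime_points, protocol_v):
    inst = model2_regime_points[EXCITABLE_SWITCH]
    instance = instantiate(model2_bundle.model, inst)
    cls, ch = classify(instance, protocol_v)
    assert cls.label == EXCITABLE_SWITCH
    assert ch.excursion_magnitude is not None
    # the excursion dwarfs the 5% perturbation of the cyclin pool
    delta = protocol_v.perturbation_rel * max(
        ch.steady_state_values["v"], max(ch.steady_state_values.values()))
    assert ch.excursion_magnitude >= protocol_v.excitability_ratio * delta


def test_stable_point_agrees_with_eigenvalue_oracle(
        model2_bundle, model2_regime_points, protocol_v):
    inst = model2_regime_points[STABLE_FIXED_POINT]
    instance = instantiate(model2_bundle.model, inst)
    cls, ch = classify(instance, protocol_v)
    assert cls.label == STABLE_FIXED_POINT
    verdict = jacobian_class_at_fixed_point(instance, ch.steady_state_values)
    assert verdict.verdict == "stable"


def test_classification_is_deterministic(model2_bundle, model2_regime_points,
                                         protocol_v):
    inst = model2_regime_points[LIMIT_CYCLE_OSCILLATION]
    instance = instantiate(model2_bundle.model, inst)
    first = classify(instance, protocol_v)
    second = classify(instance, protocol_v)
    assert first[0] == second[0]
    assert first[1].period == second[1].period
    assert first[1].amplitude_extrema == second[1].amplitude_extrema


def test_scan_single_cell_has_no_boundaries(model2_bundle, model2_regime_points,
                                            protocol_v):
    inst = model2_regime_points[STABLE_FIXED_POINT]
    rmap = scan(model2_bundle.model,
                ("k4", np.array([inst.parameter_values["k4"]])),
                ("k6", np.array([inst.parameter_values["k6"]])),
                inst, protocol_v)
    assert len(rmap.cells) == 1 and len(rmap.cells[0]) == 1
    assert rmap.boundary_edges() == []


def test_scan_constant_axes_give_uniform_map(model2_bundle, model2_regime_points,
                                             protocol_v):
    inst = model2_regime_points[STABLE_FIXED_POINT]
    k4 = inst.parameter_values["k4"]
    k6 = inst.parameter_values["k6"]
    rmap = scan(model2_bundle.model,
                ("k4", np.array([k4, k4, k4])),
                ("k6", np.array([k6, k6, k6])),
                inst, protocol_v)
    assert rmap.labels() == {STABLE_FIXED_POINT}
    assert rmap.boundary_edges() == []

    def factory(overrides):
        return instantiate(model2_bundle.model, inst.override(**overrides))

    assert locate_bifurcation(rmap, factory) == []


def test_fixed_point_to_excitable_boundary_is_not_hopf(
        model2_bundle, model2_regime_points, protocol_v):
    """Across an excitable/stable edge the equilibrium never destabilizes."""
    inst = model2_regime_points[EXCITABLE_SWITCH]
    k4 = inst.parameter_values["k4"]
    k6 = inst.parameter_values["k6"]
    rmap = scan(model2_bundle.model,
                ("k4", np.array([k4])),
                ("k6", np.geomspace(k6, 4 * k6, 4)),
                inst, protocol_v)
    labels = [c.label for c in rmap.cells[0]]
    assert labels[0] == EXCITABLE_SWITCH
    assert STABLE_FIXED_POINT in labels

    def factory(overrides):
        return instantiate(model2_bundle.model, inst.override(**overrides))

    boundaries = locate_bifurcation(rmap, factory)
    assert boundaries, "expected at least one boundary edge"
    assert all(b.label == "unknown" for b in boundaries)
    # oracle: eigenvalue real parts stay negative across the whole edge
    # (closed-form equilibrium of the two-variable model as Newton seed)
    ks = inst.parameter_values["ks"]
    alpha = inst.parameter_values["k4p"] / k4
    for value in rmap.axis2[1]:
        k6_val = float(value)
        instance = factory({"k4": k4, "k6": k6_val})
        u_star = ks / k6_val
        v_star = u_star + k6_val * u_star / (k4 * (alpha + u_star ** 2))
        eq = find_equilibrium(instance, np.array([u_star, v_star]))
        assert np.linalg.eigvals(instance.jacobian(eq)).real.max() < 0


def test_scan_refinement_keeps_interior_labels(model2_bundle, model2_regime_points,
                                               protocol_v):
    """Doubling the grid resolution never flips a non-boundary-adjacent cell."""
    base = model2_regime_points[LIMIT_CYCLE_OSCILLATION]
    k4 = base.parameter_values["k4"]
    k6 = base.parameter_values["k6"]
    ax1 = np.geomspace(k4 / 4, k4 * 4, 5)
    ax2 = np.geomspace(k6 / 2, k6 * 2, 5)
    coarse = scan(model2_bundle.model, ("k4", ax1), ("k6", ax2), base, protocol_v)
    fine = scan(model2_bundle.model,
                ("k4", np.geomspace(k4 / 4, k4 * 4, 9)),
                ("k6", np.geomspace(k6 / 2, k6 * 2, 9)),
                base, protocol_v)
    adjacent = set()
    for a, b in coarse.boundary_edges():
        adjacent |= {a, b}
    for i in range(5):
        for j in range(5):
            if (i, j) in adjacent:
                continue
            assert coarse.cells[i][j].label == fine.cells[2 * i][2 * j].label


# ---------------------------------------------------------------------------
# DYML
# ---------------------------------------------------------------------------


def test_dyml_yaml_round_trip():
    doc = DymlDocument(
        model_ref="tyson_model2",
        statements=[
            DymlStatement(constraints={"k4": (100.0, 200.0), "k6": 1.5},
                          asserted=DynamicsClass.of(STABLE_FIXED_POINT),
                          note="example"),
            DymlStatement(constraints={"k6": (0.5, 0.9)},
                          asserted=DynamicsClass.of(LIMIT_CYCLE_OSCILLATION)),
        ])
    restored = dyml_from_yaml(dyml_to_yaml(doc))
    assert restored.model_ref == doc.model_ref
    assert restored.statements == doc.statements


def test_dyml_rejects_empty_interval():
    with pytest.raises(ValueError, match="empty interval"):
        DymlStatement(constraints={"k4": (2.0, 1.0)},
                      asserted=DynamicsClass.of(STABLE_FIXED_POINT))


def test_check_dyml_empty_document(model2_bundle, model2_regime_points):
    verdicts = check_dyml(DymlDocument(model_ref="tyson_model2"),
                          model2_bundle.model,
                          model2_regime_points[STABLE_FIXED_POINT], seed=1)
    assert verdicts == []


def test_check_dyml_pass_and_fail(model2_bundle, model2_regime_points, protocol_v):
    base = model2_regime_points[STABLE_FIXED_POINT]
    k4 = base.parameter_values["k4"]
    k6 = base.parameter_values["k6"]
    box = {"k4": (k4 / 1.02, k4 * 1.02), "k6": (k6 / 1.02, k6 * 1.02)}
    doc = DymlDocument(
        model_ref="tyson_model2",
        statements=[
            DymlStatement(constraints=dict(box),
                          asserted=DynamicsClass.of(STABLE_FIXED_POINT)),
            DymlStatement(constraints=dict(box),
                          asserted=DynamicsClass.of(LIMIT_CYCLE_OSCILLATION)),
        ])
    verdicts = check_dyml(doc, model2_bundle.model, base, protocol=protocol_v,
                          n_samples=4, seed=1)
    assert verdicts[0].passed
    assert not verdicts[1].passed
    assert verdicts[1].counterexamples
    point, label = verdicts[1].counterexamples[0]
    assert label == STABLE_FIXED_POINT
    assert box["k4"][0] <= point["k4"] <= box["k4"][1]


def test_check_dyml_unknown_symbol(model2_bundle, model2_regime_points):
    doc = DymlDocument(
        model_ref="tyson_model2",
        statements=[DymlStatement(constraints={"nope": (0.0, 1.0)},
                                  asserted=DynamicsClass.of(STABLE_FIXED_POINT))])
    with pytest.raises(KeyError, match="nope"):
        check_dyml(doc, model2_bundle.model,
                   model2_regime_points[STABLE_FIXED_POINT], seed=1)


def test_check_dyml_is_seed_reproducible(model2_bundle, model2_regime_points,
                                         protocol_v):
    base = model2_regime_points[STABLE_FIXED_POINT]
    k4 = base.parameter_values["k4"]
    doc = DymlDocument(
        model_ref="tyson_model2",
        statements=[DymlStatement(constraints={"k4": (k4 / 1.05, k4 * 1.05)},
                                  asserted=DynamicsClass.of(STABLE_FIXED_POINT))])
    run1 = check_dyml(doc, model2_bundle.model, base, protocol=protocol_v,
                      n_samples=4, seed=9)
    run2 = check_dyml(doc, model2_bundle.model, base, protocol=protocol_v,
                      n_samples=4, seed=9)
    assert run1[0].passed == run2[0].passed
    assert run1[0].n_samples == run2[0].n_samples
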