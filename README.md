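# biofacets

Semantic annotation and executable semantics for kinetic bio-models.

A computational model of a biological system carries meaning on two
sides: *intrinsically* it is a formal object — an ODE system that can be
instantiated, simulated and analysed without knowing what it stands for
— and *extrinsically* its components, its intended use and its dynamics
map onto biological objects, experimental settings and phenomena.  Each
side splits into three perspectives — **structure** (S1 system, S2
entities, S3 relations), **function** (F1 intention, F2 instantiation,
F3 setup) and **behaviour** (B1 dynamics, B2 data, B3 outcome) — giving
nine facet cells, each with two named aspects per side: 36 addressable
slots in all.  `biofacets` turns that scheme into a machine-checkable
data model and implements every piece of executable machinery the slots
refer to.

The package is for modellers and database curators who want model
semantics to be *checkable*: that a record without any biological
interpretation is rejected, that the ODE programme really follows from
the reaction network, that "this model oscillates for these parameters"
is a falsifiable, re-runnable statement rather than prose.

## What is inside

| module | contents |
|---|---|
| `biofacets.facet_schema` | 36-slot facet records, MIRIAM URN / identifiers.org URL parsing, validation, coverage reports, completeness questions, taxonomy fragments with lowest-common-ancestor generalization |
| `biofacets.sbml_io` | SBML Level 2 Version 4 subset reader/writer (species, parameters, assignment rules, reactions, content-MathML kinetic laws, RDF annotations), ODE programme construction, conserved-total residuals |
| `biofacets.sim_engine` | instantiation, stiff time-course integration with perturbations and post-processing, SED-ML-lite experiment descriptions |
| `biofacets.dynamics_classifier` | qualitative dynamics classification (stable fixed point / limit-cycle oscillation / excitable switch) with TEDDY labels, closed-form Jacobian oracle, two-parameter regime scans, Hopf boundary bisection, DYML dynamics assertions |
| `biofacets.model_compare` | annotation overlap per facet cell, behavioural class-set relations, numerical verification of abstraction mappings |
| `biofacets.tyson_fixtures` | programmatic reconstruction of the two classic MPF cell-cycle models (the six-ODE protein network and its two-variable reduction), their facet records, and a seeded regime-parameter search |
| `biofacets.cli` | `biofacets` command: validate, simulate, classify, scan, check-dyml, compare, export-fixtures |

## The fixture models

Model 1 describes MPF (maturation promoting factor, the cyclin–cdc2
dimer) formation and activation with six state variables — cdc2 (C2),
phosphorylated cdc2 (CP), inactive MPF (pM), active MPF (M), cyclin (Y)
and phosphorylated cyclin (YP) — built reaction-wise so that the derived
programme is exactly

```
d[C2]/dt = k6[M] − k8[~P][C2] + k9[CP]
d[CP]/dt = −k3[CP][Y] + k8[~P][C2] − k9[CP]
d[pM]/dt = k3[CP][Y] − [pM]·F([M]) + k5[~P][M]
d[M]/dt  = [pM]·F([M]) − k5[~P][M] − k6[M]
d[Y]/dt  = k1[aa] − k2[Y] − k3[CP][Y]
d[YP]/dt = k6[M] − k7[YP]        with  F([M]) = k4' + k4([M]/[CT])²
```

where CT = [C2]+[CP]+[pM]+[M] is the conserved cdc2 total.  Model 2 is
its two-variable abstraction in u = [M]/[CT] and v = ([Y]+[pM]+[M])/[CT]:

```
du/dt = k4(v − u)(α + u²) − k6·u       α = k4'/k4
dv/dt = ks − k6·u                      ks = k1[aa]/[CT]
```

Depending on (k4, k6) both models show a stable steady state, a
spontaneous limit-cycle oscillation, or an excitable switch, with a
supercritical Hopf bifurcation separating steady state from oscillation.
No parameter table is shipped: concrete regime points are found by a
seeded random search and verified by classification.

## Worked example

Find an oscillatory parameterization of the two-variable model and
classify it:

```python
from biofacets.tyson_fixtures import tyson_model2, find_regime_parameters
from biofacets.dynamics_classifier import classify, ClassificationProtocol
from biofacets.sim_engine import instantiate
from biofacets.facet_schema import format_urn

bundle = tyson_model2()
protocol = ClassificationProtocol(perturb_symbol="v")

point = find_regime_parameters(bundle.model, "limit_cycle_oscillation", seed=1)
print("parameters:", {k: round(v, 4) for k, v in point.parameter_values.items()})
cls, ch = classify(instantiate(bundle.model, point), protocol)
print("dynamics:", cls.label)
print("period_min:", round(ch.period, 2))

stable = find_regime_parameters(bundle.model, "stable_fixed_point", seed=1)
cls2, ch2 = classify(instantiate(bundle.model, stable), protocol)
print("stable point:", {k: round(v, 4) for k, v in ch2.steady_state_values.items()},
      "teddy:", format_urn(cls2.teddy))
```

prints

```
parameters: {'k4': 229.8318, 'k4p': 0.0012, 'k6': 1.6069, 'ks': 0.0251}
dynamics: limit_cycle_oscillation
period_min: 72.86
stable point: {'u': 0.8829, 'v': 0.8835} teddy: urn:miriam:teddy:TEDDY_0000113
```

The first point sustains a relaxation oscillation with a 72.9-minute
period (rapid embryonic-division-like cycling); the second settles to a
stable steady state (metaphase-arrest-like), labelled with the TEDDY
term for a stable fixed point.  The same machinery drives the
`biofacets scan` command, which maps these regimes over a (k4, k6) grid
and bisects the stable/oscillatory boundary to the Hopf curve.

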