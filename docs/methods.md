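# Methods

This note records the models, procedures and numerical choices behind
`biofacets`, in the spirit of a package's model documentation: what is
computed, under which assumptions, with which defaults, and what the
passing test suite does and does not establish.

## The facet data model

A facet record assigns content to any of 36 addresses: {structure,
function, behaviour} × {1, 2, 3} × {intrinsic, extrinsic} × two aspect
names per cell side (e.g. S2-intrinsic holds *entities* and
*attributes*; S2-extrinsic holds *objects* and *quantities*).  Each slot
is dual-channel — free text, resource annotations, and optionally a
structured payload reference — because in practice model semantics mixes
prose with ontology cross-references, and some slots (the F3 setup, the
B1 dynamics statements, the B2/B3 data) are best carried by executable
documents rather than either.

Validation applies a single hard rule: at least one extrinsic slot must
be filled.  A model with no extrinsic interpretation describes no
biological system and is rejected as biologically meaningless.  All
other missing content is reported as *gaps*, and a non-interactive
completeness helper returns the guiding question for each unfilled
aspect.  Structured payloads are type-checked against their address (a
simulation setup belongs under F3-intrinsic, a DYML document under
B1-intrinsic, trajectories under B2/B3-intrinsic).

Cross-references use the two standard textual forms,
`urn:miriam:<namespace>:<id>` (colons in the identifier
percent-encoded) and `http(s)://identifiers.org/<namespace>/<id>`; both
parse to the same (namespace, identifier) pair and re-serialize
canonically.  No live registry resolution is performed.

Records serialize to a versioned YAML document with sorted keys so that
diffs are reviewable; round-tripping is property-tested.

## SBML subset and programme construction

The codec supports the core of SBML Level 2 Version 4: species (with
`initialAmount` and boundary/constant marking), global parameters
(optionally without a value, i.e. declared but unset), assignment rules,
reactions with reactant/product/modifier lists and content-MathML
kinetic laws, and MIRIAM-style RDF annotations with biology qualifiers.
Anything else — events, rate or algebraic rules, local kinetic-law
parameters, non-arithmetic MathML — raises an explicit
unsupported-feature error rather than being silently dropped.  Kinetic
expressions are restricted to +, −, ×, ÷ and integer powers, which is
exactly what mass-action and Hill-free autocatalytic laws need; the
MathML emitter/parser covers only this fragment and is round-trip
tested against symbolic equality.

The *programme* is derived, not stored: for every non-boundary species
the right-hand side is the sum over reactions of (product stoichiometry
− reactant stoichiometry) × kinetic law.  Algebraic definitions
(conserved totals such as CT, the activation function F) are kept
symbolic and substituted in dependency order; cyclic definitions are
rejected.  Moiety conservation is checked with
`conserved_total_residual`, the instantaneous drift of a candidate
total; for the six-ODE fixture the cdc2 total cancels symbolically and
the residual is zero to machine precision at random states.

Species naming: `~P` (ATP) is not a legal SBML identifier, so the
fixture uses the id `AP` with the display name carrying `~P`.

Units: one declared time unit (minutes) and amount unit per model,
recorded as text; no unit-conversion engine.

## Simulation engine

Instantiation must be total — every unset parameter assigned, every
initial value non-negative — before an instance can be integrated.
Integration uses LSODA with rtol = atol = 1e−9 and an analytic Jacobian
generated symbolically; the output grid is decoupled from the solver's
internal steps, so a 0.001-minute reporting step does not force 100 001
integrator steps.  The KiSAO algorithm identifier in a simulation setup
is recorded metadata, not a dispatch key: at these tolerances the
trajectory is algorithm-independent to far below every threshold used
in the tests, and the setup documents *which* routine the original
experiment named.

Perturbations are instantaneous state increments; the sample at the
perturbation instant records the pre-jump value.  Zero-delta
perturbations are exact no-ops (they do not even split the integration,
so the trajectory is bitwise unchanged).  Negative states beyond −1e−9
raise a diagnostic rather than being clipped: mass-action systems stay
non-negative, so negativity signals solver trouble and should be loud.

Post-processing expressions (e.g. `M/CT`, `YT/CT`) are evaluated
pointwise over the raw series with algebraic definitions expanded.  The
total-cyclin pool is defined as YT = Y + YP + pM + M — every species
containing a cyclin moiety; the composition is not uniquely pinned by
the source material, and this is the package's reading of "all cyclin
entities".

SED-ML-lite is a deliberately marked subset format (own namespace,
version attribute), covering a uniform time course, an algorithm
annotation, parameter/initial-value changes, perturbations and named
data generators.  It is not compliant SED-ML and refuses documents it
did not write.

## Dynamics classification

The classifier assigns one of four labels per (instance, protocol):
`stable_fixed_point`, `limit_cycle_oscillation`, `excitable_switch`,
`unclassified`.  It is purely simulation-based; eigenvalues are never
consulted, which keeps the closed-form Jacobian check available as an
independent oracle.

Protocol defaults (all pinned on the `ClassificationProtocol` object):
horizon 600 min sampled at 6000 points, transient fraction 0.5, fixed
point iff post-transient relative variation < 1e−6 in every state,
oscillation iff ≥ 5 successive peaks whose trailing intervals have a
coefficient of variation < 1% and whose trailing amplitudes are
stationary within 5%, excitability probed by perturbing the designated
trigger variable (the cyclin pool: `v` in the reduced model, `Y` in the
six-ODE model) upward by 5% of its steady-state scale, with a
suprathreshold response defined as an excursion ≥ 10× the perturbation
that returns to the fixed point.  None of these numbers comes from the
source material; they were chosen once to separate the three regimes of
the printed two-variable model cleanly and are recorded in the protocol
so tests pin them.

Three robustness devices matter in practice:

- **Horizon extension.** If one horizon leaves the verdict open (e.g.
  the trajectory is still ramping toward a distant equilibrium — at
  extreme parameter corners the reduced model's equilibrium cyclin pool
  can exceed the horizon's reach), the run continues from its endpoint
  with a doubled horizon, up to three times, at unchanged output-step
  density.  Cells that remain open stay `unclassified`; that is an
  honest statement about the protocol's bounded horizon, not an error.
- **Per-state peak analysis.** Peaks are analysed on each state in order
  of decreasing relative variation.  The slow variable of a relaxation
  oscillator yields smooth, reliably sampled peaks where the fast
  variable's narrow spikes may alias at the reporting step.
- **Attraction verification.** When a fixed-point candidate is inferred
  indirectly (from decaying peaks or from a contracting window rather
  than from settled variation), the equilibrium is Newton-polished and
  then verified by simulation: a tiny (1e−4 relative) nudge must not
  grow by more than an order of magnitude.  This rejects the unstable
  focus inside a long-period relaxation cycle, which can otherwise
  masquerade as a settling point when the analysis window straddles
  less than a full period.

An excitable switch *is* a stable fixed point with a threshold, so
every detected fixed point is probed; the two labels are mutually
exclusive by construction and the linearization at either is stable —
which is why the Jacobian oracle test only binds the
`stable_fixed_point` verdict.

Chaotic dynamics fall into `unclassified`; no Lyapunov machinery is
included.

### Regime scans and Hopf boundaries

`scan` classifies every cell of a two-parameter grid (solver failures
mark single cells unclassified and the scan continues).  Boundary edges
between a stable-fixed-point cell and an oscillation cell are refined by
`locate_bifurcation`: the equilibrium is continued by Newton from the
stable side (seeded with that cell's detected steady state), parameters
are interpolated geometrically along the edge, and bisection drives the
leading eigenvalue real part to |Re λ| < 1e−6.  The crossing is labelled
a Hopf bifurcation with its TEDDY annotation.  Supercriticality is
asserted from the known phenomenology of this model family, not
verified by normal-form coefficients — first-Lyapunov-coefficient
computation is out of scope.  Edges with any other label pair are
reported `unknown`: across a stable↔excitable edge, in particular, the
eigenvalues never cross zero.

### DYML

The dynamics assertion format is a small, versioned YAML dialect: a
model reference plus statements, each binding parameter constraints
(fixed values or closed intervals) to an asserted dynamics class.  The
concrete syntax is this package's own design; the intent it encodes —
declarative, checkable statements such as "with only k4 and k6 free in
this box, the model oscillates" — follows the envisioned
dynamics-markup idea, whose printed sketch is not machine-readable.
`check_dyml` samples each constraint box with a seeded Latin hypercube
(16 points by default) and classifies every sample; a statement passes
iff all samples match, and failures carry counterexample points.  This
is sampling, not verification: a pass bounds the violation set's
measure, it does not prove emptiness.

## Model comparison

Structural comparison intersects resource annotations per facet cell
and side by exact (namespace, identifier) match; free text matches only
on string equality and is flagged as weak evidence.  No ontology-graph
subsumption is attempted — the one deliberate exception to "no
inference" is the taxonomy fragment's lowest-common-ancestor helper,
which generalizes two organism annotations to their most specific
common taxon.

Behavioural comparison reduces two class sets (produced by the same
protocol family) to a set relation: equal, subset, superset, disjoint,
overlapping.

The abstraction check is trajectory-based: simulate source and target
on the same grid, push the source trajectory through the variable
mapping (u = M/CT, v = (Y+pM+M)/CT, with α = k4′/k4 and ks = k1[aa]/CT
relating the parameterizations), and report per-variable maximum and
RMS deviation.  The reduction is exact only in a limiting regime — no
cyclin degradation or MPF inactivation (k2 = k5 = 0) and a
fast phosphorylation/association subsystem — so the consistency verdict
is always relative to a stated tolerance.  The packaged regime
(k3 = 300, k8 = 200, k9 = 2, k6 = 1, k1 = 0.015 with CT = 1) yields a
maximum deviation of about 2×10⁻³ in u and v over 100 minutes; the
fixture tolerance is pinned at 0.02, an order of magnitude above, and is
a fixture constant rather than a universal default.

## Fixtures and the regime-parameter search

Both cell-cycle models are constructed programmatically, annotations
included (UniProt P04551 on C2, GO:0000278 for the mitotic cell cycle,
taxonomy 7625/33511/6072 as organism options, SBO terms for framework,
entity, dissociation, mass action and molar concentration, Reactome
REACT_6308 on the dissociation step, CL:0000007 for early embryonic
cells, KISAO_0000280 on the reference time-course setup).  The facet
records fill every aspect derivable from the source material and leave
exactly six extrinsic gaps — no biological initial state (F2), no
experimental settings or result calculation (F3), no measurements or
key (B2), no experimental results (B3) — which is also what the
validation-fidelity test asserts.

The original parameter table is deliberately not reproduced.
`find_regime_parameters` draws parameter points log-uniformly from
package-chosen bounds (for the reduced model: k4 ∈ [10, 3000],
k4′ ∈ [10⁻³, 3], k6 ∈ [0.05, 5], ks ∈ [0.005, 0.1], starting from
u = v = 0) and returns the first draw that classifies to the requested
regime; the search is deterministic given its seed.  For the six-ODE
model the fast rates are held fixed at the abstraction-regime values
above and the slow subsystem (k1, k4, k4′, k6) is searched, which keeps
all three regimes reachable.  Initial conditions put the whole cdc2
pool in the phosphorylated state with no cyclin (CT = 1), a
physiologically sensible pre-accumulation state.

The taxonomy fragment packages only the lineage facts used by the
examples: sea urchin (7625) and frog under Deuterostomia (33511) under
Eumetazoa (6072).  The frog node carries a label-only identifier; a
real NCBI taxon id would replace it in production use.

## What the tests do and do not show

The synthetic fixtures exercise every code path end to end — programme
derivation against the printed equations, conservation, regime
classification against the closed-form linearization, Hopf location,
round-trips of all five document formats, record validation, the
abstraction check.  They do not show that the packaged encodings are
byte-equivalent to any archived database entry (the archive is not
fetched), that the regime boundaries match any published phase-plane
analysis quantitatively (the source parameter table is not packaged),
or that the classifier protocol generalizes beyond well-separated
regimes: near bifurcation boundaries, `unclassified` is the designed
outcome at bounded horizons.

## Problem sizes used

Default analyses run at: classification horizon 600 min (6000 output
points, up to three doublings), 20×20 regime grids, 16-sample DYML
checks, 100-minute abstraction comparisons at a 0.05-minute step, and a
1000-state random conservation sweep.  These sizes keep a full
verification run in the low minutes on one core while leaving every
qualitative conclusion insensitive to further refinement (the
refinement and tolerance-halving tests check exactly that).
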