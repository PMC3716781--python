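"""Data model for the six meaning facets of a bio-model.

A bio-model carries meaning from three perspectives — its *structure*
(what the components are), its *function* (how it is meant to be used in
simulation experiments) and its *behaviour* (what dynamics it produces) —
and on each perspective from two sides: the *intrinsic* side, where the
model is a formal object, and the *extrinsic* side, where its components,
use and dynamics map onto biological reality.  Each of the nine
perspective cells (S1–S3, F1–F3, B1–B3) splits per side into two named
aspects, giving exactly 36 addressable slots.

A :class:`FacetRecord` holds free text, resource annotations
(MIRIAM-style URN / identifiers.org URL cross-references) and optional
structured payload references for any subset of those slots, together
with global meta-information (origin, access, relations to other
models).  Validation enforces the single hard rule of the framework:
a record with no filled extrinsic slot describes no biological system
at all and is rejected; everything else is reported as a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional
from urllib.parse import quote, unquote

import yaml

__all__ = [
    "PERSPECTIVES",
    "SIDES",
    "ASPECTS",
    "GUIDING_QUESTIONS",
    "FacetAddress",
    "Annotation",
    "StructuredRef",
    "FacetSlot",
    "GlobalMeta",
    "ModelRelationRef",
    "FacetRecord",
    "Issue",
    "CoverageReport",
    "TaxonomyFragment",
    "all_addresses",
    "parse_identifier",
    "format_urn",
    "format_url",
    "validate",
    "coverage",
    "completeness_questions",
    "generalize_organisms",
    "record_to_yaml",
    "record_from_yaml",
]

PERSPECTIVES = ("structure", "function", "behaviour")
SIDES = ("intrinsic", "extrinsic")

#: Per-cell aspect vocabulary.  Keys are (perspective, index, side); values
#: are the two aspect names of that cell side, in canonical order.
ASPECTS: dict[tuple[str, int, str], tuple[str, str]] = {
    ("structure", 1, "intrinsic"): ("formal_system", "formalism"),
    ("structure", 1, "extrinsic"): ("biological_system", "conceptual_level"),
    ("structure", 2, "intrinsic"): ("entities", "attributes"),
    ("structure", 2, "extrinsic"): ("objects", "quantities"),
    ("structure", 3, "intrinsic"): ("relations", "programme"),
    ("structure", 3, "extrinsic"): ("interactions", "mechanisms"),
    ("function", 1, "intrinsic"): ("intended_use", "constraints"),
    ("function", 1, "extrinsic"): ("questions", "assumptions"),
    ("function", 2, "intrinsic"): ("instantiation", "initial_values"),
    ("function", 2, "extrinsic"): ("boundary_conditions", "initial_state"),
    ("function", 3, "intrinsic"): ("setup", "post_processing"),
    ("function", 3, "extrinsic"): ("experimental_settings", "result_calculation"),
    ("behaviour", 1, "intrinsic"): ("dynamics", "diversification"),
    ("behaviour", 1, "extrinsic"): ("phenomena", "variability"),
    ("behaviour", 2, "intrinsic"): ("raw_data", "index"),
    ("behaviour", 2, "extrinsic"): ("measurements", "key"),
    ("behaviour", 3, "intrinsic"): ("outcome", "characteristics"),
    ("behaviour", 3, "extrinsic"): ("results", "observables"),
}

#: Guiding question per aspect, used by :func:`completeness_questions`.
GUIDING_QUESTIONS: dict[tuple[str, int, str, str], str] = {
    ("structure", 1, "intrinsic", "formal_system"): (
        "Which formal system is specified by the encoded model (the model itself)?"),
    ("structure", 1, "intrinsic", "formalism"): (
        "Which formalism is employed by the model (modelling framework, spatiality, stochasticity)?"),
    ("structure", 1, "extrinsic", "biological_system"): (
        "Which biological system corresponds to the formal system (species, cell type, biochemical system)?"),
    ("structure", 1, "extrinsic", "conceptual_level"): (
        "Which conceptual level is reflected by the used formalism (system type, granularity, spatial and temporal resolution)?"),
    ("structure", 2, "intrinsic", "entities"): (
        "What are the entities of the formal system (individuals, collections, agents)?"),
    ("structure", 2, "intrinsic", "attributes"): (
        "Which attributes of the entities describe the state of the system (variables, terms)?"),
    ("structure", 2, "extrinsic", "objects"): (
        "What biological objects correspond to the model entities (molecules, substances, cells)?"),
    ("structure", 2, "extrinsic", "quantities"): (
        "Which quantities (amounts, concentrations, units) correspond to the model attributes?"),
    ("structure", 3, "intrinsic", "relations"): (
        "What are the relations between the entities (inter-dependencies, correlation, neighbourhood)?"),
    ("structure", 3, "intrinsic", "programme"): (
        "What is the programme describing changes of the attributes of related entities (operations, equations, update rules)?"),
    ("structure", 3, "extrinsic", "interactions"): (
        "What biological interactions correspond to the model relations (reactions, transformations, diffusion)?"),
    ("structure", 3, "extrinsic", "mechanisms"): (
        "What biological mechanisms realising the interactions between objects correspond to the model programme (reaction steps, bonding, activity)?"),
    ("function", 1, "intrinsic", "intended_use"): (
        "What is the intended use of the model (simulation type, combination of simulations, desired outcome)?"),
    ("function", 1, "intrinsic", "constraints"): (
        "Which constraints are imposed on the model (value restrictions, ratios, conservation rules)?"),
    ("function", 1, "extrinsic", "questions"): (
        "Which biological questions are addressed to the model (explanation, hypothesis testing, exploration, dependency analysis)?"),
    ("function", 1, "extrinsic", "assumptions"): (
        "Which assumptions provide the basis for the constraints (likelihoods, justification, evidence)?"),
    ("function", 2, "intrinsic", "instantiation"): (
        "Which instantiation of the model is used for the simulation (parameter values, parameter ranges)?"),
    ("function", 2, "intrinsic", "initial_values"): (
        "Which initial values are chosen for the entities' attributes (value assignment to variables)?"),
    ("function", 2, "extrinsic", "boundary_conditions"): (
        "Which boundary conditions correspond to the model instantiation (environment, kinetic data, plausible ranges)?"),
    ("function", 2, "extrinsic", "initial_state"): (
        "Which initial state of the biological system corresponds to the initial values set for the model (initial concentrations)?"),
    ("function", 3, "intrinsic", "setup"): (
        "Which setup is used for simulation experiments (simulation algorithm, algorithm settings, perturbations)?"),
    ("function", 3, "intrinsic", "post_processing"): (
        "Which post-processing of the raw simulation data generates the desired outcome (normalisation, conversion of units, calculations)?"),
    ("function", 3, "extrinsic", "experimental_settings"): (
        "Which biological experimental settings correspond to the setup for simulations of the model (experimental protocol)?"),
    ("function", 3, "extrinsic", "result_calculation"): (
        "Which result calculation produces the requested results of the experiment (normalisation, conversion of units, calculations)?"),
    ("behaviour", 1, "intrinsic", "dynamics"): (
        "Which types of dynamics does the model show in simulations (fixed points, periodic behaviours, chaotic behaviour)?"),
    ("behaviour", 1, "intrinsic", "diversification"): (
        "Which diversification in the dynamics does the model possess (stability, bifurcations)?"),
    ("behaviour", 1, "extrinsic", "phenomena"): (
        "Which biological phenomena correspond to the model dynamics (cyclic behaviour, steady state)?"),
    ("behaviour", 1, "extrinsic", "variability"): (
        "Which variability of the biological phenomena corresponds to the diversification in the dynamics of the model (switching behaviour, excitability)?"),
    ("behaviour", 2, "intrinsic", "raw_data"): (
        "Which raw data does the model produce in simulations (series of values)?"),
    ("behaviour", 2, "intrinsic", "index"): (
        "Which index is used for the raw data (modelling time, parameter value, initial value)?"),
    ("behaviour", 2, "extrinsic", "measurements"): (
        "Which experimental measurements correspond to the yielded raw data (series of values)?"),
    ("behaviour", 2, "extrinsic", "key"): (
        "Which key is used to identify the single measurements (time, conditions, initial states)?"),
    ("behaviour", 3, "intrinsic", "outcome"): (
        "What is the outcome of the simulation (specific values, time courses, phase portraits, bifurcation diagram)?"),
    ("behaviour", 3, "intrinsic", "characteristics"): (
        "Which characteristics of the model dynamics can be identified (maximal and minimal values, periods, Lyapunov exponents)?"),
    ("behaviour", 3, "extrinsic", "results"): (
        "Which experimental results correspond to the outcome of the simulation (specific values, time courses, phase portraits, bifurcation diagram)?"),
    ("behaviour", 3, "extrinsic", "observables"): (
        "Which observables correspond to the characteristics of the model's dynamics (maximal and minimal concentrations, cycle length, stability)?"),
}

_PERSPECTIVE_LETTER = {"structure": "S", "function": "F", "behaviour": "B"}
_LETTER_PERSPECTIVE = {v: k for k, v in _PERSPECTIVE_LETTER.items()}


@dataclass(frozen=True, order=True)
class FacetAddress:
    """One of the 36 addressable facet slots, e.g. S2-extrinsic *objects*."""

    perspective: str
    index: int
    side: str
    aspect: str

    def __post_init__(self) -> None:
        key = (self.perspective, self.index, self.side)
        if key not in ASPECTS:
            raise ValueError(f"no facet cell {self.perspective}{self.index}/{self.side}")
        if self.aspect not in ASPECTS[key]:
            raise ValueError(
                f"aspect {self.aspect!r} not in cell "
                f"{self.perspective}{self.index}/{self.side} "
                f"(expected one of {ASPECTS[key]})"
            )

    @property
    def cell(self) -> str:
        """Short cell name, e.g. ``'S2'`` or ``'B1'``."""
        return f"{_PERSPECTIVE_LETTER[self.perspective]}{self.index}"

    def __str__(self) -> str:
        return f"{self.cell}:{self.side}:{self.aspect}"

    @classmethod
    def parse(cls, text: str) -> "FacetAddress":
        try:
            cell, side, aspect = text.split(":")
            perspective = _LETTER_PERSPECTIVE[cell[0]]
            index = int(cell[1:])
        except (ValueError, KeyError, IndexError) as exc:
            raise ValueError(f"malformed facet address {text!r}") from exc
        return cls(perspective, index, side, aspect)


def all_addresses() -> list[FacetAddress]:
    """The 36 valid facet addresses in canonical (S1..B3, intrinsic-first) order."""
    out = []
    for perspective in PERSPECTIVES:
        for index in (1, 2, 3):
            for side in SIDES:
                for aspect in ASPECTS[(perspective, index, side)]:
                    out.append(FacetAddress(perspective, index, side, aspect))
    return out


# ---------------------------------------------------------------------------
# Resource annotations: MIRIAM URNs and identifiers.org URLs
# ---------------------------------------------------------------------------

class IdentifierParseError(ValueError):
    """Raised when a cross-reference string is not a valid URN/URL form."""


@dataclass(frozen=True)
class Annotation:
    """A cross-reference into a registry collection, e.g. (uniprot, P04551)."""

    namespace: str
    identifier: str
    qualifier: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.namespace:
            raise ValueError("annotation namespace must be non-empty")
        if not self.identifier:
            raise ValueError("annotation identifier must be non-empty")


def format_urn(ann: Annotation) -> str:
    """Canonical URN form, e.g. ``urn:miriam:obo.go:GO%3A0000278``.

    Colons inside the identifier are percent-encoded so the namespace/
    identifier split stays unambiguous.
    """
    return f"urn:miriam:{ann.namespace}:{quote(ann.identifier, safe='')}"


def format_url(ann: Annotation) -> str:
    """Resolver URL form, e.g. ``http://identifiers.org/obo.go/GO:0000278``."""
    return f"http://identifiers.org/{ann.namespace}/{ann.identifier}"


def parse_identifier(text: str) -> Annotation:
    """Parse either textual cross-reference form into an :class:`Annotation`.

    Accepts ``urn:miriam:<namespace>:<id>`` and
    ``http(s)://identifiers.org/<namespace>/<id>``.
    """
    if not isinstance(text, str) or not text.strip():
        raise IdentifierParseError("empty identifier string")
    text = text.strip()
    if text.startswith("urn:"):
        parts = text.split(":")
        if len(parts) < 4 or parts[0] != "urn" or parts[1] != "miriam":
            raise IdentifierParseError(
                f"URN {text!r} does not match urn:miriam:<namespace>:<id>")
        namespace = parts[2]
        identifier = unquote(":".join(parts[3:]))
        if not namespace:
            raise IdentifierParseError(f"URN {text!r} has an empty namespace segment")
        if not identifier:
            raise IdentifierParseError(f"URN {text!r} has an empty identifier segment")
        return Annotation(namespace, identifier)
    for prefix in ("http://identifiers.org/", "https://identifiers.org/"):
        if text.startswith(prefix):
            rest = text[len(prefix):]
            if "/" not in rest:
                raise IdentifierParseError(
                    f"URL {text!r} lacks an identifier segment after the namespace")
            namespace, identifier = rest.split("/", 1)
            if not namespace:
                raise IdentifierParseError(f"URL {text!r} has an empty namespace segment")
            if not identifier:
                raise IdentifierParseError(f"URL {text!r} has an empty identifier segment")
            return Annotation(namespace, unquote(identifier))
    raise IdentifierParseError(
        f"{text!r} is neither a urn:miriam URN nor an identifiers.org URL")


# ---------------------------------------------------------------------------
# Slots, meta-information, records
# ---------------------------------------------------------------------------

#: Structured payload kinds and the addresses at which they are legitimate.
STRUCTURED_KIND_ADDRESSES: dict[str, set[tuple[str, int, str]]] = {
    "simulation_setup": {("function", 3, "intrinsic")},
    "dyml": {("behaviour", 1, "intrinsic")},
    "trajectory": {("behaviour", 2, "intrinsic"), ("behaviour", 3, "intrinsic")},
}


@dataclass(frozen=True)
class StructuredRef:
    """Reference to an executable payload (simulation setup, DYML doc, trajectory)."""

    kind: str
    ref: str


@dataclass
class FacetSlot:
    address: FacetAddress
    text: Optional[str] = None
    annotations: list[Annotation] = field(default_factory=list)
    structured: list[StructuredRef] = field(default_factory=list)

    @property
    def filled(self) -> bool:
        return bool(self.text) or bool(self.annotations) or bool(self.structured)


RELATION_TYPES = (
    "abstraction",
    "refinement",
    "version_of",
    "integrated_from",
    "competing",
    "modified_version_of",
)


@dataclass
class ModelRelationRef:
    other_model_id: str
    relation_type: str
    note: Optional[str] = None

    def __post_init__(self) -> None:
        if self.relation_type not in RELATION_TYPES:
            raise ValueError(
                f"relation_type {self.relation_type!r} not in {RELATION_TYPES}")


@dataclass
class AccessRef:
    location: str
    format: Optional[str] = None
    encoding_date: Optional[str] = None
    curation: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.location:
            raise ValueError("access location must be a non-empty string")


@dataclass
class GlobalMeta:
    """Origin, access and model-relation meta-information of a record."""

    publication_id: Optional[str] = None
    authors: list[str] = field(default_factory=list)
    date: Optional[str] = None
    access: list[AccessRef] = field(default_factory=list)
    relations: list[ModelRelationRef] = field(default_factory=list)


@dataclass
class FacetRecord:
    model_id: str
    slots: dict[FacetAddress, FacetSlot] = field(default_factory=dict)
    meta: GlobalMeta = field(default_factory=GlobalMeta)

    def slot(self, address: FacetAddress) -> FacetSlot:
        """Get (creating if absent) the slot at *address*."""
        if address not in self.slots:
            self.slots[address] = FacetSlot(address)
        return self.slots[address]

    def fill(
        self,
        address: FacetAddress,
        text: Optional[str] = None,
        annotations: Iterable[Annotation] = (),
        structured: Iterable[StructuredRef] = (),
    ) -> FacetSlot:
        s = self.slot(address)
        if text is not None:
            s.text = text
        s.annotations.extend(annotations)
        s.structured.extend(structured)
        return s

    def filled_addresses(self) -> set[FacetAddress]:
        return {a for a, s in self.slots.items() if s.filled}


# ---------------------------------------------------------------------------
# Validation, coverage, completeness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "gap"
    message: str
    address: Optional[FacetAddress] = None


def validate(record: FacetRecord) -> list[Issue]:
    """Check a record against the framework's rules.

    Returns one :class:`Issue` per violation.  The only hard *error*
    conditions are: no extrinsic slot filled at all (a model without any
    biological interpretation is biologically meaningless), a structured
    payload attached at an address where its kind makes no sense, and an
    annotation that does not survive the URN round-trip.  Every unfilled
    aspect is reported as a *gap*.
    """
    issues: list[Issue] = []
    filled = record.filled_addresses()
    if not any(a.side == "extrinsic" for a in filled):
        issues.append(Issue(
            "error",
            "no extrinsic interpretation: at least one extrinsic slot must be "
            "filled for the model to describe a biological system",
        ))
    for address, slot in sorted(record.slots.items(), key=lambda kv: str(kv[0])):
        for payload in slot.structured:
            allowed = STRUCTURED_KIND_ADDRESSES.get(payload.kind)
            if allowed is None:
                issues.append(Issue(
                    "error", f"unknown structured payload kind {payload.kind!r}",
                    address))
            elif (address.perspective, address.index, address.side) not in allowed:
                issues.append(Issue(
                    "error",
                    f"structured payload of kind {payload.kind!r} is not "
                    f"meaningful at {address}", address))
        for ann in slot.annotations:
            try:
                parse_identifier(format_urn(ann))
            except (IdentifierParseError, ValueError) as exc:
                issues.append(Issue("error", f"unparseable annotation: {exc}", address))
    for address in all_addresses():
        if address not in filled:
            issues.append(Issue("gap", f"aspect {address} is unfilled", address))
    return issues


@dataclass
class CoverageCell:
    covered: bool
    sources: list[str] = field(default_factory=list)


@dataclass
class CoverageReport:
    """Coverage of the 9 facet cells x 2 sides, plus the list of unfilled aspects."""

    cells: dict[tuple[str, str], CoverageCell]
    gaps: list[FacetAddress]

    def n_covered(self, side: Optional[str] = None) -> int:
        return sum(
            1 for (cell, s), c in self.cells.items()
            if c.covered and (side is None or s == side)
        )


def coverage(record: FacetRecord) -> CoverageReport:
    """Per-(cell, side) coverage: covered iff at least one aspect slot is filled."""
    cells: dict[tuple[str, str], CoverageCell] = {}
    gaps: list[FacetAddress] = []
    filled = record.filled_addresses()
    for (perspective, index, side), aspects in ASPECTS.items():
        cell_name = f"{_PERSPECTIVE_LETTER[perspective]}{index}"
        sources: list[str] = []
        for aspect in aspects:
            address = FacetAddress(perspective, index, side, aspect)
            if address in filled:
                slot = record.slots[address]
                if slot.text:
                    sources.append(f"{aspect}: text")
                sources.extend(f"{aspect}: {format_urn(a)}" for a in slot.annotations)
                sources.extend(f"{aspect}: {p.kind}({p.ref})" for p in slot.structured)
            else:
                gaps.append(address)
        cells[(cell_name, side)] = CoverageCell(covered=bool(sources), sources=sources)
    gaps.sort(key=str)
    return CoverageReport(cells=cells, gaps=gaps)


def completeness_questions(record: FacetRecord) -> list[tuple[FacetAddress, str]]:
    """The guiding question for every unfilled aspect, in canonical order."""
    filled = record.filled_addresses()
    out = []
    for address in all_addresses():
        if address not in filled:
            q = GUIDING_QUESTIONS[
                (address.perspective, address.index, address.side, address.aspect)]
            out.append((address, q))
    return out


# ---------------------------------------------------------------------------
# Taxonomy fragments and organism generalization
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyFragment:
    """A small rooted taxonomy: node ids with labels and a child -> parent map."""

    nodes: dict[str, str]  # id -> label
    parent: dict[str, str]  # child id -> parent id

    def __post_init__(self) -> None:
        for child, par in self.parent.items():
            if child not in self.nodes or par not in self.nodes:
                raise ValueError(f"parent edge {child}->{par} references unknown node")
        roots = [n for n in self.nodes if n not in self.parent]
        if len(roots) != 1:
            raise ValueError(f"taxonomy fragment must have exactly one root, got {roots}")
        # acyclicity: walking up from any node must terminate at the root
        for node in self.nodes:
            seen = set()
            cur = node
            while cur in self.parent:
                if cur in seen:
                    raise ValueError(f"cycle in parent map at {cur}")
                seen.add(cur)
                cur = self.parent[cur]

    @property
    def root(self) -> str:
        (root,) = [n for n in self.nodes if n not in self.parent]
        return root

    def lineage(self, node: str) -> list[str]:
        """Path from *node* up to the root, inclusive."""
        if node not in self.nodes:
            raise KeyError(f"unknown taxonomy node {node!r}")
        path = [node]
        while path[-1] in self.parent:
            path.append(self.parent[path[-1]])
        return path


def generalize_organisms(frag: TaxonomyFragment, a: str, b: str) -> str:
    """Lowest common ancestor of two nodes under the fragment's parent map.

    This is the organism-generalization step: the most specific taxon that
    still subsumes both annotated organisms.
    """
    ancestors_a = frag.lineage(a)
    ancestors_b = set(frag.lineage(b))
    for node in ancestors_a:
        if node in ancestors_b:
            return node
    raise ValueError(f"nodes {a!r} and {b!r} share no ancestor")  # pragma: no cover


# ---------------------------------------------------------------------------
# Serialization (YAML, stable key order)
# ---------------------------------------------------------------------------

FORMAT_VERSION = 1


def _slot_to_dict(slot: FacetSlot) -> dict:
    d: dict = {}
    if slot.text:
        d["text"] = slot.text
    if slot.annotations:
        d["annotations"] = [
            {"urn": format_urn(a), **({"qualifier": a.qualifier} if a.qualifier else {})}
            for a in slot.annotations
        ]
    if slot.structured:
        d["structured"] = [{"kind": p.kind, "ref": p.ref} for p in slot.structured]
    return d


def _slot_from_dict(address: FacetAddress, d: Mapping) -> FacetSlot:
    annotations = []
    for a in d.get("annotations", []):
        ann = parse_identifier(a["urn"])
        if a.get("qualifier"):
            ann = replace(ann, qualifier=a["qualifier"])
        annotations.append(ann)
    structured = [StructuredRef(p["kind"], p["ref"]) for p in d.get("structured", [])]
    return FacetSlot(address, text=d.get("text"), annotations=annotations,
                     structured=structured)


def record_to_yaml(record: FacetRecord) -> str:
    """Serialize a record to a versioned, stably ordered YAML document."""
    meta = record.meta
    doc = {
        "facet_record_version": FORMAT_VERSION,
        "model_id": record.model_id,
        "meta": {
            "origin": {
                "publication_id": meta.publication_id,
                "authors": list(meta.authors),
                "date": meta.date,
            },
            "access": [
                {"location": a.location, "format": a.format,
                 "encoding_date": a.encoding_date, "curation": a.curation}
                for a in meta.access
            ],
            "relations": [
                {"other_model_id": r.other_model_id,
                 "relation_type": r.relation_type, "note": r.note}
                for r in meta.relations
            ],
        },
        "slots": {
            str(address): _slot_to_dict(slot)
            for address, slot in sorted(record.slots.items(), key=lambda kv: str(kv[0]))
            if slot.filled
        },
    }
    return yaml.safe_dump(doc, sort_keys=True, allow_unicode=True, width=100)


def record_from_yaml(text: str) -> FacetRecord:
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "facet_record_version" not in doc:
        raise ValueError("not a facet-record document (missing version header)")
    if doc["facet_record_version"] != FORMAT_VERSION:
        raise ValueError(f"unsupported facet-record version {doc['facet_record_version']}")
    m = doc.get("meta", {})
    origin = m.get("origin", {})
    meta = GlobalMeta(
        publication_id=origin.get("publication_id"),
        authors=list(origin.get("authors") or []),
        date=origin.get("date"),
        access=[AccessRef(**a) for a in m.get("access", [])],
        relations=[ModelRelationRef(**r) for r in m.get("relations", [])],
    )
    record = FacetRecord(model_id=doc["model_id"], meta=meta)
    for key, d in (doc.get("slots") or {}).items():
        address = FacetAddress.parse(key)
        record.slots[address] = _slot_from_dict(address, d)
    return record
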