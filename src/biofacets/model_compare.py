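"""Facet-based comparison of two models.

Three comparisons are supported: structural overlap of resource
annotations per facet cell (exact identifier match — no ontology-graph
reasoning, so shared entries are strong evidence while text matches are
flagged weak), a set relation between behavioural class sets produced by
the same classification protocol, and a numerical check of an
abstraction mapping — simulate both models on a matched grid, push the
source trajectory through the variable mapping (e.g. u = M/CT,
v = (Y + pM + M)/CT) and report per-variable maximum and RMS deviation
from the target trajectory.  Abstractions hold only under their licensing
assumptions, so the consistency verdict is always relative to a stated
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .dynamics_classifier import DynamicsClass
from .facet_schema import ASPECTS, FacetAddress, FacetRecord
from .sim_engine import (
    SimInstance,
    SimulationSetup,
    Trajectory,
    postprocess,
    run_timecourse,
)

__all__ = [
    "VariableMapping",
    "StructuralOverlap",
    "AbstractionReport",
    "compare_structure",
    "compare_behaviour",
    "check_abstraction",
]


@dataclass
class VariableMapping:
    """Expressions defining each target variable over source symbols."""

    assignments: dict[str, str]  # target symbol -> expression text


@dataclass
class StructuralOverlap:
    """Per-(cell, side) annotation overlap between two records."""

    shared: dict[tuple[str, str], set[tuple[str, str]]]
    source_only: dict[tuple[str, str], set[tuple[str, str]]]
    target_only: dict[tuple[str, str], set[tuple[str, str]]]
    text_matches: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def all_shared(self) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for s in self.shared.values():
            out |= s
        return out


def _annotations_by_cell(record: FacetRecord) -> dict[tuple[str, str],
                                                      set[tuple[str, str]]]:
    out: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for address, slot in record.slots.items():
        key = (address.cell, address.side)
        for ann in slot.annotations:
            out.setdefault(key, set()).add((ann.namespace, ann.identifier))
    return out


def _texts_by_cell(record: FacetRecord) -> dict[tuple[str, str], set[str]]:
    out: dict[tuple[str, str], set[str]] = {}
    for address, slot in record.slots.items():
        if slot.text:
            out.setdefault((address.cell, address.side), set()).add(slot.text)
    return out


def compare_structure(recA: FacetRecord, recB: FacetRecord) -> StructuralOverlap:
    """Intersect resource annotations per facet cell and side.

    Free text is compared only by exact string match and reported
    separately as weak evidence.
    """
    a = _annotations_by_cell(recA)
    b = _annotations_by_cell(recB)
    shared, source_only, target_only = {}, {}, {}
    for key in set(a) | set(b):
        sa = a.get(key, set())
        sb = b.get(key, set())
        shared[key] = sa & sb
        source_only[key] = sa - sb
        target_only[key] = sb - sa
    ta = _texts_by_cell(recA)
    tb = _texts_by_cell(recB)
    text_matches = {
        key: sorted(ta.get(key, set()) & tb.get(key, set()))
        for key in set(ta) & set(tb)
        if ta.get(key, set()) & tb.get(key, set())
    }
    return StructuralOverlap(shared=shared, source_only=source_only,
                             target_only=target_only, text_matches=text_matches)


def compare_behaviour(
    classesA: Iterable[DynamicsClass | str],
    classesB: Iterable[DynamicsClass | str],
) -> str:
    """Set relation between two behavioural class sets.

    Returns one of ``equal``, ``subset``, ``superset``, ``disjoint``,
    ``overlapping`` (labels only; both sets must come from the same
    classification protocol family for the relation to be meaningful).
    """
    def _labels(classes):
        return {c.label if isinstance(c, DynamicsClass) else c for c in classes}

    a, b = _labels(classesA), _labels(classesB)
    if a == b:
        return "equal"
    if a < b:
        return "subset"
    if a > b:
        return "superset"
    if not a & b:
        return "disjoint"
    return "overlapping"


@dataclass
class AbstractionReport:
    conditions: str
    max_deviation: dict[str, float]
    rms_deviation: dict[str, float]
    tolerance: float
    consistent: bool


def check_abstraction(
    source: SimInstance,
    target: SimInstance,
    mapping: VariableMapping,
    setup: SimulationSetup,
    tolerance: float,
    conditions: str = "consistency expected only under the stated abstraction "
                      "assumptions; the mapping is inexact in general",
) -> AbstractionReport:
    """Numerically verify an abstraction mapping between two models.

    Both instances are simulated on the same grid; the mapping is applied
    pointwise to the source trajectory and compared per variable against
    the target trajectory.
    """
    traj_src = run_timecourse(source, setup)
    traj_tgt = run_timecourse(target, setup)
    if not np.array_equal(traj_src.index, traj_tgt.index):
        raise ValueError("source and target time grids do not match")
    mapped = postprocess(
        traj_src, source.model, mapping.assignments,
        parameter_values=source.instantiation.parameter_values,
        constant_values={
            sp.id: source.instantiation.initial_values.get(sp.id, sp.initial_amount)
            for sp in source.model.species if sp.constant})
    max_dev, rms_dev = {}, {}
    for name in mapping.assignments:
        if name not in traj_tgt.raw.columns:
            raise KeyError(f"mapped variable {name!r} is not a target state variable")
        diff = mapped.outcome[name].to_numpy() - traj_tgt.raw[name].to_numpy()
        max_dev[name] = float(np.abs(diff).max())
        rms_dev[name] = float(np.sqrt(np.mean(diff ** 2)))
    return AbstractionReport(
        conditions=conditions,
        max_deviation=max_dev,
        rms_deviation=rms_dev,
        tolerance=tolerance,
        consistent=max(max_dev.values()) < tolerance if max_dev else True,
    )
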