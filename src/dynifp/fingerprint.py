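"""Fingerprint statistics over contact time series.

Per-replica occurrence fractions, the four-class occupancy colour scheme
(white <30 %, blue 30–60 %, yellow 60–90 %, red >90 % of simulated time),
the replica-consensus significance rule (a contact is significant when it
is present for more than 60 % of simulated time in at least two replica
runs), condition-by-contact fingerprint tables, and differential labels
describing which contacts are formed or broken between two conditions —
including detection of compensating salt-bridge shifts, where a broken
charged pair is replaced by a new charged pair sharing one residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .contact_engine import ContactDefinition, ContactTimeSeries
from .structure_io import ConditionLabel, Topology

__all__ = [
    "OccupancyBins",
    "OccurrenceRecord",
    "ConsensusRecord",
    "FingerprintTable",
    "DifferentialLabel",
    "ActivationReport",
    "SaltBridgeShift",
    "occurrence_fraction",
    "classify_occupancy",
    "consensus_significant",
    "build_fingerprint_table",
    "differential_labels",
    "activation_report",
]

OCCUPANCY_CLASSES = ("white", "blue", "yellow", "red")

#: Colour legend carried into serialized tables.
COLOUR_LEGEND = {
    "white": "< 30% contact occurrence during simulation",
    "blue": "contact present 30% to 60% of simulated time",
    "yellow": "contact present in 60% to 90% of simulated time",
    "red": "contact present in > 90% of simulated time",
}


@dataclass(frozen=True)
class OccupancyBins:
    """Boundary convention for the colour bins.

    white: [0, b1)   blue: [b1, b2)   yellow: [b2, b3]   red: (b3, 1].
    Exactly-90 % occupancy falls in yellow; this boundary choice is a
    documented convention and overridable here.
    """

    b1: float = 0.30
    b2: float = 0.60
    b3: float = 0.90

    def __post_init__(self):
        if not 0 < self.b1 < self.b2 < self.b3 <= 1:
            raise ValueError("bins must satisfy 0 < b1 < b2 < b3 <= 1")


def occurrence_fraction(series: ContactTimeSeries) -> float:
    """Fraction of frames in which the contact is present (exact rational
    before float conversion)."""
    if series.n_frames == 0:
        raise ValueError("empty contact series")
    return float(Fraction(sum(series.presence), series.n_frames))


def classify_occupancy(fraction: float, bins: OccupancyBins = OccupancyBins()) -> str:
    """Map an occurrence fraction to its colour class."""
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if fraction < bins.b1:
        return "white"
    if fraction < bins.b2:
        return "blue"
    if fraction <= bins.b3:
        return "yellow"
    return "red"


def consensus_significant(fractions: Sequence[float], frac_threshold: float = 0.60,
                          min_replicas: int = 2) -> bool:
    """Replica-consensus rule: significant iff at least ``min_replicas``
    fractions strictly exceed ``frac_threshold`` (">60 % of simulated time
    in at least two runs"). A fraction exactly at the threshold does not
    qualify.
    """
    if len(fractions) == 0:
        raise ValueError("at least one replica fraction required")
    return sum(1 for f in fractions if f > frac_threshold) >= min_replicas


@dataclass(frozen=True)
class OccurrenceRecord:
    """Occurrence fraction and colour class of one contact in one replica."""

    definition: ContactDefinition
    replica_id: int
    condition: ConditionLabel
    fraction: float
    occupancy_class: str

    def __post_init__(self):
        if self.occupancy_class not in OCCUPANCY_CLASSES:
            raise ValueError(f"unknown class {self.occupancy_class!r}")


@dataclass(frozen=True)
class ConsensusRecord:
    """Per-replica fractions of one contact in one condition, plus the
    consensus significance decision."""

    definition: ContactDefinition
    condition: ConditionLabel
    fractions: tuple[float, ...]
    classes: tuple[str, ...]
    significant: bool


@dataclass(frozen=True)
class FingerprintTable:
    """Contacts × conditions table of consensus records.

    ``cells`` maps (definition, condition) → :class:`ConsensusRecord`;
    missing combinations are explicitly not evaluated. The colour legend is
    carried as metadata so serialized tables render the published scheme.
    """

    definitions: tuple[ContactDefinition, ...]
    conditions: tuple[ConditionLabel, ...]
    cells: Mapping[tuple[ContactDefinition, ConditionLabel], ConsensusRecord]
    legend: Mapping[str, str] = field(default_factory=lambda: dict(COLOUR_LEGEND))
    bins: OccupancyBins = OccupancyBins()

    def cell(self, definition: ContactDefinition,
             condition: ConditionLabel) -> ConsensusRecord | None:
        return self.cells.get((definition, condition))

    def to_dataframe(self, topology: Topology | None = None) -> pd.DataFrame:
        rows = []
        for d in self.definitions:
            for c in self.conditions:
                rec = self.cells.get((d, c))
                if rec is None:
                    continue
                rows.append({
                    "pair": d.label(topology),
                    "kind": d.kind,
                    "salt_bridge": d.charged_pair_flag,
                    "condition": str(c),
                    "fractions": ";".join(f"{f:.4f}" for f in rec.fractions),
                    "classes": ";".join(rec.classes),
                    "significant": rec.significant,
                })
        return pd.DataFrame(rows)


def build_fingerprint_table(series: Iterable[ContactTimeSeries],
                            definitions: Sequence[ContactDefinition] | None = None,
                            frac_threshold: float = 0.60,
                            min_replicas: int = 2,
                            bins: OccupancyBins = OccupancyBins(),
                            ) -> FingerprintTable:
    """Aggregate per-replica contact series into the fingerprint table.

    Series are grouped by (contact definition, condition); replicas within a
    group are ordered by replica id. When ``definitions`` is given, only
    those contacts are tabulated (an empty list gives an empty table).
    """
    grouped: dict[tuple[ContactDefinition, ConditionLabel],
                  list[ContactTimeSeries]] = {}
    cond_order: list[ConditionLabel] = []
    def_order: list[ContactDefinition] = []
    for s in series:
        if s.condition is None:
            raise ValueError("every series needs a condition label")
        if s.n_frames == 0:
            raise ValueError(f"empty series for {s.definition.label()}")
        key = (s.definition, s.condition)
        grouped.setdefault(key, []).append(s)
        if s.condition not in cond_order:
            cond_order.append(s.condition)
        if s.definition not in def_order:
            def_order.append(s.definition)
    if definitions is not None:
        def_order = list(definitions)
    cells: dict[tuple[ContactDefinition, ConditionLabel], ConsensusRecord] = {}
    for (d, c), group in grouped.items():
        if definitions is not None and d not in def_order:
            continue
        group = sorted(group, key=lambda s: s.replica_id)
        fracs = tuple(occurrence_fraction(s) for s in group)
        classes = tuple(classify_occupancy(f, bins) for f in fracs)
        cells[(d, c)] = ConsensusRecord(
            definition=d, condition=c, fractions=fracs, classes=classes,
            significant=consensus_significant(fracs, frac_threshold, min_replicas),
        )
    return FingerprintTable(definitions=tuple(def_order),
                            conditions=tuple(cond_order), cells=cells,
                            bins=bins)


@dataclass(frozen=True)
class DifferentialLabel:
    """How one contact changes between two conditions."""

    definition: ContactDefinition
    label: str  # formed | broken | present-both | absent-both

    def __post_init__(self):
        if self.label not in ("formed", "broken", "present-both", "absent-both"):
            raise ValueError(f"unknown label {self.label!r}")


def differential_labels(table: FingerprintTable, cond_from: ConditionLabel,
                        cond_to: ConditionLabel) -> list[DifferentialLabel]:
    """Label every contact evaluated in both conditions.

    formed: significant only in ``cond_to``; broken: significant only in
    ``cond_from``; otherwise present-both / absent-both.
    """
    for c in (cond_from, cond_to):
        if c not in table.conditions:
            raise ValueError(f"condition {c} not in table")
    out: list[DifferentialLabel] = []
    for d in table.definitions:
        a = table.cell(d, cond_from)
        b = table.cell(d, cond_to)
        if a is None or b is None:
            continue
        if a.significant and not b.significant:
            label = "broken"
        elif b.significant and not a.significant:
            label = "formed"
        elif a.significant and b.significant:
            label = "present-both"
        else:
            label = "absent-both"
        out.append(DifferentialLabel(definition=d, label=label))
    return out


@dataclass(frozen=True)
class SaltBridgeShift:
    """A broken charged pair whose shared residue gains a new charged partner."""

    shared: tuple[str, int, str]
    old_partner: tuple[str, int, str]
    new_partner: tuple[str, int, str]


@dataclass(frozen=True)
class ActivationReport:
    """Protein/protein contact rearrangement between two receptor states."""

    broken: tuple[ContactDefinition, ...]
    formed: tuple[ContactDefinition, ...]
    shifts: tuple[SaltBridgeShift, ...]

    def is_empty(self) -> bool:
        return not (self.broken or self.formed or self.shifts)

    def to_text(self, topology: Topology | None = None) -> str:
        def fmt(d: ContactDefinition) -> str:
            tag = " (salt bridge)" if d.charged_pair_flag else ""
            return f"  {d.label(topology)}{tag}"
        lines = ["Activation network rearrangement"]
        lines.append("broken upon activation:")
        lines += [fmt(d) for d in self.broken] or ["  (none)"]
        lines.append("formed upon activation:")
        lines += [fmt(d) for d in self.formed] or ["  (none)"]
        if self.shifts:
            lines.append("salt-bridge shifts:")
            for s in self.shifts:
                lines.append(
                    f"  {s.shared[2]}{s.shared[1]}: partner "
                    f"{s.old_partner[2]}{s.old_partner[1]} -> "
                    f"{s.new_partner[2]}{s.new_partner[1]}"
                )
        return "\n".join(lines)


def activation_report(table: FingerprintTable, inactive_cond: ConditionLabel,
                      active_cond: ConditionLabel) -> ActivationReport:
    """Summarize the differential protein/protein network between states.

    Protein/ligand contacts are excluded. A compensating shift is reported
    when a broken charged pair shares a residue with a newly formed charged
    pair; the new pair is then listed under shifts rather than under formed.
    """
    labels = differential_labels(table, inactive_cond, active_cond)
    pp = [l for l in labels
          if l.definition.side_a != "ligand" and l.definition.side_b != "ligand"]
    broken = [l.definition for l in pp if l.label == "broken"]
    formed = [l.definition for l in pp if l.label == "formed"]
    shifts: list[SaltBridgeShift] = []
    shift_new_pairs: set[ContactDefinition] = set()
    for old in broken:
        if not old.charged_pair_flag:
            continue
        for new in formed:
            if not new.charged_pair_flag or new in shift_new_pairs:
                continue
            old_sides = {old.side_a, old.side_b}
            new_sides = {new.side_a, new.side_b}
            shared = old_sides & new_sides
            if len(shared) == 1:
                sh = next(iter(shared))
                shifts.append(SaltBridgeShift(
                    shared=sh,
                    old_partner=next(iter(old_sides - shared)),
                    new_partner=next(iter(new_sides - shared)),
                ))
                shift_new_pairs.add(new)
    formed = [d for d in formed if d not in shift_new_pairs]
    return ActivationReport(broken=tuple(broken), formed=tuple(formed),
                            shifts=tuple(shifts))
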