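"""Layered cortical columns and expansion candidacy.

A column is three feedforward layers: external features drive layer IV,
layer IV drives layers II/III, and layers II/III drive the deep output layer
(V/VI).  Fraction of II/III units firing is the column's internal activity;
a column with high internal activity but no deep output is *fairly close* to
detecting its receptive field and is therefore a low-risk expansion
candidate.  There is no lateral wiring within a layer, so columns can be
evaluated in any order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .neuron import FiringMode, PyramidalUnit, integrate


@dataclass
class Column:
    id: int
    area: int
    layer4: list[PyramidalUnit]
    layer23: list[PyramidalUnit]
    deep: list[PyramidalUnit]
    context_group: Optional[int] = None   # stimulus-world group this column was seeded into

    def unit_ids(self) -> list:
        return [u.id for u in self.layer4 + self.layer23 + self.deep]


@dataclass
class ColumnStatus:
    output_active: bool
    internal_activity: float
    candidate: bool
    layer4_fired: frozenset = frozenset()
    layer23_fired: frozenset = frozenset()
    deep_fired: frozenset = frozenset()


def step_column(col: Column, external_input: Iterable, step: int,
                apical_active: Iterable = (), candidacy_floor: float = 0.5,
                output_rule: str = "any") -> ColumnStatus:
    """Evaluate one column bottom-up for one step.

    Layers are evaluated in feedforward order (IV, II/III, deep).  Deep units
    obey the compartment gate: internal activity > 0 marks sensory context,
    which blocks the apical contribution to firing (the condition detections
    on apical branches are still recorded).  ``apical_active`` carries the
    identities of currently firing P3 units for indirect activation.
    """
    ext = frozenset(external_input)
    l4_fired = set()
    for u in col.layer4:
        basal, _ = u.evaluate(ext, (), step)
        if integrate(u, basal, False, True, step) is FiringMode.BASAL:
            l4_fired.add(u.id)
    l23_fired = set()
    for u in col.layer23:
        basal, _ = u.evaluate(l4_fired, (), step)
        if integrate(u, basal, False, True, step) is FiringMode.BASAL:
            l23_fired.add(u.id)
    internal = len(l23_fired) / len(col.layer23) if col.layer23 else 0.0
    sensory_context = internal > 0.0
    apical = frozenset(apical_active)
    deep_fired = set()
    n_deep_fired = 0
    for u in col.deep:
        basal, apic = u.evaluate(l23_fired, apical, step)
        mode = integrate(u, basal, apic, sensory_context, step)
        if mode is not FiringMode.NONE:
            deep_fired.add(u.id)
            n_deep_fired += 1
    if output_rule == "any":
        output_active = n_deep_fired > 0
    else:  # fraction rule
        output_active = col.deep and (n_deep_fired / len(col.deep)) >= 0.5
    candidate = (not output_active) and internal >= candidacy_floor
    return ColumnStatus(output_active=output_active, internal_activity=internal,
                        candidate=candidate,
                        layer4_fired=frozenset(l4_fired),
                        layer23_fired=frozenset(l23_fired),
                        deep_fired=frozenset(deep_fired))


def area_detection_rate(columns: Sequence[Column],
                        statuses: Mapping[int, ColumnStatus]) -> dict[int, float]:
    """Per-area fraction of columns producing output — the quantity
    summarised to the entorhinal layer.  An empty area is signalled."""
    by_area: dict[int, list[bool]] = {}
    for col in columns:
        by_area.setdefault(col.area, []).append(statuses[col.id].output_active)
    rates: dict[int, float] = {}
    for area, flags in sorted(by_area.items()):
        if not flags:
            raise ValueError(f"area {area} holds no columns")
        rates[area] = sum(flags) / len(flags)
    if not rates:
        raise ValueError("no columns supplied")
    return rates
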