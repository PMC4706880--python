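"""Two-compartment pyramidal units built from thresholded dendritic branches.

The model abstracts a cortical pyramidal neuron to pure detection logic:
a *condition* is a group of weighted synapses on one terminal branch, detected
when the summed weight of currently active synapses reaches the branch
threshold; a *receptive field* (one per dendritic tree) is detected when
enough branches detect their conditions.  The basal tree holds the direct
(sensory) field and the apical tree the indirect (retrieval) field, and at any
step at most one tree contributes to firing.

Activity is binary per step.  There are no membrane dynamics: the dendritic
calcium event is abstracted to the boolean branch detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Hashable, Iterable, Optional

SourceId = Hashable

W_MAX_DEFAULT = 1.0


class FiringMode(str, Enum):
    """Which compartment drove firing on a given step."""

    NONE = "none"
    BASAL = "basal"
    APICAL = "apical"


@dataclass
class Synapse:
    """A weighted input from one presynaptic source.

    ``contribution_count`` increments only on steps where the synapse was
    active *and* its branch detected its condition; it is the evidence base
    for the elimination rule (synapses that never contribute are pruned).
    """

    source: SourceId
    weight: float
    last_active_step: Optional[int] = None
    contribution_count: int = 0
    created_step: int = 0
    last_contribution_step: Optional[int] = None

    def __post_init__(self) -> None:
        if self.weight < 0.0:
            raise ValueError(f"synapse weight must be non-negative, got {self.weight}")


@dataclass
class TerminalBranch:
    """One dendritic terminal branch: a set of synapses defining a condition.

    ``manager_synapse`` is the optional strong hippocampal-drive input (the
    perirhinal P2 projection); it participates in detection like any synapse
    but is exempt from pruning and, unless ``manager_alone_detects`` is set,
    cannot detect the condition with no regular synapse active.
    """

    synapses: list[Synapse]
    branch_threshold: float = 1.0
    manager_synapse: Optional[Synapse] = None
    manager_alone_detects: bool = True
    last_detected_step: Optional[int] = None

    def __post_init__(self) -> None:
        if self.branch_threshold <= 0:
            raise ValueError("branch_threshold must be positive")

    def all_synapses(self) -> list[Synapse]:
        if self.manager_synapse is None:
            return list(self.synapses)
        return list(self.synapses) + [self.manager_synapse]


@dataclass
class DendriticTree:
    """Ordered collection of branches with an integer detection threshold."""

    branches: list[TerminalBranch]
    tree_threshold: int = 3
    role: str = "basal"

    def __post_init__(self) -> None:
        if self.role not in ("basal", "apical"):
            raise ValueError(f"tree role must be basal or apical, got {self.role!r}")
        if self.branches and self.tree_threshold > len(self.branches):
            raise ValueError("tree_threshold cannot exceed the number of branches")


def detect_condition(
    branch: TerminalBranch, active_sources: Iterable[SourceId], step: int
) -> bool:
    """Evaluate one branch against the set of currently active sources.

    Returns True iff the summed weight of active synapses (manager included)
    reaches ``branch_threshold`` (boundary inclusive).  Side effects:
    ``last_active_step`` is recorded for every active synapse regardless of
    the outcome, and on detection each active synapse's contribution count
    increments.
    """
    active = active_sources if isinstance(active_sources, (set, frozenset)) else set(active_sources)
    total = 0.0
    active_syns: list[Synapse] = []
    n_regular_active = 0
    for syn in branch.synapses:
        if syn.source in active:
            syn.last_active_step = step
            total += syn.weight
            active_syns.append(syn)
            n_regular_active += 1
    mgr = branch.manager_synapse
    if mgr is not None and mgr.source in active:
        mgr.last_active_step = step
        total += mgr.weight
        active_syns.append(mgr)
    if not active_syns:
        return False
    if n_regular_active == 0 and not branch.manager_alone_detects:
        return False
    detected = total >= branch.branch_threshold
    if detected:
        branch.last_detected_step = step
        for syn in active_syns:
            syn.contribution_count += 1
            syn.last_contribution_step = step
    return detected


def detect_field(
    tree: DendriticTree, active_sources: Iterable[SourceId], step: int
) -> tuple[bool, int]:
    """Evaluate every branch of a tree; the field is detected when the number
    of detecting branches reaches ``tree_threshold``."""
    active = set(active_sources)
    count = 0
    for branch in tree.branches:
        if detect_condition(branch, active, step):
            count += 1
    return count >= tree.tree_threshold, count


@dataclass
class PyramidalUnit:
    """A unit with a basal (direct) and an apical (indirect) dendritic tree.

    ``integrate`` enforces the gating contract: while sensory context is
    active in the unit's column, interneurons block the apical path at the
    soma, so only the basal field can drive firing; with no sensory context
    the basal path carries nothing and only the apical field can fire the
    unit.  Apical *condition* detections are still recorded while gated —
    only the firing contribution is blocked.
    """

    id: SourceId
    basal: DendriticTree
    apical: DendriticTree
    apical_gate_closed: bool = False
    fired: bool = False
    fire_step: Optional[int] = None
    last_mode: FiringMode = FiringMode.NONE
    last_basal_detected: bool = False
    last_apical_detected: bool = False
    last_basal_count: int = 0
    last_apical_count: int = 0

    def evaluate(self, basal_sources: Iterable[SourceId],
                 apical_sources: Iterable[SourceId], step: int) -> tuple[bool, bool]:
        """Run both trees against their source sets and cache the results."""
        self.last_basal_detected, self.last_basal_count = detect_field(
            self.basal, basal_sources, step)
        self.last_apical_detected, self.last_apical_count = detect_field(
            self.apical, apical_sources, step)
        return self.last_basal_detected, self.last_apical_detected


def integrate(
    unit: PyramidalUnit,
    basal_detected: bool,
    apical_detected: bool,
    sensory_context_active: bool,
    step: int = 0,
) -> FiringMode:
    """Combine tree detections into a firing decision under the XOR contract."""
    unit.apical_gate_closed = sensory_context_active
    if sensory_context_active:
        mode = FiringMode.BASAL if basal_detected else FiringMode.NONE
    else:
        mode = FiringMode.APICAL if apical_detected else FiringMode.NONE
    unit.last_mode = mode
    unit.fired = mode is not FiringMode.NONE
    if unit.fired:
        unit.fire_step = step
    return mode


@dataclass
class DelayedUnit(PyramidalUnit):
    """Late-firing unit: a detection at step t emits output at t + delay.

    After emitting, the unit is refractory for ``refractory`` steps, so within
    one episode it fires once; together with heterogeneous delays across the
    population this spreads the units over the moments of an event.
    """

    delay: int = 2
    pending_fire_step: Optional[int] = None
    refractory: int = 8
    refractory_until: int = -1
    pending_trace: Optional[frozenset] = None
    last_trace: Optional[frozenset] = None

    def schedule(self, step: int, trace: Optional[frozenset] = None) -> None:
        """Register a detection; the emission happens ``delay`` steps later.

        ``trace`` records the sources active at detection time (a synaptic
        tag): when the delayed firing finally consolidates the basal branches,
        it strengthens the detection-time inputs, so the basal field binds the
        *earlier* moment while the outgoing links bind the firing-time moment
        — the substrate of in-order sequence recall.
        """
        if self.pending_fire_step is None and step >= self.refractory_until:
            self.pending_fire_step = step + self.delay
            self.pending_trace = trace

    def emit(self, step: int) -> bool:
        """Return True (and mark fired) exactly at the scheduled step."""
        if self.pending_fire_step is not None and step >= self.pending_fire_step:
            self.pending_fire_step = None
            self.refractory_until = step + self.refractory
            self.last_trace = self.pending_trace
            self.pending_trace = None
            self.fired = True
            self.fire_step = step
            return True
        self.fired = False
        return False


def brute_force_field(tree: DendriticTree, active_sources: set) -> tuple[bool, int]:
    """Stateless re-evaluation of a tree, independent of the incremental
    bookkeeping above.  Used as the oracle in equivalence tests."""
    count = 0
    for branch in tree.branches:
        total = sum(s.weight for s in branch.all_synapses() if s.source in active_sources)
        any_active = any(s.source in active_sources for s in branch.all_synapses())
        regular_active = any(s.source in active_sources for s in branch.synapses)
        if not any_active:
            continue
        if not regular_active and not branch.manager_alone_detects:
            continue
        if total >= branch.branch_threshold:
            count += 1
    return count >= tree.tree_threshold, count
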