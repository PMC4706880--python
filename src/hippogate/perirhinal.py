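"""The perirhinal interface circuit: intermediate units plus the P1/P2/P3
deep populations, episodic recording, and cued retrieval.

A perirhinal column covers a group of regular cortical columns.  Its
intermediate units read those columns' layer II/III activity; P1
(regular-spiking) detects the column's own receptive field — full familiar
activity across the member columns — and inhibits P2 through interneurons;
P2 (burst-spiking) fires when entorhinal decode drive arrives and P1 is
silent, and is the manager signal that gates receptive-field expansion; P3
(late-spiking) units fire with heterogeneous delays during expansion periods
and, through reciprocal provisional wiring with the member columns' deep
units, record each moment of an episode so that a partial cue can later
replay the episode in order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .neuron import DelayedUnit, FiringMode, PyramidalUnit, integrate
from .plasticity import PlasticityConfig, expand_branch


@dataclass
class PerirhinalColumn:
    id: int
    context_group: int
    intermediate: list[PyramidalUnit]
    P1: list[PyramidalUnit]
    P2: list[PyramidalUnit]
    P3: list[DelayedUnit]
    member_columns: frozenset
    p2_threshold: float = 0.05
    p2_match_floor: float = 0.5   # minimum own intermediate activity for P2 to fire
    expansion_hold: int = 0       # steps left in a sustained expansion period
    # per-step cached state
    last_match: float = 0.0
    last_p1_active: bool = False
    last_p2_active: bool = False
    last_int_fired: frozenset = frozenset()
    last_p3_fired: frozenset = frozenset()

    def manager_token(self) -> tuple:
        """Source identifier carried by P2 manager synapses within this column."""
        return ("MGR1", self.id)

    def p3_manager_token(self) -> tuple:
        return ("MGR3", self.id)


@dataclass
class EpisodeTrace:
    """Ground-truth encoding log: which deep units fired at each moment.

    Diagnostic only — retrieval never reads it; it is the oracle against
    which recall metrics are computed.
    """

    episode_id: int
    moments: list[set] = field(default_factory=list)

    def add_moment(self, deep_ids: Iterable) -> None:
        self.moments.append(set(deep_ids))

    @property
    def full_set(self) -> set:
        out: set = set()
        for m in self.moments:
            out |= m
        return out

    def new_units_per_moment(self) -> list[set]:
        """Units attributed to the moment where they first fired."""
        seen: set = set()
        out = []
        for m in self.moments:
            fresh = m - seen
            out.append(fresh)
            seen |= m
        return out


def sense_phase(pcol: PerirhinalColumn, step: int,
                member_l23_fired: Iterable) -> dict:
    """Intermediate units and P1: the perirhinal column's own receptive
    field, evaluated before the hippocampal competition runs."""
    l23 = frozenset(member_l23_fired)
    int_fired = set()
    for u in pcol.intermediate:
        basal, _ = u.evaluate(l23, (), step)
        if integrate(u, basal, False, True, step) is FiringMode.BASAL:
            int_fired.add(u.id)
    match = len(int_fired) / len(pcol.intermediate) if pcol.intermediate else 0.0

    p1_active = False
    for u in pcol.P1:
        basal, _ = u.evaluate(int_fired, (), step)
        if integrate(u, basal, False, True, step) is FiringMode.BASAL:
            p1_active = True

    pcol.last_match = match
    pcol.last_p1_active = p1_active
    pcol.last_int_fired = frozenset(int_fired)
    return {"int_fired": frozenset(int_fired), "p1_active": p1_active, "match": match}


def drive_phase(pcol: PerirhinalColumn, step: int, entorhinal_drive: float,
                member_deep_fired: Iterable,
                member_deep_onset: Optional[Iterable] = None) -> dict:
    """P2 gate and P3 dynamics, evaluated after release-and-decode.

    P2 fires iff the decode drive reaches its threshold and the P1 gate is
    open.  While P2 is active, P3 units are driven on their apical dendrites
    and their basal contribution is gated off (basal condition detections are
    still recorded for the episodic bookkeeping); with P2 silent the basal
    route drives P3, which is the retrieval direction.

    ``member_deep_onset`` carries the deep units whose firing *started*
    recently; the detection-time synaptic tag is restricted to them, so a
    delayed unit's basal trace binds the moment's fresh content rather than
    activity carried over from earlier moments.
    """
    deep = frozenset(member_deep_fired)
    onset = frozenset(member_deep_onset) if member_deep_onset is not None else deep
    p1_active = pcol.last_p1_active
    p2_gated_in = (entorhinal_drive >= pcol.p2_threshold
                   and pcol.last_match >= pcol.p2_match_floor
                   and not p1_active)
    # During an episode the expansion period is sustained: familiarity rising
    # mid-event (P1 coming on as fields expand) does not cut recording short.
    p2_active = p2_gated_in or pcol.expansion_hold > 0
    p2_fired = set()
    for u in pcol.P2:
        u.fired = p2_active
        u.last_mode = FiringMode.APICAL if p2_active else FiringMode.NONE
        if p2_active:
            u.fire_step = step
            p2_fired.add(u.id)

    # P3: basal branches are evaluated every step so synapse recency and
    # branch detections stay current; the firing route depends on P2.
    p3_basal_sources = deep | ({pcol.p3_manager_token()} if p2_active else frozenset())
    p3_fired = set()
    for u in pcol.P3:
        basal, _ = u.evaluate(p3_basal_sources, p2_fired, step)
        apical = u.last_apical_detected
        if p2_active:
            # P2 primes the unit apically; the delayed firing is locked to
            # the step the unit's own basal condition picks up the current
            # deep pattern, which is also the content of its synaptic tag.
            mode = integrate(u, False, apical, False, step)
            if mode is not FiringMode.NONE and basal:
                u.schedule(step, trace=onset)
        else:
            mode = integrate(u, basal, False, True, step)
            if mode is not FiringMode.NONE:
                u.schedule(step, trace=onset)
        if u.emit(step):
            p3_fired.add(u.id)

    pcol.last_p2_active = p2_active
    pcol.last_p3_fired = frozenset(p3_fired)
    return {
        "p1_active": p1_active,
        "p2_active": p2_active,
        "p2_gated_in": p2_gated_in,
        "p3_fired": frozenset(p3_fired),
        "match": pcol.last_match,
    }


def step_perirhinal(pcol: PerirhinalColumn, step: int, entorhinal_drive: float,
                    member_l23_fired: Iterable, member_deep_fired: Iterable) -> dict:
    """Evaluate one perirhinal column for one step, in the fixed order
    intermediate -> P1 -> gate -> P2 -> P3."""
    sense = sense_phase(pcol, step, member_l23_fired)
    rec = drive_phase(pcol, step, entorhinal_drive, member_deep_fired)
    rec["int_fired"] = sense["int_fired"]
    return rec


def record_episode(pcol: PerirhinalColumn, step: int, cfg: PlasticityConfig) -> dict:
    """Strengthen the P3-basal traces of the deep activity pattern.

    Called once per step during an expansion period, after the column has
    been stepped: every P3 unit that fired this step consolidates the deep
    inputs recently active on its detecting basal branches.  Refused outside
    expansion periods.
    """
    if not pcol.last_p2_active:
        raise RuntimeError("record_episode outside an expansion period")
    report: dict = {}
    for u in pcol.P3:
        if not u.fired:
            continue
        for bi, branch in enumerate(u.basal.branches):
            changes = expand_branch(branch, manager_active=True,
                                    neuron_fired_within_window=True,
                                    step=step, cfg=cfg,
                                    eligible_sources=u.last_trace)
            for src, dw in changes.items():
                report[(u.id, bi, src)] = dw
    return report


def reset_dynamic_state(pcols: Sequence[PerirhinalColumn],
                        refractory: Optional[int] = None) -> None:
    """Clear pending/refractory/fired state before a retrieval run.

    ``refractory`` optionally re-arms the delayed units with a shorter
    refractory period, letting a P3 unit discharge more than once within a
    retrieval run (a unit that misses its first window can still contribute
    once more of the episode is active)."""
    for pcol in pcols:
        for u in pcol.intermediate + pcol.P1 + pcol.P2:
            u.fired = False
            u.last_mode = FiringMode.NONE
        for u in pcol.P3:
            u.fired = False
            u.last_mode = FiringMode.NONE
            u.pending_fire_step = None
            u.refractory_until = -1
            if refractory is not None:
                u.refractory = refractory
        pcol.last_p2_active = False
        pcol.last_p1_active = False
        pcol.expansion_hold = 0


def retrieve(pcols: Sequence[PerirhinalColumn], cue: Iterable, max_steps: int,
             deep_units: Mapping, cfg: PlasticityConfig,
             sensory_context_active: bool = False) -> dict[int, frozenset]:
    """Indirect reactivation of an episode from a partial deep-unit cue.

    The cue units are clamped active; each step, active deep units drive P3
    basal detection, delayed P3 firing drives deep apical detection, and
    newly activated deep units join the active set.  Returns the timeline
    step -> newly activated deep-unit ids (step 0 holds the cue).  Plasticity
    must be frozen by the caller; retrieval itself never writes a weight.

    With sensory context active the deep apical gates are closed and nothing
    beyond the cue can reactivate.
    """
    if cfg.expansion_enabled:
        raise RuntimeError("retrieval requires plasticity to be frozen")
    cue_set = frozenset(cue)
    timeline: dict[int, frozenset] = {}
    if not cue_set:
        warnings.warn("empty retrieval cue", RuntimeWarning, stacklevel=2)
        return timeline
    timeline[0] = cue_set
    active: set = set(cue_set)
    recent_p3: list[set] = []   # late-spiking output stays effective briefly
    for t in range(1, max_steps + 1):
        p3_fired: set = set()
        for pcol in pcols:
            for u in pcol.P3:
                basal, _ = u.evaluate(active, (), t)
                mode = integrate(u, basal, False, True, t)
                if mode is FiringMode.BASAL:
                    u.schedule(t)
                if u.emit(t):
                    p3_fired.add(u.id)
        recent_p3.append(p3_fired)
        if len(recent_p3) > cfg.recent_window:
            recent_p3.pop(0)
        p3_window = set().union(*recent_p3)
        newly: set = set()
        for uid, unit in deep_units.items():
            if uid in active:
                continue
            _, apic = unit.evaluate((), p3_window, t)
            mode = integrate(unit, False, apic, sensory_context_active, t)
            if mode is FiringMode.APICAL:
                newly.add(uid)
        active |= newly
        timeline[t] = frozenset(newly)
    return timeline
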