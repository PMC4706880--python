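"""Network construction: columns, perirhinal cover, CA3 groups.

All wiring is generated from a seeded generator against a stimulus world.
Two builders are provided:

* ``build_network(world, cfg, rng, trained=False)`` — deep fields start weak
  (silent without manager drive); familiarization through the engine
  strengthens them.  This is the state before any hippocampally gated
  expansion.
* ``trained=True`` — deep fields are constructed in the post-familiarization
  state, with a per-column spread of detection robustness (the biological
  heterogeneity that makes area detection rates degrade gradually with
  novelty rather than all-or-none).

Scaled-down unit counts (a handful of branches and synapses per unit rather
than the cortical ~100x100) keep desk experiments fast; the logic is
size-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .column import Column
from .hippocampus import CA3Group
from .neuron import (DelayedUnit, DendriticTree, PyramidalUnit, Synapse,
                     TerminalBranch)
from .perirhinal import PerirhinalColumn
from .stimuli import World


@dataclass
class NetworkConfig:
    n_areas: int = 4
    columns_per_area: int = 16
    l4_per_column: int = 8
    l23_per_column: int = 8
    l23_thresholds: tuple = (2, 3, 3, 4, 4, 5, 6, 7)  # k-of-8 spread across II/III units
    deep_per_column: int = 4
    deep_branches: int = 2
    # per-column required II/III fraction; the upper tail (> 1) yields columns
    # whose deep conjunction exceeds what this context can supply — fields
    # tuned to other circumstances, silent here
    deep_robustness: tuple = (0.7, 1.2)
    trained_weight: float = 0.8
    fresh_deep_weight: float = 0.55
    fresh_deep_threshold: float = 4.5
    manager_weight: float = 1.2
    pcols_per_context: int = 4
    membership_overlap: int = 2                  # extra random members per perirhinal column
    intermediate_per_pcol: int = 6
    int_fanin: int = 10
    int_thresholds: tuple = (5, 6, 7, 8, 8, 9)
    p1_per_pcol: int = 2
    p2_per_pcol: int = 2
    p3_per_pcol: int = 45
    p3_delay_slots: int = 9
    p3_branches: int = 3
    p3_fanin: int = 12
    p3_provisional_weight: float = 0.1
    p3_manager_weight: float = 0.8
    p3_branch_threshold: float = 1.05
    p3_refractory: int = 24
    deep_apical_fanin: int = 24
    deep_apical_branches: int = 3
    deep_apical_threshold: float = 0.45
    apical_extra_pcols: int = 2   # foreign perirhinal columns also sampled by deep apical trees
    p2_threshold: float = 0.05
    p2_match_floor: float = 0.05
    candidacy_floor: float = 0.5


class Network:
    """The wired circuit plus id -> unit indices used by the engine."""

    def __init__(self, columns: list[Column], pcols: list[PerirhinalColumn],
                 groups: list[CA3Group], cfg: NetworkConfig):
        self.columns = columns
        self.pcols = pcols
        self.groups = groups
        self.cfg = cfg
        self.col_by_id = {c.id: c for c in columns}
        self.deep_units = {u.id: u for c in columns for u in c.deep}
        self.pcols_of_column: dict[int, list[int]] = {}
        for p in pcols:
            for cid in p.member_columns:
                self.pcols_of_column.setdefault(cid, []).append(p.id)

    @property
    def n_areas(self) -> int:
        return self.cfg.n_areas

    def columns_in_area(self, area: int) -> list[Column]:
        return [c for c in self.columns if c.area == area]

    def iter_units(self):
        for c in self.columns:
            yield from c.layer4
            yield from c.layer23
            yield from c.deep
        for p in self.pcols:
            yield from p.intermediate
            yield from p.P1
            yield from p.P2
            yield from p.P3

    def total_weight(self) -> float:
        """Sum of all synaptic weights (manager synapses included) — the
        conserved quantity under frozen plasticity."""
        total = 0.0
        for u in self.iter_units():
            for tree in (u.basal, u.apical):
                for br in tree.branches:
                    total += sum(s.weight for s in br.all_synapses())
        return total


def _branch(sources: Sequence, weight: float, threshold: float,
            manager: Optional[tuple] = None, manager_weight: float = 0.0,
            manager_alone: bool = True) -> TerminalBranch:
    syns = [Synapse(source=s, weight=weight) for s in sources]
    mgr = Synapse(source=manager, weight=manager_weight) if manager is not None else None
    return TerminalBranch(synapses=syns, branch_threshold=threshold,
                          manager_synapse=mgr, manager_alone_detects=manager_alone)


def _unit(uid, basal_branches, apical_branches=(), basal_thr=1, apical_thr=1) -> PyramidalUnit:
    return PyramidalUnit(
        id=uid,
        basal=DendriticTree(branches=list(basal_branches), tree_threshold=basal_thr,
                            role="basal"),
        apical=DendriticTree(branches=list(apical_branches), tree_threshold=apical_thr,
                             role="apical"),
    )


def build_network(world: World, cfg: NetworkConfig, rng: np.random.Generator,
                  trained: bool = False) -> Network:
    wcfg = world.cfg
    if cfg.n_areas != wcfg.n_areas:
        raise ValueError("network and world disagree on the number of areas")
    n_ctx = wcfg.n_contexts
    per_ctx = cfg.columns_per_area // n_ctx
    ctx_feats = [world.context_features_by_area(g) for g in range(n_ctx)]

    columns: list[Column] = []
    cid = 0
    for area in range(cfg.n_areas):
        for j in range(cfg.columns_per_area):
            group = min(j // per_ctx, n_ctx - 1)
            feats = ctx_feats[group][area]
            # each column reads a contiguous subfield of its context's
            # features, so different columns prefer different portions of the
            # context and a sliding event window recruits distinct columns
            span = min(cfg.l4_per_column, len(feats))
            offset = int(rng.integers(0, len(feats) - span + 1))
            features = feats[offset: offset + span]

            layer4 = [
                _unit(("L4", cid, i),
                      [_branch([("EXT", f)], weight=1.0, threshold=1.0)])
                for i, f in enumerate(features)
            ]
            l4_ids = [u.id for u in layer4]
            layer23 = [
                _unit(("L23", cid, i),
                      [_branch(l4_ids, weight=1.0, threshold=float(k))])
                for i, k in enumerate(cfg.l23_thresholds[: cfg.l23_per_column])
            ]
            l23_ids = [u.id for u in layer23]

            d_lo, d_hi = cfg.deep_robustness
            d_c = float(rng.uniform(d_lo, d_hi))
            deep = []
            for i in range(cfg.deep_per_column):
                branches = []
                for _ in range(cfg.deep_branches):
                    if trained:
                        need = max(1, round(d_c * len(l23_ids)))
                        # half-weight margin: k active synapses of weight w sum
                        # to k*w only up to float rounding, so the threshold
                        # sits between (need-1)*w and need*w
                        branches.append(_branch(
                            l23_ids, weight=cfg.trained_weight,
                            threshold=(need - 0.5) * cfg.trained_weight,
                            manager=("MGR", cid), manager_weight=cfg.manager_weight,
                            manager_alone=False))
                    else:
                        branches.append(_branch(
                            l23_ids, weight=cfg.fresh_deep_weight,
                            threshold=cfg.fresh_deep_threshold,
                            manager=("MGR", cid), manager_weight=cfg.manager_weight,
                            manager_alone=False))
                deep.append(_unit(("D", cid, i), branches))
            columns.append(Column(id=cid, area=area, layer4=layer4, layer23=layer23,
                                  deep=deep, context_group=group))
            cid += 1

    # --- perirhinal cover: deal each context's columns round-robin, then add
    # overlap extras so each cortical column can sit in several covers.
    pcols: list[PerirhinalColumn] = []
    pid = 0
    for g in range(n_ctx):
        g_cols = [c.id for c in columns if c.context_group == g]
        order = list(rng.permutation(g_cols))
        buckets: list[list[int]] = [[] for _ in range(cfg.pcols_per_context)]
        for i, c in enumerate(order):
            buckets[i % cfg.pcols_per_context].append(int(c))
        for members in buckets:
            extra = [int(x) for x in rng.choice(g_cols, size=cfg.membership_overlap,
                                                replace=False)]
            member_set = frozenset(members) | frozenset(extra)
            member_l23 = [u.id for c in sorted(member_set)
                          for u in columns[c].layer23]
            member_deep = [u.id for c in sorted(member_set)
                           for u in columns[c].deep]

            inter = []
            for i, k in enumerate(cfg.int_thresholds[: cfg.intermediate_per_pcol]):
                picks = rng.choice(len(member_l23),
                                   size=min(cfg.int_fanin, len(member_l23)),
                                   replace=False)
                srcs = [member_l23[int(x)] for x in picks]
                inter.append(_unit(("INT", pid, i),
                                   [_branch(srcs, weight=1.0, threshold=float(k))]))
            int_ids = [u.id for u in inter]

            p1 = []
            for i in range(cfg.p1_per_pcol):
                if trained:
                    br = _branch(int_ids, weight=cfg.trained_weight,
                                 threshold=(len(int_ids) - 1) * cfg.trained_weight + 0.1,
                                 manager=("MGR1", pid), manager_weight=cfg.manager_weight,
                                 manager_alone=False)
                else:
                    br = _branch(int_ids, weight=cfg.fresh_deep_weight,
                                 threshold=cfg.fresh_deep_threshold,
                                 manager=("MGR1", pid), manager_weight=cfg.manager_weight,
                                 manager_alone=False)
                p1.append(_unit(("P1", pid, i), [br]))

            p2 = [_unit(("P2", pid, i), []) for i in range(cfg.p2_per_pcol)]
            p2_ids = [u.id for u in p2]

            p3 = []
            for i in range(cfg.p3_per_pcol):
                branches = []
                for _ in range(cfg.p3_branches):
                    picks = rng.choice(len(member_deep),
                                       size=min(cfg.p3_fanin, len(member_deep)),
                                       replace=False)
                    srcs = [member_deep[int(x)] for x in picks]
                    branches.append(_branch(
                        srcs, weight=cfg.p3_provisional_weight,
                        threshold=cfg.p3_branch_threshold,
                        manager=("MGR3", pid), manager_weight=cfg.p3_manager_weight,
                        manager_alone=False))
                apical = [_branch(p2_ids, weight=1.0, threshold=1.0)]
                unit = DelayedUnit(
                    id=("P3", pid, i),
                    basal=DendriticTree(branches=branches, tree_threshold=1, role="basal"),
                    apical=DendriticTree(branches=apical, tree_threshold=1, role="apical"),
                    delay=1 + (i % cfg.p3_delay_slots),
                    refractory=cfg.p3_refractory,
                )
                p3.append(unit)

            pcols.append(PerirhinalColumn(
                id=pid, context_group=g, intermediate=inter, P1=p1, P2=p2, P3=p3,
                member_columns=member_set, p2_threshold=cfg.p2_threshold,
                p2_match_floor=cfg.p2_match_floor))
            pid += 1

    # --- deep apical wiring: provisional synapses from the P3 units of the
    # covering perirhinal columns, plus the P2 manager input.
    p3_by_pcol = {p.id: [u.id for u in p.P3] for p in pcols}
    cover: dict[int, list[int]] = {}
    for p in pcols:
        for c in p.member_columns:
            cover.setdefault(c, []).append(p.id)
    for col in columns:
        covering = list(cover.get(col.id, []))
        # a column records P3 groups in multiple perirhinal columns, not only
        # the ones covering it — sample a few foreign ones as well
        foreign = [p.id for p in pcols if p.id not in covering]
        if foreign and cfg.apical_extra_pcols:
            extra = rng.choice(len(foreign),
                               size=min(cfg.apical_extra_pcols, len(foreign)),
                               replace=False)
            covering = covering + [foreign[int(i)] for i in extra]
        pool = [uid for pidx in covering for uid in p3_by_pcol[pidx]]
        for u in col.deep:
            branches = []
            for _ in range(cfg.deep_apical_branches):
                if pool:
                    picks = rng.choice(len(pool),
                                       size=min(cfg.deep_apical_fanin, len(pool)),
                                       replace=False)
                    srcs = [pool[int(x)] for x in picks]
                else:
                    srcs = []
                branches.append(_branch(
                    srcs, weight=0.0, threshold=cfg.deep_apical_threshold,
                    manager=("MGRA", col.id), manager_weight=cfg.manager_weight,
                    manager_alone=True))
            u.apical = DendriticTree(branches=branches, tree_threshold=1, role="apical")

    groups = groups_from_cover(columns, pcols)
    return Network(columns, pcols, groups, cfg)


def groups_from_cover(columns: Sequence[Column],
                      pcols: Sequence[PerirhinalColumn]) -> list[CA3Group]:
    """Context-aligned CA3 groups: the post-seeding state in which columns
    that expanded together (one group per stimulus context) share a field."""
    n_ctx = 1 + max(c.context_group or 0 for c in columns)
    out = []
    for g in range(n_ctx):
        cols = frozenset(c.id for c in columns if c.context_group == g)
        pids = frozenset(p.id for p in pcols if p.context_group == g)
        areas = frozenset(c.area for c in columns if c.context_group == g)
        out.append(CA3Group(g, cols, pids, areas))
    return out


def random_groups(n_groups: int, n_areas: int, rng: np.random.Generator,
                  pcol_ids: Sequence[int] = ()) -> list[CA3Group]:
    """Random group fallback for unit tests of the competition machinery."""
    out = []
    for g in range(n_groups):
        k = int(rng.integers(1, n_areas + 1))
        areas = frozenset(int(a) for a in rng.choice(n_areas, size=k, replace=False))
        pids = frozenset(int(p) for p in rng.choice(pcol_ids, size=min(2, len(pcol_ids)),
                                                    replace=False)) if len(pcol_ids) else frozenset()
        out.append(CA3Group(g, frozenset(), pids, areas))
    return out
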