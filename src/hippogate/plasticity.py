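"""Gated receptive-field expansion and the change-constraint rules.

Expansion is the only way weights grow: when the hippocampal manager input is
driving a branch, the branch detects its condition, and the neuron fires soon
after, the backpropagating action potential strengthens the recently active
regular synapses on that branch (and only that branch).  Two further rules
keep fields small: the detection threshold of an over-detecting field is
raised, and synapses that never contribute to detections are eliminated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .neuron import PyramidalUnit, Synapse, TerminalBranch


class PlasticityFrozenError(RuntimeError):
    """Raised when expansion is requested while plasticity is frozen
    (retrieval mode must not drive receptive-field changes)."""


@dataclass
class PlasticityConfig:
    delta_w: float = 0.15          # weight increment per expansion event
    w_max: float = 1.0             # hard ceiling on any synaptic weight
    recent_window: int = 3         # steps within which a synapse is "recently active"
    overdetection_rate: float = 0.5  # detections/presentation above which threshold rises
    threshold_step: float = 1.0    # tree-threshold increment (integer ceil applied)
    prune_window: int = 20         # presentations of zero contribution before elimination
    expansion_enabled: bool = True
    manager_decay: float = 0.0     # optional per-presentation decay of manager weights

    def __post_init__(self) -> None:
        if self.delta_w > self.w_max:
            raise ValueError("delta_w cannot exceed w_max")
        if self.recent_window < 1 or self.prune_window < 1:
            raise ValueError("windows must be >= 1")


def expand_branch(
    branch: TerminalBranch,
    manager_active: bool,
    neuron_fired_within_window: bool,
    step: int,
    cfg: PlasticityConfig,
    eligible_sources=None,
) -> dict:
    """Strengthen recently active regular synapses of one gated branch.

    Returns a change report mapping synapse source -> weight increment
    (possibly empty).  The three gates — manager drive, branch condition
    detection, and neuron firing within the Hebbian window — must all be
    open, otherwise the report is empty and no weight moves.

    ``eligible_sources`` narrows the strengthened set to a detection-time
    synaptic tag (used by delayed units, whose backpropagating firing must
    consolidate the inputs that were active when the branch detected, not the
    inputs active at the later firing step).
    """
    if not cfg.expansion_enabled:
        raise PlasticityFrozenError("plasticity frozen: expansion refused")
    report: dict = {}
    branch_detected_recently = (
        branch.last_detected_step is not None
        and step - branch.last_detected_step <= cfg.recent_window
    )
    if not (manager_active and branch_detected_recently and neuron_fired_within_window):
        return report
    for syn in branch.synapses:
        if syn.last_active_step is None:
            continue
        if eligible_sources is not None:
            # detection-time synaptic tag replaces the recency test
            if syn.source not in eligible_sources:
                continue
        elif step - syn.last_active_step >= cfg.recent_window:
            # "recently active" = within the last recent_window steps, the
            # current step counting as the first
            continue
        new_w = min(cfg.w_max, syn.weight + cfg.delta_w)
        if new_w != syn.weight:
            report[syn.source] = new_w - syn.weight
            syn.weight = new_w
    return report


def raise_threshold(unit: PyramidalUnit, detection_rate: float,
                    cfg: PlasticityConfig) -> int:
    """Raise the basal tree threshold of an over-detecting field.

    The threshold rises by ceil(threshold_step) when the measured detection
    rate exceeds ``overdetection_rate``; it never exceeds the branch count.
    Returns the (possibly unchanged) tree threshold.
    """
    tree = unit.basal
    if detection_rate > cfg.overdetection_rate:
        step_int = max(1, math.ceil(cfg.threshold_step))
        tree.tree_threshold = min(len(tree.branches), tree.tree_threshold + step_int)
    return tree.tree_threshold


def prune_synapses(unit: PyramidalUnit, current_presentation: int,
                   cfg: PlasticityConfig) -> list:
    """Remove synapses that contributed to no detection over a full window.

    Manager synapses are exempt, and synapses younger than one prune window
    keep a grace period (provisional inputs must survive long enough to be
    recruited).  Returns the removed synapse sources.
    """
    removed: list = []
    for tree in (unit.basal, unit.apical):
        for branch in tree.branches:
            keep: list[Synapse] = []
            for syn in branch.synapses:
                age = current_presentation - syn.created_step
                idle = (
                    syn.last_contribution_step is None
                    or current_presentation - syn.last_contribution_step >= cfg.prune_window
                )
                if age >= cfg.prune_window and idle:
                    removed.append(syn.source)
                else:
                    keep.append(syn)
            branch.synapses = keep
    return removed


def decay_manager_weights(unit: PyramidalUnit, cfg: PlasticityConfig) -> None:
    """Optional exponential decay of manager-synapse weights (the declining
    burst-projection weights; off by default)."""
    if cfg.manager_decay <= 0.0:
        return
    for tree in (unit.basal, unit.apical):
        for branch in tree.branches:
            if branch.manager_synapse is not None:
                branch.manager_synapse.weight *= 1.0 - cfg.manager_decay
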