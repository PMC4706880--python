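"""Branch condition detection, tree-level field detection, and the
basal/apical gating contract of the two-compartment unit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippogate import (DelayedUnit, DendriticTree, FiringMode, Synapse,
                       TerminalBranch, brute_force_field, detect_condition,
                       detect_field, integrate)

from conftest import make_branch, make_unit, random_active_set, random_tree


class TestDetectCondition:
    @pytest.mark.parametrize("weights,active,threshold,expected", [
        ((0.4, 0.4, 0.3), (0, 1, 2), 1.0, True),    # 1.1 >= 1.0
        ((0.4, 0.4, 0.3), (), 1.0, False),           # empty sum
        ((0.2,) * 5, (0, 1, 2, 3, 4), 1.0, True),    # boundary uses >=
        ((0.4, 0.4), (0,), 1.0, False),              # partial activity
    ])
    def test_threshold_arithmetic(self, weights, active, threshold, expected):
        br = make_branch(weights, threshold)
        got = detect_condition(br, {("s", i) for i in active}, step=0)
        assert got is expected

    def test_side_effects(self):
        br = make_branch((0.3, 0.3), threshold=1.0)
        detect_condition(br, {("s", 0)}, step=5)
        # last_active recorded regardless of outcome; no contribution without
        # detection
        assert br.synapses[0].last_active_step == 5
        assert br.synapses[0].contribution_count == 0
        assert br.synapses[1].last_active_step is None
        detect_condition(br, {("s", 0), ("s", 1)}, step=6)
        assert not detect_condition(br, {("s", 0)}, step=7)
        br.branch_threshold = 0.25
        assert detect_condition(br, {("s", 0)}, step=8)
        assert br.synapses[0].contribution_count == 1
        assert br.last_detected_step == 8

    def test_manager_counts_toward_detection(self):
        br = make_branch((0.2, 0.2), threshold=1.0, manager_weight=0.8)
        assert detect_condition(br, {("s", 0), ("mgr", 0)}, step=0)

    def test_manager_alone_flag(self):
        strong = make_branch((0.1,), threshold=1.0, manager_weight=1.5,
                             manager_alone=True)
        assert detect_condition(strong, {("mgr", 0)}, step=0)
        gated = make_branch((0.1,), threshold=1.0, manager_weight=1.5,
                            manager_alone=False)
        assert not detect_condition(gated, {("mgr", 0)}, step=0)
        # with any regular synapse active the manager participates again
        assert detect_condition(gated, {("mgr", 0), ("s", 0)}, step=1)


class TestDetectField:
    def _tree(self, n_branches, per_branch_weight=1.0):
        branches = [make_branch((per_branch_weight,), 1.0, prefix=f"b{i}")
                    for i in range(n_branches)]
        return DendriticTree(branches=branches, tree_threshold=3, role="basal")

    def test_counting_at_threshold(self):
        tree = self._tree(100)
        active = {(f"b{i}", 0) for i in range(3)}
        assert detect_field(tree, active, 0) == (True, 3)

    def test_counting_below_threshold(self):
        tree = self._tree(100)
        active = {(f"b{i}", 0) for i in range(2)}
        assert detect_field(tree, active, 0) == (False, 2)

    def test_matches_brute_force_on_random_trees(self, rng):
        """Incremental detection equals stateless re-enumeration."""
        for _ in range(300):
            tree = random_tree(rng)
            active = random_active_set(tree, rng)
            assert detect_field(tree, active, 0) == brute_force_field(tree, active)

    def test_empty_tree_never_detects(self):
        tree = DendriticTree(branches=[], tree_threshold=1, role="apical")
        assert detect_field(tree, {("x", 0)}, 0) == (False, 0)


@given(extra=st.floats(min_value=0.0, max_value=5.0))
@settings(max_examples=50, deadline=None)
def test_monotonicity_adding_weight_preserves_detection(extra):
    """Adding weight to an active synapse never undoes a detection."""
    br = make_branch((0.5, 0.6), threshold=1.0)
    active = {("s", 0), ("s", 1)}
    assert detect_condition(br, active, 0)
    br.synapses[0].weight += extra
    assert detect_condition(br, active, 1)


class TestIntegrate:
    @pytest.mark.parametrize("basal,apical,context,expected", [
        (True, True, True, FiringMode.BASAL),    # apical blocked by context
        (False, True, False, FiringMode.APICAL),  # indirect activation
        (False, False, True, FiringMode.NONE),
        (False, False, False, FiringMode.NONE),
        (True, False, True, FiringMode.BASAL),
        # without sensory context the basal path carries nothing
        (True, True, False, FiringMode.APICAL),
    ])
    def test_gating_contract(self, basal, apical, context, expected):
        u = make_unit()
        mode = integrate(u, basal, apical, context, step=3)
        assert mode is expected
        assert u.fired is (expected is not FiringMode.NONE)
        if u.fired:
            assert u.fire_step == 3

    def test_only_one_compartment_ever_contributes(self, rng):
        """XOR contract: exhaustive over random detection states."""
        u = make_unit()
        for _ in range(200):
            b, a, c = (bool(rng.integers(2)) for _ in range(3))
            mode = integrate(u, b, a, c, 0)
            assert not (mode is FiringMode.BASAL and mode is FiringMode.APICAL)
            if c:
                assert mode is not FiringMode.APICAL
            else:
                assert mode is not FiringMode.BASAL


class TestDelayedUnit:
    def _unit(self, delay=2, refractory=8):
        return DelayedUnit(
            id="p3",
            basal=DendriticTree(branches=[make_branch((1.0,))], tree_threshold=1,
                                role="basal"),
            apical=DendriticTree(branches=[], tree_threshold=1, role="apical"),
            delay=delay, refractory=refractory)

    def test_emits_delay_steps_after_detection(self):
        u = self._unit(delay=3)
        u.schedule(5, trace=frozenset({"a"}))
        assert not u.emit(6)
        assert not u.emit(7)
        assert u.emit(8)
        assert u.fire_step == 8
        assert u.last_trace == frozenset({"a"})

    def test_one_shot_within_refractory(self):
        u = self._unit(delay=1, refractory=10)
        u.schedule(0)
        assert u.emit(1)
        u.schedule(2)   # ignored: refractory until 11
        assert u.pending_fire_step is None
        u.schedule(11)
        assert u.emit(12)

    def test_pending_not_rescheduled(self):
        u = self._unit(delay=4)
        u.schedule(0, trace=frozenset({"first"}))
        u.schedule(1, trace=frozenset({"second"}))
        assert u.emit(4)
        assert u.last_trace == frozenset({"first"})


def test_synapse_weight_validation():
    with pytest.raises(ValueError):
        Synapse(source="x", weight=-0.1)


def test_tree_threshold_validation():
    with pytest.raises(ValueError):
        DendriticTree(branches=[make_branch((1.0,))], tree_threshold=2, role="basal")
    with pytest.raises(ValueError):
        DendriticTree(branches=[], tree_threshold=1, role="sideways")
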