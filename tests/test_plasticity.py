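"""Gated expansion, threshold raising, pruning and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippogate import (PlasticityConfig, PlasticityFrozenError, Synapse,
                       detect_condition, expand_branch, prune_synapses,
                       raise_threshold)
from hippogate.plasticity import decay_manager_weights

from conftest import make_branch, make_unit


def _fig_branch():
    """Eight silent synapses at 0.1 plus a strong manager input."""
    return make_branch((0.1,) * 8, threshold=1.0, manager_weight=1.0,
                       manager_alone=False)


class TestExpandBranch:
    def test_recruits_a_new_condition(self):
        """The worked recruitment sequence: manager drive pushes the branch
        over threshold, the backpropagating firing strengthens the five
        recently active synapses, and afterwards those five alone detect."""
        br = _fig_branch()
        cfg = PlasticityConfig()   # delta_w 0.15
        active = {("s", i) for i in range(5)} | {("mgr", 0)}
        # (a) regular synapses alone: insufficient total weight
        assert not detect_condition(br, {("s", i) for i in range(5)}, step=0)
        # (b) manager input active: the branch detects
        assert detect_condition(br, active, step=1)
        # (c) neuron fires; recently active synapses strengthened
        report = expand_branch(br, manager_active=True,
                               neuron_fired_within_window=True, step=1, cfg=cfg)
        assert report == {("s", i): pytest.approx(0.15) for i in range(5)}
        for i in range(5):
            assert br.synapses[i].weight == pytest.approx(0.25)
        for i in range(5, 8):
            assert br.synapses[i].weight == pytest.approx(0.1)
        # (d) the recruited subset now sums to 1.25 >= 1.0: detection is
        # independent of the manager input
        assert sum(br.synapses[i].weight for i in range(5)) == pytest.approx(1.25)
        assert detect_condition(br, {("s", i) for i in range(5)}, step=2)

    def test_manager_inactive_changes_nothing(self):
        br = _fig_branch()
        detect_condition(br, {("s", i) for i in range(5)} | {("mgr", 0)}, 1)
        assert expand_branch(br, False, True, 1, PlasticityConfig()) == {}

    def test_no_firing_changes_nothing(self):
        br = _fig_branch()
        detect_condition(br, {("s", i) for i in range(5)} | {("mgr", 0)}, 1)
        assert expand_branch(br, True, False, 1, PlasticityConfig()) == {}

    def test_undetected_branch_changes_nothing(self):
        br = _fig_branch()
        detect_condition(br, {("s", 0)}, 1)   # far below threshold
        assert expand_branch(br, True, True, 1, PlasticityConfig()) == {}

    def test_frozen_plasticity_refuses(self):
        br = _fig_branch()
        cfg = PlasticityConfig(expansion_enabled=False)
        with pytest.raises(PlasticityFrozenError):
            expand_branch(br, True, True, 1, cfg)

    def test_stale_activity_outside_window_not_strengthened(self):
        br = _fig_branch()
        cfg = PlasticityConfig(recent_window=2)
        detect_condition(br, {("s", 0)}, step=0)
        detect_condition(br, {("s", i) for i in range(1, 5)} | {("mgr", 0)}, step=4)
        report = expand_branch(br, True, True, 4, cfg)
        assert ("s", 0) not in report          # active at 0, window is (2, 4]
        assert set(report) == {("s", i) for i in range(1, 5)}

    def test_eligible_sources_narrow_the_update(self):
        br = _fig_branch()
        detect_condition(br, {("s", i) for i in range(5)} | {("mgr", 0)}, 1)
        report = expand_branch(br, True, True, 1, PlasticityConfig(),
                               eligible_sources={("s", 0), ("s", 3)})
        assert set(report) == {("s", 0), ("s", 3)}

    def test_locality_other_branch_untouched(self):
        br1, br2 = _fig_branch(), _fig_branch()
        detect_condition(br1, {("s", i) for i in range(5)} | {("mgr", 0)}, 1)
        detect_condition(br2, {("s", i) for i in range(5)}, 1)
        expand_branch(br1, True, True, 1, PlasticityConfig())
        assert all(s.weight == pytest.approx(0.1) for s in br2.synapses)

    def test_double_encoding_compounds_and_clips(self):
        """Two passes equal one pass at doubled increment, clipped at w_max."""
        cfg = PlasticityConfig(delta_w=0.6)
        two_pass = _fig_branch()
        for step in (1, 2):
            detect_condition(two_pass, {("s", 0), ("s", 1), ("mgr", 0)}, step)
            expand_branch(two_pass, True, True, step, cfg)
        for i in (0, 1):
            expected = min(cfg.w_max, 0.1 + 2 * 0.6)
            assert two_pass.synapses[i].weight == pytest.approx(expected)
            assert two_pass.synapses[i].weight == pytest.approx(1.0)


@given(st.lists(st.tuples(st.integers(0, 7), st.booleans(), st.booleans()),
                min_size=1, max_size=40))
@settings(max_examples=60, deadline=None)
def test_no_weight_ever_exceeds_wmax(ops):
    """Clipping invariant under arbitrary operation sequences."""
    br = make_branch((0.9,) * 8, threshold=1.0, manager_weight=1.0)
    cfg = PlasticityConfig(delta_w=0.5)
    for step, (idx, mgr, fired) in enumerate(ops):
        active = {("s", idx)} | ({("mgr", 0)} if mgr else set())
        detect_condition(br, active, step)
        expand_branch(br, mgr, fired, step, cfg)
        assert all(s.weight <= cfg.w_max + 1e-12 for s in br.synapses)


class TestRaiseThreshold:
    def _unit(self, n_branches=6, thr=2):
        return make_unit(basal_branches=[make_branch((1.0,)) for _ in range(n_branches)],
                         basal_thr=thr)

    def test_overdetection_raises(self):
        u = self._unit()
        assert raise_threshold(u, 0.9, PlasticityConfig()) == 3

    def test_normal_rate_unchanged(self):
        u = self._unit()
        assert raise_threshold(u, 0.2, PlasticityConfig()) == 2

    def test_capped_at_branch_count(self):
        u = self._unit(n_branches=3, thr=3)
        assert raise_threshold(u, 1.0, PlasticityConfig()) == 3


class TestPruneSynapses:
    def _unit_with_history(self):
        syns = [Synapse(source=("s", 0), weight=0.5, created_step=0,
                        last_contribution_step=None),
                Synapse(source=("s", 1), weight=0.5, created_step=0,
                        last_contribution_step=90),
                Synapse(source=("s", 2), weight=0.5, created_step=95,
                        last_contribution_step=None)]
        br = make_branch((), threshold=1.0, manager_weight=1.0)
        br.synapses = syns
        return make_unit(basal_branches=[br])

    def test_never_contributing_removed(self):
        u = self._unit_with_history()
        removed = prune_synapses(u, 100, PlasticityConfig(prune_window=20))
        assert removed == [("s", 0)]

    def test_contributing_and_young_retained(self):
        u = self._unit_with_history()
        prune_synapses(u, 100, PlasticityConfig(prune_window=20))
        remaining = {s.source for s in u.basal.branches[0].synapses}
        assert remaining == {("s", 1), ("s", 2)}   # recent contributor + grace

    def test_manager_exempt(self):
        u = self._unit_with_history()
        prune_synapses(u, 100, PlasticityConfig(prune_window=20))
        assert u.basal.branches[0].manager_synapse is not None


def test_manager_decay_flag():
    br = make_branch((0.5,), threshold=1.0, manager_weight=1.0)
    u = make_unit(basal_branches=[br])
    decay_manager_weights(u, PlasticityConfig(manager_decay=0.0))
    assert br.manager_synapse.weight == 1.0
    decay_manager_weights(u, PlasticityConfig(manager_decay=0.1))
    assert br.manager_synapse.weight == pytest.approx(0.9)
    assert br.synapses[0].weight == 0.5   # regular weights untouched


def test_config_validation():
    with pytest.raises(ValueError):
        PlasticityConfig(delta_w=2.0, w_max=1.0)
    with pytest.raises(ValueError):
        PlasticityConfig(recent_window=0)
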