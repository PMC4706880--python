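import numpy as np
import pytest

from hippogate import (DendriticTree, PyramidalUnit, Synapse, TerminalBranch,
                       World, WorldConfig)


def make_branch(weights, threshold=1.0, manager_weight=None, manager_alone=True,
                prefix="s"):
    syns = [Synapse(source=(prefix, i), weight=w) for i, w in enumerate(weights)]
    mgr = Synapse(source=("mgr", 0), weight=manager_weight) \
        if manager_weight is not None else None
    return TerminalBranch(synapses=syns, branch_threshold=threshold,
                          manager_synapse=mgr, manager_alone_detects=manager_alone)


def make_unit(uid="u", basal_branches=(), apical_branches=(),
              basal_thr=1, apical_thr=1):
    return PyramidalUnit(
        id=uid,
        basal=DendriticTree(branches=list(basal_branches), tree_threshold=basal_thr,
                            role="basal"),
        apical=DendriticTree(branches=list(apical_branches), tree_threshold=apical_thr,
                             role="apical"),
    )


def random_tree(rng, max_branches=8, max_synapses=6):
    n_br = int(rng.integers(1, max_branches + 1))
    branches = []
    for b in range(n_br):
        n_syn = int(rng.integers(1, max_synapses + 1))
        syns = [Synapse(source=("r", b, i), weight=float(rng.uniform(0, 1)))
                for i in range(n_syn)]
        mgr = None
        if rng.random() < 0.3:
            mgr = Synapse(source=("rm", b), weight=float(rng.uniform(0, 1.5)))
        branches.append(TerminalBranch(
            synapses=syns, branch_threshold=float(rng.uniform(0.2, 2.0)),
            manager_synapse=mgr,
            manager_alone_detects=bool(rng.random() < 0.5)))
    thr = int(rng.integers(1, n_br + 1))
    return DendriticTree(branches=branches, tree_threshold=thr, role="basal")


def random_active_set(tree, rng):
    sources = [s.source for br in tree.branches for s in br.all_synapses()]
    if not sources:
        return set()
    k = int(rng.integers(0, len(sources) + 1))
    idx = rng.choice(len(sources), size=k, replace=False)
    return {sources[int(i)] for i in idx}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_world():
    return World(WorldConfig(rng_seed=7))
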