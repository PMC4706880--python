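"""JSON snapshots of unit and weight state.

The schema follows the circuit hierarchy: units -> trees -> branches ->
synapses, each synapse carrying its source id and weight.  Loading applies
weights and thresholds onto a structurally identical network (same world and
network configuration and seed); structure itself is regenerated from
configuration, not stored.
"""

from __future__ import annotations

import json
from typing import TextIO

from .network import Network
from .neuron import DendriticTree


def _tree_to_dict(tree: DendriticTree) -> dict:
    return {
        "role": tree.role,
        "tree_threshold": tree.tree_threshold,
        "branches": [
            {
                "branch_threshold": br.branch_threshold,
                "synapses": [{"source": repr(s.source), "weight": s.weight}
                             for s in br.synapses],
                "manager": ({"source": repr(br.manager_synapse.source),
                             "weight": br.manager_synapse.weight}
                            if br.manager_synapse else None),
            }
            for br in tree.branches
        ],
    }


def network_to_dict(net: Network) -> dict:
    units = []
    for u in net.iter_units():
        units.append({
            "id": repr(u.id),
            "basal": _tree_to_dict(u.basal),
            "apical": _tree_to_dict(u.apical),
        })
    return {"format": "hippogate-snapshot", "version": 1, "units": units}


def save_snapshot(net: Network, fh: TextIO) -> None:
    json.dump(network_to_dict(net), fh, indent=1)


def _apply_tree(tree: DendriticTree, data: dict) -> None:
    tree.tree_threshold = int(data["tree_threshold"])
    for br, bdata in zip(tree.branches, data["branches"]):
        br.branch_threshold = float(bdata["branch_threshold"])
        for syn, sdata in zip(br.synapses, bdata["synapses"]):
            if repr(syn.source) != sdata["source"]:
                raise ValueError(
                    f"snapshot structure mismatch at synapse {sdata['source']}")
            syn.weight = float(sdata["weight"])
        if br.manager_synapse is not None and bdata.get("manager"):
            br.manager_synapse.weight = float(bdata["manager"]["weight"])


def load_snapshot(net: Network, fh: TextIO) -> Network:
    """Apply a snapshot's weights onto a structurally identical network."""
    data = json.load(fh)
    if data.get("format") != "hippogate-snapshot":
        raise ValueError("not a hippogate snapshot")
    by_id = {repr(u.id): u for u in net.iter_units()}
    for udata in data["units"]:
        unit = by_id.get(udata["id"])
        if unit is None:
            raise ValueError(f"snapshot unit {udata['id']} not present in network")
        _apply_tree(unit.basal, udata["basal"])
        _apply_tree(unit.apical, udata["apical"])
    return net
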