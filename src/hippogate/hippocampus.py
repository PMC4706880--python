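"""The dentate-gyrus / CA3 novelty competition.

Rate-valued units iterate three coupled loops: CA3 recurrent excitation,
granule–mossy reciprocal excitation, and a granule-driven inhibitory path to
CA3 that predominates at high granule activity.  Familiar input (high area
detection rates, hence high entorhinal drive to every granule unit) yields an
equilibrium with zero CA3 activity; novelty depresses some granule units,
letting CA3 activity build until the mossy-cell feedback recruits enough
inhibition to stop it — so equilibrium CA3 activity grows with the degree of
novelty and the rise is self-limiting.

CA3 units correspond to groups of cortical columns that expanded their
receptive fields at the same time in the past; the equilibrium CA3 pattern,
once released, is decoded into expansion drive on the perirhinal columns
covering those groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class CA3Group:
    """One CA3 receptive field: a set of co-expanded cortical columns,
    the perirhinal columns covering them, and the areas they span."""

    group_id: int
    column_ids: frozenset
    pcol_ids: frozenset
    areas: frozenset


@dataclass
class CompetitionConfig:
    w_rec: float = 0.5        # CA3 recurrent gain (must keep the loop contractive)
    w_gc_exc: float = 0.5     # granule -> CA3 excitatory gain
    w_gc_inh: float = 2.0     # granule -> interneuron -> CA3 inhibitory gain
    inh_onset: float = 0.3    # granule level where the inhibitory path engages;
                              # set at the mossy-feedback floor so equilibrium
                              # CA3 is monotone in novelty over the whole range
    w_mossy: float = 1.0      # CA3 -> mossy feedback gain
    w_mossy_granule: float = 0.3  # mossy -> granule feedback gain
    tonic: float = 0.5        # tonic CA3 excitation disinhibited by low granule drive
    tol: float = 1e-6
    max_iter: int = 500
    activity_cap: float = 2.0
    rate_scale: float = 0.45  # detection rate treated as fully familiar
    decode_gain: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_rec, self.w_gc_exc, self.w_gc_inh, self.w_mossy,
               self.w_mossy_granule, self.tonic) < 0:
            raise ValueError("all gains must be non-negative")
        # Inhibitory dominance: saturated granule input must yield net CA3
        # suppression, otherwise familiar input cannot silence CA3.
        net_at_saturation = (self.tonic + self.w_gc_exc
                             - self.w_gc_inh * max(0.0, 1.0 - self.inh_onset))
        if net_at_saturation >= 0:
            raise ValueError(
                "inhibitory path must dominate at saturated granule activity "
                f"(net drive {net_at_saturation:+.3f} at granule=1)")


@dataclass
class HippocampusState:
    ec_input: np.ndarray
    granule: np.ndarray
    mossy: np.ndarray
    ca3: np.ndarray
    iteration: int
    converged: bool
    selection: dict = field(default_factory=dict)
    max_activity: float = 0.0

    @property
    def total_ca3(self) -> float:
        return float(self.ca3.sum())


def summarize_entorhinal(area_rates: Mapping[int, float] | Sequence[float],
                         rate_scale: float = 0.45) -> np.ndarray:
    """Map per-area detection rates to entorhinal drive.

    Monotone saturating normalisation: a rate at or above ``rate_scale``
    counts as fully familiar (drive 1).  ``rate_scale=1`` recovers the
    identity map.
    """
    if isinstance(area_rates, Mapping):
        rates = np.array([area_rates[a] for a in sorted(area_rates)], dtype=float)
    else:
        rates = np.asarray(area_rates, dtype=float)
    if rates.size and (rates.min() < 0 or rates.max() > 1):
        raise ValueError("detection rates must lie in [0, 1]")
    return np.clip(rates / rate_scale, 0.0, 1.0)


def run_competition(ec_input: np.ndarray, cfg: CompetitionConfig,
                    groups: Optional[Sequence[CA3Group]] = None) -> HippocampusState:
    """Iterate the granule/mossy/CA3 loop to equilibrium.

    One granule and one mossy unit per area (default granule fan-in), one CA3
    unit per column group (one per area when no groups are given).  Returns
    the state with ``converged`` False and a warning — never an exception —
    if the iteration cap is hit.
    """
    ec = np.clip(np.asarray(ec_input, dtype=float), 0.0, 1.0)
    n_areas = ec.size
    if groups is None:
        groups = [CA3Group(a, frozenset(), frozenset(), frozenset([a]))
                  for a in range(n_areas)]
    # membership matrix: groups x areas
    member = np.zeros((len(groups), n_areas))
    for i, grp in enumerate(groups):
        for a in grp.areas:
            if a < n_areas:
                member[i, a] = 1.0
    fan = member.sum(axis=1)
    fan[fan == 0] = 1.0

    granule = ec.copy()
    mossy = np.zeros(n_areas)
    ca3 = np.zeros(len(groups))
    converged = False
    max_activity = 0.0
    it = 0
    for it in range(1, cfg.max_iter + 1):
        granule = np.clip(ec + cfg.w_mossy_granule * mossy, 0.0, 1.0)
        net_area = (cfg.w_gc_exc * granule
                    - cfg.w_gc_inh * np.maximum(0.0, granule - cfg.inh_onset))
        drive = cfg.tonic + (member @ net_area) / fan
        new_ca3 = np.clip(cfg.w_rec * ca3 + drive, 0.0, cfg.activity_cap)
        # per-area mossy drive = mean CA3 of the groups spanning the area
        cols = member.sum(axis=0)
        cols[cols == 0] = 1.0
        new_mossy = np.clip(cfg.w_mossy * (member.T @ new_ca3) / cols, 0.0, 1.0)
        delta = max(np.abs(new_ca3 - ca3).max(initial=0.0),
                    np.abs(new_mossy - mossy).max(initial=0.0))
        ca3, mossy = new_ca3, new_mossy
        if ca3.size:
            max_activity = max(max_activity, float(ca3.max()))
        if delta < cfg.tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"competition did not converge in {cfg.max_iter} iterations",
                      RuntimeWarning, stacklevel=2)
    selection: dict = {}
    for i, grp in enumerate(groups):
        for pid in grp.pcol_ids:
            selection[pid] = selection.get(pid, 0.0) + float(ca3[i])
    return HippocampusState(ec_input=ec, granule=granule, mossy=mossy, ca3=ca3,
                            iteration=it, converged=converged, selection=selection,
                            max_activity=max_activity)


def release_and_decode(state: HippocampusState, pcols: Sequence,
                       cfg: CompetitionConfig) -> dict:
    """Decode the equilibrium CA3 pattern into per-perirhinal-column P2 drive.

    Release is gated on convergence (the septal release abstraction): an
    unconverged state yields zero drive everywhere.  Drive is the summed
    equilibrium activity of the CA3 groups covering the column, scaled by the
    column's own intermediate-layer activity (the internal-activity criterion
    for selecting low-risk expansion targets).
    """
    drive: dict = {}
    for pcol in pcols:
        if not state.converged:
            drive[pcol.id] = 0.0
            continue
        base = state.selection.get(pcol.id, 0.0)
        match = getattr(pcol, "last_match", 1.0)
        drive[pcol.id] = cfg.decode_gain * base * match
    return drive


def update_groups(groups: Sequence[CA3Group], expanded_by_context: Mapping[int, set],
                  pcol_of_column: Mapping, area_of_column: Mapping) -> list[CA3Group]:
    """Set-union update of group membership after an expansion episode:
    columns that expanded together join (or refresh) their context's group."""
    out = []
    for grp in groups:
        cols = set(grp.column_ids)
        newly = expanded_by_context.get(grp.group_id, set())
        cols |= newly
        pcols = set(grp.pcol_ids)
        areas = set(grp.areas)
        for c in newly:
            pcols |= set(pcol_of_column.get(c, ()))
            areas.add(area_of_column[c])
        out.append(CA3Group(grp.group_id, frozenset(cols), frozenset(pcols),
                            frozenset(areas)))
    return out
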