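"""Presentation-cycle orchestration, run modes, logging and metrics.

Each presentation executes a fixed, documented order:

1. step every cortical column bottom-up on the stimulus;
2. perirhinal sense phase (intermediate units, P1) for every perirhinal column;
3. summarise per-area detection rates to entorhinal drive;
4. run the DG/CA3 competition to equilibrium;
5. release-and-decode the equilibrium into per-column P2 drive
   (withheld entirely if the competition did not converge);
6. perirhinal drive phase (P2 gate, P3 scheduling/emission);
7. apply gated plasticity if the run mode permits (familiarize/encode);
8. log the presentation row and any weight changes.

Evaluation is single-threaded and deterministic: identical configuration and
seed reproduce byte-identical metric CSVs.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import perirhinal as perimod
from .column import area_detection_rate, step_column
from .hippocampus import (CompetitionConfig, release_and_decode, run_competition,
                          summarize_entorhinal)
from .network import Network, NetworkConfig, build_network
from .neuron import FiringMode, detect_field
from .perirhinal import EpisodeTrace, reset_dynamic_state, retrieve
from .plasticity import PlasticityConfig, expand_branch
from .stimuli import Stimulus, World, WorldConfig, generate_stream

MODES = ("familiarize", "encode", "retrieve", "experiment")


@dataclass
class RunConfig:
    world: WorldConfig = field(default_factory=WorldConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)
    episodic: PlasticityConfig = field(default_factory=lambda: PlasticityConfig(
        delta_w=0.5, recent_window=1))
    competition: CompetitionConfig = field(default_factory=CompetitionConfig)
    mode: str = "familiarize"
    out_dir: str = "runs"
    log_level: str = "INFO"
    rng_seed: int = 0
    trained: bool = False
    familiarize_presentations: int = 12
    steps_per_moment: int = 3
    retrieval_steps: int = 20
    retrieval_refractory: int = 8
    encode_tail_steps: int = 9   # last moment persists while pending P3 discharges complete
    cue_fraction: float = 0.3
    recall_target: float = 0.8
    threshold_adaptation: bool = False   # apply raise_threshold in the cycle
    pruning: bool = False                # apply prune_synapses in the cycle
    expansion_hold_steps: int = 4        # sustained expansion period after P2 onset (encode)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                    "world", "network", "plasticity", "episodic", "competition"):
                sub = {"world": WorldConfig, "network": NetworkConfig,
                       "plasticity": PlasticityConfig, "episodic": PlasticityConfig,
                       "competition": CompetitionConfig}[f.name]
                kwargs[f.name] = sub(**val)
            else:
                kwargs[f.name] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class Simulation:
    """One network plus its run state and logs."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        world_cfg = dataclasses.replace(cfg.world, rng_seed=cfg.rng_seed)
        self.world = World(world_cfg)
        self.net_rng = np.random.default_rng(cfg.rng_seed + 10)
        self.stream_rng = np.random.default_rng(cfg.rng_seed + 1)
        self.net: Network = build_network(self.world, cfg.network, self.net_rng,
                                          trained=cfg.trained)
        self.t = 0
        self.rows: list[dict] = []
        self.weight_log: list[dict] = []
        self.activity: list[dict] = []
        self.xor_violations = 0
        self._last_p3_fired: frozenset = frozenset()
        self._deep_onset: dict = {}
        self._prev_deep_fired: frozenset = frozenset()
        self._detect_hist: dict = {}
        self._tag_floor = 0   # step at which the current stimulus/moment began
        self.expanded_by_context: dict[int, set] = {}

    # ------------------------------------------------------------------ cycle

    def run_presentation_cycle(self, stim: Stimulus, mode: Optional[str] = None) -> dict:
        mode = mode or self.cfg.mode
        t = self.t
        try:
            return self._cycle(stim, mode, t)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"presentation {t} failed: {exc}") from exc

    def _cycle(self, stim: Stimulus, mode: str, t: int) -> dict:
        net, cfg = self.net, self.cfg
        ext = frozenset(("EXT", f) for f in stim.active)

        statuses = {}
        for col in net.columns:
            statuses[col.id] = step_column(
                col, ext, t, apical_active=self._last_p3_fired,
                candidacy_floor=cfg.network.candidacy_floor)

        pcol_inputs = {}
        for pcol in net.pcols:
            l23 = frozenset().union(*(statuses[c].layer23_fired
                                      for c in pcol.member_columns))
            deep = frozenset().union(*(statuses[c].deep_fired
                                       for c in pcol.member_columns))
            pcol_inputs[pcol.id] = (l23, deep)
            perimod.sense_phase(pcol, t, l23)

        rates = area_detection_rate(net.columns, statuses)
        ec = summarize_entorhinal(rates, cfg.competition.rate_scale)
        state = run_competition(ec, cfg.competition, net.groups)
        drives = release_and_decode(state, net.pcols, cfg.competition)

        # onset tracking: the synaptic tag binds the units whose firing began
        # since the current stimulus appeared (change-detection onsets), not
        # activity carried over from earlier moments
        deep_fired_now = frozenset().union(*(s.deep_fired for s in statuses.values()))
        for uid in deep_fired_now - self._prev_deep_fired:
            self._deep_onset[uid] = t
        floor = self._tag_floor
        recent_onset = {uid for uid, step0 in self._deep_onset.items()
                        if step0 >= floor}

        p3_fired_all = set()
        for pcol in net.pcols:
            _, deep = pcol_inputs[pcol.id]
            rec = perimod.drive_phase(pcol, t, drives[pcol.id], deep,
                                      member_deep_onset=deep & recent_onset)
            p3_fired_all |= rec["p3_fired"]
            if mode == "encode":
                if rec["p2_gated_in"]:
                    pcol.expansion_hold = cfg.expansion_hold_steps
                else:
                    pcol.expansion_hold = max(0, pcol.expansion_hold - 1)
            else:
                pcol.expansion_hold = 0

        n_driven = 0
        n_driven_candidates = 0
        expanded_cols: set = set()
        changes_total = 0.0
        if mode in ("familiarize", "encode") and cfg.plasticity.expansion_enabled:
            driven, driven_cand, expanded_cols, changes_total = self._apply_expansion(
                statuses, t)
            n_driven, n_driven_candidates = len(driven), len(driven_cand)
            if mode == "encode":
                changes_total += self._record_episode_step(statuses, p3_fired_all, t)
            for cid in expanded_cols:
                g = net.col_by_id[cid].context_group
                self.expanded_by_context.setdefault(g, set()).add(cid)
            self._apply_maintenance(t)

        final_deep = frozenset(uid for uid, u in net.deep_units.items() if u.fired)
        for uid in final_deep - deep_fired_now:
            if uid not in self._prev_deep_fired:
                self._deep_onset[uid] = t
        self._prev_deep_fired = final_deep

        self._log_activity(t)
        self._count_xor(t)
        self._last_p3_fired = frozenset(p3_fired_all)

        row = {
            "step": t,
            "mode": mode,
            "context": stim.context,
            "novelty": stim.novelty_label,
            "total_ca3": state.total_ca3,
            "converged": int(state.converged),
            "iterations": state.iteration,
            "mean_rate": float(np.mean(list(rates.values()))),
            "n_candidates": sum(int(s.candidate) for s in statuses.values()),
            "n_output": sum(int(s.output_active) for s in statuses.values()),
            "n_driven": n_driven,
            "n_driven_candidates": n_driven_candidates,
            "n_expanded": len(expanded_cols),
            "p1_fired": sum(int(p.last_p1_active) for p in net.pcols),
            "p2_fired": sum(int(p.last_p2_active) for p in net.pcols),
            "p3_fired": len(p3_fired_all),
            "weight_change": changes_total,
        }
        self.rows.append(row)
        self.t += 1
        self._statuses = statuses
        return row

    # --------------------------------------------------------- plasticity

    def _apply_expansion(self, statuses, t):
        """Manager-gated basal expansion in driven cortical columns and the
        P1 fields of driven perirhinal columns."""
        net, pcfg = self.net, self.cfg.plasticity
        driven: set = set()
        driven_cand: set = set()
        expanded: set = set()
        total = 0.0
        for pcol in net.pcols:
            if not pcol.last_p2_active:
                continue
            for cid in sorted(pcol.member_columns):
                st = statuses[cid]
                if st.output_active:
                    continue  # interneuron gate: producing columns get no drive
                col = net.col_by_id[cid]
                active = st.layer23_fired | {("MGR", cid)}
                branch_detections = 0
                for u in col.deep:
                    det, cnt = detect_field(u.basal, active, t)
                    u.last_basal_detected, u.last_basal_count = det, cnt
                    branch_detections += cnt
                    if not det:
                        continue
                    u.fired = True
                    u.last_mode = FiringMode.BASAL
                    u.fire_step = t
                    for bi, br in enumerate(u.basal.branches):
                        if br.last_detected_step != t:
                            continue
                        rep = expand_branch(br, True, True, t, pcfg)
                        total += self._log_changes(u.id, bi, rep, t)
                        if rep:
                            expanded.add(cid)
                # "above-threshold drive": the manager input crossed at least
                # one dendritic branch threshold in this column
                if branch_detections and cid not in driven:
                    driven.add(cid)
                    if st.candidate:
                        driven_cand.add(cid)
            # P1 receptive field expands alongside the member columns
            active1 = pcol.last_int_fired | {pcol.manager_token()}
            for u in pcol.P1:
                det, cnt = detect_field(u.basal, active1, t)
                u.last_basal_detected, u.last_basal_count = det, cnt
                if not det:
                    continue
                u.fired = True
                u.last_mode = FiringMode.BASAL
                for bi, br in enumerate(u.basal.branches):
                    if br.last_detected_step == t:
                        rep = expand_branch(br, True, True, t, pcfg)
                        total += self._log_changes(u.id, bi, rep, t)
        return driven, driven_cand, expanded, total

    def _apply_maintenance(self, t) -> None:
        """Optional change-constraint maintenance, applied prune-first then
        threshold-raise once per prune window (both off by default)."""
        cfg = self.cfg
        if not (cfg.pruning or cfg.threshold_adaptation):
            return
        window = cfg.plasticity.prune_window
        for uid, u in self.net.deep_units.items():
            hist = self._detect_hist.setdefault(uid, [])
            hist.append(int(u.last_basal_detected))
            if len(hist) > window:
                hist.pop(0)
            if (t + 1) % window:
                continue
            if cfg.pruning:
                from .plasticity import prune_synapses

                prune_synapses(u, t, cfg.plasticity)
            if cfg.threshold_adaptation and len(hist) == window:
                from .plasticity import raise_threshold

                raise_threshold(u, sum(hist) / window, cfg.plasticity)

    def _record_episode_step(self, statuses, p3_fired_all, t) -> float:
        """Episodic recording: P3 basal traces of the deep pattern, and deep
        apical traces of the active P3 units (detections are recorded on the
        gated apical branches and consolidated by the backpropagating firing
        of the basally driven unit)."""
        net, ecfg = self.net, self.cfg.episodic
        total = 0.0
        for pcol in net.pcols:
            if not pcol.last_p2_active:
                continue
            rep = perimod.record_episode(pcol, t, ecfg)
            for (uid, bi, src), dw in rep.items():
                total += self._log_changes(uid, bi, {src: dw}, t)
        driven_cols = {cid for pcol in net.pcols if pcol.last_p2_active
                       for cid in pcol.member_columns}
        for cid in sorted(driven_cols):
            col = net.col_by_id[cid]
            sources = frozenset(p3_fired_all) | {("MGRA", cid)}
            for u in col.deep:
                if not u.fired:
                    continue
                detect_field(u.apical, sources, t)
                for bi, br in enumerate(u.apical.branches):
                    if br.last_detected_step == t:
                        rep = expand_branch(br, True, True, t, ecfg)
                        total += self._log_changes(u.id, bi, rep, t)
        return total

    def _log_changes(self, uid, branch_index, report: dict, t) -> float:
        total = 0.0
        for src, dw in sorted(report.items(), key=repr):
            self.weight_log.append({
                "step": t, "unit_id": repr(uid), "branch_index": branch_index,
                "synapse_source": repr(src), "delta": dw})
            total += abs(dw)
        return total

    # ------------------------------------------------------------- logging

    def _log_activity(self, t) -> None:
        for u in self.net.iter_units():
            if u.fired:
                self.activity.append({"step": t, "unit_id": repr(u.id),
                                      "fired": 1, "mode": u.last_mode.value})

    def _count_xor(self, t) -> None:
        """Exhaustive per-step check of the one-compartment-fires contract."""
        for u in self.net.iter_units():
            if u.last_mode is FiringMode.APICAL and u.apical_gate_closed:
                self.xor_violations += 1
            if u.last_mode is FiringMode.BASAL and not u.last_basal_detected:
                # manager-assisted firing re-detects the tree, so this should
                # never trigger either
                if u.last_basal_count == 0:
                    self.xor_violations += 1

    # ----------------------------------------------------------- run modes

    def run_stream(self, stims: Sequence[Stimulus], mode: Optional[str] = None) -> list[dict]:
        return [self.run_presentation_cycle(s, mode=mode) for s in stims]

    def familiarize(self, context: int = 0, n_presentations: Optional[int] = None) -> list[dict]:
        n = n_presentations or self.cfg.familiarize_presentations
        stream = generate_stream(self.world, [
            {"context": context, "novelty_fraction": 0.0, "n_presentations": n}],
            rng=self.stream_rng)
        return self.run_stream(stream, mode="familiarize")

    def encode_event(self, moments: Sequence[Stimulus]) -> EpisodeTrace:
        trace = EpisodeTrace(episode_id=moments[0].event_id or 0)
        for moment in moments:
            self._tag_floor = self.t   # new stimulus: fresh onsets from here
            fired: set = set()
            for _ in range(self.cfg.steps_per_moment):
                self.run_presentation_cycle(moment, mode="encode")
                fired |= {u.id for u in self.net.deep_units.values() if u.fired}
            trace.add_moment(fired)
        # consolidation tail: the final moment's input persists while the
        # remaining late-spiking P3 discharges arrive and are recorded
        for _ in range(self.cfg.encode_tail_steps):
            self.run_presentation_cycle(moments[-1], mode="encode")
        return trace

    def retrieve_episode(self, cue: Iterable, max_steps: Optional[int] = None
                         ) -> tuple[dict, float]:
        """Cued retrieval with plasticity frozen; returns (timeline,
        total |weight change| observed across the run — must be 0)."""
        max_steps = max_steps or self.cfg.retrieval_steps
        frozen = dataclasses.replace(self.cfg.episodic, expansion_enabled=False)
        reset_dynamic_state(self.net.pcols, refractory=self.cfg.retrieval_refractory)
        for u in self.net.deep_units.values():
            u.fired = False
            u.last_mode = FiringMode.NONE
        w_before = self.net.total_weight()
        timeline = retrieve(self.net.pcols, cue, max_steps, self.net.deep_units,
                            frozen)
        purity = abs(self.net.total_weight() - w_before)
        return timeline, purity

    # ------------------------------------------------------------- metrics

    @staticmethod
    def recall_fraction(trace: EpisodeTrace, timeline: dict) -> float:
        full = trace.full_set
        if not full:
            return 0.0
        recalled = set().union(*timeline.values()) if timeline else set()
        return len(recalled & full) / len(full)

    @staticmethod
    def order_correlation(trace: EpisodeTrace, timeline: dict) -> float:
        """Spearman rank correlation between encoded moment order and each
        moment's reactivation time.

        A moment's reactivation time is the interquartile mean of the first-
        reactivation steps of its newly introduced units: recall arrives in
        bursts, and the interquartile mean locates the burst while staying
        insensitive to isolated early leaks or late second-wave stragglers.
        """
        from scipy.stats import spearmanr, trim_mean

        first_seen: dict = {}
        for step in sorted(timeline):
            for uid in timeline[step]:
                first_seen.setdefault(uid, step)
        times = []
        for fresh in trace.new_units_per_moment():
            steps = [first_seen[u] for u in fresh if u in first_seen]
            if steps:
                times.append(float(trim_mean(steps, 0.25)))
        if len(times) < 2:
            return float("nan")
        rho, _ = spearmanr(range(len(times)), times)
        return float(rho)

    # ----------------------------------------------------------------- I/O

    def write_outputs(self, out_dir: str) -> dict:
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        frames = {
            "run_log.csv": pd.DataFrame(self.rows),
            "weight_changes.csv": pd.DataFrame(
                self.weight_log,
                columns=["step", "unit_id", "branch_index", "synapse_source", "delta"]),
            "activity.csv": pd.DataFrame(
                self.activity, columns=["step", "unit_id", "fired", "mode"]),
        }
        for name, df in frames.items():
            path = os.path.join(out_dir, name)
            df.to_csv(path, index=False, float_format="%.6g")
            paths[name] = path
        return paths
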