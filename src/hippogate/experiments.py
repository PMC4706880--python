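"""Prediction experiments: seeded schedules that turn the model's falsifiable
claims into automated pass/fail assertions.

Every experiment builds fresh simulations from derived seeds, runs a fixed
stimulus schedule, computes one named property, and reports the metric
distribution together with the verdict.  Observation blocks run with
plasticity disengaged (mode ``experiment``) so the measured quantity is not
contaminated by the measurement.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional

import numpy as np
from scipy.stats import binomtest

from .engine import RunConfig, Simulation
from .hippocampus import run_competition
from .stimuli import generate_event, generate_stream

NOVELTY_GRID = (0.25, 0.5, 0.75, 1.0)


def _derive_seed(base: int, k: int) -> int:
    return int((base * 1_000_003 + k * 7919) % (2**31 - 1))


def _sim(cfg: RunConfig, seed: int, trained: bool, mode: str = "familiarize") -> Simulation:
    sub = dataclasses.replace(cfg, rng_seed=seed, trained=trained, mode=mode)
    return Simulation(sub)


def _block(world, rng, context: int, nu: float, n: int):
    return generate_stream(world, [
        {"context": context, "novelty_fraction": nu, "n_presentations": n}], rng=rng)


# --------------------------------------------------------------- experiments

def zero_novelty_null(cfg: RunConfig, n_seeds: int = 10, seed: int = 0,
                      block_len: int = 50) -> dict:
    """After familiarization, a familiar block must show equilibrium CA3
    activity of exactly zero and no weight change on any presentation."""
    max_ca3, max_dw, per_seed = 0.0, 0.0, []
    for k in range(n_seeds):
        sim = _sim(cfg, _derive_seed(seed, k), trained=False, mode="familiarize")
        sim.familiarize(context=0)
        stream = _block(sim.world, sim.stream_rng, 0, 0.0, block_len)
        rows = sim.run_stream(stream, mode="familiarize")
        ca3 = max(r["total_ca3"] for r in rows)
        dw = sum(r["weight_change"] for r in rows)
        per_seed.append({"max_ca3": ca3, "weight_change": dw})
        max_ca3, max_dw = max(max_ca3, ca3), max(max_dw, dw)
    return {"name": "zero_novelty_null", "passed": max_ca3 == 0.0 and max_dw == 0.0,
            "max_ca3": max_ca3, "max_weight_change": max_dw,
            "n_presentations": block_len, "per_seed": per_seed}


def novelty_monotonicity(cfg: RunConfig, n_seeds: int = 10, seed: int = 0,
                         block_len: int = 5) -> dict:
    """Mean equilibrium CA3 activity must rise strictly with the novelty
    fraction of the stimulus block."""
    grid = NOVELTY_GRID
    means = {nu: [] for nu in grid}
    for k in range(n_seeds):
        sim = _sim(cfg, _derive_seed(seed, k), trained=True, mode="experiment")
        for nu in grid:
            stream = _block(sim.world, sim.stream_rng, 0, nu, block_len)
            rows = sim.run_stream(stream, mode="experiment")
            means[nu].append(float(np.mean([r["total_ca3"] for r in rows])))
    grand = [float(np.mean(means[nu])) for nu in grid]
    increasing = all(b > a for a, b in zip(grand, grand[1:]))
    return {"name": "novelty_monotonicity", "passed": increasing,
            "novelty_grid": list(grid), "mean_ca3": grand, "per_seed": means}


def competition_boundedness(cfg: RunConfig, n_inputs: int = 1000, seed: int = 0) -> dict:
    """CA3 activity must stay at or below the saturation cap at every
    iteration for arbitrary entorhinal input."""
    rng = np.random.default_rng(_derive_seed(seed, 99))
    cap = cfg.competition.activity_cap
    worst = 0.0
    for _ in range(n_inputs):
        ec = rng.uniform(0.0, 1.0, size=cfg.network.n_areas)
        state = run_competition(ec, cfg.competition)
        worst = max(worst, state.max_activity)
    return {"name": "competition_boundedness", "passed": worst <= cap + 1e-12,
            "max_activity": worst, "activity_cap": cap, "n_inputs": n_inputs}


def candidacy_targeting(cfg: RunConfig, n_seeds: int = 10, seed: int = 0,
                        block_len: int = 8, novelty: float = 0.25) -> dict:
    """Columns receiving above-threshold expansion drive must almost always
    be candidates (strong internal activity, no output) at selection time."""
    driven = 0
    driven_candidates = 0
    for k in range(n_seeds):
        sim = _sim(cfg, _derive_seed(seed, k), trained=True, mode="familiarize")
        stream = _block(sim.world, sim.stream_rng, 0, novelty, block_len)
        rows = sim.run_stream(stream, mode="familiarize")
        driven += sum(r["n_driven"] for r in rows)
        driven_candidates += sum(r["n_driven_candidates"] for r in rows)
    precision = driven_candidates / driven if driven else float("nan")
    return {"name": "candidacy_targeting",
            "passed": bool(driven) and precision >= 0.9,
            "precision": precision, "n_driven": driven, "novelty": novelty}


def _episode_run(cfg: RunConfig, seed: int) -> dict:
    sim = _sim(cfg, seed, trained=True, mode="encode")
    event = generate_event(sim.world, context=0, event_id=1, rng=sim.stream_rng)
    trace = sim.encode_event(event)
    rng = np.random.default_rng(seed + 5)
    moment1 = sorted(trace.moments[0], key=repr)
    if not moment1:
        # encoding produced no first-moment activity: nothing to cue
        return {"recall_fraction": 0.0, "order_correlation": float("nan"),
                "purity": 0.0, "weight_rows_added": 0,
                "episode_size": len(trace.full_set), "xor_violations": sim.xor_violations}
    n_cue = max(1, round(cfg.cue_fraction * len(moment1)))
    cue = [moment1[int(i)] for i in rng.choice(len(moment1), size=n_cue, replace=False)]
    n_weight_rows = len(sim.weight_log)
    timeline, purity = sim.retrieve_episode(cue)
    xor = sim.xor_violations
    for u in sim.net.deep_units.values():
        if u.last_mode.value == "apical" and u.apical_gate_closed:
            xor += 1
    return {
        "recall_fraction": Simulation.recall_fraction(trace, timeline),
        "order_correlation": Simulation.order_correlation(trace, timeline),
        "purity": purity,
        "weight_rows_added": len(sim.weight_log) - n_weight_rows,
        "episode_size": len(trace.full_set),
        "xor_violations": xor,
    }


def recall_completion(cfg: RunConfig, n_seeds: int = 10, seed: int = 0) -> dict:
    """A 30% cue of the first moment must reactivate at least the recall
    target of the whole episode deep-set in nearly every seed."""
    fracs = [_episode_run(cfg, _derive_seed(seed, k))["recall_fraction"]
             for k in range(n_seeds)]
    hits = sum(f >= cfg.recall_target for f in fracs)
    return {"name": "recall_completion", "passed": hits >= max(1, int(0.8 * n_seeds)),
            "recall_fractions": fracs, "hits": hits, "target": cfg.recall_target}


def recall_order(cfg: RunConfig, n_seeds: int = 10, seed: int = 0) -> dict:
    """Recalled moment order must match encoded order exactly."""
    rhos = [_episode_run(cfg, _derive_seed(seed, k))["order_correlation"]
            for k in range(n_seeds)]
    ok = all(r >= 1.0 - 1e-9 for r in rhos)   # spearmanr returns 1.0 up to rounding
    return {"name": "recall_order", "passed": ok, "order_correlations": rhos}


def retrieval_purity(cfg: RunConfig, n_seeds: int = 10, seed: int = 0) -> dict:
    """Total |weight change| during every retrieval run must be exactly 0."""
    res = [_episode_run(cfg, _derive_seed(seed, k)) for k in range(n_seeds)]
    total = sum(r["purity"] for r in res)
    rows = sum(r["weight_rows_added"] for r in res)
    return {"name": "retrieval_purity", "passed": total == 0.0 and rows == 0,
            "total_weight_change": total, "log_rows_during_retrieval": rows}


def gating_xor(cfg: RunConfig, n_seeds: int = 3, seed: int = 0) -> dict:
    """No unit-step may have both compartments contributing to firing."""
    violations = 0
    checked = 0
    for k in range(n_seeds):
        s = _derive_seed(seed, k)
        sim = _sim(cfg, s, trained=False, mode="familiarize")
        sim.familiarize(context=0)
        stream = _block(sim.world, sim.stream_rng, 0, 0.5, 10)
        sim.run_stream(stream, mode="familiarize")
        violations += sim.xor_violations
        checked += sim.t
        res = _episode_run(cfg, s)
        violations += res["xor_violations"]
    return {"name": "gating_xor", "passed": violations == 0,
            "violations": violations, "presentations_checked": checked}


def novelty_p2(cfg: RunConfig, n_seeds: int = 10, seed: int = 0,
               block_len: int = 15, novelty: float = 0.5) -> dict:
    """P2 (burst) firing must be higher in novel blocks than in familiarized
    blocks in nearly every seed (sign test)."""
    wins = 0
    pairs = []
    for k in range(n_seeds):
        sim = _sim(cfg, _derive_seed(seed, k), trained=False, mode="familiarize")
        sim.familiarize(context=0)
        fam = sim.run_stream(_block(sim.world, sim.stream_rng, 0, 0.0, block_len),
                             mode="experiment")
        nov = sim.run_stream(_block(sim.world, sim.stream_rng, 0, novelty, block_len),
                             mode="experiment")
        fam_rate = float(np.mean([r["p2_fired"] for r in fam]))
        nov_rate = float(np.mean([r["p2_fired"] for r in nov]))
        pairs.append((fam_rate, nov_rate))
        wins += int(nov_rate > fam_rate)
    pval = float(binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue)
    return {"name": "novelty_p2", "passed": wins >= int(0.9 * n_seeds) and pval < 0.05,
            "wins": wins, "n_seeds": n_seeds, "p_value": pval, "rates": pairs}


REGISTRY: dict[str, Callable] = {
    "zero_novelty_null": zero_novelty_null,
    "novelty_monotonicity": novelty_monotonicity,
    "competition_boundedness": competition_boundedness,
    "candidacy_targeting": candidacy_targeting,
    "recall_completion": recall_completion,
    "recall_order": recall_order,
    "retrieval_purity": retrieval_purity,
    "gating_xor": gating_xor,
    "novelty_p2": novelty_p2,
}


def run_experiment(name: str, cfg: Optional[RunConfig] = None, **kwargs) -> dict:
    """Run one named prediction experiment; unknown names return the menu."""
    if name not in REGISTRY:
        return {"name": name, "passed": None,
                "error": f"unknown experiment {name!r}",
                "options": sorted(REGISTRY)}
    cfg = cfg or RunConfig()
    return REGISTRY[name](cfg, **kwargs)
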