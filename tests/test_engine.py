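"""Presentation-cycle orchestration, run modes, logging, reproducibility."""

import dataclasses
import filecmp
import warnings

import numpy as np
import pytest

from hippogate import RunConfig, Simulation, run_experiment
from hippogate.stimuli import generate_event, generate_stream


def _sim(seed=3, trained=False, mode="familiarize", **kw):
    cfg = dataclasses.replace(RunConfig(**kw), rng_seed=seed, trained=trained,
                              mode=mode)
    return Simulation(cfg)


def _block(sim, nu, n, context=0):
    return generate_stream(sim.world, [
        {"context": context, "novelty_fraction": nu, "n_presentations": n}],
        rng=sim.stream_rng)


class TestPresentationCycle:
    def test_familiar_after_familiarization_is_quiescent(self):
        sim = _sim()
        sim.familiarize(context=0)
        rows = sim.run_stream(_block(sim, 0.0, 5), mode="familiarize")
        for row in rows:
            assert row["total_ca3"] == 0.0
            assert row["n_expanded"] == 0
            assert row["weight_change"] == 0.0

    def test_novel_input_drives_ca3_and_expansion(self):
        sim = _sim()
        sim.familiarize(context=0)
        rows = sim.run_stream(_block(sim, 0.5, 5), mode="familiarize")
        assert any(r["total_ca3"] > 0 for r in rows)
        assert any(r["n_expanded"] > 0 for r in rows)

    def test_competition_always_converges_in_the_cycle(self):
        sim = _sim()
        rows = sim.familiarize(context=0)
        assert all(r["converged"] == 1 for r in rows)

    def test_observation_mode_moves_no_weight(self):
        sim = _sim(trained=True, mode="experiment")
        rows = sim.run_stream(_block(sim, 0.5, 5), mode="experiment")
        assert all(r["weight_change"] == 0.0 for r in rows)
        assert not sim.weight_log

    def test_errors_carry_presentation_index(self):
        sim = _sim()
        sim.net.groups = 123   # force a failure inside the cycle
        stim = _block(sim, 0.0, 1)[0]
        with pytest.raises(RuntimeError, match="presentation 0"):
            sim.run_presentation_cycle(stim)


class TestReproducibility:
    def test_identical_seed_gives_byte_identical_csvs(self, tmp_path):
        outs = []
        for sub in ("a", "b"):
            sim = _sim(seed=9)
            sim.familiarize(context=0)
            sim.run_stream(_block(sim, 0.4, 5), mode="familiarize")
            paths = sim.write_outputs(str(tmp_path / sub))
            outs.append(paths)
        for name in outs[0]:
            assert filecmp.cmp(outs[0][name], outs[1][name], shallow=False)

    def test_logging_completeness(self):
        """Every weight change in the run appears in exactly one log row."""
        sim = _sim(seed=5)
        sim.familiarize(context=0)
        sim.run_stream(_block(sim, 0.5, 5), mode="familiarize")
        total_rows = sum(abs(r["delta"]) for r in sim.weight_log)
        total_cycle = sum(r["weight_change"] for r in sim.rows)
        assert total_rows == pytest.approx(total_cycle)
        assert total_rows > 0


class TestEpisodes:
    def test_encode_then_retrieve_round_trip(self):
        sim = _sim(seed=21, trained=True, mode="encode")
        event = generate_event(sim.world, context=0, event_id=1,
                               rng=sim.stream_rng)
        trace = sim.encode_event(event)
        assert len(trace.moments) == 3
        assert trace.full_set
        cue = sorted(trace.moments[0], key=repr)[:6]
        timeline, purity = sim.retrieve_episode(cue)
        assert purity == 0.0
        recalled = set().union(*timeline.values())
        assert recalled >= set(cue)

    def test_retrieval_leaves_plasticity_enabled_afterwards(self):
        sim = _sim(seed=21, trained=True, mode="encode")
        event = generate_event(sim.world, context=0, rng=sim.stream_rng)
        trace = sim.encode_event(event)
        sim.retrieve_episode(sorted(trace.moments[0], key=repr)[:6])
        assert sim.cfg.plasticity.expansion_enabled
        assert sim.cfg.episodic.expansion_enabled


class TestMaintenanceFlags:
    def test_pruning_flag_removes_idle_synapses(self):
        sim = _sim(seed=6, pruning=True,
                   plasticity=__import__("hippogate").PlasticityConfig(prune_window=5))
        n_before = sum(len(br.synapses)
                       for u in sim.net.deep_units.values()
                       for br in u.basal.branches)
        sim.familiarize(context=0, n_presentations=12)
        n_after = sum(len(br.synapses)
                      for u in sim.net.deep_units.values()
                      for br in u.basal.branches)
        assert n_after < n_before   # never-contributing inputs eliminated

    def test_threshold_adaptation_flag_raises_overdetecting_fields(self):
        sim = _sim(seed=6, threshold_adaptation=True,
                   plasticity=__import__("hippogate").PlasticityConfig(prune_window=5))
        sim.familiarize(context=0, n_presentations=12)
        thresholds = [u.basal.tree_threshold for u in sim.net.deep_units.values()]
        assert max(thresholds) > 1   # constantly detecting fields were raised


class TestRunExperiment:
    def test_unknown_name_lists_options(self):
        report = run_experiment("does_not_exist")
        assert report["passed"] is None
        assert "zero_novelty_null" in report["options"]
        assert "recall_completion" in report["options"]

    def test_boundedness_experiment_smoke(self):
        report = run_experiment("competition_boundedness", RunConfig(),
                                n_inputs=50, seed=2)
        assert report["passed"]


class TestRunConfig:
    def test_mode_validated(self):
        with pytest.raises(ValueError):
            RunConfig(mode="replay")

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = RunConfig(rng_seed=7)
        path = tmp_path / "run.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh)
        loaded = RunConfig.from_yaml(str(path))
        assert loaded.rng_seed == 7
        assert loaded.network.columns_per_area == cfg.network.columns_per_area
        assert loaded.competition.w_rec == cfg.competition.w_rec
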