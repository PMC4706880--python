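# hippogate

A discrete-time circuit simulator of the hippocampal system acting as the
cortex's *change manager*: the subsystem that decides when and where cortical
receptive fields may expand, drives those expansions, and — as a by-product
of recording which fields changed together — supports episodic pattern
completion and in-order sequence recall.

## Who this is for

Computational neuroscientists and students who want an executable, testable
version of the change-manager account of hippocampal–cortical interaction:
every qualitative claim of the model (novelty-proportional CA3 activity,
candidacy-targeted expansion, retrieval without plasticity, basal/apical
firing exclusivity, elevated burst-cell activity under novelty, cued replay
in encoded order) runs as a seeded experiment with a pass/fail verdict.

## The model in brief

**Units.** A pyramidal unit is pure detection logic over two dendritic trees.
A terminal branch with synaptic weights `w_i` and threshold `θ_b` detects its
*condition* at step `t` iff `Σ_{i active} w_i ≥ θ_b`; a tree detects its
*receptive field* iff at least `θ_T` branches detect. The basal tree holds
the direct (sensory) field and the apical tree the indirect (retrieval)
field; interneuron gating ensures at most one compartment drives firing at
any step.

**Columns.** Cortical columns are three feedforward layers (IV → II/III →
V/VI). A column with strong II/III activity but no deep output is *fairly
close* to detecting its field — an expansion **candidate**.

**Competition.** Per-area detection rates feed entorhinal drive `ec_a` to
dentate granule units. Rate dynamics iterate to equilibrium:

    g_a  = clip(ec_a + w_mg·m_a, 0, 1)                      granule
    c_k ← clip(w_rec·c_k + b + mean_a[w_ge·g_a − w_gi·relu(g_a − θ_g)], 0, cap)   CA3
    m_a  = clip(w_cm·⟨c⟩_a, 0, 1)                            mossy

Familiar input saturates the granule layer, the inhibitory path dominates,
and equilibrium CA3 activity is exactly zero; novelty depresses `ec`,
disinhibiting CA3 until the mossy feedback recruits enough inhibition — the
rise is self-limiting and equilibrium total CA3 grows monotonically with the
novelty fraction.

**Perirhinal interface.** Each perirhinal column covers a group of cortical
columns and holds three deep populations: P1 (regular-spiking) detects the
group's familiar conjunction and inhibits P2; P2 (burst-spiking) fires when
the decoded CA3 selection arrives and P1 is silent, sending the *manager*
synapse that gates Hebbian expansion (weight `+Δw`, clipped at `w_max`, only
on recently active synapses of a manager-driven, detecting branch of a unit
that fired); P3 (late-spiking, heterogeneous delays) records each moment of
an episode through reciprocal provisional wiring with the columns' deep
units, so a partial cue later replays the episode in order while plasticity
stays frozen.

## Worked example

```python
from hippogate import RunConfig, Simulation
from hippogate.stimuli import generate_event
import dataclasses

cfg = dataclasses.replace(RunConfig(), rng_seed=2, trained=True, mode="encode")
sim = Simulation(cfg)
event = generate_event(sim.world, context=0, event_id=1, rng=sim.stream_rng)
trace = sim.encode_event(event)                   # three-moment episode
cue = sorted(trace.moments[0], key=repr)[:14]     # ~30% of moment 1
timeline, purity = sim.retrieve_episode(cue)
recalled = set().union(*timeline.values())
print(len(trace.full_set), round(len(recalled & trace.full_set) / len(trace.full_set), 2), purity)
print(Simulation.order_correlation(trace, timeline))
```

prints

```
108 1.0 0.0
1.0
```

meaning: the encoded episode spanned 108 deep units; cueing with 14 of the
first moment's units reactivated 100% of the whole episode; retrieval moved
zero synaptic weight; and the three moments reactivated in exactly their
encoded order (Spearman rank correlation 1.0).

From a shell, the same machinery runs as:

```
hippogate simulate --seed 3 --out runs/demo --presentations 20 --novelty 0.25
hippogate experiment novelty_p2 --seeds 10 --out runs/exp
hippogate experiment recall_completion
hippogate snapshot --in runs/demo/network.json --seed 3
```

`simulate` writes `run_log.csv` (one row per presentation: equilibrium CA3
total, per-population firing counts, columns driven/expanded),
`weight_changes.csv` (every synaptic change), `activity.csv` (fired
unit-steps with compartment), and a JSON network snapshot.
`experiment` runs one named prediction experiment and exits 0 on pass
(an unknown name prints the menu).

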