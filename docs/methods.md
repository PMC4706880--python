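# Methods

This note documents the model implemented by `hippogate`, the assumptions
behind it, the parameters that matter, what the synthetic world does and does
not emulate, and the numerical and design choices made where the underlying
account leaves the implementation open.

## 1. The model

### 1.1 Detection units

Activity is binary per step and there are no membrane dynamics: the account
is stated in detection/threshold terms, so a unit is pure detection logic.
A *terminal branch* carries a set of weighted synapses and detects its
*condition* at step `t` iff the summed weight of synapses active at `t`
reaches the branch threshold; the boundary is inclusive (`≥`), which keeps
worked examples checkable with exact arithmetic. A dendritic tree detects
its *receptive field* iff at least `tree_threshold` branches detect. The
dendritic calcium event is abstracted to the boolean branch detection.

Each unit carries two trees. The basal tree is the direct field (current
sensory input); the apical tree is the indirect field (circumstances in
which the unit should be reactivated from memory). Interneurons are modelled
as gate booleans computed from their stated driver populations, not as
explicit units: while a column has intermediate-layer activity (sensory
context), the apical contribution to firing is blocked at the soma, so
exactly one compartment can drive firing at any step. Apical *condition*
detections are still recorded while gated — the gate blocks the firing
contribution, not the dendritic event — which is what lets episodic
book-keeping proceed on gated apical branches.

A branch may carry one *manager synapse*: the strong perirhinal-P2 input
that embodies hippocampal selection. On pathways where selectivity matters
(deep basal, P1, P3 basal) the manager is deliberately **insufficient
alone** (`manager_alone_detects=False`): drive crosses the dendritic
threshold only where partial regular input already exists, which is the
mechanism that confines expansion to near-detecting targets.

### 1.2 Plasticity

Receptive-field expansion is the only way weights grow. `expand_branch`
strengthens, by `delta_w` (clipped at `w_max`), exactly the recently active
regular synapses of a branch, and only when three gates are open: the
manager input is driving, the branch detected its condition recently, and
the unit fired within the Hebbian window. "Recently active" means within
the last `recent_window` steps, the current step counting as the first.
With expansion disabled the operation refuses with a frozen-plasticity
error, which is how retrieval proves it moves no weight.

Two further change-constraint rules exist as operations and are unit-tested:
`raise_threshold` (integer increment of an over-detecting field's tree
threshold, capped at the branch count) and `prune_synapses` (removal of
synapses that contributed to no detection over a full `prune_window`, with
manager exemption and a one-window grace period for provisional synapses).
The presentation cycle applies them only when the `threshold_adaptation` /
`pruning` flags are set (default off): a familiar context detected on every
presentation is not "detected too often" in the over-generality sense the
rules address, and leaving them off keeps the familiar steady state exactly
weight-stable. When both are enabled the cycle applies prune before raise.
Declining burst-projection weights are available as optional exponential
decay of manager weights (`manager_decay`, default 0).

### 1.3 Cortical columns

Three feedforward layers (the usual five simplified to three): external
features drive layer IV, IV drives II/III, II/III drives the deep output
layer. There is no lateral within-layer wiring, so evaluation order is
irrelevant (property-tested). Layer IV units are single-feature detectors;
II/III units need `k` of their 8 layer-IV inputs with `k` spread over
(2,3,3,4,4,5,6,7), so average detection frequency falls with depth
(IV ≥ II/III ≥ deep — the complexity gradient). The fraction of II/III
units firing is the column's *internal activity*; `candidate` means
internal activity at or above `candidacy_floor` (default 0.5) with no deep
output. Deep output uses the "any deep unit fired" rule (a fraction rule is
available).

Each column reads a **contiguous subfield** of its context's ordered
features. This makes different columns prefer different portions of a
context, so a sliding event window recruits distinct column subsets — the
substrate of distinguishable episode moments.

### 1.4 The competition

One granule and one mossy rate unit per area, one CA3 rate unit per column
group; all rate-valued with clipped-linear saturation. Per iteration:

    granule_a = clip(ec_a + w_mossy_granule * mossy_a, 0, 1)
    net_a     = w_gc_exc * granule_a − w_gc_inh * relu(granule_a − inh_onset)
    ca3_k     = clip(w_rec * ca3_k + tonic + mean_{a∈areas(k)} net_a, 0, cap)
    mossy_a   = clip(w_mossy * mean_{k∋a} ca3_k, 0, 1)

until the largest per-unit change falls below `tol` (1e-6) or `max_iter`
(500) is reached; non-convergence returns a state flagged unconverged with a
warning, never an exception, and release to decoding is withheld (the septal
release abstraction — no oscillator objects).

Gain defaults: `w_rec=0.5`, `w_gc_exc=0.5`, `w_gc_inh=2.0`, `inh_onset=0.3`,
`w_mossy=1.0`, `w_mossy_granule=0.3`, `tonic=0.5`, `cap=2.0`. Two
constraints fix their region: (i) the inhibitory path must dominate at
saturated granule activity (`tonic + w_gc_exc < w_gc_inh·(1−inh_onset)`,
validated at construction), so familiar input yields equilibrium CA3 of
exactly zero; (ii) `inh_onset` sits at the mossy-feedback floor
(`w_mossy_granule·1`), so over the whole reachable range the net granule
effect is monotone and equilibrium CA3 decreases monotonically in entorhinal
drive — below that floor the excitatory branch of the crossover would make
small amounts of familiarity *increase* CA3. The linearised loop gain is
`w_rec + (w_gc_exc − w_gc_inh)·w_mossy_granule·w_mossy = 0.05`, a strong
contraction; convergence takes a few dozen iterations.

Entorhinal summarisation is `ec = clip(rate / rate_scale, 0, 1)` with
`rate_scale = 0.45`: with multiple contexts sharing one column pool, the
fraction of columns producing output saturates near 0.5 for fully familiar
input, and the normalisation maps that operating point to full drive.
`rate_scale=1` recovers the identity map.

Decode drive to a perirhinal column is the summed equilibrium activity of
the CA3 groups covering it, scaled by the column's own intermediate-layer
activity (`match`) — the internal-activity criterion for selecting low-risk
targets enters multiplicatively here, and again at the dendrite through the
manager-synapse geometry. A hard match floor exists (`p2_match_floor`) but
defaults to a nominal 0.05: in calibration, hard floors blocked legitimate
event-onset recording while the dendritic mechanism already provides the
selectivity.

Groups are "columns that expanded together": the familiarize mode records
co-expansion per context and updates groups by set-union; the pre-trained
builder constructs the equivalent context partition directly (the
post-seeding state). A random-group generator exists for unit tests.

### 1.5 Perirhinal interface and episodes

Per perirhinal column: 6 intermediate units sampling 10 member-column II/III
units each (threshold spread 5–9, a sharp estimator of mean member
activity); 2 P1 units wired as near-AND over the intermediates (the column's
familiar conjunction) which inhibit P2; 2 P2 units that fire iff decode
drive reaches `p2_threshold` and P1 is silent; and 45 P3 delayed units with
delays cycling 1–9 steps.

During encoding (mode `encode`):

- P2 onset opens a sustained *expansion period* (`expansion_hold_steps=4`,
  refreshed while the gate stays open): familiarity rising mid-event as
  fields expand (P1 coming on) does not cut episodic recording short.
- Expansion drive reaches member columns through manager synapses, withheld
  from columns whose deep output is already active (changes only where
  needed). A column counts as *driven* when the manager input actually
  crossed at least one deep-branch threshold.
- P3 units are primed apically by P2 but each unit's delayed one-shot firing
  is *scheduled* at the step its own basal condition (manager + sampled deep
  content) first detects, and the unit captures a **detection-time synaptic
  tag**: the deep units whose firing began since the current stimulus
  appeared (change-detection onsets). When the unit fires `delay` steps
  later, the backpropagating consolidation strengthens exactly the tagged
  basal synapses, while the firing-time deep units strengthen their apical
  synapses from the currently firing P3. A P3 unit therefore binds an
  *earlier* moment on its basal tree and a `delay`-later moment on its
  outgoing links — the sequence substrate.
- After the last moment, the input persists for `encode_tail_steps=9` while
  the pending late discharges arrive and are recorded.
- Deep apical trees sample P3 units of the covering perirhinal columns plus
  `apical_extra_pcols=2` others (a column records P3 groups in multiple
  perirhinal columns); without the extra sampling, columns engaged through
  shared features but covered by other perirhinal columns are unreachable
  from a partial cue.

During retrieval (plasticity frozen): cue units are clamped; active deep
units drive P3 basal detection (no manager; threshold `1.05` reachable by
two strengthened synapses at `0.1+0.5`, or one plus provisional background);
P3 fire after their delays (re-armed with a shorter `retrieval_refractory=8`
so a unit that misses its first window can still contribute) and their
strengthened apical links reactivate deep units through the open apical
gates. Newly active units join the active set; the timeline maps step →
newly activated units. Firing routes obey the compartment contract
throughout: P2 activity switches P3 between apical (encoding) and basal
(retrieval) drive; deep units fire apically only without sensory context.

### 1.6 Recall metrics

Recall fraction = |reactivated ∩ episode| / |episode| where the episode is
the union of deep units that fired during encoding (the `EpisodeTrace`
ground-truth log, which retrieval never reads). Order: each unit is
attributed to the moment where it first fired during encoding; a moment's
reactivation time is the **interquartile mean** of the first-reactivation
steps of its attributed units (recall arrives in bursts; the interquartile
mean locates the burst and is insensitive to isolated early leaks and
second-wave stragglers, where the plain mean is not and the median ties on
the integer step grid); the order statistic is the Spearman rank correlation
between encoded moment index and reactivation time.

## 2. The synthetic world

A context is a fixed sparse pattern (default: 16 of 64 features per area,
4 areas). A presentation with novelty fraction `ν` replaces a `ν`-share of
the context's active features with same-area features never used by any
context, so the novelty label is genuine by construction and its measured
value matches the label up to rounding (property-tested). Events are
windows sliding over the ordered context features **without wrap-around**
(window 10 of 16 per area, stride 3 for three moments), each moment carrying
`event_novelty=0.2` fresh features — almost all events have some novelty,
which is what triggers encoding. Consecutive moments share at least the
configured overlap (default 0.5; actual 0.7 with the default geometry).
Sampling is integer-only from seeded generators, so streams are reproducible
across platforms.

What the generator does *not* emulate: natural image statistics, continuous
time, reward, modality structure, gradual context drift, or multi-episode
interference within one run. Passing tests therefore show that the circuit
logic produces the claimed phenomena under clean, label-controlled
conditions — not that it would survive the correlational structure of real
sensory data.

## 3. Networks, sizes and the trained/fresh distinction

Default scale: 4 areas × 16 columns; per column 8/8/4 units with one or two
branches of ≤ 12 synapses each (the cortical ~100 branches × ~100 synapses
scaled down; the logic is size-independent and these sizes keep every desk
experiment inside seconds). Two builders share all wiring topology:

- **fresh**: deep and P1 fields start weak (8 × 0.55 against threshold 4.5 —
  silent without the 1.2 manager input). Familiarization strengthens them
  through the full loop: novelty → CA3 → decode → P2 → manager-gated
  Hebbian steps — and stops by itself when area rates are high enough that
  equilibrium CA3 is exactly zero (typically 2–3 presentations at this
  scale).
- **trained**: the post-familiarization state constructed directly, with a
  per-column robustness spread: the deep conjunction needs a fraction
  `d_c ~ U(0.7, 1.2)` of its II/III inputs. The upper tail (> 1) yields
  columns whose requirement exceeds what this context can supply — fields
  tuned to other circumstances, silent here — and the lower tail supplies
  the detectors that keep area rates informative even at 75% novelty.
  Thresholds are set at `(need − 0.5)·w` so that detection needs exactly
  `need` active synapses regardless of floating-point rounding in the sum.

## 4. Fixed evaluation order

Each presentation: step all columns bottom-up → perirhinal sense phase
(intermediates, P1) → area rates → entorhinal summary → competition to
equilibrium → release-and-decode (withheld if unconverged) → perirhinal
drive phase (P2 gate, P3) → gated plasticity if the mode permits → logs.
Single-threaded and deterministic: identical configuration and seed give
byte-identical metric CSVs (tested). Errors inside a cycle propagate with
the presentation index attached.

## 5. Experiments

`run_experiment` exposes the six prediction experiments plus three that make
the competition properties runnable through the same harness:
`zero_novelty_null`, `novelty_monotonicity`, `competition_boundedness`,
`candidacy_targeting`, `recall_completion`, `recall_order`,
`retrieval_purity`, `gating_xor`, `novelty_p2`. Observation blocks run with
plasticity disengaged so measurement does not contaminate the measured
state. Defaults: 10 derived seeds per experiment; novel blocks at ν=0.5 for
the P2 comparison and ν=0.25 for candidacy targeting (moderate novelty is
the regime in which expansion targeting is meaningful — at high novelty
there are no near-detecting candidates to select).

## 6. Known limitations

- The competition is a mean-field rate loop per area/group; no spiking, no
  theta/gamma structure (release is the convergence gate), no
  mammillary/amygdala biasing.
- CA3 groups discriminate contexts through the perirhinal match factor, not
  through within-CA3 competition between overlapping groups.
- Single-episode retrieval is tested; P3 reuse across episodes is allowed by
  the design but interference across many episodes is not characterised.
- Expansion recruits pre-placed silent synapses only; there is no structural
  synaptogenesis.
- The order statistic needs each moment to introduce at least one new unit;
  an event whose windows add nothing new yields an undefined correlation
  (reported as NaN, counted as failure in the experiments).
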