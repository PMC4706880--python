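# Default run configuration: every tunable of the simulator with its
# shipped value. Override any subset and pass via --config.
world:
  n_features: 256
  n_areas: 4
  n_contexts: 2
  pattern_density: 0.25
  novelty_fraction: 0.25
  event_length: 3
  event_overlap: 0.5
  event_novelty: 0.2
  rng_seed: 0
network:
  n_areas: 4
  columns_per_area: 16
  l4_per_column: 8
  l23_per_column: 8
  l23_thresholds:
  - 2
  - 3
  - 3
  - 4
  - 4
  - 5
  - 6
  - 7
  deep_per_column: 4
  deep_branches: 2
  deep_robustness:
  - 0.7
  - 1.2
  trained_weight: 0.8
  fresh_deep_weight: 0.55
  fresh_deep_threshold: 4.5
  manager_weight: 1.2
  pcols_per_context: 4
  membership_overlap: 2
  intermediate_per_pcol: 6
  int_fanin: 10
  int_thresholds:
  - 5
  - 6
  - 7
  - 8
  - 8
  - 9
  p1_per_pcol: 2
  p2_per_pcol: 2
  p3_per_pcol: 45
  p3_delay_slots: 9
  p3_branches: 3
  p3_fanin: 12
  p3_provisional_weight: 0.1
  p3_manager_weight: 0.8
  p3_branch_threshold: 1.05
  p3_refractory: 24
  deep_apical_fanin: 24
  deep_apical_branches: 3
  deep_apical_threshold: 0.45
  apical_extra_pcols: 2
  p2_threshold: 0.05
  p2_match_floor: 0.05
  candidacy_floor: 0.5
plasticity:
  delta_w: 0.15
  w_max: 1.0
  recent_window: 3
  overdetection_rate: 0.5
  threshold_step: 1.0
  prune_window: 20
  expansion_enabled: true
  manager_decay: 0.0
episodic:
  delta_w: 0.5
  w_max: 1.0
  recent_window: 1
  overdetection_rate: 0.5
  threshold_step: 1.0
  prune_window: 20
  expansion_enabled: true
  manager_decay: 0.0
competition:
  w_rec: 0.5
  w_gc_exc: 0.5
  w_gc_inh: 2.0
  inh_onset: 0.3
  w_mossy: 1.0
  w_mossy_granule: 0.3
  tonic: 0.5
  tol: 1.0e-06
  max_iter: 500
  activity_cap: 2.0
  rate_scale: 0.45
  decode_gain: 1.0
mode: familiarize
out_dir: runs
log_level: INFO
rng_seed: 0
trained: false
familiarize_presentations: 12
steps_per_moment: 3
retrieval_steps: 20
retrieval_refractory: 8
encode_tail_steps: 9
cue_fraction: 0.3
recall_target: 0.8
threshold_adaptation: false
pruning: false
expansion_hold_steps: 4
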