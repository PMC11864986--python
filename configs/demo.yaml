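# Desk-scale demo: ~2,000 synthetic ROIs, 5 Hz, ~10 min protocol.
# Procedure parameters keep their reference defaults (see config.py);
# simulation/permutation scale knobs are set for a single-CPU run.
seed: 0
synthetic:
  n_cells_per_type: 333        # 6 t-types -> 1,998 ROIs
  coupling_mode: type_position # per-type anterior/posterior archetype bias
  coupling_strength: 0.7
ftype:
  k: 5
  min_members: 10
layers:
  n_perm: 100
overlap:
  n_shuffles: 20
  grid_size: 20
classify:
  n_repeats: 10
  upsample_to: 300
match:
  jitter_sd: 0.5
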