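# Minimal resumable experiment: one small synthetic dataset, two parameter
# points, reduced realization counts.  Run with:
#   sirmix experiment examples/experiment_config.yaml
datasets:
  demo_3x20:
    groups: 3
    group_size: 20
    duration_days: 3
    target_ratio: 50
points:
  - [1.4, 0.3456]
  - [2.1, 0.3456]
n_real: 1000
n_real_fit: 5000
n_reps_r0: 1000
master_seed: 1
outdir: scratch/experiment_demo
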