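# Demo configuration: seeded synthetic multi-source study with known
# embedded signals. Run with
#   adrscreen run --config examples/demo_config.yaml --out scratch/demo
seed: 0
data:
  mode: demo
registry:
  alpha: 0.05
  # the demo fixture's embedded risk ratios are large and its baseline
  # reporting sparse, so pairs below this count are background noise
  min_count: 15
  point_estimate_only: false
dispro:
  threshold: 0.05
  mc_draws: 5000
metalab:
  window_days: 365
  comparator: other_drugs
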