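# Demo run: 40x50-cell (5 km) landscape, three simulated invaders with
# contrasting drivers, two algorithms plus the ensemble, 99 permutations.
seed: 1
synthio:
  nx: 40
  ny: 50
  cell_km: 5.0
  detection_prob: 0.8
  use_accessibility_bias: true
  related_coverage: 0.72
  native_base_rate: 0.15
  species:
    - name: crayfish_like
      driver: anthropic
      n_steps: 25
    - name: frog_like
      driver: environmental
      n_steps: 25
    - name: mussel_like
      driver: mixed
      n_steps: 25
scenarios: [INVADED, NATIVE, MIXED]
algorithms: [GLM, MAXENT]
ensemble: true
n_null: 99
vif_threshold: 10.0
train_frac: 0.7
pwd_tr: 0.33
test_abs_pool_factor: 10
pseudoabsence_pool: all
buffer_km: 200.0
null_mode: joint
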