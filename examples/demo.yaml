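# Small synthetic single-center run exercising every pipeline stage.
# Usage: csfnet run-all --config examples/demo.yaml --out demo_out
seed: 1
synthetic:
  design: single_center            # 101 subjects, 6 TMT batches, 1 GIS channel each
  n_proteins: 300
  n_modules: 5
  max_module_size: 60
  min_module_size: 15
  subthreshold_module_size: 0
  n_decoy_sets: 10
network:
  min_module_size: 10      # modules are scaled down with the proteome
preservation:
  enabled: true
  n_perm: 50
comparisons:
  - [control, sALS]
  - [control, C9_ALS]
panels:
  k: 6
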