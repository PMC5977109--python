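# Desk-scale demo: 1 keV proton on H2, single impact parameter.
# Runs in under a minute:  slend run examples/h2_1kev.yaml
scenario:
  kind: collision
  system: h2
  basis: sto-3g
  energy_kev: 1.0
  b_list: [1.0]
  orientations: 1
  seed: 7
dynamics:
  etf_mode: static
  record_every: 10
  stopping:
    max_time: 800.0
    projectile_separation: 45.0
output:
  directory: runs/h2_1kev
  text_export: true
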