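# Full-scale one-electron-transfer cross section: 100 keV proton on the
# water monomer with the 6-31G* basis and the travelling basis mode.
#
#   slend run examples/h2o_100kev_xsec.yaml
#   slend xsec runs/h2o_100kev/manifest.json
#
# This is the expensive campaign configuration (hours on one CPU: the
# travelling-basis integrals go through the reference engine).  Reduce
# b_list/orientations for a scaled-down estimate; the cross section is
# then grid- and orientation-truncated accordingly.
scenario:
  kind: collision
  system: h2o
  basis: 6-31g*
  energy_kev: 100.0
  b_list: [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.5, 8.0]
  orientations: 8
  seed: 2024
dynamics:
  etf_mode: travelling
  record_every: 20
  stopping:
    max_time: 120.0
    projectile_separation: 45.0
output:
  directory: runs/h2o_100kev
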