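# Full-scale reference system: 100 nm tube, 14,500 lipids, 4 nm scaffold.
# Remove the scaffold section for bare-tube runs, or set scaffold_length: 20
# for the long-scaffold scenario.
build:
  kind: tube
  length: 100.0
  lumen_diameter: 11.0
  outer_diameter: 20.0
  n_lipids: 14500
  ps_fraction: 0.40
  seed: 0
  scaffold:
    scaffold_length: 4.0
    ring_diameter: 25.0
    sites_per_ring: 35
    ring_spacing: 0.25
protocol:
  timestep: 1.0
  equilibration_steps: 1000000
  ramp_start: 10.0
  ramp_end: 310.0
  production_steps: 10000000
  thermostat_target: 310.0
  damping: 100.0
  dump_interval: 10000
  seed: 0
protein_potential:
  sigma: 0.2
  epsilon: 1.0
  cutoff: 0.5
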