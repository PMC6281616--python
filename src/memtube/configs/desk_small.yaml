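# Desk-scale preset: 30 nm tube, proportional lipid count, short runs.
# The scaffold ring sits at a fixed 1.5 nm radial gap above the tube and
# the protein-head attraction uses a widened cutoff (5 sigma) so that the
# attraction band remains within reach of thermal undulations at this
# scale.
build:
  kind: tube
  length: 30.0
  lumen_diameter: 5.5
  ps_fraction: 0.40
  seed: 0
  scaffold:
    length_fraction: 0.10
    ring_gap: 1.5
    sites_per_ring: 35
    ring_spacing: 0.25
protocol:
  timestep: 1.0
  equilibration_steps: 20000
  ramp_start: 10.0
  ramp_end: 310.0
  production_steps: 60000
  thermostat_target: 310.0
  damping: 100.0
  dump_interval: 2000
  seed: 0
protein_potential:
  sigma: 0.2
  epsilon: 1.0
  cutoff: 1.0
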