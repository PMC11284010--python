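# Default study configuration: clinical flow/infusion design and the
# idealized vessel/catheter geometry.  Temperatures in degC, flows in
# mL/min, lengths in mm unless suffixed otherwise.

blood_temperature_C: 37.0
# infusate temperature where it exits the catheter in simulation mode
# (room-temperature saline warms on its way through the catheter in vivo)
infusate_exit_temperature_C: 29.0
# infusate temperature in the bench mode (room-temperature saline)
bench_infusate_temperature_C: 23.0
cardiac_period_s: 1.0

# mean coronary flow per category, mL/min
flow_categories:
  LOW: 50
  MED: 150
  HIGH: 250

# the nine clinically used (category, infusion rate) combinations
clinical_combinations:
  LOW: [8, 10, 15]
  MED: [15, 20, 25]
  HIGH: [20, 25, 30]

# the subset carried through the transport simulator (per catheter type)
simulated_combinations:
  - [LOW, 8]
  - [LOW, 15]
  - [MED, 15]
  - [HIGH, 25]

geometry:
  vessel_diameter: 4.0
  vessel_length: 70.0
  catheter_outer_diameter: 0.84
  catheter_inner_diameter: 0.60
  wire_diameter: 0.36
  outlet_axial_position: 10.0
  side_hole_diameter_um: 100.0
  side_hole_count: 4

run:
  catheters: [sidehole, endhole]
  # combos: [LOW:8, MED:15]        # optional subset; defaults to the
  #                                # simulated_combinations above
  stations_cm: [1.2, 4.4]
  profile_stations_cm: {start: 0.0, stop: 4.8, step: 0.4}
  resolution:
    n_axial: 42
    n_radial: 8
    n_angular: 12
    snapshots_per_cycle: 24
    n_cycles: 2
  mixing:
    molecular_diffusivity: 0.143   # mm^2/s, water
    side_jet_coefficient: 0.02
    end_jet_coefficient: 0.002
    decay_length_mm: 15.0
  pullback:
    duration_s: 20.0
    sample_rate_hz: 10.0
    noise_sd: 0.0
  cv_threshold: 0.35
  pulsatility: 0.9
  seed: 0
  outdir: coromix_out
  write_fields: false
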