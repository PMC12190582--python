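# Baseline shear-deformability-cytometry run (surface units: um, uL/min,
# mPa.s, Pa, ms).  Omitted keys take the documented defaults; unknown keys
# are rejected.
geometry:
  width: 20.0             # channel width (um)
  depth: 20.0             # out-of-plane depth, used for Q -> velocity (um)
  channel_length: 200.0   # straight-section length (um)
  reservoir_width: 60.0   # entry/exit reservoir width (um); 0 length disables
  reservoir_length: 60.0
fluid:
  viscosity: 1.0          # mPa.s
  density: 1000.0         # kg/m^3
  flow_rate: 20.0         # uL/min
cell:
  diameter: 12.0          # um (leukocyte-scale, 8-16)
  young_modulus: 1500.0   # Pa; shear modulus G = E/3 (incompressible)
  relaxation_time: 0.04   # ms; Kelvin-Voigt dashpot eta_c = tau_r * G
solver:
  grid_spacing: 1.0       # um; width/20
  output_stride: 25       # steps between trajectory samples
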