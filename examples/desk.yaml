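# Desk-scale base configuration (18 x 36 columns, 15 layers).
label: desk_base
n_lat: 18
n_lon: 36
seafloor: 5200.0
transport_scheme: overturning
po4_init: 1.5
n_years_max: 100
convergence_tol: 1.0e-4
calendar:
  dt: 0.5
attenuation:
  b_ref: 1.388
  delta_b: 0.0
  lam: 0.05
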