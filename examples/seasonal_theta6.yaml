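# 60% seasonal amplitude, phase theta = 6 months.
extends: smoke.yaml
label: seasonal_db0.6_theta6
attenuation:
  delta_b_frac: 0.6
  theta: 6.0
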