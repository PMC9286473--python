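# Column-count-reduced smoke preset for quick runs and CI.
extends: desk.yaml
label: smoke
n_lat: 8
n_lon: 2
n_years_max: 25
convergence_tol: 1.0e-7
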