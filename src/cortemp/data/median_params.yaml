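# Across-animal median Model 2 parameters (published optimized values).
# T0 is a placeholder: the prediction workflow replaces it with the
# occurrence-regression estimate, and fitting sets it from the data.
L_base: 34.26
U_base: 36.28
tau_wr: 0.21
tau_n: 0.11
pw_size: 3.0
pw_shift: -1.4
pw_scale: 1.01
circ_amp: 0.19
circ_phase: -0.63
T0: 35.3
enable_pw: true
enable_circ: true
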