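# Control parameter set of the minimal calcium-release-unit model.
# Units: concentrations uM, time ms, volumes as fractions of v.
#
# Provenance: PAPER = printed in the source literature; DERIVED = fixed by
# the package's calibration (volume ratio v/v_sr = 45.6 and release gain
# g*tau_i/K_o^2 = 2/2240 from the printed onset pair 2.28 mM / 0.86 mM;
# remaining rates tuned once to the printed bifurcation loci and the ~1 s
# noise-driven period; see docs/methods.md).

[params]
g = 25.11160714285714
tau_i = 0.008
g_up = 0.25586698507891475
K_s = 0.187
K_o = 15.0
k_p = 0.00038222222222222216
k_m = 0.086
v_i = 0.9770701754385965
v_sr = 0.021929824561403508
v_d = 0.001
B_b = 80.0
K_b = 0.5
B_SQ = 0.0
K_SQ = 650.0

[provenance]
g = "DERIVED"
tau_i = "DERIVED"
g_up = "DERIVED"
K_s = "DERIVED"
K_o = "PAPER"
k_p = "DERIVED"
k_m = "DERIVED"
v_i = "DERIVED"
v_sr = "DERIVED"
v_d = "DERIVED"
B_b = "PAPER"
K_b = "PAPER"
B_SQ = "PAPER"
K_SQ = "PAPER"
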