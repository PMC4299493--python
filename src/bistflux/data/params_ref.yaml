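# Reference parameter set of the flux-sensing bistable circuit.
# Calibrated by bifurcation scan so that (i) a bistable substrate window
# spans roughly 0.33-2.6 g/l, (ii) the high-branch growth rate Y*J at
# s = 2 g/l equals the Monod value 0.272 h^-1 (mu_max = 0.34, K_S = 0.5),
# and (iii) the high-branch flux is buffered against changes in the
# Cra-activated production rate beta1 (flux-sensor compensation).
k_E: 1.0        # catalytic scale, flux a.u. per E a.u.
K_s: 5.2        # uptake half-saturation of the lumped transport step, g/l
u: 1.0          # transporter capacity multiplier
V_f: 5.94       # Fbp maximal rate, flux a.u.
K_F: 0.3        # Fbp substrate constant, FBP a.u.
K_J: 0.367      # flux-activation half-point of Fbp, flux a.u.
n: 4.0          # flux-activation Hill coefficient
K_I: 0.0443     # Cra-inhibition constant, FBP a.u.
h: 6.0          # Cra-inhibition Hill coefficient
beta0: 0.105    # basal E production, E a.u. / h
beta1: 2.0      # Cra-activated E production, E a.u. / h
delta: 0.0813   # E degradation, 1/h
Y: 0.35475      # growth yield on flux, 1/h per flux a.u.
f_fbp: 1.0      # Fbp activity multiplier
dilute_F: true
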