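# Published parameter values for the effector-cell / tumour / IL-2 model.
# Dimensional rates in day^-1, densities in cells cm^-1, b in cm cells^-1.
# The diffusivities and the immune-response rate c are ranges in the source
# and are therefore arguments of the fixture factories, not stored here.
# Note: the published tumour-motility lower bound 1.21e-6 cm^2/day
# corresponds to an 11 um cell diameter in d_T = D^2 lambda, although the
# source text quotes diameters "on the order of 10 um" (1.0e-6); the printed
# 1.21e-6 is kept.

[dimensional]
p_E = 0.1245
p_T = 0.1
p_IL = 5.0
g_E = 2.0e7
g_T = 1.0e5
g_IL = 1.0e3
m_E = 0.03
m_IL = 10.0
r_T = 0.18
b = 1.0e-6

[nondimensional]
mu_u = 0.167
rho_u = 0.692
gamma_v = 0.1
mu_w = 55.56
rho_w = 2.5
gamma_w = 1.0e-3
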