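# Wild-type parameter set for the coarse-grained mechanistic growth model
# (nutrient import -> metabolism -> energy-activated transcription ->
# ribosome-mRNA binding -> translation).  Values follow the published
# defaults of the Weisse et al. coarse-grained cell model: the ribosomal
# mRNA class has its own transcription threshold theta_r, and the three
# non-ribosomal classes share theta_x (see docs/methods.md).
#
# Units: time in minutes, lengths in amino acids, species in molecules per
# cell, energy in arbitrary "energy units".
s_ext: 10000.0     # external nutrient concentration (held fixed)
v_t: 726.0         # max nutrient import rate per transporter (1/min)
K_t: 1000.0        # import Michaelis constant (nutrient units)
v_m: 5800.0        # max metabolic rate per enzyme (1/min)
K_m: 1000.0        # metabolic Michaelis constant (internal nutrient units)
n_s: 0.5           # energy units yielded per metabolised nutrient
w_r: 930.0         # max ribosomal transcription rate (mRNA/min)
w_e: 4.14          # max transporter/enzyme transcription rate (mRNA/min)
w_q: 948.93        # max housekeeping transcription rate (mRNA/min)
theta_r: 426.87    # ribosomal transcription Michaelis constant (energy units)
theta_x: 4.38      # non-ribosomal transcription Michaelis constant (gamma = 1/theta_x)
K_q: 152219.0      # housekeeping autoinhibition threshold (molecules)
h_q: 4.0           # housekeeping autoinhibition Hill exponent
k_b: 1.0           # ribosome-mRNA binding rate (1/(molecule*min))
k_u: 1.0           # ribosome-mRNA unbinding rate (1/min)
d_m: 0.1           # mRNA degradation rate (1/min)
g_max: 1260.0      # max translation elongation rate (aa/min)
K_p: 7.0           # translation energy Michaelis constant (energy units)
M: 100000000.0     # total cell mass (aa); growth dilutes at lambda = g(a)*sum(c)/M
n_r: 7459.0        # ribosome length (aa)
n_x: 300.0         # non-ribosomal protein length (aa)
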