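"""Physical constants used throughout, in the mixed units of gas-phase
anion spectroscopy: energies in eV, vibrational frequencies in cm^-1,
wavelengths in nm, times in seconds."""

#: hc, eV nm (CODATA)
HC_EV_NM = 1239.84193

#: Planck constant, eV s
PLANCK_EV_S = 4.135667696e-15

#: Boltzmann constant, eV / K
KB_EV_K = 8.617333e-5

#: 1 eV expressed in cm^-1
EV_TO_CM1 = 8065.544
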