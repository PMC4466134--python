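"""Physical constants (CODATA 2018 exact values) and unit helpers.

The package works in the mixed unit system customary for elastic neutron
scattering on backscattering/time-of-flight spectrometers:

* momentum transfer Q in inverse aangstroem (1/AA),
* mean square displacements <u2> in AA^2,
* energy resolution dE in micro-eV (FWHM),
* oscillator force constants k in N/m, frequencies nu in 1/ps,
* temperature in K.

``planck_h`` is Planck's constant; hydration (g D2O per g protein) is always
called ``hydration`` in this package to avoid the clash with the symbol h.
"""

#: Planck constant, J*s
PLANCK_H = 6.62607015e-34
#: reduced Planck constant, eV*s
HBAR_EV_S = 6.582119569e-16
#: Boltzmann constant, J/K
K_B = 1.380649e-23

#: 1 m^2 in AA^2
M2_TO_A2 = 1.0e20
#: 1 ps^-1 in s^-1
PER_PS_TO_PER_S = 1.0e12
#: 1 micro-eV in eV
UEV_TO_EV = 1.0e-6
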