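"""Physical constants used throughout the package.

Units follow the conventions of the rest of the package: energies in keV,
lengths in mm for geometry and cm for attenuation, wavelengths in Angstrom.
"""

#: hc, keV * Angstrom (CODATA)
HC_KEV_ANGSTROM = 12.398419

#: classical electron radius, cm
R_E_CM = 2.8179403e-13

#: classical electron radius, Angstrom
R_E_ANGSTROM = 2.8179403e-5

#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23

#: electron rest energy, keV
ELECTRON_REST_KEV = 510.99895

#: Thomson cross section, cm^2
SIGMA_THOMSON_CM2 = 6.6524587e-25

#: keV -> Joule
KEV_TO_JOULE = 1.602176634e-16

#: default photon-tracking energy cutoff, keV
ENERGY_CUTOFF_KEV = 1.0
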