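"""Physical constants and unit conventions.

Units used throughout the package: length nm, energy kJ/mol, time ps,
temperature K, charge in elementary charges, mass amu (g/mol).
"""

#: Boltzmann constant, kJ/(mol K)
KB = 0.008314462618

#: Coulomb constant times e^2 times Avogadro, kJ nm / mol  (e^2 / 4 pi eps0)
COULOMB_KJ_NM = 138.935458

#: 1 atm expressed in kJ/(mol nm^3)
ATM_IN_KJ_PER_MOL_NM3 = 0.0610193586

#: Debye-length prefactor, nm * sqrt(M): kappa^-1 = 0.304 / sqrt(I) nm
DEBYE_PREFACTOR_NM = 0.304
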