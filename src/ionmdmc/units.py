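"""Internal unit system: angstrom, picosecond, kJ/mol, elementary charge.

Energies are molar (kJ/mol), so forces are kJ/mol/A and the thermal energy
at 300 K is kB*300 ~ 2.494 kJ/mol.
"""

#: Boltzmann constant, kJ/mol/K (molar gas constant in kJ).
KB = 0.008314462618

#: Force on one elementary charge in a 1 V/A field, in kJ/mol/A.
EV_PER_ANG = 96.48533212

#: Coulomb prefactor e^2/(4 pi eps0) in kJ/mol * A (vacuum).
COULOMB = 1389.35457644
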