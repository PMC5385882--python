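"""Physical constants in the package's working units (kcal/mol, Å, amu, ps, e)."""

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872041

#: Coulomb constant, kcal·Å/mol/e²
COULOMB = 332.0637

#: 1 kcal/mol expressed in amu·Å²/ps² (converts energies to MD units)
KCAL_TO_MD = 418.4

#: Default simulation temperature, K
T_REF = 298.0
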