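"""Physical constants and unit conventions.

Package-wide units: lengths in nm, charges in elementary charge e,
dipoles in e*nm, energies in eV, electric potentials in V and fields in
V/nm. With these units the Coulomb energy of two unit charges 1 nm apart
is K_E eV, and a potential expressed in eV/e is numerically a potential
in volts, so no Faraday factor ever appears explicitly.
"""

# Coulomb constant, eV*nm/e^2 (= 14.39964 eV*Angstrom/e^2)
K_E = 1.439964

# Boltzmann constant, eV/K
K_B = 8.617333262e-5

# 1 debye in e*nm
DEBYE_TO_E_NM = 0.0208194

# Absolute potential of the standard hydrogen electrode, V
V_SHE_DEFAULT = 4.281

# Default guard distance between an environment charge and any evaluation
# point, nm: classical configurations occasionally clash and a silent 1/r
# spike would corrupt ensemble averages.
D_MIN_DEFAULT = 0.05
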