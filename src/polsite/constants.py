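"""Physical constants shared across modules."""

# Gas constant / Boltzmann constant, kcal mol^-1 K^-1
R_KCAL = 1.98720425e-3
KB_KCAL = R_KCAL

# Electrostatic conversion factor, kcal Å mol^-1 e^-2 (vacuum, no dielectric)
COULOMB_KCAL = 332.0636

# Representative atoms used for backbone-level metrics
REPRESENTATIVE_ATOMS = frozenset({"CA", "C1'"})
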