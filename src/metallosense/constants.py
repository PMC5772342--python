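"""Physical constants shared across the package.

All concentrations are molar internally; masses are monoisotopic daltons
unless an average-mass mode is requested explicitly.
"""

#: Gas constant in kcal mol^-1 K^-1 (thermochemical calorie).
R_KCAL: float = 1.987e-3

#: Default temperature (25 degC) in kelvin.
T_DEFAULT: float = 298.15

#: Monoisotopic mass of a proton (Da), used for [M+H]+ and charge arithmetic.
PROTON: float = 1.00727646688

#: Monoisotopic mass of water (Da).
WATER: float = 18.0105646863

#: Mass difference 2H - 1H (Da).
DEUTERIUM_SHIFT: float = 2.0141017781 - 1.0078250319

#: N-ethylmaleimide Michael adduct, C6H7NO2 (Da).
NEM_MASS: float = 125.04767846

#: Pentadeuterated NEM adduct, C6H2D5NO2 (Da).
D5_NEM_MASS: float = NEM_MASS + 5 * DEUTERIUM_SHIFT

#: Porod-volume to molecular-weight conversion (A^3 per Da).
POROD_DENSITY: float = 1.66
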