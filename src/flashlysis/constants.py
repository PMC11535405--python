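"""Physical constants and unit-bridge factors used across the package.

All chemistry is carried in SI-adjacent radiolysis units: concentrations in
mol/L, time in seconds, dose in gray, yields (G values) in entities per
100 eV of energy imparted, fluence in um^-2.
"""

#: CODATA elementary charge, J per eV.
ELEMENTARY_CHARGE_J = 1.602176634e-19

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: Molar concentration of pure liquid water at 25 degC, mol/L.
WATER_MOLARITY = 55.3

#: Density of the aqueous target, kg/L (== 1 g/cm^3).
WATER_DENSITY_KG_PER_L = 1.0

#: 1 Gy expressed as MeV per gram (4 significant figures kept downstream).
GY_TO_MEV_PER_G = 6.242e9

#: mol/L produced per unit G (per 100 eV) per Gy in unit-density water:
#: C = G * D / (100 * e * N_A)  ->  1.0364e-7 M per (G * Gy).
CONC_PER_G_PER_GY = WATER_DENSITY_KG_PER_L / (
    100.0 * ELEMENTARY_CHARGE_J * AVOGADRO
)

#: Oxygen concentration of O2-saturated water at 25 degC, mol/L.
O2_SATURATION_M = 1.25e-3

#: Default "1% oxygen" level: 1% of O2-saturated water.
O2_ONE_PERCENT_M = 0.01 * O2_SATURATION_M
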