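"""Physical constants (CODATA 2018 exact values).

Single ledger so every module and test sees identical numbers.
"""

#: Molar gas constant, J K^-1 mol^-1.
R_GAS = 8.314462618

#: Boltzmann constant, J K^-1.
K_BOLTZMANN = 1.380649e-23

#: Avogadro constant, mol^-1.
N_AVOGADRO = 6.02214076e23

#: Default dynamic viscosity of air near skin-surface temperature (32 degC), Pa s.
AIR_VISCOSITY_32C = 1.89e-5

#: Dynamic viscosity of water at ~32 degC, Pa s (used for aqueous-phase diffusivities).
WATER_VISCOSITY_32C = 7.65e-4

#: Antoine coefficients for water, log10(P/mmHg) = A - B/(C + T_degC), valid 1-100 degC.
WATER_ANTOINE = (8.07131, 1730.63, 233.426)

#: mmHg -> Pa.
MMHG_TO_PA = 133.322
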