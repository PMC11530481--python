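"""Chemical records, the ambient environment, and air-phase evaporation parameters.

All quantities are strict SI internally (kg, m, s, mol, K, Pa); molar mass is
carried as g/mol — the convention every chemical database prints — and divided
by 1000 at the point of use.

The two closed-form relations of the evaporation model live here:

* the Stokes–Einstein gas diffusivity ``D = k_B T / (6 pi eta r)``, using the
  viscosity of air and a sphere-equivalent molecular radius, and
* the legacy wind-speed evaporative mass-transfer coefficient
  ``K_evap = 1.756e-5 P MW^(2/3) u^0.78 / (R T)`` (EPA liquid-spill
  correlation), retained as an alternative "legacy" evaporation mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import (
    AIR_VISCOSITY_32C,
    K_BOLTZMANN,
    MMHG_TO_PA,
    N_AVOGADRO,
    R_GAS,
    WATER_ANTOINE,
)
from .errors import InvalidChemicalError, PBPKEError

__all__ = [
    "Chemical",
    "Environment",
    "FluxRecord",
    "molecular_radius",
    "air_diffusivity",
    "legacy_kevap",
    "water_saturation_pressure",
    "water_ambient_concentration",
]


@dataclass(frozen=True)
class Chemical:
    """Immutable physicochemical record of one vehicle component / permeant.

    Parameters
    ----------
    name, cas : str
        Identifiers; ``name`` is the key used in vehicles and configs.
    mw : float
        Molar mass, g/mol.
    log_kow : float, optional
        log10 octanol-water partition coefficient (needed for skin QSPRs,
        not for evaporation).
    vapour_pressure : float
        Pure-component vapour pressure at scenario temperature, Pa.
    density : float
        Liquid density, kg/m^3.
    radius : float, optional
        Molecular radius, m.  Estimated from the liquid molar volume when
        absent (see :func:`molecular_radius`).
    solubility : float, optional
        Saturation concentration in the vehicle, kg/m^3; only used to emit
        supersaturation warnings during solvent dry-down.
    d_air : float, optional
        Override for the gas-phase diffusivity, m^2/s.  When absent the
        Stokes–Einstein value is used.
    is_water : bool
        Water exchanges bidirectionally with the humid ambient; everything
        else sees a zero-concentration ambient by default.
    """

    name: str
    mw: float
    cas: str = ""
    log_kow: float | None = None
    vapour_pressure: float = 0.0
    density: float = 1000.0
    radius: float | None = None
    solubility: float | None = None
    d_air: float | None = None
    is_water: bool = False

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise InvalidChemicalError(f"{self.name}: mw must be > 0, got {self.mw}")
        if self.vapour_pressure < 0:
            raise InvalidChemicalError(
                f"{self.name}: vapour_pressure must be >= 0, got {self.vapour_pressure}"
            )
        if self.density <= 0:
            raise InvalidChemicalError(
                f"{self.name}: density must be > 0, got {self.density}"
            )
        if self.radius is not None and self.radius <= 0:
            raise InvalidChemicalError(
                f"{self.name}: radius must be > 0 when given, got {self.radius}"
            )

    @property
    def molar_mass_kg(self) -> float:
        """Molar mass in kg/mol."""
        return self.mw / 1000.0


@dataclass
class Environment:
    """Ambient conditions above the donor chamber.

    ``donor_height`` is the distance from the vehicle surface to the top of
    the donor-chamber wall — the diffusion length of the mechanistic
    evaporation model.  ``wind_speed`` is only consulted by the legacy mode.
    """

    temperature: float = 305.15          # K (32 degC skin surface)
    relative_humidity: float = 0.5       # fraction in [0, 1]
    donor_height: float = 0.01           # m
    air_viscosity: float = AIR_VISCOSITY_32C   # Pa s
    wind_speed: float = 0.2              # m/s, legacy mode only
    ambient_concentrations: dict[str, float] = field(default_factory=dict)  # mol/m^3
    p_sat_water: float | None = None     # Pa; Antoine default when None
    allow_water_condensation: bool = False

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise PBPKEError(f"temperature must be > 0 K, got {self.temperature}")
        if self.donor_height <= 0:
            raise PBPKEError(f"donor_height must be > 0 m, got {self.donor_height}")
        if self.air_viscosity <= 0:
            raise PBPKEError(f"air_viscosity must be > 0, got {self.air_viscosity}")
        if not 0.0 <= self.relative_humidity <= 1.0:
            raise PBPKEError(
                f"relative_humidity must be in [0, 1], got {self.relative_humidity}"
            )
        if self.wind_speed < 0:
            raise PBPKEError(f"wind_speed must be >= 0, got {self.wind_speed}")

    def water_psat(self) -> float:
        """Saturation vapour pressure of water at ``temperature``, Pa."""
        if self.p_sat_water is not None:
            return self.p_sat_water
        return water_saturation_pressure(self.temperature)

    def ambient_concentration(self, chem: Chemical) -> float:
        """Ambient gas concentration M_a of a chemical, mol/m^3.

        Zero for everything except water (humidity via the ideal gas law),
        unless explicitly overridden per chemical name.
        """
        if chem.name in self.ambient_concentrations:
            return self.ambient_concentrations[chem.name]
        if chem.is_water:
            return water_ambient_concentration(self, self.water_psat())
        return 0.0


@dataclass(frozen=True)
class FluxRecord:
    """Evaporative flux of one component at one instant (positive out of the vehicle)."""

    component: Chemical
    d_evap: float          # m^2/s (gas diffusivity; 0 in legacy/occluded modes)
    m_s: float             # surface gas concentration, mol/m^3
    m_a: float             # ambient gas concentration, mol/m^3
    j_molar: float         # mol m^-2 s^-1
    j_mass: float          # kg m^-2 s^-1; always j_molar * mw / 1000
    k_evap_legacy: float | None = None   # m/s, legacy mode only

    def __post_init__(self) -> None:
        expected = self.j_molar * self.component.molar_mass_kg
        if self.j_mass != expected:
            raise PBPKEError(
                f"inconsistent FluxRecord for {self.component.name}: "
                f"j_mass={self.j_mass} != j_molar*mw/1000={expected}"
            )


def molecular_radius(chem: Chemical) -> float:
    """Molecular radius (m): stored value, else sphere-equivalent from liquid molar volume.

    The estimate treats one molecule as a sphere occupying its share of the
    liquid molar volume: ``r = (3 (mw/1000) / (4 pi rho N_A))^(1/3)``.
    """
    if chem.radius is not None:
        return chem.radius
    if chem.mw <= 0 or chem.density <= 0:
        raise InvalidChemicalError(f"{chem.name}: need mw, density > 0 to estimate radius")
    molar_volume = chem.molar_mass_kg / chem.density          # m^3/mol
    return (3.0 * molar_volume / (4.0 * math.pi * N_AVOGADRO)) ** (1.0 / 3.0)


def air_diffusivity(chem: Chemical, env: Environment) -> float:
    """Gas-phase diffusivity via Stokes–Einstein, m^2/s.

    ``D = k_B T / (6 pi eta r)`` with the viscosity of air.  A per-chemical
    ``d_air`` override bypasses the formula (useful where tabulated gas-phase
    diffusivities are preferred).
    """
    if chem.d_air is not None:
        return chem.d_air
    r = molecular_radius(chem)
    if r <= 0:
        raise InvalidChemicalError(f"{chem.name}: radius must be > 0")
    return K_BOLTZMANN * env.temperature / (6.0 * math.pi * env.air_viscosity * r)


def legacy_kevap(chem: Chemical, env: Environment) -> float:
    """Legacy evaporative mass-transfer coefficient, m/s.

    EPA liquid-spill correlation with wind speed u:
    ``K_evap = 1.756e-5 P MW^(2/3) u^0.78 / (R T)`` (MW in Da).
    Zero in still air (u = 0) and for non-volatiles (P = 0).
    """
    return (
        1.756e-5
        * chem.vapour_pressure
        * chem.mw ** (2.0 / 3.0)
        * env.wind_speed**0.78
        / (R_GAS * env.temperature)
    )


def water_saturation_pressure(temperature: float) -> float:
    """Saturation vapour pressure of water (Pa) from the Antoine equation.

    Coefficients for log10(P/mmHg) = A - B/(C + T_degC), valid 1-100 degC.
    """
    a, b, c = WATER_ANTOINE
    t_c = temperature - 273.15
    return MMHG_TO_PA * 10.0 ** (a - b / (c + t_c))


def water_ambient_concentration(env: Environment, p_sat_water: float) -> float:
    """Ambient water-vapour concentration from relative humidity, mol/m^3.

    Ideal gas law: ``M_a = RH * p_sat / (R T)``.
    """
    if p_sat_water < 0:
        raise PBPKEError(f"p_sat_water must be >= 0, got {p_sat_water}")
    return env.relative_humidity * p_sat_water / (R_GAS * env.temperature)
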