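"""Vapour-pressure-driven evaporation from a multi-component liquid film.

The surface gas concentration of each component follows Raoult's law plus the
ideal gas law, ``M_s = P x_l a_l / (R T)`` (activity coefficient a_l = 1 for
ideal vehicles), and the evaporative flux is Fickian diffusion across the
stagnant air column of the donor chamber, ``J = D_evap (M_s - M_a) / h``.
J is stored as a positive outward magnitude, so the vehicle mass balances
subtract it.  Shrinkage of the film assumes ideal (additive) partial volumes:
``dV/dt = -sum_i J_mass,i A / rho_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import Chemical, Environment, FluxRecord, air_diffusivity, legacy_kevap
from .constants import R_GAS
from .errors import EmptyVehicleError, InvalidGeometryError, UnknownComponentError

__all__ = [
    "VehicleState",
    "mole_fractions",
    "surface_gas_concentration",
    "evaporative_flux",
    "component_fluxes",
    "vehicle_volume_rate",
    "MASS_FLOOR",
]

#: Component mass (kg) below which a component is treated as dried down.
MASS_FLOOR = 1e-15

#: Valid evaporation modes.
MODES = ("mechanistic", "legacy", "occluded")


@dataclass
class VehicleState:
    """Instantaneous state of the liquid vehicle film.

    ``components`` maps each :class:`Chemical` to its current mass (kg);
    ``volume`` is the film volume (m^3).  Activity coefficients default to 1
    (ideal liquid) and may be supplied per component name.
    """

    components: list[tuple[Chemical, float]]
    volume: float
    activity_coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise InvalidGeometryError(f"vehicle volume must be >= 0, got {self.volume}")
        for chem, mass in self.components:
            if mass < 0:
                raise EmptyVehicleError(
                    f"component {chem.name} has negative mass {mass}"
                )

    @property
    def chemicals(self) -> list[Chemical]:
        return [chem for chem, _ in self.components]

    def mass(self, name: str) -> float:
        for chem, m in self.components:
            if chem.name == name:
                return m
        raise UnknownComponentError(f"{name} is not a vehicle component")

    def moles(self) -> np.ndarray:
        """Moles of each component, in declaration order."""
        return np.array([m / chem.molar_mass_kg for chem, m in self.components])

    def total_mass(self) -> float:
        return float(sum(m for _, m in self.components))

    def concentration(self, name: str) -> float:
        """Mass concentration of a component, kg/m^3 (inf-safe: 0 if V == 0)."""
        m = self.mass(name)
        return m / self.volume if self.volume > 0 else 0.0

    def activity_coefficient(self, name: str) -> float:
        return self.activity_coefficients.get(name, 1.0)


def mole_fractions(state: VehicleState) -> dict[str, float]:
    """Mole fraction of each component (Raoult basis, all components counted).

    Raises :class:`EmptyVehicleError` when every mass is zero — the vehicle
    is depleted and fractions are undefined.
    """
    n = state.moles()
    total = n.sum()
    if total <= 0:
        raise EmptyVehicleError("all component masses are zero; vehicle is depleted")
    return {chem.name: float(ni / total) for chem, ni in zip(state.chemicals, n)}


def surface_gas_concentration(
    chem: Chemical, state: VehicleState, env: Environment
) -> float:
    """Gas concentration at the vehicle surface, mol/m^3.

    ``M_s = P x_l a_l / (R T)``: Raoult's law scaled by the (default ideal)
    activity coefficient, converted to concentration by the ideal gas law.
    """
    x = mole_fractions(state)
    if chem.name not in x:
        raise UnknownComponentError(f"{chem.name} is not a vehicle component")
    a_l = state.activity_coefficient(chem.name)
    return chem.vapour_pressure * x[chem.name] * a_l / (R_GAS * env.temperature)


def evaporative_flux(
    chem: Chemical,
    state: VehicleState,
    env: Environment,
    mode: str = "mechanistic",
) -> FluxRecord:
    """Evaporative flux of one component, as a positive outward magnitude.

    mechanistic
        ``j = D_evap (M_s - M_a) / h`` across the donor-chamber air column.
    legacy
        ``j = K_evap (M_s - M_a)`` with the wind-speed mass-transfer
        coefficient.
    occluded
        zero flux (covered vehicle).

    Net condensation (ambient above surface concentration) is clamped to
    zero except for water when ``env.allow_water_condensation`` is set.
    """
    if mode not in MODES:
        raise ValueError(f"unknown evaporation mode {mode!r}; expected one of {MODES}")
    if mode == "occluded":
        return FluxRecord(chem, 0.0, 0.0, 0.0, 0.0, 0.0)

    m_s = surface_gas_concentration(chem, state, env)
    m_a = env.ambient_concentration(chem)
    if state.mass(chem.name) <= MASS_FLOOR:
        # dried-down component: no further exchange
        return FluxRecord(chem, 0.0, m_s, m_a, 0.0, 0.0)

    if mode == "mechanistic":
        if env.donor_height <= 0:
            raise InvalidGeometryError("donor_height must be > 0 for mechanistic mode")
        d_evap = air_diffusivity(chem, env)
        j_molar = d_evap * (m_s - m_a) / env.donor_height
        k_legacy = None
    else:  # legacy
        d_evap = 0.0
        k_legacy = legacy_kevap(chem, env)
        j_molar = k_legacy * (m_s - m_a)

    if j_molar < 0 and not (chem.is_water and env.allow_water_condensation):
        j_molar = 0.0
    j_mass = j_molar * chem.molar_mass_kg
    return FluxRecord(chem, d_evap, m_s, m_a, j_molar, j_mass, k_legacy)


def component_fluxes(
    state: VehicleState, env: Environment, mode: str = "mechanistic"
) -> list[FluxRecord]:
    """Evaporative flux records for every vehicle component (declaration order)."""
    return [evaporative_flux(chem, state, env, mode) for chem in state.chemicals]


def vehicle_volume_rate(
    state: VehicleState, fluxes: list[FluxRecord], area: float
) -> float:
    """Rate of change of vehicle volume, m^3/s (non-positive).

    Ideal-solution additive volumes: ``dV/dt = -sum_i j_mass,i A / rho_i``.
    Volume loss through skin permeation is neglected.
    """
    return -sum(f.j_mass * area / f.component.density for f in fluxes)
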