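"""Raoult-law surface concentrations, evaporative flux, and film shrinkage."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pbpke.chem import Chemical, Environment
from pbpke.constants import R_GAS
from pbpke.errors import EmptyVehicleError, InvalidGeometryError, UnknownComponentError
from pbpke.evaporation import (
    VehicleState,
    component_fluxes,
    evaporative_flux,
    mole_fractions,
    surface_gas_concentration,
    vehicle_volume_rate,
)


class TestMoleFractions:
    def test_pure_liquid(self, acetophenone):
        state = VehicleState([(acetophenone, 1e-6)], volume=1e-9)
        assert mole_fractions(state) == {"Acetophenone": 1.0}

    def test_equal_moles_symmetry(self, acetophenone, tolunitrile):
        state = VehicleState(
            [(acetophenone, 0.12015), (tolunitrile, 0.11715)], volume=1e-4
        )
        x = mole_fractions(state)
        assert x["Acetophenone"] == pytest.approx(0.5, rel=1e-12)
        assert x["4-Tolunitrile"] == pytest.approx(0.5, rel=1e-12)

    def test_water_ethanol_mole_arithmetic(self, water):
        ethanol = Chemical(name="ethanol", mw=46.07, density=789.0)
        state = VehicleState(
            [(water, 0.18015), (ethanol, 0.04607)], volume=2e-4
        )
        x = mole_fractions(state)
        assert x["water"] == pytest.approx(10.0 / 11.0, rel=1e-4)
        assert x["ethanol"] == pytest.approx(1.0 / 11.0, rel=1e-4)

    def test_depleted_vehicle_signals(self, acetophenone):
        state = VehicleState([(acetophenone, 0.0)], volume=0.0)
        with pytest.raises(EmptyVehicleError):
            mole_fractions(state)

    @given(
        masses=st.lists(st.floats(1e-12, 1e-3), min_size=1, max_size=5),
    )
    def test_fractions_partition_unity(self, masses):
        chems = [
            Chemical(name=f"c{i}", mw=50.0 + 25.0 * i, density=900.0 + 50.0 * i)
            for i in range(len(masses))
        ]
        state = VehicleState(list(zip(chems, masses)), volume=1e-6)
        x = np.array(list(mole_fractions(state).values()))
        assert np.all((x >= 0) & (x <= 1))
        assert x.sum() == pytest.approx(1.0, abs=1e-12)


class TestSurfaceGasConcentration:
    def test_pure_acetophenone_hand_value(self, acetophenone):
        state = VehicleState([(acetophenone, 1e-6)], volume=1e-9)
        env = Environment(temperature=305.15)
        m_s = surface_gas_concentration(acetophenone, state, env)
        assert m_s == pytest.approx(52.90 / (R_GAS * 305.15), rel=1e-12)
        assert m_s == pytest.approx(0.02085, rel=1e-3)

    def test_absent_component_zero_and_unknown_raises(self, acetophenone, water):
        state = VehicleState([(acetophenone, 0.0), (water, 1e-6)], volume=1e-9)
        assert surface_gas_concentration(acetophenone, state, Environment()) == 0.0
        other = Chemical(name="other", mw=100.0)
        with pytest.raises(UnknownComponentError):
            surface_gas_concentration(other, state, Environment())

    def test_linearity_in_mole_fraction(self, acetophenone, water):
        env = Environment()
        # dilute the permeant with an equimolar, then 3x molar, amount of water
        n_ace = 1e-6 / acetophenone.molar_mass_kg
        s1 = VehicleState(
            [(acetophenone, 1e-6), (water, n_ace * water.molar_mass_kg)], volume=1e-9
        )
        s2 = VehicleState(
            [(acetophenone, 1e-6), (water, 3 * n_ace * water.molar_mass_kg)],
            volume=1e-9,
        )
        m1 = surface_gas_concentration(acetophenone, s1, env)
        m2 = surface_gas_concentration(acetophenone, s2, env)
        assert m1 == pytest.approx(2.0 * m2, rel=1e-9)

    def test_activity_coefficient_scales(self, acetophenone):
        state = VehicleState(
            [(acetophenone, 1e-6)], volume=1e-9,
            activity_coefficients={"Acetophenone": 0.5},
        )
        ideal = VehicleState([(acetophenone, 1e-6)], volume=1e-9)
        env = Environment()
        assert surface_gas_concentration(acetophenone, state, env) == pytest.approx(
            0.5 * surface_gas_concentration(acetophenone, ideal, env), rel=1e-12
        )


class TestEvaporativeFlux:
    def test_mechanistic_hand_value(self, acetophenone, dry_env):
        chem = Chemical(
            name="Acetophenone", mw=120.15, vapour_pressure=52.90,
            density=1028.0, d_air=3.94e-8,
        )
        state = VehicleState([(chem, 1e-6)], volume=1e-9)
        rec = evaporative_flux(chem, state, dry_env)
        m_s = 52.90 / (R_GAS * 305.15)
        assert rec.j_molar == pytest.approx(3.94e-8 * m_s / 0.01, rel=1e-12)
        assert rec.j_molar == pytest.approx(8.21e-8, rel=5e-3)
        assert rec.j_mass == pytest.approx(9.87e-9, rel=5e-3)

    def test_equilibrium_means_zero_flux(self, acetophenone):
        state = VehicleState([(acetophenone, 1e-6)], volume=1e-9)
        m_s = 52.90 / (R_GAS * 305.15)
        env = Environment(ambient_concentrations={"Acetophenone": m_s})
        assert evaporative_flux(acetophenone, state, env).j_molar == 0.0

    def test_occluded_mode_zero(self, acetophenone, dry_env):
        state = VehicleState([(acetophenone, 1e-6)], volume=1e-9)
        rec = evaporative_flux(acetophenone, state, dry_env, mode="occluded")
        assert rec.j_molar == 0.0 and rec.j_mass == 0.0

    def test_legacy_mode_uses_kevap(self, tolunitrile):
        env = Environment(relative_humidity=0.0, wind_speed=0.2)
        state = VehicleState([(tolunitrile, 1e-6)], volume=1e-9)
        rec = evaporative_flux(tolunitrile, state, env, mode="legacy")
        assert rec.k_evap_legacy is not None
        assert rec.j_molar == pytest.approx(rec.k_evap_legacy * rec.m_s, rel=1e-12)

    def test_condensation_clamped_except_water_with_flag(self, acetophenone, water):
        state = VehicleState([(acetophenone, 1e-9), (water, 1e-6)], volume=1e-9)
        # supersaturated ambient for the permeant -> clamped to zero
        env = Environment(
            relative_humidity=1.0,
            ambient_concentrations={"Acetophenone": 1.0},
        )
        assert evaporative_flux(acetophenone, state, env).j_molar == 0.0
        # humid ambient above the dilute film's water activity: condensation
        # allowed only with the flag
        env_flag = Environment(relative_humidity=1.0, allow_water_condensation=True,
                               ambient_concentrations={"water": 10.0})
        env_noflag = Environment(relative_humidity=1.0,
                                 ambient_concentrations={"water": 10.0})
        assert evaporative_flux(water, state, env_flag).j_molar < 0.0
        assert evaporative_flux(water, state, env_noflag).j_molar == 0.0

    def test_mechanistic_requires_positive_donor_height(self, acetophenone):
        state = VehicleState([(acetophenone, 1e-6)], volume=1e-9)
        env = Environment()
        env.donor_height = -1.0  # bypass constructor validation
        with pytest.raises(InvalidGeometryError):
            evaporative_flux(acetophenone, state, env)

    def test_zero_vapour_pressure_zero_in_both_modes(self, dry_env):
        inert = Chemical(name="inert", mw=100.0, vapour_pressure=0.0)
        state = VehicleState([(inert, 1e-6)], volume=1e-9)
        assert evaporative_flux(inert, state, dry_env, "mechanistic").j_molar == 0.0
        assert evaporative_flux(inert, state, dry_env, "legacy").j_molar == 0.0


class TestVehicleVolumeRate:
    def test_occluded_no_shrinkage(self, acetophenone, dry_env):
        state = VehicleState([(acetophenone, 1e-6)], volume=1e-9)
        fluxes = component_fluxes(state, dry_env, "occluded")
        assert vehicle_volume_rate(state, fluxes, 1e-4) == 0.0

    def test_single_component_hand_value(self, dry_env):
        chem = Chemical(
            name="Acetophenone", mw=120.15, vapour_pressure=52.90,
            density=1028.0, d_air=3.94e-8,
        )
        state = VehicleState([(chem, 1e-6)], volume=1e-9)
        fluxes = component_fluxes(state, dry_env)
        rate = vehicle_volume_rate(state, fluxes, 1e-4)
        assert rate == pytest.approx(-fluxes[0].j_mass * 1e-4 / 1028.0, rel=1e-12)
        assert rate == pytest.approx(-9.60e-16, rel=1e-2)

    def test_two_component_additivity(self, dry_env, water):
        chem = Chemical(
            name="x", mw=120.0, vapour_pressure=50.0, density=1000.0, d_air=4e-8
        )
        both = VehicleState([(chem, 1e-6), (water, 1e-6)], volume=2e-9)
        fluxes = component_fluxes(both, dry_env)
        total = vehicle_volume_rate(both, fluxes, 1e-4)
        parts = sum(
            vehicle_volume_rate(both, [f], 1e-4) for f in fluxes
        )
        assert total == pytest.approx(parts, rel=1e-12)
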