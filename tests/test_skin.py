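"""QSPR providers, grid construction, and the finite-volume diffusion operator."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pbpke.chem import Chemical
from pbpke.errors import ConfigurationError, InvalidGeometryError
from pbpke.skin import (
    SkinGeometry,
    TransportParams,
    build_skin_grid,
    diffusion_rhs,
    qspr_sc_params,
    qspr_viable_params,
    resolve_transport_params,
    skin_flux,
)


def _chem(mw=150.0, log_kow=2.0, density=1050.0):
    return Chemical(name="probe", mw=mw, log_kow=log_kow, density=density)


class TestQSPR:
    def test_override_precedence(self):
        p = qspr_sc_params(_chem(), {"k_sc": 5.0, "d_sc": 1e-13})
        assert p.k_sc == 5.0 and p.d_sc == 1e-13

    def test_unknown_override_key_rejected(self):
        with pytest.raises(ConfigurationError):
            resolve_transport_params(_chem(), {"k_bogus": 1.0})

    def test_missing_log_kow_without_override(self):
        chem = Chemical(name="nolog", mw=150.0, density=1050.0)
        with pytest.raises(ConfigurationError):
            qspr_sc_params(chem)
        with pytest.raises(ConfigurationError):
            qspr_viable_params(chem)

    def test_lipid_partition_monotone_in_log_kow(self):
        ks = [
            qspr_sc_params(_chem(log_kow=lk)).k_lip
            for lk in np.linspace(-0.1, 4.2, 20)
        ]
        assert np.all(np.diff(ks) > 0)

    def test_pure_function_of_mw_and_log_kow(self):
        a = resolve_transport_params(_chem())
        b = resolve_transport_params(
            Chemical(name="other", cas="1-1-1", mw=150.0, log_kow=2.0, density=1050.0)
        )
        assert a == b

    def test_viable_epidermis_equals_dermis(self):
        p = qspr_viable_params(_chem())
        assert p.k_ve == p.k_de and p.d_ve == p.d_de

    def test_viable_diffusivity_decreasing_in_mw(self):
        ds = [
            qspr_viable_params(_chem(mw=mw)).d_ve for mw in np.linspace(90, 500, 15)
        ]
        assert np.all(np.diff(ds) < 0)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            TransportParams(k_sc=-1.0)


class TestGridConstruction:
    def test_1d_depth_partitions_layers(self):
        geom = SkinGeometry()
        p = resolve_transport_params(_chem())
        grid = build_skin_grid(geom, p)
        assert grid.total_depth == pytest.approx(geom.total_thickness, rel=1e-12)
        for layer, thick in (
            ("sc", geom.sc_thickness),
            ("ve", geom.ve_thickness),
            ("de", geom.dermis_thickness),
        ):
            assert grid.volume[grid.layer == layer].sum() == pytest.approx(
                thick, rel=1e-12
            )

    def test_homogeneous_k1_reduces_to_harmonic_mean(self):
        # uniform D, K=1 grid: conductance must equal the classic two-point
        # harmonic-mean formula 1/(dx_i/2D + dx_j/2D)
        geom = SkinGeometry(sc_cells=4, ve_cells=4, dermis_cells=4,
                            sc_thickness=10e-6, ve_thickness=10e-6,
                            dermis_thickness=10e-6)
        p = TransportParams(k_sc=1.0, d_sc=1e-12, k_ve=1.0, d_ve=1e-12,
                            k_de=1.0, d_de=1e-12)
        grid = build_skin_grid(geom, p)
        dx = grid.volume
        for i, j, g in zip(grid.iface_i, grid.iface_j, grid.iface_g):
            expected = 1.0 / (dx[i] / (2e-12) + dx[j] / (2e-12))
            assert g == pytest.approx(expected, rel=1e-12)

    def test_2d_zero_lipid_thickness_rejected(self):
        with pytest.raises(InvalidGeometryError):
            SkinGeometry(lipid_thickness=0.0)

    def test_2d_grid_depth_and_phases(self):
        p = resolve_transport_params(_chem())
        geom = SkinGeometry(sc_cells=4, ve_cells=4, dermis_cells=4)
        grid = build_skin_grid(geom, p, "brick_mortar_2d")
        assert grid.total_depth == pytest.approx(geom.total_thickness, rel=1e-9)
        assert set(grid.phase[grid.layer == "sc"]) == {"lipid", "corneocyte"}

    def test_grid_refinement_converges(self):
        # refining 2x at >= 50 cells changes steady-state flux by < 0.5%
        p = resolve_transport_params(_chem())
        geom_a = SkinGeometry(sc_cells=25, ve_cells=13, dermis_cells=17)
        geom_b = SkinGeometry(sc_cells=50, ve_cells=26, dermis_cells=34)
        _, ja = build_skin_grid(geom_a, p).steady_state(10.0)
        _, jb = build_skin_grid(geom_b, p).steady_state(10.0)
        assert abs(ja - jb) / jb < 0.005

    def test_2d_homogeneous_limit_matches_1d(self):
        # corneocytes given lipid properties -> uniform medium; the 2D
        # staggered grid must reproduce the 1D slab flux
        k, d = 2.0, 1e-12
        p = TransportParams(k_lip=k, d_lip=d, k_cor=k, d_cor=d, k_sc=k, d_sc=d,
                            k_ve=k, d_ve=d, k_de=k, d_de=d)
        geom = SkinGeometry(sc_cells=10, ve_cells=10, dermis_cells=10)
        _, j1 = build_skin_grid(geom, p, "layered_1d").steady_state(10.0)
        _, j2 = build_skin_grid(geom, p, "brick_mortar_2d").steady_state(10.0)
        assert j2 == pytest.approx(j1, rel=1e-6)
        assert j2 == pytest.approx(d * k * 10.0 / geom.total_thickness, rel=1e-6)

    def test_2d_corneocytes_slow_transport(self):
        base = resolve_transport_params(_chem())
        geom = SkinGeometry(sc_cells=4, ve_cells=4, dermis_cells=4)
        grid = build_skin_grid(geom, base, "brick_mortar_2d")
        _, j_real = grid.steady_state(10.0)
        # replacing corneocytes by lipid opens the fast path -> more flux
        open_p = TransportParams(
            k_lip=base.k_lip, d_lip=base.d_lip, k_cor=base.k_lip, d_cor=base.d_lip,
            k_sc=base.k_sc, d_sc=base.d_sc, k_ve=base.k_ve, d_ve=base.d_ve,
            k_de=base.k_de, d_de=base.d_de,
        )
        _, j_open = build_skin_grid(geom, open_p, "brick_mortar_2d").steady_state(10.0)
        assert j_real < j_open


class TestDiffusionOperator:
    @pytest.fixture
    def uniform_grid(self):
        geom = SkinGeometry(sc_cells=5, ve_cells=5, dermis_cells=5)
        p = TransportParams(k_sc=2.0, d_sc=1e-12, k_ve=2.0, d_ve=1e-12,
                            k_de=2.0, d_de=1e-12)
        return build_skin_grid(geom, p)

    def test_uniform_activity_is_equilibrium(self, uniform_grid):
        conc = 3.0 * uniform_grid.k
        psi_top = 3.0
        dconc, j_top, j_bot = diffusion_rhs(uniform_grid, conc, psi_top, psi_rf=3.0)
        assert np.allclose(dconc, 0.0, atol=1e-20)
        assert j_top == pytest.approx(0.0, abs=1e-20)
        assert j_bot == pytest.approx(0.0, abs=1e-20)

    def test_closed_domain_conserves_mass(self, uniform_grid):
        rng = np.random.default_rng(7)
        conc = rng.uniform(0.1, 5.0, uniform_grid.n_cells)
        dconc, _, j_bot = diffusion_rhs(uniform_grid, conc, None, psi_rf=0.0)
        # add the bottom flux back: interior exchange alone must conserve
        total = np.sum(dconc * uniform_grid.volume) + j_bot
        assert abs(total) < 1e-16 * np.sum(np.abs(conc) * uniform_grid.volume)

    def test_state_dimension_mismatch(self, uniform_grid):
        with pytest.raises(Exception):
            diffusion_rhs(uniform_grid, np.zeros(3), 1.0)

    def test_membrane_steady_state_and_lag(self):
        # Crank's slab: J_ss = K D C/L ; t_lag = L^2/6D
        length, diff, part, c0 = 100e-6, 1e-12, 2.0, 10.0
        geom = SkinGeometry(
            sc_thickness=length / 3, ve_thickness=length / 3,
            dermis_thickness=length / 3, sc_cells=20, ve_cells=20, dermis_cells=20,
        )
        p = TransportParams(k_sc=part, d_sc=diff, k_ve=part, d_ve=diff,
                            k_de=part, d_de=diff)
        grid = build_skin_grid(geom, p)
        j_exact = diff * part * c0 / length
        lag_exact = length**2 / (6 * diff)

        def rhs(_t, y):
            dconc, _, j_bot = grid.rhs(y[:-1], c0, 0.0)
            return np.append(dconc, j_bot)

        t_end = 10 * lag_exact
        sol = solve_ivp(rhs, (0, t_end), np.zeros(grid.n_cells + 1),
                        method="BDF", rtol=1e-8, atol=1e-14)
        q_end = sol.y[-1, -1]
        j_end = rhs(t_end, sol.y[:, -1])[-1]
        lag_sim = t_end - q_end / j_end
        assert j_end == pytest.approx(j_exact, rel=0.01)
        assert lag_sim == pytest.approx(lag_exact, rel=0.01)


class TestSkinFlux:
    @pytest.fixture
    def grid_and_params(self):
        p = resolve_transport_params(_chem())
        grid = build_skin_grid(SkinGeometry(), p)
        return grid, p

    def test_empty_system_zero_flux(self, grid_and_params):
        grid, p = grid_and_params
        assert skin_flux(grid, np.zeros(grid.n_cells), 0.0, p) == 0.0

    def test_partition_equilibrium_zero_flux(self, grid_and_params):
        grid, p = grid_and_params
        c_veh = 7.0
        conc = np.zeros(grid.n_cells)
        conc[grid.top_idx] = grid.k[grid.top_idx] * c_veh / p.k_veh
        assert skin_flux(grid, conc, c_veh, p) == pytest.approx(0.0, abs=1e-18)

    def test_linear_in_vehicle_concentration(self, grid_and_params):
        grid, p = grid_and_params
        empty = np.zeros(grid.n_cells)
        j1 = skin_flux(grid, empty, 5.0, p)
        j2 = skin_flux(grid, empty, 10.0, p)
        assert j2 == pytest.approx(2.0 * j1, rel=1e-12)
        # back-diffusion: loaded skin against an empty vehicle
        loaded = np.ones(grid.n_cells)
        assert skin_flux(grid, loaded, 0.0, p) < 0.0
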