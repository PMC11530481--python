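"""Coupled evaporation + skin-absorption simulation of a finite-dose exposure.

The vehicle is a well-mixed liquid film losing each component i to the
atmosphere (evaporative flux J_evap,i) and the permeant to the skin
(J_skin).  The governing balances are

    dV/dt    = - sum_i J_evap,i A / rho_i                 (film shrinkage)
    d(V C_i)/dt = - J_evap,i A - J_skin,i A               (component mass)

which, expanded by the product rule, give the concentration form

    V dC_i/dt = - J_evap,i A + C_i sum_k J_evap,k A / rho_k - J_skin,i A.

The integrator works on the algebraically identical per-component *mass*
form (dm_i/dt = -J_evap,i A - J_skin,i A) together with dV/dt, which has no
1/V singularity at dry-down; the concentration form is exposed as
:func:`vehicle_rhs` and verified against the mass form in the tests.

The skin is the method-of-lines grid from :mod:`pbpke.skin`; the receptor
fluid is a well-mixed finite volume (or a perfect sink).  Everything is
integrated together with an adaptive stiff (BDF) solver.  The model is
deterministic throughout — the scenario ``seed`` exists only for interface
stability.

Dry-down handling: when a component's mass falls below the 1e-15 kg floor
its evaporative flux is zeroed; when the whole film volume falls below
1e-6 of its initial value the vehicle is frozen as a residue film — no
further evaporation, skin contact maintained with the residual
concentrations — and the event is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .chem import Chemical, Environment, FluxRecord, air_diffusivity, legacy_kevap
from .constants import R_GAS
from .errors import ConfigurationError, PBPKEError, SolverError
from .evaporation import MASS_FLOOR, MODES, VehicleState, component_fluxes
from .skin import (
    SkinGeometry,
    SkinGrid,
    TransportParams,
    build_skin_grid,
    resolve_transport_params,
)

__all__ = ["Scenario", "SimulationResult", "vehicle_rhs", "run_scenario", "mass_balance"]

#: Fraction of the initial film volume below which the vehicle freezes as residue.
RESIDUE_VOLUME_FRACTION = 1e-6

#: Mass scale (kg) of the smooth evaporative-flux roll-off near depletion.
MASS_SMOOTHING = 1e-13

#: Names of the tracked permeant compartments, in reporting order.
COMPARTMENTS = ("atmosphere", "vehicle", "sc", "ve", "dermis", "rf")


@dataclass
class Scenario:
    """One finite-dose IVPT exposure.

    ``vehicle`` lists (chemical, initial mass kg); ``permeant`` names the
    component whose skin absorption is tracked.  ``mode`` selects the
    evaporation model: ``mechanistic`` (PBPK-E), ``legacy`` (wind-speed
    mass-transfer coefficient) or ``occluded`` (no evaporation — the plain
    PBPK pathway; same code path with evaporative fluxes zero).
    """

    vehicle: list[tuple[Chemical, float]]
    permeant: str
    environment: Environment = field(default_factory=Environment)
    geometry: SkinGeometry = field(default_factory=SkinGeometry)
    transport_overrides: dict[str, float] = field(default_factory=dict)
    mode: str = "mechanistic"
    grid_mode: str = "layered_1d"
    duration: float = 86400.0
    rtol: float = 1e-6
    atol: float = 1e-12          # interpreted on the kg mass scale
    max_step: float = np.inf
    report_interval: float = 300.0
    seed: int | None = None      # unused: the model is deterministic

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError(f"duration must be > 0, got {self.duration}")
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        names = [chem.name for chem, _ in self.vehicle]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate vehicle components: {names}")
        if self.permeant not in names:
            raise ConfigurationError(
                f"permeant {self.permeant!r} is not a vehicle component ({names})"
            )
        if not any(m > 0 for _, m in self.vehicle):
            raise ConfigurationError("vehicle has no mass")

    @property
    def permeant_chemical(self) -> Chemical:
        for chem, _ in self.vehicle:
            if chem.name == self.permeant:
                return chem
        raise ConfigurationError(f"permeant {self.permeant!r} missing")  # pragma: no cover

    @property
    def dose(self) -> float:
        """Applied permeant mass, kg."""
        for chem, m in self.vehicle:
            if chem.name == self.permeant:
                return m
        raise ConfigurationError(f"permeant {self.permeant!r} missing")  # pragma: no cover

    def initial_volume(self) -> float:
        """Initial film volume from ideal (additive) partial volumes, m^3."""
        return float(sum(m / chem.density for chem, m in self.vehicle))


@dataclass
class SimulationResult:
    """Time series of the permeant's compartmental distribution plus diagnostics."""

    time: np.ndarray                         # s
    compartment_mass: dict[str, np.ndarray]  # kg of permeant per compartment
    dose: float                              # applied permeant mass, kg
    vehicle_masses: dict[str, np.ndarray]    # kg per vehicle component
    vehicle_volume: np.ndarray               # m^3
    evaporated: dict[str, np.ndarray]        # cumulative kg per component
    fluxes: list[list[FluxRecord]]           # per output time, per component
    skin_concentration: np.ndarray           # (n_cells, n_times), kg/m^3
    grid: SkinGrid
    events: list[dict]
    solver_stats: dict
    scenario: Scenario

    def compartment_percent(self, name: str) -> np.ndarray:
        return self.compartment_mass[name] / self.dose * 100.0

    def percentages(self) -> dict[str, np.ndarray]:
        return {c: self.compartment_percent(c) for c in COMPARTMENTS}

    def dermal_delivery_percent(self) -> np.ndarray:
        """VE + dermis + RF, % of dose — the headline absorption endpoint."""
        return (
            self.compartment_percent("ve")
            + self.compartment_percent("dermis")
            + self.compartment_percent("rf")
        )

    def mass_balance(self, t: float) -> dict[str, float]:
        """Per-compartment % of applied dose at time t (interpolated).

        Includes ``dermal_delivery`` = VE + dermis + RF and ``total``.
        """
        if not self.time[0] <= t <= self.time[-1]:
            raise ValueError(
                f"t={t} outside simulated range [{self.time[0]}, {self.time[-1]}]"
            )
        out = {
            c: float(np.interp(t, self.time, self.compartment_percent(c)))
            for c in COMPARTMENTS
        }
        out["dermal_delivery"] = out["ve"] + out["dermis"] + out["rf"]
        out["total"] = sum(out[c] for c in COMPARTMENTS)
        return out


def vehicle_rhs(
    state: VehicleState,
    fluxes: list[FluxRecord],
    j_skin: dict[str, float],
    area: float,
) -> tuple[dict[str, float], float]:
    """Concentration-form vehicle balance (product-rule expansion).

    Returns (dC_i/dt per component, dV/dt):

        V dC_i/dt = -J_evap,i A + C_i sum_k J_evap,k A / rho_k - J_skin,i A

    For a pure single volatile with no skin flux the two right-hand terms
    cancel exactly and C stays at the liquid density while V shrinks.
    """
    if state.volume <= 0:
        raise PBPKEError("vehicle depleted (V <= 0); switch to the residue-film regime")
    shrink = sum(f.j_mass * area / f.component.density for f in fluxes)
    dvdt = -shrink
    dcdt = {}
    for (chem, _), f in zip(state.components, fluxes):
        c = state.concentration(chem.name)
        js = j_skin.get(chem.name, 0.0)
        dcdt[chem.name] = (-f.j_mass * area + c * shrink - js * area) / state.volume
    return dcdt, dvdt


class _System:
    """Packs the coupled vehicle + skin + RF state for solve_ivp.

    Layout: [masses (nc), V, skin conc (ncell), m_rf, evaporated (nc)].
    """

    def __init__(self, scenario: Scenario, params: TransportParams, grid: SkinGrid):
        self.sc = scenario
        self.params = params
        self.grid = grid
        self.chems = [chem for chem, _ in scenario.vehicle]
        self.nc = len(self.chems)
        self.perm = next(
            i for i, c in enumerate(self.chems) if c.name == scenario.permeant
        )
        self.ncell = grid.n_cells
        env = scenario.environment
        self.mw = np.array([c.molar_mass_kg for c in self.chems])
        self.rho = np.array([c.density for c in self.chems])
        self.pvap = np.array([c.vapour_pressure for c in self.chems])
        self.m_amb = np.array([env.ambient_concentration(c) for c in self.chems])
        self.water_bidir = np.array(
            [c.is_water and env.allow_water_condensation for c in self.chems]
        )
        if scenario.mode == "mechanistic":
            self.transfer = np.array(
                [air_diffusivity(c, env) / env.donor_height for c in self.chems]
            )
        elif scenario.mode == "legacy":
            self.transfer = np.array([legacy_kevap(c, env) for c in self.chems])
        else:
            self.transfer = np.zeros(self.nc)
        self.rt = R_GAS * env.temperature
        self.area = scenario.geometry.area
        self.v0 = scenario.initial_volume()
        self.v_freeze = RESIDUE_VOLUME_FRACTION * self.v0
        self.rf_sink = scenario.geometry.rf_sink
        self.rf_volume = scenario.geometry.rf_volume

    # -- state packing -------------------------------------------------
    @property
    def n_state(self) -> int:
        return 2 * self.nc + self.ncell + 2

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n_state)
        for i, (_, m) in enumerate(self.sc.vehicle):
            y0[i] = m
        y0[self.nc] = self.v0
        return y0

    def unpack(self, y: np.ndarray):
        nc = self.nc
        masses = y[:nc]
        vol = y[nc]
        conc = y[nc + 1 : nc + 1 + self.ncell]
        m_rf = y[nc + 1 + self.ncell]
        evap = y[nc + 2 + self.ncell :]
        return masses, vol, conc, m_rf, evap

    # -- physics -------------------------------------------------------
    def evap_mass_fluxes(self, masses: np.ndarray) -> np.ndarray:
        """Per-component evaporative mass flux, kg m^-2 s^-1 (>= 0 outward)."""
        m = np.maximum(masses, 0.0)
        moles = m / self.mw
        total = moles.sum()
        if total <= 0:
            return np.zeros(self.nc)
        x = moles / total
        m_s = self.pvap * x / self.rt
        j_molar = self.transfer * (m_s - self.m_amb)
        j_molar = np.where((j_molar < 0) & ~self.water_bidir, 0.0, j_molar)
        # smooth depletion roll-off: Raoult's law keeps x (hence the flux) finite
        # for a pure component even as its mass vanishes into the skin, so a
        # hard cutoff would make the RHS discontinuous at zero mass
        j_molar = j_molar * (m / (m + MASS_SMOOTHING))
        j_molar = np.where(m <= MASS_FLOOR, 0.0, j_molar)
        return j_molar * self.mw

    def rhs(self, frozen: bool):
        """Right-hand side; ``frozen`` selects the residue-film regime."""

        def fun(_t: float, y: np.ndarray) -> np.ndarray:
            masses, vol, conc, m_rf, _ = self.unpack(y)
            j_mass = (
                np.zeros(self.nc) if frozen else self.evap_mass_fluxes(masses)
            )
            shrink = float(np.sum(j_mass * self.area / self.rho))

            v_contact = max(vol, self.v_freeze) if not frozen else self.v_freeze
            if v_contact > 0:
                c_veh = max(masses[self.perm], 0.0) / v_contact
                psi_top = c_veh / self.params.k_veh
            else:
                psi_top = None
            psi_rf = 0.0 if self.rf_sink else (m_rf / self.rf_volume) / self.params.k_rf

            dconc, j_top, j_bot = self.grid.rhs(conc, psi_top, psi_rf)

            dy = np.zeros_like(y)
            dy[: self.nc] = -j_mass * self.area
            dy[self.perm] -= j_top * self.area
            dy[self.nc] = 0.0 if frozen else -shrink
            dy[self.nc + 1 : self.nc + 1 + self.ncell] = dconc
            dy[self.nc + 1 + self.ncell] = j_bot * self.area
            dy[self.nc + 2 + self.ncell :] = j_mass * self.area
            return dy

        return fun

    def freeze_event(self):
        def event(_t: float, y: np.ndarray) -> float:
            return y[self.nc] - self.v_freeze

        event.terminal = True
        event.direction = -1.0
        return event

    def jac_sparsity(self) -> sp.lil_matrix:
        n = self.n_state
        nc, ncell = self.nc, self.ncell
        pat = sp.lil_matrix((n, n), dtype=bool)
        vehicle_block = list(range(nc)) + [nc]
        # evaporation couples every component mass (mole fractions) and V
        for i in vehicle_block + list(range(nc + 2 + ncell, n)):
            for j in vehicle_block:
                pat[i, j] = True
        cells = self.grid.connectivity()
        off = nc + 1
        ci, cj = cells.nonzero()
        for a, b in zip(ci, cj):
            pat[off + a, off + b] = True
        top = [off + int(i) for i in self.grid.top_idx]
        bot = [off + int(i) for i in self.grid.bot_idx]
        rf = nc + 1 + ncell
        for i in top:  # top cells see the vehicle concentration (m_perm, V)
            pat[i, self.perm] = True
            pat[i, nc] = True
        for i in bot:
            pat[i, rf] = True
            pat[rf, i] = True
        pat[rf, rf] = True
        for j in top:  # permeant mass sees the top-cell activities
            pat[self.perm, j] = True
        return pat

    def atol_vector(self, atol: float) -> np.ndarray:
        """Absolute tolerance on the kg scale, mapped onto concentration states."""
        v = np.full(self.n_state, atol)
        cell_vol = self.grid.volume * self.area
        v[self.nc + 1 : self.nc + 1 + self.ncell] = atol / cell_vol
        v[self.nc] = max(atol, 1e-9 * self.v0)
        return v


def run_scenario(scenario: Scenario) -> SimulationResult:
    """Integrate a scenario to its duration and assemble the mass balances."""
    params = resolve_transport_params(
        scenario.permeant_chemical, scenario.transport_overrides
    )
    grid = build_skin_grid(scenario.geometry, params, scenario.grid_mode)
    sys = _System(scenario, params, grid)

    t_grid = np.arange(0.0, scenario.duration, scenario.report_interval)
    t_grid = np.append(t_grid, scenario.duration)

    events: list[dict] = []
    segments = []
    stats = {"nfev": 0, "njev": 0, "segments": 0}
    sparsity = sys.jac_sparsity()
    atol = sys.atol_vector(scenario.atol)

    def integrate(t0, t1, y0, frozen):
        t_eval = t_grid[(t_grid > t0) & (t_grid <= t1)]
        sol = solve_ivp(
            sys.rhs(frozen),
            (t0, t1),
            y0,
            method="BDF",
            t_eval=t_eval if t_eval.size else None,
            events=None if frozen else [sys.freeze_event()],
            rtol=scenario.rtol,
            atol=atol,
            max_step=scenario.max_step,
            jac_sparsity=sparsity,
        )
        if sol.status == -1:
            raise SolverError(
                f"integrator failed: {sol.message}",
                last_time=sol.t[-1] if sol.t.size else t0,
                last_state=sol.y[:, -1] if sol.t.size else y0,
            )
        stats["nfev"] += sol.nfev
        stats["njev"] += sol.njev
        stats["segments"] += 1
        return sol

    y0 = sys.initial_state()
    sol = integrate(0.0, scenario.duration, y0, frozen=False)
    t_parts = [np.array([0.0])]
    y_parts = [y0[:, None]]
    if sol.t.size:
        t_parts.append(sol.t)
        y_parts.append(sol.y)

    if sol.status == 1:  # vehicle dried down to the residue threshold
        t_dry = float(sol.t_events[0][0])
        y_dry = sol.y_events[0][0]
        events.append({"type": "vehicle_dried", "time_s": t_dry, "component": None})
        t_parts.append(np.array([t_dry]))
        y_parts.append(y_dry[:, None])
        sol2 = integrate(t_dry, scenario.duration, y_dry, frozen=True)
        if sol2.t.size:
            t_parts.append(sol2.t)
            y_parts.append(sol2.y)

    t_all = np.concatenate(t_parts)
    y_all = np.concatenate(y_parts, axis=1)
    order = np.argsort(t_all, kind="stable")
    t_all, y_all = t_all[order], y_all[:, order]
    keep = np.concatenate([[True], np.diff(t_all) > 0])
    t_all, y_all = t_all[keep], y_all[:, keep]
    segments.append(sol)

    # -- assemble result -------------------------------------------------
    nc, ncell = sys.nc, sys.ncell
    masses = y_all[:nc]
    vol = y_all[nc]
    conc = y_all[nc + 1 : nc + 1 + ncell]
    m_rf = y_all[nc + 1 + ncell]
    evap = y_all[nc + 2 + ncell :]
    area = scenario.geometry.area

    comp = {
        "atmosphere": evap[sys.perm].copy(),
        "vehicle": masses[sys.perm].copy(),
        "sc": np.array([grid.layer_amount(conc[:, i], "sc", area) for i in range(t_all.size)]),
        "ve": np.array([grid.layer_amount(conc[:, i], "ve", area) for i in range(t_all.size)]),
        "dermis": np.array([grid.layer_amount(conc[:, i], "de", area) for i in range(t_all.size)]),
        "rf": m_rf.copy(),
    }

    # per-component dry-down events and solubility warnings (post-hoc scan)
    for i, chem in enumerate(sys.chems):
        if y_all[i, 0] > MASS_FLOOR:
            below = np.nonzero(masses[i] <= MASS_FLOOR)[0]
            if below.size:
                events.append(
                    {
                        "type": "component_drydown",
                        "time_s": float(t_all[below[0]]),
                        "component": chem.name,
                    }
                )
        if chem.solubility is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                c_series = np.where(vol > 0, masses[i] / np.maximum(vol, sys.v_freeze), 0.0)
            above = np.nonzero(c_series > chem.solubility)[0]
            if above.size:
                events.append(
                    {
                        "type": "solubility_exceeded",
                        "time_s": float(t_all[above[0]]),
                        "component": chem.name,
                    }
                )

    # flux records on the output grid (recomputed from state; diagnostics only)
    flux_series: list[list[FluxRecord]] = []
    frozen_after = next(
        (e["time_s"] for e in events if e["type"] == "vehicle_dried"), np.inf
    )
    for it, t in enumerate(t_all):
        state = VehicleState(
            components=[(c, max(float(masses[i, it]), 0.0)) for i, c in enumerate(sys.chems)],
            volume=max(float(vol[it]), 0.0),
        )
        if t >= frozen_after or state.total_mass() <= 0:
            flux_series.append(
                [FluxRecord(c, 0.0, 0.0, 0.0, 0.0, 0.0) for c in sys.chems]
            )
        else:
            flux_series.append(
                component_fluxes(state, scenario.environment, scenario.mode)
            )

    stats["method"] = "BDF"
    stats["n_cells"] = ncell
    stats["residue_film"] = any(e["type"] == "vehicle_dried" for e in events)

    return SimulationResult(
        time=t_all,
        compartment_mass=comp,
        dose=scenario.dose,
        vehicle_masses={c.name: masses[i].copy() for i, c in enumerate(sys.chems)},
        vehicle_volume=vol.copy(),
        evaporated={c.name: evap[i].copy() for i, c in enumerate(sys.chems)},
        fluxes=flux_series,
        skin_concentration=conc.copy(),
        grid=grid,
        events=events,
        solver_stats=stats,
        scenario=scenario,
    )


def mass_balance(result: SimulationResult, t: float) -> dict[str, float]:
    """Per-compartment % of applied dose at time t (see SimulationResult.mass_balance)."""
    return result.mass_balance(t)
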