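"""Configuration parsing, the 23-chemical fixture panel, templates, and result I/O.

Configs use the units the IVPT literature prints (mg/cm^2, cm, degC, h, %);
everything is converted to strict SI in one place (`_TO_SI`) on load and back
on dump.  The fixture panel transcribes the 23 volatile permeants of the
Cosmetics Europe / Hewitt IVPT study (name, CAS, MW, log Kow, vapour
pressure at ~32 degC); liquid densities are an auxiliary table of
approximate literature values (they enter only the molecular-radius estimate
and the film-volume bookkeeping, not the evaporation driving force).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chem import Chemical, Environment, water_saturation_pressure
from .errors import ConfigurationError, PBPKEError
from .simulate import COMPARTMENTS, Scenario, SimulationResult
from .skin import SkinGeometry

__all__ = [
    "PanelEntry",
    "table1_fixtures",
    "panel_names",
    "panel_chemical",
    "solvent_chemical",
    "load_scenario",
    "dump_scenario",
    "scenario_from_panel",
    "write_results",
    "read_results",
    "TEMPLATES",
]

# name, cas, mw (g/mol), log Kow, vapour pressure (Pa), vehicle, density (kg/m^3)
# The first five columns are the published panel values (digit for digit);
# densities are the auxiliary table (approximate literature liquid/solid values).
_PANEL_ROWS = [
    ("4-Tolunitrile", "104-85-8", 117.15, 1.58, 41.72, "PBS", 978.0),
    ("Acetophenone", "98-86-2", 120.15, 0.20, 52.90, "PBS", 1028.0),
    ("Aminophenol", "95-55-6", 109.13, 0.62, 0.01, "PBS", 1330.0),
    ("Benylidene Acetone", "122-57-6", 146.19, 2.07, 1.65, "PBS", 1038.0),
    ("Benzophenone (Ethanol)", "119-61-9", 182.22, 3.18, 0.26, "Ethanol", 1110.0),
    ("Benzophenone (PBS)", "119-61-9", 182.22, 3.18, 0.26, "PBS", 1110.0),
    ("Cinnamaldehyde", "14371-10-9", 132.16, 1.90, 5.12, "PBS", 1050.0),
    ("Diethylmaleate", "141-05-9", 172.18, 0.82, 14.00, "PBS", 1066.0),
    ("Dimethyl fumarate", "624-49-7", 144.13, 1.74, 40.00, "PBS", 1370.0),
    ("Dimethyl phthalate", "131-11-3", 194.19, 1.58, 0.41, "PBS", 1190.0),
    ("Ethylhexyl Acrylate", "103-11-7", 184.28, 4.20, 23.70, "PBS", 885.0),
    ("Eugenol", "97-53-0", 164.20, 2.27, 3.02, "PBS", 1067.0),
    ("Geraniol (Ethanol)", "106-24-1", 154.25, 3.56, 4.00, "Ethanol", 889.0),
    ("Geraniol (PBS)", "106-24-1", 154.25, 3.56, 4.00, "PBS", 889.0),
    ("Isoeugenol", "97-54-1", 164.20, 3.04, 1.60, "PBS", 1080.0),
    ("Methyl Methane sulfonate", "66-27-3", 110.13, 0.74, 55.20, "PBS", 1294.0),
    ("Methylisothiazolinone", "2682-20-4", 115.15, -0.10, 4.13, "PBS", 1250.0),
    ("Naphthalene", "91-20-3", 128.17, 3.30, 11.30, "PBS", 1140.0),
    ("Nitrobenzene", "98-95-3", 123.11, 1.85, 32.70, "PBS", 1199.0),
    ("Propylparaben (Ethanol)", "94-13-3", 180.20, 3.04, 0.24, "Ethanol", 1063.0),
    ("Tetramethyl thiuram disulfide", "137-26-8", 240.42, 1.73, 0.0023, "PBS", 1290.0),
    ("Thioglycolic Acid", "68-11-1", 92.11, 0.09, 11.60, "PBS", 1325.0),
    ("Vanillin", "121-33-5", 152.15, 1.19, 0.02, "PBS", 1056.0),
]


@dataclass(frozen=True)
class PanelEntry:
    """A fixture-panel chemical plus the vehicle it was applied in."""

    chemical: Chemical
    vehicle: str    # "PBS" or "Ethanol"


def table1_fixtures() -> list[PanelEntry]:
    """The 23-chemical volatile permeant panel (stable order)."""
    return [
        PanelEntry(
            Chemical(
                name=name, cas=cas, mw=mw, log_kow=log_kow,
                vapour_pressure=pvap, density=rho,
            ),
            vehicle,
        )
        for name, cas, mw, log_kow, pvap, vehicle, rho in _PANEL_ROWS
    ]


def panel_names() -> list[str]:
    return [row[0] for row in _PANEL_ROWS]


def panel_chemical(name: str) -> PanelEntry:
    for entry in table1_fixtures():
        if entry.chemical.name == name:
            return entry
    raise ConfigurationError(
        f"unknown chemical {name!r}; available panel chemicals: {panel_names()}"
    )


def solvent_chemical(name: str, temperature: float = 305.15) -> Chemical:
    """Vehicle solvent record: PBS (treated as water) or ethanol.

    Water's vapour pressure is evaluated from the Antoine equation at the
    scenario temperature; ethanol's near-32 degC value and both densities
    are documented auxiliary constants.
    """
    if name.lower() in ("pbs", "water"):
        return Chemical(
            name="water", cas="7732-18-5", mw=18.015, log_kow=-1.38,
            vapour_pressure=water_saturation_pressure(temperature),
            density=995.0, is_water=True,
        )
    if name.lower() == "ethanol":
        return Chemical(
            name="ethanol", cas="64-17-5", mw=46.07, log_kow=-0.31,
            vapour_pressure=11600.0, density=789.0,
        )
    raise ConfigurationError(f"unknown solvent {name!r}; expected 'PBS' or 'Ethanol'")


# ----------------------------------------------------------------------
# config schema
# ----------------------------------------------------------------------

#: Documented default exposure for the Hewitt-style finite-dose IVPT
#: reproduction.  Cell dimensions and doses are assumptions (the study's
#: exact per-chemical values live in its supplementary inputs): 1 cm^2
#: application area, 10 mg/cm^2 formulation load at 1% w/w permeant,
#: 1 cm donor chamber, 32 degC, 50% RH, unoccluded, 24 h, 5 mL receptor.
TEMPLATES: dict[str, dict] = {
    "hewitt_ivpt_default": {
        "vehicle_load_mg_per_cm2": 10.0,
        "dose_mg_per_cm2": 0.1,
        "area_cm2": 1.0,
        "donor_height_cm": 1.0,
        "temperature_c": 32.0,
        "relative_humidity_pct": 50.0,
        "duration_h": 24.0,
        "mode": "pbpk-e",
        "wind_speed_m_s": 0.2,
        "rf_volume_ml": 5.0,
        "rf_sink": False,
    }
}

_MODE_ALIASES = {
    "pbpk-e": "mechanistic",
    "mechanistic": "mechanistic",
    "pbpk": "occluded",
    "occluded": "occluded",
    "legacy": "legacy",
}
_MODE_NAMES = {"mechanistic": "pbpk-e", "occluded": "pbpk", "legacy": "legacy"}

_SCALAR_KEYS = {
    "template", "chemical", "vehicle", "vehicle_load_mg_per_cm2",
    "dose_mg_per_cm2", "area_cm2", "donor_height_cm", "temperature_c",
    "relative_humidity_pct", "duration_h", "mode", "wind_speed_m_s",
    "rf_volume_ml", "rf_sink", "grid_mode",
}
_DICT_KEYS = {"solver", "transport_overrides", "grid"}
_SOLVER_KEYS = {"rtol", "atol", "max_step"}
_GRID_KEYS = {"sc_cells", "ve_cells", "dermis_cells"}


def load_scenario(source: str | Path | dict) -> Scenario:
    """Build a validated SI :class:`Scenario` from a YAML file or dict.

    Missing keys are filled from the named template (default
    ``hewitt_ivpt_default``); every filled default is echoed to the
    ``pbpke.scenario`` logger.  Unknown keys are rejected with the offending
    names.
    """
    import logging

    log = logging.getLogger("pbpke.scenario")

    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config must be a mapping, got {type(cfg).__name__}")

    unknown = set(cfg) - _SCALAR_KEYS - _DICT_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    solver = dict(cfg.get("solver") or {})
    if set(solver) - _SOLVER_KEYS:
        raise ConfigurationError(
            f"unknown solver keys: {sorted(set(solver) - _SOLVER_KEYS)}"
        )
    grid_cfg = dict(cfg.get("grid") or {})
    if set(grid_cfg) - _GRID_KEYS:
        raise ConfigurationError(f"unknown grid keys: {sorted(set(grid_cfg) - _GRID_KEYS)}")

    template_name = cfg.get("template", "hewitt_ivpt_default")
    if template_name not in TEMPLATES:
        raise ConfigurationError(
            f"unknown template {template_name!r}; available: {sorted(TEMPLATES)}"
        )
    template = TEMPLATES[template_name]

    if "chemical" not in cfg:
        raise ConfigurationError("config must name a 'chemical'")
    entry = panel_chemical(cfg["chemical"])

    def get(key):
        if key in cfg:
            return cfg[key]
        value = template[key]
        log.info("default %s = %r (template %s)", key, value, template_name)
        return value

    vehicle_name = cfg.get("vehicle", entry.vehicle)
    if "vehicle" not in cfg:
        log.info("default vehicle = %r (panel annotation)", vehicle_name)

    t_kelvin = _num(get("temperature_c"), "temperature_c") + 273.15
    area = _num(get("area_cm2"), "area_cm2") * 1e-4
    dose = _num(get("dose_mg_per_cm2"), "dose_mg_per_cm2") * 1e-2 * area   # kg
    load = _num(get("vehicle_load_mg_per_cm2"), "vehicle_load_mg_per_cm2") * 1e-2 * area
    if dose <= 0 or load <= dose:
        raise ConfigurationError(
            f"need 0 < dose ({dose} kg) < vehicle load ({load} kg)"
        )
    mode_key = str(get("mode")).lower()
    if mode_key not in _MODE_ALIASES:
        raise ConfigurationError(
            f"unknown mode {mode_key!r}; expected one of {sorted(_MODE_ALIASES)}"
        )

    solvent = solvent_chemical(vehicle_name, t_kelvin)
    env = Environment(
        temperature=t_kelvin,
        relative_humidity=_num(get("relative_humidity_pct"), "relative_humidity_pct") / 100.0,
        donor_height=_num(get("donor_height_cm"), "donor_height_cm") * 1e-2,
        wind_speed=_num(get("wind_speed_m_s"), "wind_speed_m_s"),
    )
    geom = SkinGeometry(
        area=area,
        rf_volume=_num(get("rf_volume_ml"), "rf_volume_ml") * 1e-6,
        rf_sink=bool(get("rf_sink")),
        **{k: int(v) for k, v in grid_cfg.items()},
    )
    return Scenario(
        vehicle=[(entry.chemical, dose), (solvent, load - dose)],
        permeant=entry.chemical.name,
        environment=env,
        geometry=geom,
        transport_overrides=dict(cfg.get("transport_overrides") or {}),
        mode=_MODE_ALIASES[mode_key],
        grid_mode=cfg.get("grid_mode", "layered_1d"),
        duration=_num(get("duration_h"), "duration_h") * 3600.0,
        rtol=float(solver.get("rtol", 1e-6)),
        atol=float(solver.get("atol", 1e-12)),
        max_step=float(solver.get("max_step", np.inf)),
    )


def _num(value, key: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ConfigurationError(f"cannot parse {key} = {value!r} as a number") from None


def dump_scenario(scenario: Scenario) -> dict:
    """Inverse of :func:`load_scenario` for panel-based scenarios.

    Human-unit values are rounded to 9 decimals so that
    ``load_scenario(dump_scenario(s)) == s`` for any scenario built by
    :func:`load_scenario`.
    """
    names = [chem.name for chem, _ in scenario.vehicle]
    solvent = next(
        (c for c, _ in scenario.vehicle if c.name in ("water", "ethanol")), None
    )
    if solvent is None or len(names) != 2:
        raise ConfigurationError(
            "dump_scenario supports panel scenarios (permeant + one solvent)"
        )
    area = scenario.geometry.area
    dose = scenario.dose
    load = sum(m for _, m in scenario.vehicle)

    def r(x):
        return round(float(x), 9)

    cfg = {
        "chemical": scenario.permeant,
        "vehicle": "PBS" if solvent.name == "water" else "Ethanol",
        "dose_mg_per_cm2": r(dose / area * 1e2),
        "vehicle_load_mg_per_cm2": r(load / area * 1e2),
        "area_cm2": r(area * 1e4),
        "donor_height_cm": r(scenario.environment.donor_height * 1e2),
        "temperature_c": r(scenario.environment.temperature - 273.15),
        "relative_humidity_pct": r(scenario.environment.relative_humidity * 100.0),
        "duration_h": r(scenario.duration / 3600.0),
        "mode": _MODE_NAMES[scenario.mode],
        "wind_speed_m_s": r(scenario.environment.wind_speed),
        "rf_volume_ml": r(scenario.geometry.rf_volume * 1e6),
        "rf_sink": scenario.geometry.rf_sink,
        "grid_mode": scenario.grid_mode,
        "grid": {
            "sc_cells": scenario.geometry.sc_cells,
            "ve_cells": scenario.geometry.ve_cells,
            "dermis_cells": scenario.geometry.dermis_cells,
        },
        "solver": {
            "rtol": scenario.rtol,
            "atol": scenario.atol,
            "max_step": scenario.max_step,
        },
    }
    if scenario.transport_overrides:
        cfg["transport_overrides"] = dict(scenario.transport_overrides)
    return cfg


def scenario_from_panel(name: str, mode: str = "pbpk-e", **overrides) -> Scenario:
    """Default-template scenario for one panel chemical (vehicle per annotation)."""
    cfg = {"chemical": name, "mode": mode}
    cfg.update(overrides)
    return load_scenario(cfg)


# ----------------------------------------------------------------------
# result writers
# ----------------------------------------------------------------------

def write_results(result: SimulationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write tidy CSVs + a JSON run manifest; returns the paths written.

    Files: ``timeseries.csv`` (time_s, compartment, mass_kg, percent_dose),
    ``fluxes.csv`` (time_s, component, j_molar, j_mass, m_s,
    cumulative_evaporated_kg), ``profiles.csv`` (time_s, depth_m, layer,
    concentration) and ``manifest.json`` (mode, events, solver stats).
    """
    if result.time.size == 0:
        raise PBPKEError("refusing to write an empty result")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for name in COMPARTMENTS:
        mass = result.compartment_mass[name]
        pct = result.compartment_percent(name)
        for t, m, p in zip(result.time, mass, pct):
            rows.append((t, name, m, p))
    ts = pd.DataFrame(rows, columns=["time_s", "compartment", "mass_kg", "percent_dose"])
    ts_path = out / "timeseries.csv"
    ts.to_csv(ts_path, index=False, float_format="%.17g")

    frows = []
    for t, recs in zip(result.time, result.fluxes):
        for rec in recs:
            frows.append(
                (t, rec.component.name, rec.j_molar, rec.j_mass, rec.m_s,
                 result.evaporated[rec.component.name][
                     np.searchsorted(result.time, t)
                 ])
            )
    fx = pd.DataFrame(
        frows,
        columns=["time_s", "component", "j_molar", "j_mass", "m_s",
                 "cumulative_evaporated_kg"],
    )
    fx_path = out / "fluxes.csv"
    fx.to_csv(fx_path, index=False, float_format="%.17g")

    # depth profiles on a thinned time grid (hourly) to keep files small
    hourly = np.unique(
        np.searchsorted(result.time, np.arange(0, result.time[-1] + 1, 3600.0))
    )
    hourly = hourly[hourly < result.time.size]
    prows = []
    for it in hourly:
        for depth, layer, c in zip(
            result.grid.depth, result.grid.layer, result.skin_concentration[:, it]
        ):
            prows.append((result.time[it], depth, layer, c))
    pf = pd.DataFrame(prows, columns=["time_s", "depth_m", "layer", "concentration"])
    pf_path = out / "profiles.csv"
    pf.to_csv(pf_path, index=False, float_format="%.17g")

    manifest = {
        "mode": _MODE_NAMES[result.scenario.mode],
        "grid_mode": result.scenario.grid_mode,
        "permeant": result.scenario.permeant,
        "dose_kg": result.dose,
        "duration_s": result.scenario.duration,
        "events": result.events,
        "solver_stats": result.solver_stats,
        "scenario": dump_scenario(result.scenario)
        if len(result.scenario.vehicle) == 2
        else None,
        "final_mass_balance_pct": result.mass_balance(float(result.time[-1])),
    }
    mf_path = out / "manifest.json"
    with open(mf_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)

    return {"timeseries": ts_path, "fluxes": fx_path, "profiles": pf_path,
            "manifest": mf_path}


def read_results(out_dir: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read back (timeseries DataFrame, manifest dict) written by write_results."""
    out = Path(out_dir)
    ts = pd.read_csv(out / "timeseries.csv")
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    return ts, manifest
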