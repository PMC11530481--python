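"""Skin-side transport: QSPR parameter providers and the discretized skin domain.

The skin is a stack of three layers — stratum corneum (SC), viable epidermis
(VE) and dermis — above a well-mixed receptor-fluid (RF) compartment.  Each
cell of the finite-volume grid carries a diffusion coefficient D and a
partition coefficient K (phase/water); fluxes act on the thermodynamic
activity ``psi = C / K`` so that equilibrium across a phase boundary means
equal activity, not equal concentration.  The interface conductance between
adjacent cells i, j is the two-point series formula

    U_ij = 1 / (delta_i / (D_i K_i) + delta_j / (D_j K_j))

with delta the centroid-to-face distance, which reduces to the standard
harmonic-mean conductance when K = 1 everywhere.

Two discretizations expose the same operator interface:

* ``layered_1d`` — one column of cells; the SC carries homogenized effective
  parameters (series transcellular resistance in parallel with a tortuous
  intercellular lipid pathway).
* ``brick_mortar_2d`` — staggered corneocyte bricks embedded in lipid
  channels, laterally periodic, resolving the two SC microphases explicitly.

QSPR coefficient values live in one constants table (``QSPR``) and every
parameter can be overridden per chemical; the providers are pure functions
of (MW, log Kow).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .chem import Chemical, molecular_radius
from .constants import K_BOLTZMANN, WATER_VISCOSITY_32C
from .errors import ConfigurationError, InvalidGeometryError, PBPKEError

__all__ = [
    "TransportParams",
    "SkinGeometry",
    "SkinGrid",
    "qspr_sc_params",
    "qspr_viable_params",
    "resolve_transport_params",
    "build_skin_grid",
    "skin_flux",
    "diffusion_rhs",
    "QSPR",
]

# One version-stamped coefficient ledger for the lipid/corneocyte (SC) and
# viable-tissue QSPRs.  Forms: partition coefficients are power laws in Kow;
# diffusion coefficients decay with molecular size (radius in angstrom,
# derived from the liquid molar volume).  Override per chemical via
# `resolve_transport_params(..., overrides=...)` — overrides are first-class
# because coefficient sets differ between literature transcriptions.
QSPR = {
    "version": "2024.1",
    # SC lipid phase: K_lip = a * Kow^b ; D_lip = d0 * exp(-alpha * r_A^2)
    "lipid_partition_prefactor": 0.9,
    "lipid_partition_exponent": 0.69,
    "lipid_d0_m2s": 2.0e-9,
    "lipid_size_alpha_A2": 0.46,
    # SC corneocyte phase (hydrated keratin): K_cor = a * Kow^b ;
    # D_cor = D_aq * exp(-alpha * r_A)  (steric + binding hindrance)
    "cor_partition_prefactor": 5.6,
    "cor_partition_exponent": 0.27,
    "cor_hindrance_alpha_A": 3.0,
    # viable epidermis / dermis (single aqueous phase):
    # K_ve = a * Kow^b ; D_ve = D_aq / tortuosity
    "ve_partition_prefactor": 0.7,
    "ve_partition_exponent": 0.31,
    "ve_tortuosity": 2.6,
    # SC composition used by the 1D homogenization
    "sc_lipid_volume_fraction": 0.1,
    # tortuous intercellular pathway: vertical lipid area fraction / tortuosity
    "sc_intercellular_area_fraction": 0.002,
    "sc_intercellular_tortuosity": 13.0,
}

_OVERRIDE_KEYS = {
    "k_lip", "d_lip", "k_cor", "d_cor", "k_sc", "d_sc",
    "k_ve", "d_ve", "k_de", "d_de", "k_veh", "k_rf",
}


@dataclass(frozen=True)
class TransportParams:
    """Per-phase diffusion (m^2/s) and partition (phase/water) coefficients.

    Fields left ``None`` by the SC provider are filled by the viable-tissue
    provider and vice versa; :func:`resolve_transport_params` returns a fully
    populated record.
    """

    k_lip: float | None = None
    d_lip: float | None = None
    k_cor: float | None = None
    d_cor: float | None = None
    k_sc: float | None = None      # homogenized effective SC
    d_sc: float | None = None
    k_ve: float | None = None
    d_ve: float | None = None
    k_de: float | None = None      # dermis (== VE by the single-phase assumption)
    d_de: float | None = None
    k_veh: float = 1.0             # vehicle/water partition (1 for aqueous vehicles)
    k_rf: float = 1.0              # receptor fluid/water partition

    def __post_init__(self) -> None:
        for name in (
            "k_lip", "d_lip", "k_cor", "d_cor", "k_sc", "d_sc",
            "k_ve", "d_ve", "k_de", "d_de", "k_veh", "k_rf",
        ):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ConfigurationError(f"transport parameter {name} must be > 0, got {v}")


def _aqueous_diffusivity(chem: Chemical, temperature: float = 305.15) -> float:
    """Free aqueous diffusivity (m^2/s) by Stokes–Einstein in water."""
    r = molecular_radius(chem)
    return K_BOLTZMANN * temperature / (6.0 * math.pi * WATER_VISCOSITY_32C * r)


def _radius_angstrom(chem: Chemical) -> float:
    return molecular_radius(chem) * 1e10


def _require_log_kow(chem: Chemical) -> float:
    if chem.log_kow is None:
        raise ConfigurationError(
            f"{chem.name}: log_kow is required for QSPR parameter estimation "
            "(supply it or override the transport parameters)"
        )
    return chem.log_kow


def qspr_sc_params(chem: Chemical, overrides: dict[str, float] | None = None) -> TransportParams:
    """Stratum-corneum phase parameters (lipid, corneocyte, homogenized effective).

    Lipid partition is a power law in Kow; lipid diffusivity decays with the
    square of molecular radius.  Corneocyte partition reflects keratin
    binding; corneocyte diffusivity is the free aqueous value damped by a
    steric/binding hindrance factor.  The effective 1D (K_sc, D_sc) combines
    a series transcellular resistance with a parallel tortuous intercellular
    lipid pathway, volume-weighted by the SC lipid fraction.

    User overrides take precedence over every QSPR output.
    """
    overrides = _check_overrides(overrides)
    need_qspr = not {"k_sc", "d_sc"} <= overrides.keys() or not {
        "k_lip", "d_lip", "k_cor", "d_cor"
    } <= overrides.keys()
    if need_qspr and chem.log_kow is None and not (
        {"k_lip", "d_lip", "k_cor", "d_cor", "k_sc", "d_sc"} <= overrides.keys()
    ):
        _require_log_kow(chem)

    if {"k_lip", "d_lip", "k_cor", "d_cor", "k_sc", "d_sc"} <= overrides.keys():
        vals = {k: overrides[k] for k in ("k_lip", "d_lip", "k_cor", "d_cor", "k_sc", "d_sc")}
        return TransportParams(**vals)

    kow = 10.0 ** _require_log_kow(chem)
    r_a = _radius_angstrom(chem)
    k_lip = overrides.get(
        "k_lip", QSPR["lipid_partition_prefactor"] * kow ** QSPR["lipid_partition_exponent"]
    )
    d_lip = overrides.get(
        "d_lip", QSPR["lipid_d0_m2s"] * math.exp(-QSPR["lipid_size_alpha_A2"] * r_a**2)
    )
    k_cor = overrides.get(
        "k_cor", QSPR["cor_partition_prefactor"] * kow ** QSPR["cor_partition_exponent"]
    )
    d_cor = overrides.get(
        "d_cor",
        _aqueous_diffusivity(chem) * math.exp(-QSPR["cor_hindrance_alpha_A"] * r_a),
    )

    f_lip = QSPR["sc_lipid_volume_fraction"]
    k_sc = overrides.get("k_sc", f_lip * k_lip + (1.0 - f_lip) * k_cor)
    if "d_sc" in overrides:
        d_sc = overrides["d_sc"]
    else:
        dk_trans = 1.0 / (f_lip / (d_lip * k_lip) + (1.0 - f_lip) / (d_cor * k_cor))
        dk_inter = (
            QSPR["sc_intercellular_area_fraction"]
            / QSPR["sc_intercellular_tortuosity"]
            * d_lip
            * k_lip
        )
        d_sc = (dk_trans + dk_inter) / k_sc
    return TransportParams(k_lip=k_lip, d_lip=d_lip, k_cor=k_cor, d_cor=d_cor,
                           k_sc=k_sc, d_sc=d_sc)


def qspr_viable_params(chem: Chemical, overrides: dict[str, float] | None = None) -> TransportParams:
    """Viable epidermis / dermis parameters (identical by the single-phase assumption).

    Partition is a weak power law in Kow; diffusivity is the free aqueous
    Stokes–Einstein value reduced by a tissue tortuosity factor, hence
    decreasing in MW at fixed log Kow.
    """
    overrides = _check_overrides(overrides)
    if {"k_ve", "d_ve"} <= overrides.keys():
        k_ve, d_ve = overrides["k_ve"], overrides["d_ve"]
    else:
        kow = 10.0 ** _require_log_kow(chem)
        k_ve = overrides.get(
            "k_ve", QSPR["ve_partition_prefactor"] * kow ** QSPR["ve_partition_exponent"]
        )
        d_ve = overrides.get("d_ve", _aqueous_diffusivity(chem) / QSPR["ve_tortuosity"])
    k_de = overrides.get("k_de", k_ve)
    d_de = overrides.get("d_de", d_ve)
    return TransportParams(k_ve=k_ve, d_ve=d_ve, k_de=k_de, d_de=d_de)


def _check_overrides(overrides: dict[str, float] | None) -> dict[str, float]:
    overrides = dict(overrides or {})
    unknown = set(overrides) - _OVERRIDE_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown transport override keys {sorted(unknown)}; "
            f"allowed: {sorted(_OVERRIDE_KEYS)}"
        )
    return overrides


def resolve_transport_params(
    chem: Chemical, overrides: dict[str, float] | None = None
) -> TransportParams:
    """Fully populated transport parameters: QSPR defaults + user overrides."""
    overrides = _check_overrides(overrides)
    sc = qspr_sc_params(chem, overrides)
    ve = qspr_viable_params(chem, overrides)
    return replace(
        sc,
        k_ve=ve.k_ve, d_ve=ve.d_ve, k_de=ve.k_de, d_de=ve.d_de,
        k_veh=overrides.get("k_veh", 1.0),
        k_rf=overrides.get("k_rf", 1.0),
    )


@dataclass
class SkinGeometry:
    """Geometry of the diffusion-cell skin mount.

    Thicknesses in m, area in m^2, RF volume in m^3.  Brick-and-mortar
    parameters are consulted only in 2D mode.  Defaults describe dermatomed
    human skin on a Franz cell.
    """

    area: float = 1.0e-4                 # 1 cm^2
    sc_thickness: float = 20e-6
    ve_thickness: float = 80e-6
    dermis_thickness: float = 400e-6
    rf_volume: float = 5.0e-6            # 5 mL
    sc_cells: int = 20
    ve_cells: int = 10
    dermis_cells: int = 14
    rf_sink: bool = False
    # brick-and-mortar microstructure (2D mode)
    corneocyte_width: float = 40e-6
    corneocyte_height: float = 0.8e-6
    lipid_thickness: float = 75e-9
    brick_offset_frac: float = 0.5
    corneocyte_cells_z: int = 2

    def __post_init__(self) -> None:
        for name in ("area", "sc_thickness", "ve_thickness", "dermis_thickness",
                     "rf_volume", "corneocyte_width", "corneocyte_height",
                     "lipid_thickness"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("sc_cells", "ve_cells", "dermis_cells"):
            if getattr(self, name) < 2:
                raise InvalidGeometryError(f"{name} must be >= 2, got {getattr(self, name)}")
        if not 0.0 < self.brick_offset_frac < 1.0:
            raise InvalidGeometryError("brick_offset_frac must be in (0, 1)")

    @property
    def total_thickness(self) -> float:
        return self.sc_thickness + self.ve_thickness + self.dermis_thickness


@dataclass
class SkinGrid:
    """Finite-volume skin grid, normalized per unit (1 m^2) of skin area.

    ``volume`` is each cell's volume per m^2 of skin (m); interface and
    boundary conductances are specific conductances: multiplying an activity
    difference (kg/m^3) gives a flux in kg m^-2 s^-1 of skin.  ``layer``
    tags cells 'sc' / 've' / 'de' for mass accounting; ``phase`` additionally
    distinguishes 'lipid' / 'corneocyte' in 2D mode.
    """

    layer: np.ndarray            # (n,) str
    phase: np.ndarray            # (n,) str
    depth: np.ndarray            # (n,) centroid depth below vehicle contact, m
    volume: np.ndarray           # (n,) m^3 per m^2 skin
    d: np.ndarray                # (n,) m^2/s
    k: np.ndarray                # (n,) phase/water partition
    iface_i: np.ndarray          # (m,) int
    iface_j: np.ndarray          # (m,) int
    iface_g: np.ndarray          # (m,) specific conductance
    top_idx: np.ndarray          # cells in contact with the vehicle
    top_g: np.ndarray
    bot_idx: np.ndarray          # cells in contact with the RF
    bot_g: np.ndarray
    total_depth: float
    mode: str = "layered_1d"

    def __post_init__(self) -> None:
        if np.any(self.iface_g <= 0) or np.any(self.top_g <= 0) or np.any(self.bot_g <= 0):
            raise PBPKEError("interface conductances must be strictly positive")

    @property
    def n_cells(self) -> int:
        return self.volume.size

    def activity(self, conc: np.ndarray) -> np.ndarray:
        return conc / self.k

    def rhs(
        self,
        conc: np.ndarray,
        psi_top: float | None,
        psi_rf: float,
    ) -> tuple[np.ndarray, float, float]:
        """Method-of-lines right-hand side.

        Parameters
        ----------
        conc : per-cell concentration, kg/m^3.
        psi_top : vehicle-side activity C_veh/K_veh (None = no vehicle contact).
        psi_rf : receptor-side activity C_rf/K_rf (0 for a perfect sink).

        Returns
        -------
        dconc : per-cell dC/dt (kg m^-3 s^-1)
        j_top : flux from vehicle into skin, kg m^-2 s^-1 (positive into skin)
        j_bot : flux from skin into RF, kg m^-2 s^-1
        """
        if conc.shape != self.volume.shape:
            raise PBPKEError(
                f"state dimension mismatch: {conc.shape} vs {self.volume.shape}"
            )
        psi = conc / self.k
        flow = self.iface_g * (psi[self.iface_j] - psi[self.iface_i])
        dmass = np.zeros_like(conc)          # kg m^-2 s^-1 per cell
        np.add.at(dmass, self.iface_i, flow)
        np.add.at(dmass, self.iface_j, -flow)

        j_top = 0.0
        if psi_top is not None:
            top_flow = self.top_g * (psi_top - psi[self.top_idx])
            np.add.at(dmass, self.top_idx, top_flow)
            j_top = float(top_flow.sum())

        bot_flow = self.bot_g * (psi[self.bot_idx] - psi_rf)
        np.add.at(dmass, self.bot_idx, -bot_flow)
        j_bot = float(bot_flow.sum())

        return dmass / self.volume, j_top, j_bot

    def layer_amount(self, conc: np.ndarray, layer: str, area: float) -> float:
        """Mass (kg) held in one layer for a skin of the given area."""
        mask = self.layer == layer
        return float((conc[mask] * self.volume[mask]).sum() * area)

    def steady_state(self, psi_top: float, psi_rf: float = 0.0) -> tuple[np.ndarray, float]:
        """Steady-state concentrations and flux for fixed boundary activities.

        Solves the linear balance equations; returns (conc, flux kg m^-2 s^-1).
        """
        n = self.n_cells
        rows, cols, vals = [], [], []
        b = np.zeros(n)
        diag = np.zeros(n)

        for i, j, g in zip(self.iface_i, self.iface_j, self.iface_g):
            diag[i] += g
            diag[j] += g
            rows += [i, j]
            cols += [j, i]
            vals += [-g, -g]
        for i, g in zip(self.top_idx, self.top_g):
            diag[i] += g
            b[i] += g * psi_top
        for i, g in zip(self.bot_idx, self.bot_g):
            diag[i] += g
            b[i] += g * psi_rf

        rows += list(range(n))
        cols += list(range(n))
        vals += list(diag)
        a = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        psi = spla.spsolve(a, b)
        flux = float(np.sum(self.bot_g * (psi[self.bot_idx] - psi_rf)))
        return psi * self.k, flux

    def connectivity(self) -> sp.lil_matrix:
        """Sparsity pattern of the cell-to-cell coupling (incl. diagonal)."""
        n = self.n_cells
        pat = sp.lil_matrix((n, n), dtype=bool)
        pat.setdiag(True)
        for i, j in zip(self.iface_i, self.iface_j):
            pat[i, j] = True
            pat[j, i] = True
        return pat


def _series_conductance(area_frac, delta_i, dk_i, delta_j, dk_j) -> float:
    return area_frac / (delta_i / dk_i + delta_j / dk_j)


def build_skin_grid(
    geom: SkinGeometry, params: TransportParams, mode: str = "layered_1d"
) -> SkinGrid:
    """Discretize the skin domain.

    ``layered_1d`` uses the homogenized effective SC parameters; the 2D
    ``brick_mortar_2d`` mode resolves staggered corneocyte bricks inside
    lipid channels (laterally periodic) and needs the per-phase lipid and
    corneocyte parameters.
    """
    if mode == "layered_1d":
        return _build_1d(geom, params)
    if mode == "brick_mortar_2d":
        return _build_2d(geom, params)
    raise ConfigurationError(f"unknown grid mode {mode!r}")


def _require(params: TransportParams, names: list[str], mode: str) -> None:
    missing = [n for n in names if getattr(params, n) is None]
    if missing:
        raise ConfigurationError(f"{mode} grid requires transport params {missing}")


def _build_1d(geom: SkinGeometry, params: TransportParams) -> SkinGrid:
    _require(params, ["k_sc", "d_sc", "k_ve", "d_ve", "k_de", "d_de"], "layered_1d")
    widths, dd, kk, layer = [], [], [], []
    for n, thick, d, k, tag in (
        (geom.sc_cells, geom.sc_thickness, params.d_sc, params.k_sc, "sc"),
        (geom.ve_cells, geom.ve_thickness, params.d_ve, params.k_ve, "ve"),
        (geom.dermis_cells, geom.dermis_thickness, params.d_de, params.k_de, "de"),
    ):
        widths += [thick / n] * n
        dd += [d] * n
        kk += [k] * n
        layer += [tag] * n
    widths = np.asarray(widths)
    dd = np.asarray(dd)
    kk = np.asarray(kk)
    dk = dd * kk

    n = widths.size
    ii = np.arange(n - 1)
    jj = ii + 1
    g = 1.0 / (0.5 * widths[ii] / dk[ii] + 0.5 * widths[jj] / dk[jj])
    depth = np.cumsum(widths) - 0.5 * widths
    return SkinGrid(
        layer=np.asarray(layer),
        phase=np.asarray(layer).copy(),
        depth=depth,
        volume=widths,
        d=dd,
        k=kk,
        iface_i=ii,
        iface_j=jj,
        iface_g=g,
        top_idx=np.array([0]),
        top_g=np.array([dk[0] / (0.5 * widths[0])]),
        bot_idx=np.array([n - 1]),
        bot_g=np.array([dk[-1] / (0.5 * widths[-1])]),
        total_depth=float(widths.sum()),
        mode="layered_1d",
    )


def _build_2d(geom: SkinGeometry, params: TransportParams) -> SkinGrid:
    _require(params, ["k_lip", "d_lip", "k_cor", "d_cor", "k_ve", "d_ve",
                      "k_de", "d_de"], "brick_mortar_2d")
    w_cor, t_cor = geom.corneocyte_width, geom.corneocyte_height
    g_lip = geom.lipid_thickness
    width = w_cor + g_lip                      # lateral period

    offset = geom.brick_offset_frac * width
    if offset < g_lip or offset + g_lip > width:
        raise InvalidGeometryError(
            "brick_offset_frac places the offset lipid channel over the base channel"
        )
    # lateral edges resolve both channel positions ([0, g) and [offset, offset+g))
    x_edges = np.unique([0.0, g_lip, offset, offset + g_lip, width])
    dx = np.diff(x_edges)
    x_mid = 0.5 * (x_edges[:-1] + x_edges[1:])
    nx = dx.size

    # vertical layout of the SC: N x (lipid sheet + corneocyte row) + capping sheet,
    # scaled so the SC depth matches geom.sc_thickness exactly
    n_rows = max(1, round((geom.sc_thickness - g_lip) / (t_cor + g_lip)))
    scale = geom.sc_thickness / (n_rows * (t_cor + g_lip) + g_lip)
    t_cor_s, g_lip_s = t_cor * scale, g_lip * scale

    # z-slabs: (thickness, kind, row_index); kind in {lipid_sheet, cor_row, ve, de}
    slabs: list[tuple[float, str, int]] = []
    for row in range(n_rows):
        slabs.append((g_lip_s, "lipid_sheet", row))
        for _ in range(geom.corneocyte_cells_z):
            slabs.append((t_cor_s / geom.corneocyte_cells_z, "cor_row", row))
    slabs.append((g_lip_s, "lipid_sheet", n_rows))
    for _ in range(geom.ve_cells):
        slabs.append((geom.ve_thickness / geom.ve_cells, "ve", -1))
    for _ in range(geom.dermis_cells):
        slabs.append((geom.dermis_thickness / geom.dermis_cells, "de", -1))

    def channel_x(row: int) -> float:
        return 0.0 if row % 2 == 0 else offset

    layer, phase, vol, dd, kk, depth = [], [], [], [], [], []
    z_top = np.concatenate([[0.0], np.cumsum([s[0] for s in slabs])[:-1]])
    cell_id = np.full((len(slabs), nx), -1, dtype=int)
    for iz, (dz, kind, row) in enumerate(slabs):
        for ix in range(nx):
            if kind == "lipid_sheet":
                tag, d, k, lay = "lipid", params.d_lip, params.k_lip, "sc"
            elif kind == "cor_row":
                cx = channel_x(row)
                in_channel = cx <= x_mid[ix] < cx + g_lip
                if in_channel:
                    tag, d, k = "lipid", params.d_lip, params.k_lip
                else:
                    tag, d, k = "corneocyte", params.d_cor, params.k_cor
                lay = "sc"
            elif kind == "ve":
                tag, d, k, lay = "ve", params.d_ve, params.k_ve, "ve"
            else:
                tag, d, k, lay = "de", params.d_de, params.k_de, "de"
            cell_id[iz, ix] = len(vol)
            layer.append(lay)
            phase.append(tag)
            vol.append(dx[ix] * dz / width)
            dd.append(d)
            kk.append(k)
            depth.append(z_top[iz] + 0.5 * dz)

    vol = np.asarray(vol)
    dd = np.asarray(dd)
    kk = np.asarray(kk)
    dk = dd * kk
    dz_arr = np.asarray([s[0] for s in slabs])

    ii, jj, gg = [], [], []
    # vertical interfaces
    for iz in range(len(slabs) - 1):
        for ix in range(nx):
            a, b = cell_id[iz, ix], cell_id[iz + 1, ix]
            gg.append(_series_conductance(
                dx[ix] / width,
                0.5 * dz_arr[iz], dk[a],
                0.5 * dz_arr[iz + 1], dk[b],
            ))
            ii.append(a)
            jj.append(b)
    # lateral interfaces (periodic)
    for iz in range(len(slabs)):
        for ix in range(nx):
            ix2 = (ix + 1) % nx
            a, b = cell_id[iz, ix], cell_id[iz, ix2]
            gg.append(_series_conductance(
                dz_arr[iz] / width,
                0.5 * dx[ix], dk[a],
                0.5 * dx[ix2], dk[b],
            ))
            ii.append(a)
            jj.append(b)

    top_idx = cell_id[0, :]
    top_g = dx / width * dk[top_idx] / (0.5 * dz_arr[0])
    bot_idx = cell_id[-1, :]
    bot_g = dx / width * dk[bot_idx] / (0.5 * dz_arr[-1])

    return SkinGrid(
        layer=np.asarray(layer),
        phase=np.asarray(phase),
        depth=np.asarray(depth),
        volume=vol,
        d=dd,
        k=kk,
        iface_i=np.asarray(ii),
        iface_j=np.asarray(jj),
        iface_g=np.asarray(gg),
        top_idx=top_idx,
        top_g=top_g,
        bot_idx=bot_idx,
        bot_g=bot_g,
        total_depth=float(dz_arr.sum()),
        mode="brick_mortar_2d",
    )


def skin_flux(
    grid: SkinGrid,
    skin_state: np.ndarray,
    c_vehicle: float,
    params: TransportParams,
) -> float:
    """Vehicle -> skin mass flux, kg m^-2 s^-1 (negative = back-diffusion).

    ``J_skin = sum_top U_top (C_veh/K_veh - C_cell/K_cell)``: the driving
    force is the activity difference between the well-mixed vehicle and the
    uppermost SC cells.
    """
    psi_top = c_vehicle / params.k_veh
    psi = skin_state[grid.top_idx] / grid.k[grid.top_idx]
    return float(np.sum(grid.top_g * (psi_top - psi)))


def diffusion_rhs(
    grid: SkinGrid,
    skin_state: np.ndarray,
    psi_top: float | None,
    psi_rf: float = 0.0,
) -> tuple[np.ndarray, float, float]:
    """Module-level wrapper over :meth:`SkinGrid.rhs` (see its docstring)."""
    return grid.rhs(skin_state, psi_top, psi_rf)
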