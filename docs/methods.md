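# Methods

## Scope and model structure

`pbpke` models one finite-dose, unoccluded exposure on a diffusion cell as
two coupled subsystems:

1. **The vehicle film** — a well-mixed, multi-component liquid layer of
   volume `V` on area `A`. Each component evaporates with flux
   `J_evap = D_evap (M_s − M_a)/h`, where the surface gas concentration
   `M_s = P x_l a_l/(R T)` follows Raoult's law (ideal liquid, `a_l = 1`
   by default) and the ambient concentration `M_a` is zero for everything
   except water, whose value comes from relative humidity via the ideal
   gas law. Film shrinkage assumes ideal additive partial volumes,
   `dV/dt = −Σ J_evap,i A/ρ_i`; volume loss through skin permeation is
   neglected (the permeant is a small fraction of the film).
2. **The skin** — stratum corneum (SC), viable epidermis (VE) and dermis
   over a well-mixed receptor fluid (RF), discretized by a finite-volume
   method of lines. Inter-cell fluxes act on the activity `ψ = C/K` with
   the series two-point conductance `U_ij = 1/(δ_i/(D_iK_i) + δ_j/(D_jK_j))`,
   which preserves flux continuity across partition jumps and reduces to
   the harmonic-mean conductance for `K = 1`.

The two subsystems are advanced together as one ODE system (BDF, adaptive)
so that vehicle depletion, solvent dry-down and skin uptake interact
consistently. The integrator works on per-component *masses* plus `V`,
which is algebraically identical to the concentration-form balance
`V dC/dt = −J_evap A + C Σ J_evap A/ρ − J_skin A` but nonsingular at
dry-down; the concentration form is exposed (`simulate.vehicle_rhs`) and
cross-checked in the tests.

Three evaporation modes share this code path: `mechanistic` (the default,
vapour-pressure-driven diffusion), `legacy` (the EPA liquid-spill
wind-speed correlation `K_evap = 1.756e-5 P MW^(2/3) u^0.78/(R T)`), and
`occluded` (all evaporative fluxes zero). The occluded mode *is* the plain
no-evaporation PBPK pathway — comparisons between the two models are a
mode switch, never a separate implementation — and it is bit-identical to
the mechanistic mode when every component has `P = 0`.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| temperature | 305.15 | K | 32 °C skin-surface temperature |
| relative humidity | 0.5 | — | affects water only |
| donor height `h` | 0.01 | m | vehicle surface → top of donor wall |
| air viscosity `η` | 1.89e-5 | Pa·s | air near 32 °C; overridable |
| wind speed `u` | 0.2 | m/s | legacy mode only (free convection) |
| area `A` | 1e-4 | m² | 1 cm² |
| SC / VE / dermis thickness | 20 / 80 / 400 | µm | dermatomed skin |
| RF volume | 5 | mL | well-mixed; perfect sink by flag |
| grid | 20 / 10 / 14 | cells | SC / VE / dermis (1D default) |
| rtol / atol | 1e-6 / 1e-12 | — / kg | atol mapped onto concentration states by cell volume |
| report interval | 300 | s | output grid; event times added |

Molecular radius, when not supplied, is the sphere-equivalent of the
liquid molar volume, `r = (3 (MW/1000)/(4π ρ N_A))^(1/3)` — it uses only
fields every chemical record already carries. Water's saturation pressure
defaults to the classic Antoine correlation (8.07131, 1730.63, 233.426 in
mmHg/°C form), overridable per environment.

### Gas diffusivity

`D_evap` is Stokes–Einstein with the viscosity of *air*, as the
mechanistic formulation prescribes. This is a deliberate, documented
choice: Stokes–Einstein is a liquid-phase hydrodynamic result, and with
air viscosity it yields values (~3e-8 m²/s for a 120 Da permeant) two
orders of magnitude below tabulated experimental gas-phase diffusivities
(~1e-5 m²/s). Default-scenario evaporated fractions are correspondingly
conservative. Users who want tabulated or Chapman–Enskog-scale
diffusivities set the per-chemical `d_air` override; several tests use
`d_air = 1e-5 m²/s` precisely to exercise the regime where evaporation
visibly competes with absorption. No other part of the model depends on
this choice.

### Skin QSPRs

This package's transport QSPRs live in one version-stamped constants table
(`pbpke.skin.QSPR`) and are pure functions of (MW, log K_ow):

- SC lipid: `K_lip = 0.9 K_ow^0.69`; `D_lip = 2e-9 exp(−0.46 r_Å²)` m²/s.
- SC corneocyte: `K_cor = 5.6 K_ow^0.27` (keratin binding);
  `D_cor = D_aq exp(−3.0 r_Å)` (steric/binding hindrance of the free
  aqueous diffusivity).
- VE and dermis share one set (single-phase assumption):
  `K_ve = 0.7 K_ow^0.31`; `D_ve = D_aq / 2.6`.

with `D_aq` the Stokes–Einstein value in water at 32 °C. The hindrance
exponent was chosen so that the resulting SC permeability for a mid-range
permeant (MW ≈ 120, log K_ow ≈ 1.6) lands on the Potts–Guy scale
(~5e-3 cm/h). Because published QSPR coefficient sets differ between
transcriptions, **every parameter is overridable per chemical** and the
test suite pins property-level behaviour (monotonicity in log K_ow and MW,
override precedence, VE ≡ dermis) rather than specific coefficients.

The 1D default homogenizes the SC: capacity-weighted partition
`K_sc = f_lip K_lip + (1−f_lip) K_cor` (lipid fraction 0.1) and a
conductivity that combines the series transcellular path with a parallel
tortuous intercellular lipid pathway (area fraction 0.002, tortuosity 13).
The 2D `brick_mortar_2d` grid instead resolves staggered corneocyte bricks
(40 × 0.8 µm) in 75 nm lipid channels, laterally periodic with a
half-period offset per layer; it exposes the same operator interface and
collapses to the 1D solution when both phases are given equal properties.

## Numerical choices and degenerate inputs

- **Sign convention.** `J_evap` is stored as a positive outward magnitude;
  the balances subtract it. Net condensation is clamped to zero except for
  water with the `allow_water_condensation` flag (humid ambient above a
  dilute film's water activity).
- **Dry-down.** A component's evaporative flux rolls off smoothly below
  ~1e-13 kg (`m/(m + 1e-13)`) — for a pure component Raoult's law keeps
  the flux finite as mass vanishes into the skin, and a hard cutoff would
  make the right-hand side discontinuous — and is zeroed below the 1e-15 kg
  floor. When the film volume falls below 1e-6 of its initial value a
  terminal event fires, the vehicle is frozen as a residue film (no further
  evaporation; skin contact continues at the residual concentrations), and
  the event is recorded in the result and manifest. Per-component dry-down
  and solubility-exceeded warnings are logged from the output series.
- **Conservation.** The right-hand side sums exactly to zero over
  {vehicle, atmosphere, skin cells, RF}, so the integrator preserves the
  total to round-off; mass-balance closure is asserted at 0.1 % in the
  tests and is typically ~1e-6 %.
- **Jacobian sparsity** for the BDF solver is assembled from the grid
  connectivity plus the vehicle coupling, keeping 24 h panel runs below a
  second each.
- Empty vehicles signal `EmptyVehicleError` (mole fractions undefined);
  non-physical records and unknown config keys fail loudly at
  construction/parse time.

## What the fixture panel does and does not represent

The 23-chemical panel encodes the published identities (name, CAS, MW,
log K_ow, vapour pressure, application vehicle) of the volatile permeants
from the Cosmetics Europe finite-dose IVPT dataset. Liquid densities and
solvent properties are an auxiliary table of approximate literature
values. The default exposure template (1 cm², 10 mg/cm² formulation at 1 %
w/w permeant, 1 cm donor height, 32 °C, 50 % RH, 24 h, 5 mL receptor) is a
documented *assumption*: the study's exact per-cell doses and dimensions
are not in its main text and must be supplied per chemical (e.g. via
`pbpke batch --inputs`) for a faithful reproduction. Consequently the
package's panel outputs demonstrate the model's mechanics and internal
consistency — conservation, mode equivalences, monotonicity in vapour
pressure — not agreement with the experimental mass balances, which also
requires the experimental observation table that ships with the original
study's supplementary material.

## Evaluation conventions

R² is reported in two conventions, squared Pearson correlation (default)
and 1 − SS_res/SS_tot about the identity line, because published
comparisons rarely state which they use and the two differ whenever
predictions are biased. The volatility screen classifies a chemical as
volatile when its experimental recovery (sum of recovered compartments,
atmosphere excluded) is strictly below 90 %; observed "mass loss" for
atmosphere comparisons is 100 − recovery.

## Known limitations

- No skin metabolism, keratin-binding kinetics, appendageal transport, or
  precipitation physics (supersaturation only raises a warning event).
- Activity coefficients default to 1; non-ideal vehicles require
  user-supplied `a_l`.
- The ambient above the donor chamber is a perfect sink at height `h` for
  the whole exposure; vapour build-up in the chamber is not modelled.
- Vapour pressure is taken at scenario temperature; no
  temperature-dependence model is included.
- Single-permeant skin transport: co-permeation of multiple solutes is not
  currently coupled (solvents evaporate but do not permeate).
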