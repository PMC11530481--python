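# pbpke — dermal absorption of volatile chemicals with mechanistic evaporation

`pbpke` simulates the competition between **evaporation** and **skin
permeation** when a finite dose of a volatile chemical is applied,
unoccluded, to skin mounted in a diffusion cell (an *in-vitro* permeation
test, IVPT). It is aimed at researchers in percutaneous absorption,
cosmetic/pharmaceutical safety assessment and dermal exposure modelling who
need fully predictive (no-fitting) estimates of where an applied dose ends
up after 24 h: lost to the atmosphere, left in the vehicle, held in the
stratum corneum (SC), viable epidermis (VE) or dermis, or delivered to the
receptor fluid (RF).

## The model

Evaporation is treated as Fickian diffusion through the stagnant air column
of the donor chamber rather than through an empirical wind-speed transfer
coefficient. For each vehicle component,

```
J_evap = D_evap (M_s − M_a) / h            (evaporative flux, outward)
M_s    = P x_l a_l / (R T)                 (Raoult's law + ideal gas)
D_evap = k_B T / (6 π η r)                 (Stokes–Einstein in air)
```

where `P` is the pure-component vapour pressure, `x_l` its liquid mole
fraction, `a_l` the activity coefficient (1 for ideal vehicles), `h` the
donor-chamber height and `r` a sphere-equivalent molecular radius. The
legacy wind-speed correlation
`K_evap = 1.756e-5 P MW^(2/3) u^0.78 / (R T)` is retained as a selectable
`legacy` mode, and `occluded` mode disables evaporation entirely — that is
the plain PBPK pathway, as a mode switch on the same code path.

The shrinking multi-component film is coupled to the skin through the
vehicle mass balances (ideal additive volumes; permeation volume loss
neglected):

```
dV/dt     = − Σ_i J_evap,i A / ρ_i
V dC_i/dt = − J_evap,i A + C_i Σ_k J_evap,k A / ρ_k − J_skin,i A
```

Skin transport is a finite-volume method-of-lines discretization of
diffusion through SC, VE and dermis into a well-mixed RF, with fluxes
driven by activity differences `ψ = C/K` so that partitioning between
phases is honoured. Partition and diffusion coefficients come from QSPRs
in (MW, log K_ow) — every value user-overridable — with the SC available
either as a homogenized 1D layer (default) or as an explicit 2D
brick-and-mortar corneocyte/lipid microstructure. The whole system is
integrated with an adaptive stiff (BDF) solver, with event handling for
solvent dry-down and a residue-film regime afterwards.

## Worked example

```
pbpke run --config examples/tolunitrile.yaml --out results/tolunitrile
```

simulates 0.1 mg/cm² of 4-tolunitrile in 10 µL/cm² PBS on 1 cm² of skin at
32 °C for 24 h, and prints the final six-compartment mass balance:

```
simulated 4-Tolunitrile for 24.0 h (pbpk-e mode)
  atmosphere          0.008 % of dose
  vehicle             0.343 % of dose
  sc                  0.867 % of dose
  ve                  0.338 % of dose
  dermis              1.682 % of dose
  rf                 96.763 % of dose
  dermal_delivery    98.782 % of dose
```

The six compartments always sum to 100 % of the applied dose (the dose is
the only source); `dermal_delivery` = VE + dermis + RF is the headline
absorption endpoint. Full kinetics (`timeseries.csv`), per-component
evaporative fluxes (`fluxes.csv`), depth–concentration profiles
(`profiles.csv`) and a run manifest with events and solver statistics are
written to the output directory.

The same thing from Python:

```python
from pbpke import scenario_from_panel, run_scenario

result = run_scenario(scenario_from_panel("4-Tolunitrile"))
print(result.mass_balance(86400.0))
```

Batch the whole 23-chemical volatile panel and score predictions against
experimental mass balances:

```
pbpke batch --panel table1 --mode pbpk-e --out results/
pbpke batch --panel table1 --mode pbpk   --out results/
pbpke evaluate --pred results/summary_pbpk-e.csv \
               --pred-pbpk results/summary_pbpk.csv \
               --obs observations.csv --out report.csv
```

`observations.csv` follows `examples/observations_template.csv`
(per-chemical recovery and compartment percentages); the report gives
per-compartment R² for each model in both the Pearson and identity-line
conventions. Per-chemical exposure conditions can be supplied to `batch`
via `--inputs` (CSV or XLSX, layout in `examples/inputs_template.csv`).

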