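# Finite-dose, unoccluded exposure of 4-tolunitrile in PBS on a Franz cell.
# Any key omitted here is filled from the hewitt_ivpt_default template.
chemical: 4-Tolunitrile
mode: pbpk-e          # pbpk-e | pbpk | legacy
duration_h: 24
temperature_c: 32
relative_humidity_pct: 50
dose_mg_per_cm2: 0.1
vehicle_load_mg_per_cm2: 10
area_cm2: 1.0
donor_height_cm: 1.0
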