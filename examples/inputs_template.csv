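chemical,dose_mg_per_cm2,vehicle_load_mg_per_cm2,area_cm2,donor_height_cm,temperature_c,relative_humidity_pct,duration_h
4-Tolunitrile,0.1,10,1.0,1.0,32,50,24
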