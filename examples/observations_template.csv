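chemical,recovery_pct,vehicle_pct,sc_pct,ve_pct,dermis_pct,rf_pct
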