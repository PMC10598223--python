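component,healthy_lo,healthy_hi,oa_lo,oa_hi,ra_lo,ra_hi,units
protein,10,30,24,44,27,63,mg/ml
hyaluronic_acid,2,4,0.5,1.0,0.1,0.9,mg/ml
phospholipids,0.1,0.1,0.1,0.5,0.4,0.8,mg/ml
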