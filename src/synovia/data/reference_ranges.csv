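population,n_samples,eta0_lo,eta0_hi,c_lo,c_hi,d,ha_mg_ml,reliable,note
normal_dintenfass,2,20,,10,,0.75,4.1,true,zero-shear viscosity and consistency reported only as lower bounds
normal_review,,10,340,,,,1.0,true,consistency and rate index not reported
postmortem,,6,12,40,100,0.7,2.4,true,
oa,4,,,1,1,0.6,0.9,false,zero-shear viscosity range typographically garbled in source table
ra,2,,,,,0.0,0.7,false,zero-shear viscosity not recoverable from source table; reported as Newtonian (d=0)
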