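# Absorption coefficient of pure water in the near infrared,
# interpolated from the standard Hale & Querry / Segelstein lineage
# tabulations. Units: cm^-1. Used for the background (label 0) medium.
wavelength_nm,mua_cm
700,0.0060
750,0.0262
800,0.0196
850,0.0433
900,0.0679
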