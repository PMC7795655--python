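# Molar extinction coefficients of human hemoglobin in the near infrared.
# Compiled from the standard OMLC (Prahl) tabulation of oxy- and
# deoxyhemoglobin; units are cm^-1 / (mol/L), base-10 convention
# (mu_a = ln(10) * epsilon * c when concentrations are molar).
# Rows at 750 and 850 nm are the values used by the default probe;
# intermediate wavelengths are provided for interpolation only.
wavelength_nm,eps_hbo2,eps_hbr
700,290.0,1794.28
750,518.0,1405.24
800,816.0,761.84
850,1058.0,691.32
900,1198.0,761.84
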