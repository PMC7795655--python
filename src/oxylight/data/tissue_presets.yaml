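# Named optical-property presets (mu_a and reduced scattering mu_s', 1/cm;
# Henyey-Greenstein anisotropy g) for the media used with the default probe.
# The mouse_thigh preset lists two rows tagged 850 nm, exactly as published
# in its source; loading it emits a warning and the caller must state which
# row stands for which wavelength.
anisotropy_g: 0.9
presets:
  soft_tissue_phantom:
    - {wavelength_nm: 750, mua_cm: 0.101, musp_cm: 10.5}
    - {wavelength_nm: 850, mua_cm: 0.089, musp_cm: 9.0}
  mouse_thigh:
    - {wavelength_nm: 850, mua_cm: 0.76, musp_cm: 5.3}
    - {wavelength_nm: 850, mua_cm: 0.64, musp_cm: 4.8}
  human_forearm:
    - {wavelength_nm: 750, mua_cm: 0.41, musp_cm: 7.2}
    - {wavelength_nm: 850, mua_cm: 0.30, musp_cm: 6.5}
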