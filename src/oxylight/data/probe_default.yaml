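# Default dual-wavelength LED/ultrasound probe (commercial LED-array system geometry).
# Two 50 x 10 mm LED units flank the linear transducer array, inclined at
# 41.4 degrees toward the imaging plane, each carrying four element rows
# (two 36-element rows at 850 nm, two 24-element rows at 750 nm).
unit_length_mm: 50.0
unit_width_mm: 10.0
tilt_angle_deg: 41.4
unit_standoff_mm: 0.15
inter_unit_gap_mm: 9.56
element_pitch_mm: 1.4
row_pitch_mm: 1.72
# Row order runs from the unit's outer (shallow) edge toward the advanced
# (deep) edge; wavelengths alternate with 850 nm first.
rows_per_unit:
  - [850, 36]
  - [750, 24]
  - [850, 36]
  - [750, 24]
cone_full_angle_deg: 120.0
pulse_energy_uJ:
  850: 200.0
  750: 100.0
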