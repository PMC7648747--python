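# Nonpregnant adult female reference physiology (ICRP-style reference
# values). Volumes are fractions of body weight (assuming unit tissue
# density, kg == L); flows are fractions of cardiac output. The richly
# perfused lump covers brain, heart, kidneys, lungs and spleen; the slowly
# perfused lump covers muscle, skin, adipose and bone.
body_weight_kg: 60.0
cardiac_output_L_h: 354.0
liver_mass_g: 1400.0
mppgl_mg_g: 40.0
fractional_volumes:
  plasma: 0.040
  gut: 0.01833
  liver: 0.02333
  richly_perfused: 0.055
  slowly_perfused: 0.700
fractional_flows:
  gut: 0.150
  liver_arterial: 0.065
  richly_perfused: 0.440
  slowly_perfused: 0.345
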