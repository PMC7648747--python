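# Gestational-age dependent physiology, parameterized against published
# longitudinal pregnancy data. Polynomials are in gestational age (weeks):
# value(GA) = offset + c1*GA + c2*GA^2 + ... ; "ratio" quantities have
# offset 1 (multiplier on the nonpregnant value), "gain" quantities have
# offset 0 (additive change). CYP activity multipliers use either a
# polynomial or a saturating Emax form 1 + emax*GA^h/(ga50^h + GA^h).
#
# The curves reproduce, at term-relevant gestational ages: ~12.5 kg total
# weight gain, ~45% plasma-volume expansion, ~31% cardiac-output increase,
# ~5 L combined placental-fetal-amniotic volume, ~3.4 kg maternal fat gain,
# ~27% fall in serum albumin, ~2x CYP3A4 activity and ~3x CYP2D6 activity.
body_weight_gain_kg:
  offset: 0.0
  coeffs: [0.125, 0.0047]
plasma_volume_ratio:
  offset: 1.0
  coeffs: [0.00325, 0.0002]
cardiac_output_ratio:
  offset: 1.0
  coeffs: [0.0145, -0.000166]
placental_fetal_volume_L:
  offset: 0.0
  coeffs: [0.0, 0.0, 7.8e-05]
fat_gain_kg:
  offset: 0.0
  coeffs: [0.0, 0.0021]
albumin_ratio:
  offset: 1.0
  coeffs: [-0.0036736197, -7.866167e-05]
cyp_activity:
  CYP3A4:
    form: emax
    emax: 1.2972
    ga50: 25.0
    hill: 2.459
  CYP2D6:
    form: polynomial
    offset: 1.0
    coeffs: [0.05]
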