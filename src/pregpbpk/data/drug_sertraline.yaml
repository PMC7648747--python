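# Sertraline parameter set.
#
# Physicochemical constants (molecular weight, logP, pKa) are the DrugBank
# values for sertraline. fu0 is the experimentally measured fraction unbound
# in nonpregnant plasma (sertraline is 98.5% protein bound). fu_mic = 1 is
# assumed for the recombinant-CYP incubations.
#
# cyp_kinetics is a SYNTHETIC stand-in for the recombinant-CYP in vitro
# kinetic table: the original per-enzyme Vmax/ISEF values are not publicly
# tabulated, so Vmax values here were back-calculated so that the IVIVE
# chain (Vmax/S * ISEF * abundance * MPPGL * liver mass) reproduces the
# reported per-enzyme contributions to total sertraline hepatic intrinsic
# clearance (CYP3A4/2B6/2C9/2C19/2D6 = 73/9/8/7/3 %). Abundances are
# standard mean hepatic CYP abundances (pmol per mg microsomal protein) in
# adults; ISEFs are typical recombinant-to-microsome conversion factors.
#
# absorption / enterohepatic / calibration hold the model constants fitted
# once against the nonpregnant steady-state plasma profile (200 mg daily for
# 30 days) and frozen thereafter.
name: sertraline
molecular_weight_g_mol: 306.23
logp: 5.29
pka: 9.16
fu0: 0.015
fu_mic: 1.0
blood_plasma_ratio: 1.0
tablet_strengths_mg: [25.0, 50.0, 100.0]
substrate_conc_um: 0.5
cyp_kinetics:
  CYP3A4:  {vmax_pmol_min_pmol: 5.000, isef: 0.30, abundance_pmol_mg: 137.0, gestational_scaling: true}
  CYP2B6:  {vmax_pmol_min_pmol: 2.980, isef: 0.50, abundance_pmol_mg: 17.0,  gestational_scaling: false}
  CYP2C9:  {vmax_pmol_min_pmol: 0.514, isef: 0.60, abundance_pmol_mg: 73.0,  gestational_scaling: false}
  CYP2C19: {vmax_pmol_min_pmol: 2.814, isef: 0.50, abundance_pmol_mg: 14.0,  gestational_scaling: false}
  CYP2D6:  {vmax_pmol_min_pmol: 1.508, isef: 0.70, abundance_pmol_mg: 8.0,   gestational_scaling: true}
absorption:
  ka_max_per_h: 0.236
  tau_a_h: 3.33
enterohepatic:
  cl_bile_L_h: 600.0
  k_empty_per_h: 0.25
calibration:
  clint_scalar: 2.2796
  kp_adjustment:
    gut: 1.0
    liver: 1.0
    richly_perfused: 3.0
    slowly_perfused: 4.24
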