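# Methods

## Model structure

The engine integrates eight state variables (amounts, µg): gut lumen,
gallbladder, gut tissue, liver, plasma, lumped richly perfused tissue, lumped
slowly perfused tissue, and cumulative metabolized mass. All tissues are
perfusion-limited: uptake is flow-limited with venous blood leaving each
tissue at `C_tissue / Kp`. The liver receives hepatic-arterial blood plus the
gut venous outflow (portal route), so absorbed drug undergoes first-pass
metabolism. Internal units are µg / L / h; doses are mg at the interface.

The system is linear in the amounts. Two exact consequences are used
throughout the package and its tests: dose proportionality of all
concentrations, and the steady-state identity `CL/F = fu · CLint_u` (shown by
integrating the gut and liver balances over a dosing interval: the integral
of the liver venous-equivalent concentration equals the plasma AUC). The
identity means body weight, flows, volumes and partition coefficients cannot
move steady-state AUC — only binding and intrinsic clearance can — which is
why the local sensitivity scan shows AUC24 responding only to `fu0` and
`clint` while Cmax also responds to absorption and distribution parameters.

### Absorption

Sertraline is a BCS class II compound (dissolution-limited). A first-order
constant-Ka model cannot reproduce its late Tmax at reasonable Cmax, so the
absorption rate constant is time-dependent:

    Ka(t) = ka_max · (1 − exp(−t_since_dose / τa)),   Ka(0) = 0

with the clock reset at every dose event. The saturating-exponential form was
chosen for being the simplest monotone two-parameter delay; calibrated values
are ka_max = 0.236 h⁻¹ and τa = 3.33 h.

### Enterohepatic recirculation

Biliary secretion is modeled as an unbound intrinsic clearance from the liver
(CL_bile = 600 L/h, about 12% of the metabolic route) into a gallbladder pool
that empties continuously into the gut lumen at k_empty = 0.25 h⁻¹.
Continuous first-order emptying (rather than meal-triggered boluses) keeps
the system smooth and linear; both constants were estimated in calibration.
No fecal loss is modeled, so recycled drug is eventually reabsorbed and oral
availability is limited only by first-pass metabolism.

### Distribution

Partition coefficients come from the tissue-composition method for highly
lipophilic compounds, using a standard composition table (neutral lipid,
phospholipid, water per tissue), `P = 10^logP` with logP = 5.29, plasma
binding fu0 = 0.015, tissue binding `fu_t = 1/(1 + 0.5·(1−fu_p)/fu_p)`
(adipose: fu_t = 1). Individual tissues are volume-lumped (richly perfused:
brain, heart, kidneys, lungs, spleen; slowly perfused: muscle, skin, adipose,
bone). Ionization is ignored (logP, not logD): sertraline is a lipophilic
base and the composition method with a fitted adjustment already absorbs the
systematic error. Per-compartment adjustment factors (richly ×3.0, slowly
×4.24, gut and liver ×1) were fitted once against the nonpregnant
steady-state profile and frozen; raw composition-based Kp values
underestimate sertraline's very large distribution volume (~20 L/kg, partly
lysosomal trapping, which is out of scope), and the adjustment factors carry
that correction.

### Metabolism and IVIVE

Elimination is 100% hepatic CYP metabolism (renal clearance negligible).
Per-enzyme in vivo intrinsic clearance is `(Vmax/S)/fu_mic × ISEF ×
abundance × MPPGL × liver mass`, with S = 0.5 µM, fu_mic = 1, MPPGL =
40 mg/g, liver mass 1400 g. The packaged kinetic table is a synthetic
stand-in: the original recombinant-CYP study's per-enzyme Vmax/ISEF values
are not publicly tabulated, so abundances and ISEFs are standard adult means
and the Vmax values were back-calculated so that the chain reproduces the
reported enzyme contribution shares (CYP3A4/2B6/2C9/2C19/2D6 =
73/9/8/7/3%). The absolute total is set by a single calibrated scalar
(2.2796, giving CLint_u = 4312 L/h and CL/F = 64.7 L/h at fu0 = 0.015);
calibration never alters the shares.

## Gestational scaling

All pregnancy effects are continuous functions of gestational age (weeks),
evaluated once per simulation (quasi-steady snapshot). The packaged curves
are parameterized against typical longitudinal pregnancy physiology and
validated against aggregate outputs rather than transcribed coefficient by
coefficient: total weight gain ≈ 12.5 kg at term (quadratic), plasma volume
+45% (quadratic), cardiac output +31% saturating near term (quadratic),
placental-fetal volume ≈ 5 L at term (cubic), maternal fat gain ≈ 3.4 kg
(quadratic), serum albumin −27% at term (quadratic). Pregnancy-gained mass is
routed by type: placental-fetal volume plus residual lean growth into the
richly perfused compartment, fat gain into the slowly perfused compartment.

Binding: with linear, non-saturated albumin binding,
`fu(GA) = 1/(1 + ((1−fu0)/fu0)·albumin_ratio(GA))`, which yields Fu increases
of ~3%, 12% and 27% at the representative trimester gestational ages (7, 20
and 34 weeks).

CYP activity: gestational data exist only for CYP3A4 and CYP2D6; the other
three enzymes keep multiplier 1 (a known limitation — their variability is
instead covered by the Monte Carlo CV on total clearance). CYP2D6 rises
linearly to 3× at 40 weeks. CYP3A4 uses a saturating Emax curve
`1 + 1.297·GA^2.459/(25^2.459 + GA^2.459)` (≈2× at term) rather than a
polynomial: the Emax form is monotone by construction on any GA range and
matches the reported aggregate trajectory of total hepatic intrinsic
clearance (+11/37/63% at GA 10/20/30) when combined with the enzyme shares
above. With these curves the model predicts a 143% rise in CL/F and a 59%
fall in AUC24 at GA 40, and AUC-matching dose increases of ~9%, 53% and 115%
at the trimester-representative gestational ages.

## Calibration workflow

The nonpregnant model was calibrated once against the steady-state profile
of 200 mg daily for 30 days (mean Cmax 166 µg/L at Tmax ~6.7 h, AUC24
3063 µg·h/L, t½ ~26–32 h): the clearance scalar sets AUC24, the slow-tissue
Kp adjustment sets the terminal half-life (26.2 h), and (ka_max, τa,
CL_bile, k_empty) shape Cmax and Tmax. All five constants are frozen in the
shipped drug configuration. `pregpbpk.calibrate` re-implements this fit
generically (log-space least squares on the mean curve) so the closed loop
can be tested: from a noise-free synthetic dataset the optimizer recovers
all five generating values to better than 1%, and with 20% observation noise
the clearance scalar stays within 15% over seeded replicates. The
finite-difference step of the fit (0.1% in log space) deliberately dominates
the ODE-solver tolerance so numerical Jacobians stay meaningful.

## Population simulation

Monte Carlo (default n = 1000, seeded NumPy Generator) samples: body weight
and cardiac output lognormal (CV 30%), fractional volumes and flows normal
(CV 30%, renormalized per draw so flows sum to 1 and volumes to the
reference sum), partition coefficients lognormal (CV 20%), absorption,
enterohepatic and clearance constants lognormal (CV 30%), and fraction
unbound lognormal with CV 15% (binding is experimentally measured and varies
less than the assigned defaults for unmeasured parameters). Lognormal
distributions are parameterized so the arithmetic mean equals the reference
value. Sampling is rejection-based within the 2.5th–97.5th percentile bounds
of each family. Parameter correlations are not modeled, and gestational
trajectories are identical across subjects. Reported outputs are pointwise
2.5/50/97.5 percentile concentration bands and the NCA of the median curve.

## Non-compartmental analysis

Cmax/Tmax by grid maximum over the final dosing interval (0.25 h
resolution), AUC24 by linear trapezoid, λz by log-linear regression on
washout points at least 12 h after the last Tmax (minimum 5 points; flagged
unreliable below r² = 0.95), t½ = ln2/λz, CL/F = dose/AUC24, Vd/F = CL/F /
λz. Simulations that feed half-life estimates extend 72 h past the last
dose.

## Numerical choices

LSODA (stiff-capable, adaptive) with rtol 1e-8, atol 1e-10 µg, an analytic
Jacobian, and hard restarts at every dose event; the fastest time scale is
plasma turnover (~147 h⁻¹) against a 0.026 h⁻¹ terminal slope. "Steady
state" is operationalized as the 30th daily dose (>7 terminal half-lives;
residual approach error ~1e-9 relative). Mass balance holds to machine
precision and is asserted to 0.1% in tests. Tablet rounding enumerates sums
of at most 3 tablets (configurable) and breaks ties toward the lower dose,
the conservative choice for fetal exposure.

## Synthetic datasets

`pregpbpk.fixtures` emulates the two study designs the workflow needs: a
calibration-like study (11 nonpregnant subjects, 200 mg × 30 days, serial
samples 0.5–72 h after the last dose) and a verification-like study
(subjects on 25–200 mg daily with Cmax/AUC24 summaries at a 22–26-week and a
30–34-week visit). Observations are model predictions times multiplicative
lognormal noise, so generating parameters are known exactly. These fixtures
exercise estimation and evaluation code end to end, but they inherit the
model's own structure: passing closed-loop tests demonstrates internal
consistency (estimator correctness, metric identities), not agreement with
real clinical data, which shows features the generator omits —
between-subject kinetic heterogeneity beyond the sampled parameters, assay
error structure, nonadherence, and covariates such as CYP polymorphisms.

## Known limitations

No ionization or lysosomal-trapping term in distribution (absorbed into
fitted adjustment factors); no gestational change in absorption; no
placental-fetal disposition beyond a lumped volume (fetal exposure is out of
scope); no gestational data for CYP2B6/2C9/2C19; linear (non-saturable)
metabolism; no metabolite, transporter or polymorphism effects. Predictions
at gestational ages beyond 42 weeks are rejected rather than extrapolated.
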