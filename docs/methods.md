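# Model and methods

## Scope and model structure

`tofasim` is a mechanistic whole-body PBPK model of orally administered
tofacitinib. The state vector tracks drug amounts (µmol) in

* a gut lumen: an undissolved stomach pool, a dissolved stomach pool, and
  three small-intestine transit segments;
* 14 systemic compartments: arterial and venous blood, lung, and 11
  perfusion-limited tissues (adipose, bone, brain, gut, heart, kidney,
  liver, muscle, skin, spleen, and a lumped "rest");
* four cumulative elimination tallies (CYP3A4, CYP2C19, urine, feces).

Internal units are µmol / L / h; the plasma I/O unit is ng/mL via the molar
mass 312.40 g/mol. The blood-to-plasma ratio is fixed at 1, so blood and
plasma concentrations coincide and regional blood flows act directly on
plasma-equivalent concentrations.

### Absorption

Tablet dissolution follows the Weibull form F(t) = 1 − exp(−ln2 (t/t50)^b),
parameterized by the 50% dissolution time and shape of each marketed
formulation (IR 0.29 h / 0.59, XR 3.22 h / 2.42, fed state 1.25 h / 1.01);
oral solution and conventional tablets dissolve immediately. Dissolution is
implemented as a time-since-dose hazard h(t) = F′/(1 − F) acting on the
undissolved pool, capped at 50 h⁻¹ to regularize the integrable singularity
of shapes < 1 at t → 0⁺ (the cap shifts dissolved mass by well under a
minute). A solubility guard (2.9 mg/mL in 0.25 L stomach fluid) caps the
dissolved lumen concentration; at clinical doses it never engages. Gastric
emptying is first order (2.8 h⁻¹), the three transit segments give a mean
small-intestine residence of 3.3 h, and each segment absorbs into the portal
inflow at k_a = P_int · 60 · A_eff (specific intestinal permeability
7.24×10⁻⁶ cm/min times a calibrated effective area-to-volume factor).
Dissolved drug leaving the last segment is an irreversible fecal loss, which
is what makes the absorbed fraction F_a ≈ 0.85 < 1. Gut-wall metabolism is
not modeled; the bioavailability calibration (below) absorbs it. The
transcellular (cellular) permeability is carried as a compound datum but
plays no role in a perfusion-limited model.

### Distribution

Each tissue is perfusion-limited: dA_t/dt = Q_t (C_art − C_t/Kp_t). Partition
coefficients come from the Rodgers–Rowland tissue-composition method for a
monoprotic base whose pKa (5.07) lies below intracellular pH — i.e., the
compound is >99% neutral everywhere, water and neutral-lipid/phospholipid
partitioning dominate, and residual binding is to interstitial albumin with
an association constant back-calculated from the plasma unbound fraction
(0.61). The published composition constants (water fractions, lipid
fractions, tissue:plasma albumin ratios) are embedded as package data. A
consequence of the modest logP is a modest steady-state volume, so the
profile shows a fast effective phase (~3 h half-life) followed by a shallow
redistribution-limited terminal phase.

### Elimination

Liver: CYP3A4 metabolism is Michaelis–Menten in the unbound liver outflow
concentration, v = V_max·C_u/(K_m + C_u) with K_m = 10.61 µmol/L; CYP2C19 is
first order, v = CL_int·C_u. Both scale with the individual's enzyme
abundance, functional liver fraction and liver volume. Kidney: filtration
GFR·f_u plus a linear tubular-secretion intrinsic clearance acting on the
unbound kidney concentration; secretion capacity scales with the
individual's GFR ratio (maturation and disease affect filtration and
secretion together).

### Calibration of the "optimized" parameters

Four scalars — the reference-liver CYP3A4 capacity (187.0 µmol/h), the
CYP2C19 intrinsic clearance (5.46 L/h), the tubular-secretion intrinsic
clearance (4.73 L/h) and the absorptive area factor (2517 cm⁻¹) — were
calibrated once by root-finding against four disposition anchors of the
reference adult and then frozen as package defaults:

* cumulative elimination fractions CYP3A4 : CYP2C19 : renal = 53.67% :
  16.67% : 29.67% after a 5 mg single dose (the reported 53/16/29 split sums
  to 98%, so the 2-point rounding excess is distributed evenly, keeping each
  fraction within 0.7 points of its nominal value);
* absolute oral bioavailability F = 0.74, measured against an internal
  venous-bolus reference simulation;
* total systemic plasma clearance 17.4 L/h, the literature-consistent value
  implied by the compound's apparent oral clearance and F.

With Cmax ≈ 0.06 µmol/L ≪ K_m, the model is linear at clinical doses;
dose-normalized AUC varies < 1% between 0.3 and 100 mg.

## Virtual individuals and populations

The reference adult is a 30-year-old male with ICRP-style organ volumes,
regional flows (cardiac output 390 L/h), hematocrit 0.45 and GFR
110 mL/min; a female reference (60 kg, CO 350 L/h, GFR 100 mL/min) covers
mixed-sex cohorts. Venous return equals cardiac output by construction.

Pediatric subjects (2–18 y) interpolate embedded growth tables at ages
{2,4,6,9,12,15,17} for weight, height, liver, kidney and brain volumes and
absolute GFR; remaining organs scale with the weight ratio and flows
allometrically (weight^0.75). CYP3A4/CYP2C19 ontogeny is treated as complete
at age ≥ 2 y and plasma protein binding as adult — a deliberate
simplification appropriate above infancy; it is the main reason predictions
in the youngest (2-to-<6 y) group carry the largest uncertainty. Adolescent
females carry an age-interpolated body- and organ-size factor.

Population sampling is log-normal around the age/sex-consistent reference
with CVs of 16% (volumes, GFR), 20% (flows), 25% (enzyme abundances) and 30%
(intestinal permeability) — typical PBPK population defaults — with uniform
ages and Bernoulli sex assignment, all driven by one seed.

### Organ impairment

Hepatic impairment is a multiplicative Child–Pugh state on CYP3A4 abundance,
functional liver fraction, hepatic (arterial + portal) flow, the unbound
fraction and GFR. The scalers were calibrated once against the exposure
anchors used for dose guidance — class A AUC ratio within [1.0, 1.25]
(original dosing retained), class B ratio ≈ 2.0 (half dosing) — giving
A = {0.80, 0.90, 0.90, ×1.05, 0.95} and B = {0.29, 0.50, 0.65, ×1.15, 0.90}.
The hepatic studies use the fed-state formulation, matching post-prandial
administration.

Renal impairment scales GFR (and with it tubular secretion) by the ratio of
the class-representative eGFR to the healthy reference (100 mL/min/1.73 m²);
the representative values 100/75/45/22.5 are midpoints of the standard
KDOQI bands. Hepatic parameters are untouched — renal-only scaling
reproduces the ~33% exposure increase in severe impairment that motivates
the 75% dose recommendation.

## Drug–drug interactions

Perpetrators are reduced one-compartment oral models (closed-form Bateman
superposition of daily doses) whose unbound concentration drives the
victim's enzymes: competitive inhibition multiplies activity by
1/(1 + C_u/K_i); induction integrates enzyme turnover
dE/dt = k_deg (E₀(1 + E_max C_u/(EC₅₀ + C_u)) − E) with k_deg = 0.03 h⁻¹
(enzyme half-life ≈ 23 h) and multiplies activity by E/E₀. The victim is
simulated twice — with the perpetrator at steady state and without — and the
effect is AUCR and C_maxR of a single victim dose.

Fixture regimens follow the clinical designs (fluconazole 400 mg loading +
200 mg QD; ketoconazole 400 mg QD; rifampicin 600 mg QD for 8 days).
Perpetrator PK constants are adopted from published models; the potency
constants were calibrated once against this model's predicted ratios and
frozen: fluconazole K_i(CYP3A4) 12.2 µmol/L and K_i(CYP2C19) 2.5 µmol/L
(moderate 3A4 / potent 2C19 inhibitor), ketoconazole K_i(CYP3A4)
0.0135 µmol/L unbound at f_u 0.03 (potent 3A4 inhibitor), rifampicin
E_max 4.78 (CYP3A4) and 1.5 (CYP2C19) at EC₅₀ 0.34 µmol/L. The victim dose
form is part of the frozen fixture (solution in the inhibitor studies, IR
tablet in the induction study). AUC ratios reproduce the calibration targets
to < 1%; Cmax ratios sit 8–14% below them because this model's slower
absorption makes the peak more clearance-sensitive than in the platform the
targets came from — a known structural difference, not a fitting residual.

## Dose selection

Exposure matching minimizes |median AUC(target, dose) − median AUC(reference,
standard dose)|: the near-linearity makes the one-step ratio estimate
d = d_ref·AUC_ref/AUC_target(d_ref) accurate, and a bisection refinement
brings the population median within 2% before rounding (0.1 mg for pediatric
doses; 5% granularity for dose fractions). The matching statistic is the
population median — the robust center of the skewed exposure distribution.
Default matching cohorts are 100 subjects with fixed seeds; the full-size
cohorts (200 adults 50% female, 100 children 70% female, 1000 impairment
subjects 25%/50% female) are what the bundled study fixtures specify, and
the medians are stable well below that size.

## Parameter identification and evaluation

`mc_fit` implements seeded Monte Carlo random search over bounded
(log-)uniform parameter boxes with an optional coordinate-wise
golden-section polish, minimizing summed squared log-concentration residuals
(points below the 0.1 ng/mL quantification limit excluded). Log residuals
match the multiplicative error of PK assays and make the objective invariant
to concentration units. The sample stream depends only on the seed, so runs
are reproducible and enlarging the sample budget can only improve the best
objective.

NCA uses linear-up/log-down trapezoids on dense simulated grids (pure linear
for sparse tables of ≤ 8 points), the earliest-time tie-break for T_max, and
a terminal log-linear regression over the best adjusted-R² window of the
last 3–6 points after T_max (ties prefer the longer window). GMFE uses the
absolute-log convention, 10^(Σ|log₁₀ FE|/n): without the absolute value,
symmetric over- and under-prediction would cancel and the statistic could
not serve as an error magnitude. Local sensitivity uses a forward +10%
perturbation.

## Synthetic observed data

The evaluation data the original studies rest on are digitized published
concentration curves; `synthetic` emulates such tables from the model
itself: median-subject profiles sampled at nominal times, log-normal
proportional error (CV 15%, σ = √ln(1+cv²)), additive assay noise (SD
0.05 ng/mL, truncated at zero) and LLOQ censoring at 0.1 ng/mL — magnitudes
typical of LC-MS/MS PK assays. Passing round-trip and recovery tests on
these tables demonstrates the pipeline's internal consistency (the fitter
recovers the generating parameters; metrics count correctly), not external
predictive accuracy against real patients, which requires the clinical
tables themselves.

## Numerical choices

* Stiff integration (BDF) with analytic Jacobian; rtol 10⁻⁸, atol
  10⁻¹⁰ µmol, 0.05 h output grid. Population-scale work (dose matching,
  fitting) uses a coarse preset (10⁻⁶/10⁻⁹, 0.2 h); the two agree on AUC to
  < 0.1%.
* Doses are instantaneous additions to the stomach (or venous blood for the
  internal bioavailability reference) at scheduled times; integration is
  piecewise between dose events.
* Mass balance (lumen + body + eliminated + fecal = administered) holds to
  machine precision and is asserted to 0.1% in the tests.
* Steady state is declared when consecutive dosing-interval AUCs agree
  within 1% (reached by dose 4–5 for a 3 h effective half-life; the engine
  extends the schedule automatically up to a cap).

## Known limitations

* T_max (~3 h for IR) is later than typically observed (~0.5–1 h): with
  renal excretion fixed at ~29% and F at 0.74, the minimal 3-segment gut
  forces absorption to be transit-limited. Exposure metrics (AUC, ratios,
  dose fractions) are insensitive to this; the peak is, which is also why
  predicted C_maxR values sit slightly below their targets.
* No gut-wall CYP3A4, no transporters, no mechanism-based inactivation, no
  intravenous clinical model.
* Pediatric ontogeny is treated as complete at 2 y; predictions below ~6 y
  are the least certain.
* The impairment scalers and DDI potencies are exposure-calibrated, not
  measured; they are frozen package constants, flagged as calibratable.
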