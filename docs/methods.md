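# Methods

## Scope and model structure

`cnspk` simulates the distribution of small-molecule drugs between plasma
and eight CNS compartments: brain microvascular blood, brain extracellular
fluid (ECF), brain intracellular fluid (ICF), lysosomes, and the
cerebrospinal fluid of the lateral ventricles (LV), third+fourth ventricle
(TFV), cisterna magna (CM) and subarachnoid space (SAS, which includes the
lumbar sampling site). Plasma is a forcing function: the CNS carries a
negligible fraction of the body's drug mass, so there is no feedback, and
an identical plasma profile can be fed to different CNS physiologies to
isolate their effect.

The state vector is drug amount per compartment; every exchange is a
clearance (mL/min) acting on the unbound concentration, so the system is
linear and the response scales exactly with dose. Integration uses LSODA
(`scipy.integrate.solve_ivp`) at rtol 1e-8 / atol 1e-10; the plasma forcing
is evaluated analytically (sums of exponentials with geometric-series
superposition over doses), so stiff steps never interpolate tabulated
input. Steady state under constant infusion is obtained directly as the
solution of the linear system, without time stepping.

## Transport routes

**Paracellular (BBB, BCSFB).** `CL = f_para · P_para · SA`, symmetric and
carried by ionized and neutral species alike. `P_para = 3e-6 cm/min` at the
reference MW 350, scaled by `MW^(−1/3)` (Stokes–Einstein). The reference
value is anchored to the brain uptake clearance of classical paracellular
markers (sucrose/mannitol), ~0.5 mL/min for a healthy human BBB of 15 m².
`f_para` is the population's barrier-integrity multiplier (1 in health,
4.4 at the AD BBB).

**Transcellular (barriers, cell membranes, lysosomes).** Only the neutral
species permeates: `CL = P_trans · SA · f_n(pH_donor)` with Henderson–
Hasselbalch neutral fraction `f_n` (at most one acidic and one basic group;
ampholytes multiply the two factors). The permeability map is log-linear:

    log10 P_trans [cm/min] = −3.9 + 0.35·logP − log10(MW/350)

The coefficients were chosen so that moderately lipophilic CNS drugs get
barrier equilibration half-lives of tens of minutes to ~1 h (e.g.
semagacestat: P·SA ≈ 25 mL/min at the AD BBB), the physiologically expected
scale. Because the asymmetry-factor calibration (below) absorbs barrier-
level error, steady-state compartment *ratios* are robust to this map;
absolute equilibration *rates* — and hence peak/trough shapes — are
sensitive to it, which is why the headline fluctuation ratios are checked
against order-of-magnitude bands rather than point values.

The same pH-partition logic at the ECF/ICF and ICF/lysosome membranes
produces the intracellular accumulation of bases and lysosomal trapping
(for a base with pKb ≥ 8 the steady-state lysosome:ICF unbound ratio equals
`f_n(pH_ICF)/f_n(pH_lyso)` exactly). The effective exchange areas of the
cell and lysosomal membranes (1070 and 107 cm² per mL brain) are package
design parameters: the anatomical membrane area is far larger, but
unstirred layers and tortuosity limit the effective value; results at the
target sites are only weakly sensitive to them because the ECF/ICF pool is
shared.

**Active transport.** Net carrier-mediated asymmetry at the BBB and at the
LV- and TFV-facing blood–CSF barrier is a directional multiplier (AF ≥ 1)
on the transcellular clearance: AF_in on blood→tissue, AF_ef on
tissue→blood; paracellular transport is AF-free (transporters are membrane
proteins). For each barrier the scalar AF is found by Brent root finding so
that the steady-state unbound compartment:plasma ratio under constant
infusion equals the drug's measured Kpuu. Targets: Kpuu,BBB at brain ECF;
Kpuu,LV at the LV; Kpuu,lumbar at the **SAS** (the site where lumbar Kpuu
is defined), with the factor located at the TFV-facing barrier upstream.
Targeting the sampling site keeps the simulated lumbar ratio equal to the
measured one for every drug regardless of how much brain-ECF drainage mixes
into the CSF; with a TFV-compartment target that identity fails for drugs
whose brain and lumbar Kpuu differ strongly (e.g. memantine, 2 vs 0.89).
An unreachable target (outside what AF ≤ 1e6 can produce, e.g. a lumbar
ratio below the ECF-drainage mixing floor) raises a calibration error
reporting the achievable range.

Rat-derived Kpuu,BBB values (donepezil, memantine) are calibrated first and
the resulting factor is translated to human by multiplying its directional
magnitude by the product of human:rat transporter expression ratios for the
transporters the drug is a substrate of (donepezil: P-gp 0.22 × BCRP 1.1);
if the magnitude drops below 1 the direction flips and the magnitude is
reciprocated. For memantine the human:rat brain-to-plasma ratios are
similar, so the scaling is unity.

Asymmetry factors are calibrated **once, on the mild-AD physiology** — the
population in which the underlying CSF Kpuu data were obtained — and then
treated as drug properties: the CHY/CHE/AD comparison reuses them, so
inter-population differences reflect physiology, not re-calibration. The
sensitivity analysis likewise holds them fixed (re-calibration would cancel
barrier-parameter perturbations by construction); a `recalibrate` flag
exposes the alternative.

**Flows.** Cerebral blood flow exchanges plasma and microvascular blood.
CSF is produced at the LV (drug-free) at `q_csf` and flows LV → TFV → CM →
SAS → venous blood; brain-ECF bulk flow drains to the cisterna magna by
default (configurable to LV or SAS) and is carried down the rest of the
chain. The SAS outflow is the only irreversible CNS elimination route.

**Binding.** Brain non-specific binding is instantaneous equilibrium to
phospholipids: the homogenate unbound fraction f_u,b defines a binding
capacity `(1/f_u,b − 1)` referenced to the healthy phospholipid fraction
(5 % of brain volume); the bound pool enlarges the apparent ICF volume and
scales with the population's phospholipid fraction, so AD's phospholipid
loss raises the effective unbound fraction, as observed.

## Population physiology

The reference CHY set (default config, fully overridable, one provenance
label per field): 1400 mL brain (density 1.045 g/mL), ECF/ICF fractions
0.2/0.8, phospholipid 5 %, microvascular blood 35 mL, CSF volumes
22.5/7.5/7.5/175 mL (LV/TFV/CM/SAS incl. spinal), normalised CBF
48 mL/min/100 g, ECF bulk flow 0.2 mL/min, CSF production 0.35 mL/min
(turnover ≈ 2.4/day), BBB 15 m², BCSFB 7.5 m² (split 50/50 between LV- and
TFV-facing portions), pH 7.4/7.3/7.0/5.0/7.3 (plasma/ECF/ICF/lysosome/CSF).

Aging (CHE) compounds yearly percentage rates from age 60: brain −0.401 %/y;
LV and TFV +3.45 %/y; CM +1.09 %/y; SAS +0.78 %/y. The ECF volume fraction
drops 16 % (a categorical senescent-vs-adult contrast, applied as a step
past onset), with ICF as the complement. Phospholipids decline piecewise
linearly (−10 % over 60–80, a further −8 % over 80–100). Bulk flow is
atrophy-corrected then reduced 33 %; the BBB area atrophy-corrected then
reduced 10 %; ICF pH drifts −0.001/y. Normalised CBF is age-invariant, so
total CBF is recomputed on the shrunken brain, and the microvascular volume
preserves the young microvasculature:CBF ratio. CSF production, CSF/ECF pH
and barrier-integrity multipliers do not age.

Mild AD (relative to age-matched CHE): brain ×0.95; ECF fraction ×1.4
(ICF complement); phospholipid ×0.90; ventricles ×1.39; extraventricular
CSF ×1.21; normalised CBF ×0.85 (total recomputed on the atrophied brain);
bulk flow ×0.85 plus atrophy; BBB area atrophy-corrected then ×1.1123;
BBB paracellular ×4.4; BCSFB paracellular and CSF flow unchanged; lumbar
CSF pH +0.018. The reported AD brain-pH change spans 0 to +0.009, so the
default brain shift is 0 (configurable). Only mild AD is parameterised —
quantitative physiology for moderate/severe disease does not exist — and
requesting it raises an explicit error. Representative ages default to 35 y
(CHY) and 70 y (CHE and AD, age-matched); they are configurable because no
canonical simulation age exists.

All %/year rates compound multiplicatively, `v(age) = v(60)·(1±r)^(age−60)`
(a linear-accumulation alternative is available behind the
`AgingRates(compounding=False)` switch for comparison);
"corrected for brain atrophy" means: scale by the atrophied:baseline brain
volume ratio first, then apply the population-specific factor.

## Steady state, metrics and engagement

Chronic dosing is simulated interval by interval (closed-form plasma
superposition; the CNS state carries over) until the interdose AUC of every
compartment changes < 0.5 % between consecutive intervals and at least five
terminal plasma half-lives have elapsed; 0.5 % is far below any effect size
of interest here. The final interval is re-indexed to time post dose.
Metrics per compartment: Cmax/Cmin/Tmax (grid scan plus local quadratic
refinement), trapezoidal AUC, terminal half-life (least squares on the log
tail, last 30 % of the interval after Tmax; undefined rather than an
exception if the tail is non-positive), and fluctuation Cmax:Cmin.
Engagement against an unbound IC50: crossing times by linear interpolation,
fraction of the interval at or above the IC50, and the drug-free onset —
the final downward crossing after which the profile does not recover.
"Drug-free" is operationalised as below the unbound IC50 (an absolute
concentration floor is available as an alternative flag).

## Sensitivity analysis

One parameter at a time, ×2 and ×10 up and down (±1 and ±2 units for pH),
on the mild-AD model with asymmetry factors fixed; %change =
100·(perturbed − reference)/reference for Cmax, Tmax, terminal half-life
and AUC at brain ECF, brain ICF and SAS, ranked by the largest absolute
change. Perturbations that violate a physiological invariant (e.g. an ECF
fraction ≥ 1) are recorded as skipped. All physiology fields are perturbed
by default; the set is restrictable. Default problem size for one
parameter/factor pair is one steady-state run at 361 grid points per
interval, which keeps a full scan at interactive cost.

## Synthetic data

The generator draws random but physically consistent drugs: logP in
[−1, 5], MW in [150, 600], at most one acidic (pKa 3–11) and one basic
(pKb 5–12) group, log-uniform unbound fractions in (0.01, 1] and Kpuu
targets in (0.1, 5). The lumbar Kpuu is floored at 0.4× the BBB Kpuu: in a
flow-coupled CNS the lumbar CSF drains brain ECF, so a lumbar ratio far
below the brain ratio is unreachable by any barrier calibration — drawing
the two independently would manufacture physically impossible drugs.
Observation noise is multiplicative log-normal with unit geometric mean and
a stated CV (default 20 %), the standard model for CV-characterised assays
of positive concentrations; the interpolated truth is retained for recovery
tests. Everything is seeded.

What the generator does *not* emulate: inter-individual variability,
correlated physicochemical properties (logP–MW–pKa correlations of real
chemical series), nonlinear binding, or assay limits of quantification.
Passing tests therefore demonstrate internal consistency of the pipeline on
plausible single molecules, not calibration against any clinical dataset.

## Numerical and design notes

* Units are fixed internally: mL, min, ng, cm², pH units; doses in mg are
  converted at the boundary (×1e6 ng/mg).
* The 1-compartment oral solution switches to the `t·e^(−kt)` Bateman limit
  when |ka − ke| < 1e-9 relative; coincident rates in the 2-compartment
  model raise rather than return NaN.
* Multi-dose superposition uses stable geometric-series closed forms, so
  hundreds of doses cost the same as one.
* The donepezil plasma row ships as a 1-compartment model (its
  inter-compartmental clearance and peripheral volume are zero).
* Rivastigmine's 6 mg regimen carries a relative bioavailability of 1.4
  (referenced to the 1–5 mg range).
* A closed-system mode (no plasma exchange, no CSF sink) yields an exactly
  conservative generator, used to verify mass balance to 1e-6.
* The config dialect is YAML: the round-trip invariant (write → reload →
  identical values) requires a writable format.

## Known limitations

* The governing equations are this package's own concrete parameterisation
  of the named transport routes; printed AF tables from any source are not
  transcribed — factors are always re-calibrated from Kpuu targets.
* Absolute equilibration rates inherit the uncertainty of the permeability
  map; order-of-magnitude statements (brain vs CSF fluctuation) are robust,
  point predictions of Tmax or half-life at the target site are not.
* Lumbar CSF is not resolved as a separate sub-compartment of the SAS.
* No saturable transport, target-mediated disposition, brain metabolism or
  regional (grey/white) resolution.
* The elderly/AD translations rest on sparse, partly contradictory
  literature; parameters with no usable data (lysosomal volume and pH,
  BCSFB area and paracellular integrity) are held at healthy values, a
  choice the sensitivity analysis shows to be benign for the brain-ECF
  target site.
* Intracellular exposure contrasts close to an IC50 (within ~2-fold) are
  below the model's resolution; the rivastigmine dual-inhibition comparison
  is reported as a qualitative contrast for this reason.
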