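# Methods

This package models hemoglobin (Hb) as an oxygen-dependent buffer of
red-cell glutathione (GSH): oxygenated Hb carries four non-covalent GSH
binding pockets per tetramer, deoxygenated Hb two, so the R→T quaternary
transition can liberate up to two GSH molecules per tetramer into the
cytosol. The package implements the quantitative skeleton of that
hypothesis — unit conversions, the redox readout, the linkage model, the
calorimetric binding analysis, the quantification regression, and the
cohort statistics — together with synthetic-data generators that emulate
the study designs the analyses expect.

## Cell composition and unit conversions (`composition`)

Metabolite measurements arrive as μmol per g Hb; reasoning about binding
equilibria needs concentrations in cell water. Three constants drive all
conversions:

| constant | default | why |
|---|---|---|
| MCHC | 335 g/L | standard mean corpuscular Hb concentration |
| water volume fraction | 0.68 | see below |
| Hb tetramer molar mass | 64,000 g/mol | makes 335 g/L ↔ 5.23 mM |

The canonical water:dry ratio of the red cell is 0.67:0.33, but the worked
conversions this package reproduces (2.5 μmol/g Hb ↔ 1.23 mmol/L cell
water; 6 μmol/g Hb ↔ 2.96 mmol/L) are exact at 0.68 and off by ~1.5% at
0.67; whether the ratio was meant as mass or volume fraction is
underdetermined, so 0.68 is the default and 0.67 remains available via
`RbcComposition`. All conversions are pure linear functions with no hidden
state.

The capacity bookkeeping follows directly: 5.23 mM Hb × 2 releasable
sites = 10.5 mM storage capacity; the observed rise from 1.23 to 2.96 mM
on deep deoxygenation liberates 1.73 mM, i.e. 16.5% of capacity.

## Redox potential (`redox`)

The GSH/GSSG couple (2 GSH ⇌ GSSG + 2H⁺ + 2e⁻) is reported as the fixed
25 °C, pH 7.0 half-cell form

    E_hc (mV) = −240 − (59.1/2) · log10([GSH]² / [GSSG]),

concentrations in mol/L. The squared numerator makes E_hc twice as
sensitive to GSH as to GSSG (−17.8 vs +8.9 mV per doubling). The argument
of the logarithm is dimensionful (units of M); this is accepted as the
convention of the printed form rather than generalised. No temperature or
pH rescaling is provided on purpose: the constant −240 mV already folds in
the pH 7.0 proton term, and a half-generalised Nernst form would be more
misleading than none.

## The linkage model (`linkage`)

No O₂-binding equations accompany the buffering hypothesis itself, so the
package adopts the simplest framework that expresses state-linked release:
a two-state (MWC) model in which every tetramer is wholly R or wholly T.

* `L = 1.7e5` (T/R ratio at zero O₂), `c = KR/KT = 0.014`, and `KR`
  calibrated so that P50 = 26 mmHg are package constructs chosen to give
  a realistic adult O₂ equilibrium curve (Hill coefficient ≈ 2.4 at P50).
  They are configurable and carry no experimental authority.
* GSH sites: `n_r = 4`, `Kd_r = 2 μM` (R/oxy); `n_t = 2`, `Kd_t = 17 μM`
  (T/deoxy) — the calorimetric values.
* φ ∈ [0,1], the mean occupancy of the releasable pockets, is the free
  parameter of the stoichiometric model. The default 0.18 makes the
  predicted release at 20% SO₂ equal 1.74 mM, consistent with the
  capacity arithmetic above (φ·fT(0.2) ≈ 0.165).

Two release models are shipped deliberately:

1. **Stoichiometric** (default): released GSH = φ·(n_r−n_t)·[Hb]·fT.
   This matches the capacity arithmetic and is the reproduction path.
2. **Equilibrium**: free GSH solves the mass balance
   g + [Hb]·(fR·n_r·g/(g+Kd_r) + fT·n_t·g/(g+Kd_t)) = g_total
   by bisection on [0, g_total] (the left side is strictly increasing, so
   the bracket is guaranteed; residual < 1e-9 relative).

They disagree at cellular concentrations, and that disagreement is
informative: micromolar Kd's against ~5 mM of tetramer imply that
millimolar total GSH would sit almost entirely bound in both states, so
simple mass action cannot simultaneously accommodate the calorimetric
affinities and millimolar free GSH. The package does not guess a
reconciliation (crowding, activity coefficients, deproteinization
artifacts are all candidates); it exposes both models.

The same inconsistency surfaces in the heterotropic P50 computation,
which rescales the allosteric constant to
L_app = L·(1+g/Kd_t)^n_t / (1+g/Kd_r)^n_r (and multiplies by
(1+b/Kd_deoxy)/(1+b/Kd_oxy) for BPG's single central-cavity site, Kd's
4.75 mM oxy / 0.1 mM deoxy). Directions are robust — GSH left-shifts,
BPG right-shifts, monotonically — but with micromolar Kd's the GSH shift
saturates below 0.5 mM free GSH at an implausibly large magnitude. Treat
the P50 module as a direction/ordering tool, not a calibrated predictor.

A structural point worth recording: in any two-state parameterization the
T-state fraction is nearly linear in saturation (at intermediate pressures
the R state is nearly full and the T state nearly empty, so Y ≈ fR).
fT-proportional release therefore rises gradually across the whole
saturation range and cannot by itself produce a curve that is flat above
~55% SO₂ and rises steeply below — the shape tonometry experiments show.
The threshold behaviour must involve something beyond quaternary-state
counting (e.g. cooperative pocket occupancy); the package treats the
threshold as an empirical feature (below) rather than forcing the MWC
curve to fake it.

### Threshold estimation

`estimate_threshold` fits the flat-then-exponential form

    g(S) = a                       for S ≥ S*
    g(S) = a + b·(exp(k·(S*−S))−1) for S < S*

by grid search over S* (0.05…0.95, step 0.01) with a bounded 1-D
optimisation over k (0.01…60) and an exact linear solve for (a, b) at
each candidate — the model is linear in (a, b) given (S*, k), so no
nonlinear optimiser over the full parameter set is needed. A threshold is
only reported when the exponential term passes an F-style SSE-ratio test
(3 extra parameters, default α = 0.05) and its amplitude is positive;
flat or pure-noise series return a "no threshold" result rather than a
number. Grid values are rounded to exact decimals so reported thresholds
are clean grid points.

### Occupancy fitting

For fixed binding parameters the stoichiometric model is linear in
(baseline, φ), so `fit_phi` is an ordinary least-squares solve with φ
clipped to [0,1] (baseline re-estimated if clipping binds). Degenerate
designs (all saturations equal) raise an identifiability error.

## ITC (`itc`)

The forward model is the standard one-set-of-sites isotherm for a
perfusion cell, with the displaced-volume bookkeeping stated explicitly in
the module docstring (cumulative dilution of the macromolecule,
accumulation of ligand, and the (v_i/V0)·(Q_i+Q_{i−1})/2 correction on
per-injection heats). Default protocol: 19 × 2.0 μL injections of 4 mM
ligand into 200 μL of 85 μM macromolecule at 298.15 K — a low-volume
instrument protocol whose syringe capacity caps the injection series.
Heats are joules internally; μcal accepted at I/O (1 cal = 4.184 J).

Fitting minimises per-injection residuals over (N, log10 Ka, ΔH) with
`scipy.optimize.least_squares`, initialised from the half-heat molar
ratio (N₀), the first-injection heat per mole (ΔH₀) and Ka₀ = 1e5 M⁻¹,
with a restart grid over log10 Ka₀ ∈ {3…8}. A constant heat-of-dilution
offset is co-fitted by default; the first injection can be excluded
(default off). ΔH ≈ 0 traces raise an identifiability error instead of
returning noise. ΔG = −RT ln Ka and TΔS = ΔH − ΔG hold exactly by
construction on every returned parameter set.

Precision under noise: with i.i.d. Gaussian noise of sd 2% of the
largest injection heat, the Fisher information of this 19-injection
design caps the achievable relative precision of Kd at ≈13–15% (1 sd)
for both anchor parameter sets (N=4/Kd=2 μM gives Wiseman c ≈ 170,
N=2/Kd=17 μM gives c ≈ 10). The fitter's observed scatter sits at that
bound; single noisy titrations therefore land within ±15% of the true Kd
only ~two-thirds of the time, which is why replicate titrations are
simulated and averaged wherever a Kd is reported.

## Quantification (`quantification`)

Standard additions: ordinary least squares of intensity on added amount,
m₀ = intercept/slope, standard error by first-order (delta-method)
propagation including the intercept–slope covariance; a residual
bootstrap is available behind a flag. OLS is unweighted on purpose (no
weighting scheme is part of the stated procedure). Non-positive slopes
are rejected — the signal must grow with additions for the method to make
sense. Spectral integration is out of scope; inputs are integrated
intensities.

## Synthetic data (`simulate`)

Every generator is a pure function of (parameters, seed) drawing from a
named stream, so adding a generator never perturbs another's draws, and
equal seeds give byte-identical outputs.

* **Cohort**: 12 subjects × 7 timepoints (2 pre-ascent, altitude days 3
  and 18, 3 post-descent). GSH 3.4 ± 0.65 μmol/g Hb at sea level,
  4.6 ± 0.64 at altitude — the anchored cohort values. GSSG (0.8 ± 0.15,
  condition-independent), venous SO₂ (70 vs 45%), Hb (150 vs 168 g/L) and
  the subject random-intercept sd (0.3) are invented, physiologically
  plausible placeholders, flagged as such in the dataclass. Concentration
  draws are redrawn (not clipped) at zero to keep densities smooth. E_hc
  is computed per row from cell-water molarities.
* **Tonometry**: 40-point saturation grid from 98 down to 5%, noise sd
  0.2 μmol/g Hb. The default curve is the empirical flat-then-exponential
  shape: baseline 2.5 μmol/g Hb, threshold at 50% SO₂, steepness k = 5,
  amplitude calibrated so the curve passes 6.0 μmol/g Hb at 20% SO₂ —
  the features tonometry measurements show. The exponential keeps rising
  below ~15% SO₂ rather than saturating at the storage capacity; treat
  the extreme-hypoxia tail as extrapolation. A mechanistic `shape="mwc"`
  variant draws from the linkage model instead (and, per the structural
  point above, rises gradually with no flat plateau). BSO series reuse
  the control draws (synthesis blockade leaves the bound pool untouched);
  NEM series are flat at 0.2 μmol/g Hb (thiols alkylated).
* **ITC / standard additions**: the deterministic forward models plus
  i.i.d. Gaussian noise.

Because the generators draw exactly from the models the analyses fit
(plus Gaussian noise), passing recovery tests demonstrate correctness of
the estimation machinery — inverse consistency, calibration, type-I
control — not robustness to the ways real data deviate (baseline drift,
heteroscedastic integrals, hemolysis artifacts, inter-donor curve-shape
variation).

## Cohort statistics (`analysis`)

The repeated-measures design is analysed by four within-subject paired
contrasts (altitude vs sea level, late vs early altitude, post vs pre,
late vs first post day): each collapses a subject's rows to means and
applies a paired t-test. This is a deliberate simplification of a mixed
ANOVA with subject as random factor — exact for balanced designs,
transparent, and sufficient for the package's calibration claims;
correlated-error modelling across days is out of scope. P-values are
unadjusted by default (Holm available). The permutation null used in
testing shuffles condition labels within subject, which preserves each
subject's value multiset while destroying the condition effect; the
nominal-0.05 paired t-test rejects at ≈2–5% under this null (slightly
conservative, as the permuted mixture is heavier-tailed than normal).

## Problem sizes

Simulation studies use 20 seeds (threshold, φ, ITC noise) or 200 seeds
(additions coverage, permutation null) at the design sizes above — 40
tonometry points, 30-point φ fits, 19-injection titrations, 84-row
cohorts — sizes chosen to match the emulated experiments while keeping
the full suite fast.

## Known limitations

* The MWC parameters are constructs; only SO₂-level behaviour anchored to
  observations (P50, curve shape plausibility) constrains them.
* The stoichiometric and equilibrium release models cannot both be
  quantitatively right with the calorimetric Kd's; the package keeps the
  tension visible instead of resolving it.
* The P50 linkage module is directional, not calibrated (see above).
* BPG is modelled as a pure T-state effector with no GSH–BPG site
  competition; kinetics, the Bohr effect and per-subunit (Adair)
  descriptions are out of scope.
* The empirical tonometry curve is an unsaturating exponential below the
  threshold; its tail below ~15% SO₂ overshoots what capacity bookkeeping
  would allow if extrapolated far enough.
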