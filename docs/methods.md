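# Methods

## The problem

Deuterated-glucose labeling estimates lymphocyte turnover from the
fraction of labeled deoxyadenosine in sorted cell populations. The
estimate is conditional on the label availability U(t) — the plasma
enrichment of labeled glucose — which the conventional analysis
approximates as a "square pulse" of constant enrichment over the
labeling window. Because plasma glucose is a small, fast pool, U(t) in
fed protocols dips sharply after every meal, runs higher overnight, and
decays with a glycogen-fed tail after the infusion ends. This package
simulates U(t) mechanistically, builds the square-pulse approximation
from sparse samples the way practitioners do, and propagates both
representations through the same turnover model so the difference in
the resulting rate estimates can be measured.

## Reduced tracer model

The simulator is a deliberately reduced compartmental system, not an
organ-resolved physiological model. Its contract is behavioral: fasting
enrichment proportional to infusion rate at tracer doses, postprandial
dilution dips, and a recycling-fed delabelling tail.

State (masses in grams, time in hours): plasma glucose carried as two
species (tracer and background) in one well-mixed pool of volume
`vd × weight` (0.19 L/kg); a stomach and a gut compartment per species;
basal-normalized insulin `I`; and the labeled fraction `y_gly` of a
fixed 100 g hepatic glycogen store. Concentration uses 0.18016 g/mmol;
the two species have identical kinetics (the 2 Da mass difference is
ignored everywhere except molar I/O conversion, where the labeled
species is 182.17 g/mol).

Fluxes:

- **Meals** deliver CHO as free glucose into the stomach over the meal
  duration (default 10 min). Gastric emptying is first order with
  half-time `0.25 h + 5·10⁻⁴ h/kcal × meal energy` (energy defaults to
  4 kcal/g CHO); gut-to-plasma absorption is first order at 2 h⁻¹. The
  linear energy rule is a modeling choice — the literature ties
  emptying to energy, volume and solid fraction without a canonical
  formula.
- **Insulin**: `dI/dt = s·max(C − C_basal, 0) − k·(I − 1)` with
  secretion s = 0.4 (mmol/L)⁻¹h⁻¹ and clearance k = 0.8 h⁻¹.
- **Disposal**: `(k₀ + 0.25·(I−1)₊)·G_total`, partitioned between
  species by current enrichment; k₀ is set so disposal balances basal
  EGP at fasting glucose (5 mmol/L), i.e. ~8 g/h for 70 kg.
- **EGP**: `EGP_basal·max(0, 1 − 0.1·(I−1))`, basal 8/70 g/h/kg.
- **Renal** spill above 10 mmol/L at 7 L/h (inactive at tracer doses).
- **Glycogen recycling**: glycogen exchanges with plasma at a constant
  flux (2 g/h, capped by current EGP and disposal) that is a slice of
  EGP (glycogenolysis) and of disposal (glycogenesis), so the store's
  total mass is fixed. The labeled fraction obeys
  `dy/dt = (flux/100 g)·(0.4·u − y)`; 40% is the label-retention
  efficiency of a glycogen passage, and released label `flux·y` feeds
  the post-infusion tail.

Feedback gains were chosen weak enough that tracer-level infusions
(0.4–3 g/h) barely perturb EGP — at 1 g/h the realized EGP stays within
2% of basal, so the isotope-dilution reading `Rd = I/e` is meaningful —
while a 75 g meal still produces a realistic several-mmol/L glucose
excursion and a deep enrichment dip.

Integration proceeds piecewise between schedule breakpoints (meal and
infusion boundaries) with LSODA at rtol 1e-8/atol 1e-10; primes are
state jumps. Cumulative input/output fluxes are carried as extra
states, so the mass audit is algebraic and closes to ~1e-15 relative
independent of output grid.

Known omissions: no glucagon species (counter-regulation is folded into
the EGP suppression term), no incretin effect, no inter-subject
variability in model constants beyond weight scaling, single glucose
pool (no slow exchange compartment). Consequently absolute postprandial
dynamics are stylized; the quantities the analysis consumes (AUCs and
their timing structure) are the fidelity target.

## Square pulse

`trapezoid_auc` sums trapezoids between samples inside the labeling
window, clamping window-edge values to the nearest sample (no
extrapolation). The tail adjustment assumes mono-exponential washout of
the last measured enrichment from a pool of mass `pool` at disappearance
rate `rd`, giving area `e_last·pool/rd`; this closed form is this
package's reconstruction of the conventional correction, with `pool`
defaulting to the basal plasma pool mass and `rd` to total disposal at
end of label. The rectangle is rendered with vanishing (1e-12 h) edge
ramps so trapezoidal integration on any refined grid reproduces the
area exactly.

## Turnover model and solver

The kinetic-heterogeneity model treats the population as proliferating
at rate p (day⁻¹) while labeled cells disappear at d* (day⁻¹),
with normalization b = 0.65 (maximum attainable labeled fraction) and a
0.5-day blood-appearance lag with en-route loss `e^(−lag·d*)`. Because
the ODE is linear with piecewise-linear forcing, the solver uses the
exact per-interval exponential update (with series fallback for
d*·Δt → 0) rather than a generic integrator; against the analytic
square-pulse solution it agrees to ~1e-16 sup-norm, and it is exactly
linear in U — the property that makes exposure misestimation translate
reciprocally into proliferation-rate misestimation.

## Fitting

- **Meal CHO** (`fit_meal_cho`): orthogonal (total) least squares
  between the dense simulated enrichment curve and plasma samples, both
  axes z-standardized by the data's mean/SD, because time and
  enrichment both carry measurement uncertainty. The orthogonal
  distance is approximated by the nearest dense-grid point (default
  0.05 h step). Optimized by Nelder–Mead from the recorded meal size
  plus seeded uniform restarts.
- **Turnover** (`fit_kh`): vertical least squares on the observed blood
  fraction — the orthogonal scheme is specific to the plasma/meal
  problem. A seeded pseudorandom search (default 200 uniform draws in
  p ∈ [0,1], d* ∈ [0,10] per day, plus deterministic bound-corner
  anchors so boundary optima like all-zero data resolve exactly) seeds
  trust-region least squares from the three best draws. Every fit is
  reproducible from (data, bounds, seed).
- **Required exposure** (`fit_required_auc`): one shared square-pulse
  AUC and one loss rate per population, proliferation fixed at
  published rates (defaults 1/210 and 1/341 day⁻¹ for CD4+/CD8+ from
  7-day labeling). Linearity in U lets the model be evaluated once per
  loss rate on a unit-AUC pulse and scaled, so the AUC bound
  (default 100 %·day, where estimates pin when the data cannot be
  reconciled) never produces an unphysical rendered profile.

## Statistics

The signed-rank test enumerates the exact null distribution of the
positive-rank sum by dynamic programming over sign assignments for
n ≤ 15 (midrank ties handled by doubling), dropping zero differences;
larger n uses the tie-corrected normal approximation. The rank-sum test
delegates to scipy (exact for small tie-free samples). Both are
validated against independent brute-force enumeration oracles in the
test suite. The fasting regression is OLS with a pointwise 95% mean
confidence band. No multiplicity correction is applied; all p values
are two-tailed.

## Synthetic data

The generator emulates three study designs: short fasted primed
infusions (prime 5.95 mg/kg, 0.1 mg/kg·min for 2.5/5/14.5 h, sampled
around end of infusion), a 1-day fed protocol (~1 g/kg over 24 h, prime
6.6% of the dose, five meals of 30–90 g CHO at jittered daytime hours,
eight intermittent daytime plasma samples plus two post-infusion — the
sampling pattern whose square-pulse summary is under scrutiny), and a
7-day low-CHO protocol (30 g/day, prime 6.6% of the daily dose,
45 g/day CHO over three meals, one overnight-fasted sample per day).
After labeling, all fed templates deliver 237 g CHO/day over three
meals for five days. DNA observations are generated from the turnover
model driven by the subject's own simulated profile, at 8 time points
over 21 days, with ground truth stored separately.

Measurement noise is multiplicative log-normal with unit mean,
CV 5% (plasma) and 10% (DNA). The original assays' error structure is
not published; these are round-number placeholders intended to be
varied in sensitivity analyses. The generator reproduces the
statistical *structure* the analysis assumes — not GC/MS error
chemistry, inter-occasion physiological variability, or real
anthropometric covariance — so recovery results bound estimator
behavior under the stated noise model only.

## Numerical and design choices

- Enrichment is a fraction internally, percent in every file interface;
  AUCs are reported in %·day; rates per day at the turnover interface,
  per hour inside the simulator.
- U between plasma profile nodes is interpolated linearly (exposed as
  the only interpolation rule; the forcing is stored densely enough
  that the choice is immaterial).
- Combined naive/memory enrichments are pointwise weighted means of
  blood fractions; the analyses here fit combined curves directly.
- Degenerate inputs: zero total glucose reports zero enrichment; data
  that are identically zero pin p at its lower bound with the
  disappearance rate flagged unidentifiable; all-zero paired
  differences return p = 1 with a flag.
- Test and acceptance problem sizes (3-subject directional fixture,
  50-subject recovery study, 0.05–0.1 h grids) were chosen as the
  smallest that exercise every pathway with stable statistics; the
  directional result is asserted at a fixed seed because it is a
  property of the sampling design, not of a particular noise draw.
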