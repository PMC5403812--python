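# glucotrace

Kinetics of *in vivo* deuterated-glucose labeling for measuring human
T cell turnover.

In stable-isotope labeling studies, [6,6-²H₂]-glucose is infused
intravenously; dividing cells incorporate the deuterium into DNA via the
pentose phosphate pathway, and the fraction of labeled deoxyadenosine in
sorted T cell populations is measured over the following weeks. Turning
those measurements into proliferation and disappearance rates requires
knowing the *label availability* — the plasma glucose enrichment
U(t) — throughout the experiment. Because the body glucose pool is
small (~12 g) and turns over in about 90 minutes, U(t) fluctuates
strongly with meals and decays with a glycogen-fed tail after the
infusion; the conventional analysis nevertheless summarizes it as a
"square pulse": a constant level over the labeling window whose area
matches the trapezoidal AUC of a handful of plasma samples plus a
washout-tail correction.

`glucotrace` implements the full chain needed to quantify what that
approximation does to turnover estimates:

- **`tracer_simulator`** — a reduced whole-body glucose–insulin ODE
  model with parallel labeled/unlabeled glucose species, oral CHO
  absorption via a stomach/gut chain, insulin-driven disposal and EGP
  suppression, and hepatic glycogen label recycling (40% efficiency),
  producing dense U(t) profiles under arbitrary primed-infusion and
  meal schedules.
- **`square_pulse`** — the classical approximation: trapezoid AUC over
  the labeling window, exponential-washout tail adjustment
  (e·pool/Rd), and the equal-area rectangle.
- **`kh_turnover`** — the kinetic-heterogeneity model of DNA labeling,
  dX*/dt = b·p·U(t) − d*·X*, L*(t) = X*(t−lag)·e^(−lag·d*), with
  b = 0.65 and lag = 0.5 day, solved exactly on piecewise-linear U,
  plus the analytic square-pulse solution used as an oracle.
- **`estimation`** — orthogonal-distance meal-CHO fitting, seeded
  pseudorandom + local least-squares estimation of (p, d*), and the
  inverse "required label exposure" fit with proliferation fixed.
- **`stats_report`** — exact small-sample Wilcoxon signed-rank and
  Mann–Whitney tests, the fasting enrichment-vs-infusion-rate
  regression, isotope-dilution disposal rates (Rd = I/e), and the
  label-exposure comparison summary.
- **`synthetic_data`** — seeded generators of complete study bundles
  (cohorts, protocols, plasma samples, DNA enrichment with known
  ground truth) for the fasted short-infusion, 1-day fed, and 7-day
  low-CHO study designs.

## Worked example

Simulate a one-day primed infusion (~1 g/kg) with meals, summarize the
sparse daytime samples as a square pulse, and fit turnover both ways:

```python
from glucotrace.synthetic_data import generate_bundle
from glucotrace.workflows import compare_methods

bundle = generate_bundle("oneday", 3, seed=42)
results = compare_methods(bundle, seed=42, n_starts=60)
print(results["auc_comparison"])
print(results["rate_comparison"][["method", "population", "id", "p_per_day"]])
```

prints (seed 42):

```
    id     auc_sq    auc_sim
0  S01  15.010559  18.518366
1  S02  15.974877  19.706511
2  S03  16.850342  18.887795
         method population   id  p_per_day
0      sq_pulse        cd4  S01   0.036655
1   sim_profile        cd4  S01   0.028451
2      sq_pulse        cd8  S01   0.007359
3   sim_profile        cd8  S01   0.005558
...
```

so the square-pulse summary built from intermittent daytime samples
underestimates true label exposure by ~20% on this design — the sparse
samples fall disproportionately in postprandial dips and the rectangle
ends when the infusion stops, while the simulated profile carries the
higher overnight enrichment and the glycogen tail. The fitted
proliferation rates compensate in the opposite direction
(`sq_pulse` rows have p ≈ 1.2× the `sim_profile` rows), which is the
mechanism by which the conventional analysis overestimates turnover in
short fed studies, while the simulated-profile fits recover the
generating parameters closely.

The same machinery exposes a CLI:

```sh
glucotrace make-synthetic --seed 42 --out bundle/
glucotrace compare-methods --bundle bundle/ --out reports/
glucotrace required-auc --bundle bundle/ --out reports/required_auc.csv
```

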