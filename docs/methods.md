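# Methods

## Scope and model

`biochipscreen` implements the cut-off validation calculus used for
qualitative/semi-quantitative screening methods for veterinary drug residues,
specialised to a competitive multiplex biochip immunoassay read out in
relative light units (RLU). The package has four layers:

1. **Panel configuration** — analyte constants (MRL or prohibited status,
   spike level, calibration range, LOD) and study-design constants.
2. **Synthetic signals** — a competitive calibration curve per analyte plus a
   structured noise model, generating seeded blank/spiked validation cohorts
   and survey cohorts.
3. **Validation statistics** — threshold `T`, cut-off factor `Fm`, the
   `T > Fm` usability check, false-positive/false-negative accounting under
   either rule, and the CCβ decision.
4. **Screening** — survey classification against validated cut-offs,
   optional concentration back-calculation, and MRL-compliance summaries.

### The decision rules

Per analyte, with blank RLUs `b` and spiked RLUs `s` (spiked at the chosen
validation level):

* `T = mean(b) − t_factor · sd(b)`, default `t_factor = 1.6`;
* `Fm = mean(s) + fm_factor · sd(s)`, default `fm_factor = 1.64`, the
  one-sided 5% standard-normal quantile;
* signals are competitive, so a sample screens **positive** iff its RLU is
  *strictly below* the cut-off; equality is a presumptive negative (ties have
  probability zero for continuous signals, but the boundary must be
  deterministic);
* the validation level is usable iff `T > Fm`;
* under the Fm rule, the method is **validated** — CCβ set equal to the spike
  level — iff at most `max_false_compliant` (default 1) of the `n_spiked`
  (default 20) spiked controls screen negative. Otherwise the decision is
  **escalate**: the package reports it and leaves regeneration at a higher
  spike level to the caller, since a fresh cohort is new data by definition.

If spiked signals were exactly normal and `Fm` known, the false-compliant
rate would be `P(Z > 1.64) = 5.05%`; the acceptance script verifies this
calibration by Monte Carlo (2 × 100,000 draws, agreeing to within ±0.5
percentage points).

Standard deviations use the n−1 denominator (configurable via `ddof` in the
estimator), the usual choice for n = 20 validation cohorts. No multiplicity
adjustment is made across the 15 analytes: the per-analyte error model is
applied as the guideline prescribes, and panel-level statements ("all
validated") are conjunctions of per-analyte decisions.

### Estimator interface

`CutoffScreener` is a scikit-learn `BaseEstimator`: `fit(X, y)` takes a
column of control RLUs and cohort labels (`"blank"`/`"spiked"`, or 0/1) and
exposes `blank_mean_`, `blank_sd_`, `spiked_mean_`, `spiked_sd_`,
`t_value_`, `fm_value_`, `valid_` and the rule-selected `cutoff_`;
`predict` maps RLUs to `"positive"`/`"negative"`; `decision_function`
returns the signed margin above the cut-off. `validate_panel` and
`screen_samples` are thin wrappers that run the estimator per analyte over
tidy sample tables.

## Synthetic data

### Calibration curves

Competition is modelled with a four-parameter logistic,

    RLU(c) = bottom + (top − bottom) / (1 + (c / c50)^slope),

strictly decreasing in concentration, with the closed-form inverse used for
back-calculation. The packaged default curves are *illustrative*: tops sit
near the blank-signal magnitudes reported for this panel (≈1,500–7,900 RLU)
and mid-curve signals near its spiked-cohort magnitudes (≈260–1,160 RLU),
but they are not fitted instrument calibrations — the kit's raw calibrator
data are not public.

Curves live on the **assay-level (diluted) concentration scale**. Milk is
diluted 1:1 with wash buffer before the assay (`dilution_factor = 2`), so
generators evaluate the curve at `true_conc / dilution_factor`, and the
screening stage multiplies back-calculated concentrations by
`dilution_factor`. The dilution is therefore applied exactly once in each
direction, and a noise-free round trip (generate → screen) recovers the true
sample concentration exactly. Printed calibration ranges (which already
account for the dilution) are stored as-is and only used as range checks.

Inverse-signal boundary contracts: an RLU at/above `top` reports 0 µg/kg
with a *below-detection* flag; at/below `bottom` it is *saturated* — the
concentration is censored (NaN), never fabricated, and any sulphonamide sum
involving a censored member is likewise reported as unknown.

### Noise model

Measured RLU for sample *i*, analyte *a*:

    rlu = RLU_a(c_i / d) · shift(milk type) · m_i · e_ia + ε_ia ,  clipped at 0

* `m_i` — per-sample **matrix factor**, shared by all analytes of one
  physical sample (the same milk is measured on one biochip; its matrix
  moves all spots together). Nominal CV 0.08.
* `e_ia` — independent per-measurement factor, nominal CV 0.06.
* `ε_ia` — additive Gaussian detector floor, SD 5 RLU.
* `shift` — per-milk-type multiplier, default 1.0 (fat content does not
  affect the assay).

Both multiplicative factors are **left-skewed and bounded**: each is
`(1 + k) − W` with `W` lognormal (mean `k = skew_cap · cv`, SD `cv`,
`skew_cap = 0.6`), clipped below at `1 − 3 · cv`. Rationale: the
chemiluminescent yield of a test region is ceiling-limited — loss mechanisms
(matrix interference, incomplete binding, washing losses) can only subtract
light from the bound-conjugate maximum — and gross outlier runs are removed
in practice by QC-gated reanalysis. The signature of such noise is exactly
what competitive-assay validation data show: blanks occasionally dip below
the blank-based threshold T (a few false positives under the T rule), while
spiked signals essentially never exceed the spiked-based Fm by more than the
one-or-none allowance (zero or one false negative under the Fm rule).

This tail shape matters more than the CV itself. For *any* iid noise with a
Gaussian-weight upper tail, the count of the 20 spiked controls falling at or
above their own `mean + 1.64·sd` is ≥ 2 with probability ≈ 0.12–0.23 per
analyte, which would make a fully-validated 15-analyte run a rare event —
contrary to how such validations behave. With the bounded-above noise and the
shared matrix factor, a seeded default run validates the whole panel with
probability ≈ 0.98 (measured over 8,000 simulated studies), while still
producing the realistic 0–3 false positives under the T rule. Lower-tail
clipping truncates the heavy side of the lognormal, so the realized factor
SD is somewhat below the nominal CV (≈ 0.056 at cv 0.08).

What the generator does **not** emulate: inter-assay drift and reagent-lot
effects, cross-reactivity between sulphonamides (none reported for this
panel), spatial/imaging artefacts, true heavy-tailed outliers (assumed
removed by QC), and real raw-RLU dispersion — no raw validation data are
published, so all CVs are declared assumptions. Passing tests therefore
demonstrate the correctness of the decision calculus and the qualitative
behaviour of a well-behaved assay, not quantitative agreement with any
instrument.

### Cohort designs

* **Validation cohort**: 20 blanks (true concentration 0) + 20 spiked (at the
  analyte's spike level) per analyte, the same 40 physical samples across all
  15 analytes; milk types cycle skimmed/semi/full-fat. The 100 µL-into-900 µL
  spiking step is absorbed into "true concentration = spike level".
* **Survey cohort**: n samples (default 53) measured for all 15 analytes;
  milk-type mix defaults to 15/53 skimmed, 17/53 semi, 21/53 full-fat.
  Contamination is Bernoulli per analyte with configurable prevalence
  (default 0); contaminated concentrations default to
  `Uniform(spike_level, 2·spike_level)`, which stays inside every analyte's
  calibration range. `forced_contamination` deterministically contaminates
  chosen sample indices — used to reproduce the one-positive-of-53 survey
  scenario exactly.

All generators are bit-reproducible functions of their integer seed (NumPy
`default_rng`); the command-line default seed is 0.

## Numerical and reporting choices

* Exactness: `T`/`Fm` match an independent two-pass mean/SD computation to
  ≤ 1e-9 relative error (property-tested).
* The logistic inverse round-trips to ≤ 1e-9 relative error on the working
  range (concentrations within roughly two decades of `c50`); far below
  `c50` the forward curve is flat to machine precision and the inverse is
  correspondingly ill-conditioned, which is immaterial at screening levels.
* Insufficient data (< 2 values per cohort) raises an error rather than
  returning an SD-free statistic.
* Survey percentage tables *truncate* to two decimals (1/53 → "1.88"), the
  convention of the original occurrence tables; JSON reports always carry
  full-precision values.
* Problem sizes used by the test suite: validation runs at the design size
  (15 × (20+20)); the seed-robustness property uses 50 seeds at 1.9× noise;
  survey sensitivity uses 1,000 simulated samples; the β-calibration uses
  2 × 100,000 draws. These sizes give Monte-Carlo error well inside the
  asserted tolerances.

## Known limitations

* CCα / confirmatory decision limits are out of scope (screening only), as
  is fitting calibration curves from calibrator data.
* "Compliant" is a screening-level statement (negative for every analyte);
  the sulphonamide concentration-sum check against the 100 µg/kg group MRL
  is a separate, optional concentration-level report, only available when
  back-calculated concentrations exist and are uncensored.
* The escalation loop (raise spike level, revalidate) is surfaced as a
  decision, not executed automatically.
* Default curve and noise parameters are design choices documented above,
  not estimates; conclusions about any real instrument require refitting
  them from that instrument's data.
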