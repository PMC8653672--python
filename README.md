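# biochipscreen

Validation and screening statistics for multiplex competitive biochip
immunoassays, built around a 15-analyte antimicrobial panel for milk
(13 sulphonamides, dapsone and trimethoprim).

## The problem

Residues of veterinary antibiotics in milk are regulated by maximum residue
limits (MRLs): 100 µg/kg for the *sum* of all sulphonamides, 50 µg/kg for
trimethoprim, while dapsone is prohibited outright. Laboratories screen milk
with multiplex biochip arrays: each chip carries discrete antibody spots and
runs a **competitive** chemiluminescent immunoassay, so more analyte means
*less* light — the read-out is a relative light unit (RLU) value that falls
with concentration.

Before such a screening method may be used, EU rules for screening-method
validation require demonstrating its **detection capability CCβ**: the lowest
concentration at which the method flags a contaminated sample with a
false-compliant (false-negative) rate β ≤ 5%. When the screening target is at
or below half the regulatory limit, 20 spiked control samples with at most one
false compliant result suffice to demonstrate CCβ below the MRL.

`biochipscreen` implements this validation calculus end to end, plus a seeded
synthetic-signal generator to exercise it, for assay developers and residue
labs who want the decision rules as tested, reusable code.

## The statistics

From 20 blank and 20 spiked control samples per analyte, on the RLU scale:

```
T  = mean(blank RLU)  − 1.6  · SD(blank RLU)      (threshold)
Fm = mean(spiked RLU) + 1.64 · SD(spiked RLU)     (cut-off factor)
```

(sample SDs, n−1 denominator; both multipliers configurable). A sample
screens **positive** when its RLU lies strictly below the chosen cut-off.
The validation level is usable only when `T > Fm`; otherwise the spike level
must be raised and the study repeated. Under the Fm rule, if at most one of
the 20 spiked controls screens negative, the method is validated and
**CCβ = spike level**; 1.64 is the one-sided 5% normal quantile, so the rule
targets the β ≤ 5% false-compliant rate. Survey samples are then screened
against the per-analyte cut-offs, and a sample is MRL-compliant at screening
level when it screens negative for every analyte.

The core is exposed as a scikit-learn estimator, `CutoffScreener`
(`fit` on labelled blank/spiked controls → `t_value_`, `fm_value_`,
`cutoff_`, `valid_`; `predict` → positive/negative calls), with
`validate_panel` / `screen_samples` as thin panel-wide wrappers.

## Worked example

```python
import biochipscreen as bs

panel = bs.default_panel()            # 15 analytes, MRLs, spike levels
models = bs.default_models()          # illustrative competitive 4PL curves
noise = bs.NoiseModel()               # bounded left-skewed signal noise

records = bs.generate_validation_cohort(panel, models, noise, seed=0)
report = bs.validate_panel(records, panel, cutoff_rule="Fm")
sdz = report.analytes["SDZ"]
print(f"SDZ: T = {sdz.cutoff.t_value:.2f} RLU, Fm = {sdz.cutoff.fm_value:.2f} RLU, "
      f"T > Fm: {sdz.cutoff.valid}")
print(f"panel: all T > Fm: {report.all_valid}, all validated: {report.all_validated}")

survey = bs.generate_survey_cohort(panel, models, noise, 53, seed=0,
                                   forced_contamination={"SMTZ": {11: 25.0}})
screening = bs.screen_samples(survey, report.chosen_cutoffs, models,
                              panel.validation.dilution_factor)
summary = bs.survey_summary(screening, panel)
print(f"survey: SMTZ positives = {summary.per_analyte['SMTZ'].n_positive}/53, "
      f"compliant samples = {summary.n_compliant}/53")
```

prints

```
SDZ: T = 4547.76 RLU, Fm = 433.98 RLU, T > Fm: True
panel: all T > Fm: True, all validated: True
survey: SMTZ positives = 1/53, compliant samples = 52/53
```

The blank-derived threshold T sits far above the spiked-derived cut-off Fm,
so the 20 µg/kg validation level is usable for sulphadiazine; every analyte
meets the one-or-none false-compliant allowance, so each CCβ equals its spike
level (at or below half the MRL). In the simulated 53-sample retail survey
with one sulphamethazine-contaminated milk, exactly that sample screens
positive (1.88% of samples) and the remaining 52 are compliant.

The same pipeline runs from the shell:

```
biochipscreen simulate --cohort validation --seed 0 --output validation.csv
biochipscreen validate --samples validation.csv --output validation.json
biochipscreen simulate --cohort survey --n 53 --contaminate SMTZ:11:25 --output survey.csv
biochipscreen screen --samples survey.csv --validation-report validation.json --output survey.json
```

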