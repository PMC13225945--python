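# vancopk

Individualized vancomycin therapeutic drug monitoring (TDM) from
encounter-level EHR event streams, built around a hybrid of a recurrent
neural network and a two-compartment pharmacokinetic (PK) model.

Vancomycin needs concentration monitoring: its PK varies widely between
patients, levels are drawn sparsely (mostly troughs), and the modern
efficacy target — the ratio of the area under the concentration-time curve
to the pathogen's minimum inhibitory concentration (AUC/MIC) — requires
the whole curve, not a single trough. `vancopk` estimates that curve per
patient: a GRU reads the event stream (doses, labs, vitals, co-medications,
previously observed levels) and emits, at every event, random effects
η = (η1…η4) that set the individual parameters of a two-compartment model,

    V1 = 33.1·e^η1 L      CL = 0.0396·CrCL·e^η2 L/h
    Q  = 6.99·e^η3 L/h    V2 = 48.3·e^η4 L

with CrCL the Cockcroft–Gault creatinine clearance and
η ~ MVN(0, diag(0.120, 0.149, 0.416, ·)). A closed-form PK layer then
advances central/peripheral concentrations exactly over each inter-event
interval — gradients flow through the analytic solution. A one-compartment
variant (mass-conserving, the classical baseline), a MAP-Bayesian
estimator on the same prior, a peak/trough sampling-design simulation
framework, and a synthetic EHR cohort generator complete the package, so
every experiment runs without access to any protected hospital data.

Audience: pharmacometricians and clinical-informatics researchers
studying model-informed precision dosing and sampling-strategy design.

## Worked example

Generate a 30-patient synthetic cohort, train the two-compartment model,
and compare one- vs two-compartment estimators on data simulated from it
under the "peak and trough for every dose" design:

```bash
vancopk gen-data --n 30 --seed 7 --events-out events.csv --static-out static.csv
printf 'model:\n  max_epochs: 20\n' > cfg.yaml
vancopk train --config cfg.yaml --events events.csv --static static.csv \
        --model 2cm --seed 1 --checkpoint-out model.json --out train.json
vancopk compare --config cfg.yaml --events events.csv --static static.csv \
        --checkpoint model.json --design both_all --repeats 2 --seed 3 --out cmp.json
```

which prints

```
trained 2cm for 11 epochs; test RMSE 6.846 mg/L
design                           1cm                   2cm
both_all                 3.00 (0.21)           1.39 (0.72)   p=0.0931
```

Reading the numbers: the trained model predicts the cohort's sparse held-out
levels with RMSE 6.8 mg/L (typical levels here run 10–45 mg/L; random
effects are drawn from the full prior, so much of this error is irreducible
individual variability). The table is the sampling-design comparison: with
peak+trough samples simulated from the trained two-compartment "derived"
model for every dose, a freshly trained two-compartment estimator recovers
the ground-truth curves to 1.39 mg/L mean test RMSE (SD over 2 retraining
seeds) while the misspecified one-compartment estimator, unable to
reproduce the distribution-phase peaks, stalls at 3.00 mg/L; the last
column is the two-sample t-test p-value.

The library mirrors the CLI: `synthgen.generate_cohort`,
`ehr_model.read_events` / `impute_and_standardize` / `split_patients`,
`pkrnn.train` / `predict_prospective`, `simkit.run_comparison` /
`auc_mic_comparison`, `pk_core.map_bayes_update`. See `docs/methods.md`
for the model, assumptions, and numerical details.

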