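# Methods

## The model

`vancopk` couples a recurrent neural network to a two-compartment
pharmacokinetic (PK) model of vancomycin. Drug disposition is described by
central and peripheral concentrations (C_A, C_B) obeying

    dC_A/dt = I/V1 − (CL/V1)·C_A − (Q/V1)(C_A − C_B)
    dC_B/dt = (Q/V2)(C_A − C_B)

with infusion rate I (mg/h), central and peripheral volumes V1, V2 (L),
central clearance CL (L/h) and intercompartmental clearance Q (L/h). The
individual parameters are exponential perturbations of population typical
values by random effects η = (η1…η4):

    V1 = 33.1·e^η1   CL = 0.0396·CrCL·e^η2   Q = 6.99·e^η3   V2 = 48.3·e^η4

where CrCL is the Cockcroft–Gault creatinine clearance
(140 − age)·weight / (72·SCr), ×0.85 for women, in mL/min. The η prior is a
diagonal multivariate normal with mean zero. The published prior lists four
means but only three variances (0.120, 0.149, 0.416); the fourth (η4,
peripheral volume) defaults to the volume-scale value 0.120 and is
configurable (`pk_core.EtaPrior`).

### Closed-form PK layer

Over any span with constant rate and parameters the system is linear,
C' = AC + b, and is solved exactly by spectral interpolation of e^{At} and
its first two time integrals (`_linode.py`). For strictly positive
parameters A always has two distinct real non-positive eigenvalues, so no
matrix exponential routine is needed; expm1 keeps small-|λ·dt| spans
accurate. The same scalar expressions run on plain arrays (deterministic
core) and on autodiff tensors (the network's PK layer), so the two paths
agree to machine precision. Degenerate edges — Q = 0, a zero eigenvalue,
(near-)repeated eigenvalues with |λ1 − λ2| < 1e-9·|λ| — are handled by
NumPy-only limiting forms in `pk_core` (series guards below |λ·dt| ≈ 1e-6
for the integrals). AUC over a segment is the exact integral of the closed
form, so total AUC obeys the dose/CL identity and the mass balance
V1·C_A + V2·C_B + CL·∫C_A dt = mass infused to ~1e-14 relative.

### Network architecture

Per event step, medication codes (vocabulary 911, representing 324 generic
drugs) are embedded in 8 dimensions and averaged (zero vector when a step
has no codes); concatenated with 40 standardized continuous features they
form a 48-d input to a single-layer GRU with hidden size 64. A linear
(64, 4) head emits η per step for the two-compartment model; a (64, 2)
head emits log-scale multipliers (log k, log V) for the one-compartment
baseline, with k anchored at CL_pop/V1_pop = 0.0396·CrCL/33.1 and V at
33.1 L so that a zero head output reproduces the population model in both
cases. The PK layer advances the compartment state over each inter-event
interval (splitting it into constant-rate sub-segments at infusion ends)
using the parameters of the step that opened the interval.

Two state conventions, by design: the two-compartment head carries
**concentrations** across parameter changes (the curve is continuous, and
the model corrects itself smoothly), while the one-compartment head
carries **mass** (mass is conserved; concentration may jump when the
estimated volume changes).

Causality: the vancomycin-level input feature at a step is the most recent
level observed *strictly before* that step (0 before the first), and the
prediction at a level event is the propagated concentration at arrival —
computed before the event's own features touch the recurrent state.
Truncating a timeline after time t therefore leaves every prediction at
≤ t bitwise unchanged (tested).

### Loss and training

    total = MSE + w1·prior + w2·smoothness

MSE is over observed levels; the prior penalty is the mean over steps of
ηᵀ Σ_prior⁻¹ η; the smoothness penalty is the mean over consecutive step
pairs of ‖η_t − η_{t−1}‖². Means (rather than raw sums) keep the penalty
strength independent of batch size and sequence length; the decomposition
identity holds exactly and each component is reported separately. The
penalty weights w1 = w2 = 1e-3 are package defaults (no published values
exist); sweeps over 0.1 and 1.0 did not change any qualitative outcome.

Training uses Adamax (lr 1e-2, weight decay 0.2 added to the gradient),
minibatches of 50 encounters, and early stopping on validation MSE with
patience 10, restoring the best-validation weights. `max_epochs` defaults
to 50, sized for the desk-scale cohorts this package targets. Batch
membership is fixed per run (a seeded permutation of the training
encounters); everything is deterministic given `ModelConfig.seed`. The
whole computation — GRU, embedding average, and the closed-form PK layer —
is differentiated by the package's small reverse-mode engine
(`autodiff.py`); gradients flow through the analytic solution, never
through a discretized ODE.

## Data model and preprocessing

Encounters are ordered event timelines (doses, other medication
administrations, labs, vitals, measured levels, end-of-day markers) with
times in hours from the earliest record; the training view keeps
encounters with ≥ 1 level after the first dose and trims them at the last
level. Simultaneous events merge into one step. Preprocessing:
within-encounter forward fill, then training-split mean imputation, then
z-scoring with training-split statistics (zero-variance features map to
0) — statistics are provably untouched by test data. The 40-name feature
registry (4 core: time, time difference, dose, last observed level;
4 demographics; 5 vitals; 27 labs) is configurable; the checkpoint stores
its hash and the loader refuses mismatches. Serum creatinine is forward
filled and CrCL recomputed at every event where it changes. Splits are by
patient (50:30:20 by default), seeded.

Infusions run at a uniform 1 g/h by default (duration = dose/1000 h); the
dose-banded duration table (1000 mg → 1 h, ≤1500 → 1.5 h, ≤2000 → 2 h,
>2000 → 2.5 h) is available as `policy="mhhs"`.

## Sampling-design simulation

A trained "derived" model is the ground truth: its prospective curves,
evaluated at protocol times, replace the source cohort's measured levels
while every other event is kept verbatim. Designs combine location —
peak (2 h after infusion start for doses ≤ 1000 mg, 3 h above; the anchor
at infusion *start* is our reading of "post-infusion") and/or trough (1 h
before the next infusion; never before an encounter's first dose) — with
coverage (all doses, or a seeded random half; `every_other` available). A
scheduled sample falling inside a running infusion or not after the
previous sample is dropped, not moved, and counted. Estimated models are
trained from scratch on the simulated levels (provenance hashes prove no
weight sharing with the derived model); reports give mean ± SD test RMSE
over seeded repeats and a two-sample t-test (Student's pooled-variance;
Welch behind a flag).

The AUC/MIC metric is (total AUC / span) / MIC / max encounter dose, in
1/mg, with MIC defaulting to 1 mg/L (a susceptible-organism convention;
normalization makes it a scale factor). Comparison reports the RMSE of
each estimated model's per-encounter metric against the derived model's.

## Synthetic cohort generator

The generator emulates the *structure* of a hospital vancomycin-TDM
cohort, not its clinical content. Demographics are drawn to match the
published cohort summaries (age ≈ N(61, 18.5²) clipped to [18, 100];
weight lognormal with median 82.9 and IQR 65.5–101.6; height ≈ N(172,
11.9²); 55% male). Serum creatinine follows a patient-level AR(1) process
on the log scale (ρ = 0.9, innovation sd 0.08 around a lognormal
baseline), sampled daily. Dosing: ~15 mg/kg rounded to 750–2000 mg
strengths, every 8/12/24 h by CrCL band, 6–20 doses per encounter, infused
at 1 g/h. Measured levels are sparse and trough-dominant (1–4 per
encounter, 15% peaks) — values come from the exact two-compartment curve
under per-encounter η ~ prior plus additive Gaussian noise (sd 1 mg/L
default). Labs/vitals are Gaussian noise around typical values with 30%
missingness; medication codes are Poisson(2) draws from a Zipf-weighted
911-code vocabulary (structural realism only). Ground truth (η, noiseless
curves, CrCL series) lives in a sidecar, never in the observable CSVs.
Everything is deterministic per seed.

What passing tests on this cohort do **not** show: real EHR data have
physiologic correlations between labs and PK (here labs are pure noise),
measurement-time irregularities, dosing adjustments reacting to levels,
and renal trajectories far rougher than AR(1). Results on the synthetic
cohort validate the machinery and the relative model ordering, not
absolute clinical error levels.

`generate_recovery_suite` produces identification cohorts: static known η
per patient, dense peak+trough sampling for every dose, configurable
noise. Encounters whose source dosing course was truncated below 6 doses
are extended so every recovery encounter is informative.

## MAP baseline and identifiability

`map_bayes_update` maximizes the Gaussian log-prior plus the Gaussian
observation log-likelihood under the exact two-compartment curve
(L-BFGS-B from the prior mode; non-convergence is flagged with
diagnostics, and zero observations return the prior mode). The assumed
measurement sd should match the data's: for noiseless recovery data we
floor it at 0.001 mg/L (the interpolation regime). This matters because peak+trough-only sampling
leaves a *near-flat identifiability ridge* — η vectors exist that fit
every sampled point to < 0.01 mg/L while the curves differ by several
mg/L inside the unsampled distribution phases. With an inflated assumed
sd the prior slides the estimate along this ridge; with a matched (small) sd the
tiny but nonzero residuals off truth dominate, and the estimate converges
to the generating eta as the assumed sd shrinks (componentwise error
~0.005 at the 0.001 mg/L floor).

The same ridge explains a broader finding quantified in our experiments:
with static η drawn from the prior, a *prospective MAP filter*
(re-estimating η from all past levels before each prediction) reaches
test RMSE ≈ 2 mg/L at 1 mg/L noise — essentially the Bayes floor. A
recurrent network trained on ~25 encounters cannot amortize that filter
and plateaus near the population-model error; on cohorts an order of
magnitude larger it improves but remains far from the floor. By contrast,
when the ground truth is itself a derived *model* (a deterministic
function of the observable inputs, as in the sampling-design simulation),
the matching estimator learns it readily — there the two-compartment
estimator attains sub-mg/L RMSE while the misspecified one-compartment
estimator cannot reproduce the distribution-phase peaks, and the ordering
between them is stable across seeds.

## Numerical choices and degenerate inputs

- Zero-duration segments are exact identities; zero-dose timelines give
  identically zero predictions.
- Padded batch entries carry CrCL 100 and zero durations so the shared
  closed form never sees a singular system; padded steps are masked out of
  every loss term.
- Non-finite activations or a non-finite loss abort training with the
  step/epoch in the message.
- t-test convention: two zero-variance groups with equal means give
  p = 1.
- Curve evaluation at a piece boundary is continuous to < 1e-9 for the
  two-compartment model by construction.

## Known limitations

- The closed form covers two compartments with linear elimination only;
  no nonlinear (Michaelis–Menten) clearance, no 3+ compartments.
- The embedding vocabulary is structural; no attempt is made to give
  medication codes pharmacological meaning.
- The one-compartment head shares the GRU architecture and differs only
  in its PK layer, which is the intended controlled comparison, but means
  conclusions about "1CM vs 2CM" are conditional on this shared backbone.
- Reported problem sizes (50-patient recovery cohorts, 150–200-patient
  simulation cohorts, 3–5 repeats) are the package's desk-scale defaults;
  all are configurable upward.
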