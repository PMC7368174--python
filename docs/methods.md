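# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `dshrisk`, and what the synthetic cohort does and does not show.

## Severity hierarchy and scoring

Each condition is represented as a complete binary tree whose root encodes
disease presence and whose levels refine severity; right branches always
denote intensification. The default decision ladder, truncated to the
configured depth (2–6, default 4), is

| level transition | right branch |
|---|---|
| 1 → 2 | requires therapy |
| 2 → 3 | second-line-or-beyond therapy |
| 3 → 4 (depth 5–6 only) | last-line therapy / dose increase |
| final | uncontrolled (control measurement outside its reference range) |

At depth 4 the ladder is presence → treated → line → control. Scores obey
root ∈ {0, 1}, left child = parent, right child = 2 × parent, so the depth-4
maximum is 8 and in general 2^(depth−1).

Classification of a patient state at age *t* within the baseline window:

- **Presence** is sticky: once a condition is indicated (diagnosis code or
  any lab criterion met at an encounter) it remains present — the chronic
  conditions modeled here do not resolve. Therapy for a condition also
  implies presence, which reproduces the situation of a well-controlled
  treated patient whose labs never cross the diagnostic threshold.
- **Treatment** derives from medication orders of the condition's mapped
  drug classes; an order keeps its class active until the end of the
  baseline window (EHR order data carry no reliable stop dates). Therapy
  line is the highest line among active classes; for hypertension, three
  or more concurrent classes count as last line.
- **Control** uses the most recent control measurement at or before *t*
  (HbA1c < 6.5%, SBP/DBP < 140/90 mmHg, LDL < 100 mg/dL). An unknown
  control status maps to the left (non-intensifying) branch rather than
  being imputed as uncontrolled.
- **Obesity** is graded by BMI bands (≥ 30 presence, ≥ 35, ≥ 40) with a
  rising BMI trend as the final intensification, since its management is
  not drug-line structured.
- Events sharing an age are ordered diagnosis → medication → lab/vital
  before classification, so the day's actions are visible to the state.

The blood-pressure indication 140/90 is read as SBP ≥ 140 **or**
DBP ≥ 90 (the standard clinical reading); lab indications require a single
occurrence, not confirmation on repeat. Diagnosis codes are opaque strings
checked against the configured set; the shipped code lists are
illustrative, not curated terminologies.

## Feature engineering

Per patient, the time-varying baseline observations collapse to:

- `dsh_<condition>_{sum,mean,last}` — aggregates of the per-encounter score
  trajectory (12 columns for the default four conditions);
- `com_<condition>_{rolling,most_frequent}` — rolling comorbidity (ever
  indicated, persisting under stickiness) and the modal raw per-encounter
  indication with ties resolved to 1;
- `med_<class>_{freq,any}` — order counts and any-use indicators per drug
  class;
- `lv_<measurement>_{freq,median,last}` — lab/vital summaries; columns with
  ≥ 35% missingness are dropped (the strict "< 35%" retained-set reading),
  the rest imputed by iterative random-forest conditional modeling
  (30 trees, 5 rounds, seeded). Only lab/vital columns can be missing; all
  other groups are structurally complete. Inside cross-validation the
  imputer is fit on training folds only and applied to held-out folds to
  avoid leakage — a deliberate tightening of the usual impute-then-model
  practice.
- Sex and race enter as reference-coded indicators and are left
  unpenalized by default (they are adjusters, not selectable features);
  `CoxnetCPH(unpenalized=...)` overrides this.

## Left-truncated elastic-net Cox

The fit maximizes the Breslow partial likelihood on the age scale with
delayed entry (risk set of an event at age *t* is {entry < t ≤ exit}),
penalized by λ·Σ pf_j(α|β_j| + (1−α)/2 β_j²) with the likelihood normalized
per observation. No installed library combines delayed entry with a
coordinate-descent elastic net, so the solver is implemented here:
iteratively reweighted least squares with the Poisson-trick weights
(w = expected event count, giving the exact score equation at the fixed
point) and cyclic coordinate descent with soft thresholding — coefficients
are exactly zero under the lasso. Columns are standardized internally;
coefficients are reported on the original scale.

Numerical safeguards: the linear predictor is centered and clipped at ±30
(the likelihood is shift-invariant); standardized coefficients are bounded
at ±15, since a hazard ratio beyond e¹⁵ per standard deviation signals
quasi-separation rather than signal; risk-set sums are computed in
O(n log n) via sorted suffix sums. Path fits use warm starts over 50
log-spaced strengths per mixing value (λ_min/λ_max = 0.01 by default) and a
convergence tolerance of 1e-5 on standardized coefficients (1e-7 for the
final refit); ties in cross-validated deviance resolve to the stronger
penalty.

Penalty selection uses the Verweij–Van Houwelingen cross-validated
deviance, −2·(ℓ(all data; β₋f) − ℓ(training folds; β₋f)), which remains
defined when a held-out fold has few events; folds are stratified by event
status with a fixed seed. Prediction at horizon *h* is
1 − exp(−H₀(h)·exp(lp − l̄p)) with the Breslow baseline cumulative hazard
anchored at the mean linear predictor; risks are therefore 0 below the
first observed event age and non-decreasing in *h*.

## Censoring-aware evaluation

At horizon *h*, "event by *h*" vs "event-free at *h*" is decided only for
patients with entry < *h*; later entrants are alive at *h* by the
truncation condition alone and would dilute the negative class. IPCW
weights come from a Kaplan–Meier fit of the censoring distribution with
delayed entry: events by *h* weigh 1/G(exit⁻), survivors 1/G(h), patients
censored before *h* weigh 0. Weights are capped (default 10⁴) with a
warning; with ~5-year administrative censoring on the age scale G(80) is of
order 10⁻³, so a tight cap would silently bias late horizons. When a
cross-validation fold is evaluated, G is estimated on the full cohort —
small-fold KM tails are too unstable.

The weighted AUC is the probability that an event patient outranks a
survivor (ties ½), computed by a grouped sweep that exactly matches pair
enumeration. The decision threshold for accuracy/sensitivity/specificity/
PPV maximizes the weighted Youden index on training data and is applied
unchanged to held-out data. Gain curves pool tied risks (so exchangeable
risks give the diagonal) and the Gini score is the area between the gain
curve and the diagonal normalized by the same area for the
label-sorted perfect ranker; net benefit is
(TP − FP·p/(1−p))/n_effective; calibration uses equal-frequency bins with
weighted observed event fractions, merging bins when risks have fewer
distinct values.

`compare_models` is a nested cross-validation: an outer stratified 10-fold
loop holds out each fold once, while imputation, penalty selection (inner
cross-validation) and threshold choice all happen on the training side.
Fold means are reported with normal-approximation 95% intervals. Inner
folds default to 5 — with 10 the training risk sets at early horizons
become too thin to be informative, and the selection is stable from 5 up.

## Synthetic cohort

The generator writes **raw events only** — dated diagnoses, control
labs/vitals, medication orders with dose-change flags — and keeps the
intended severity as ground truth, so "the hierarchy recovers severity" is
a falsifiable claim, not a tautology (Spearman ρ between derived `dsh_sum`
and integrated latent severity exceeds 0.85 per condition under defaults).

Defaults describe a primary-care cohort: index age uniform on 45–79, a
6-year baseline window, ~4 encounters/year, 5 years of follow-up,
administrative censoring plus 3%/year dropout. Per condition: onset
probability (t2d 0.28, hypertension 0.75, hyperlipidemia 0.65, obesity
0.45) with a prevalent fraction before index; control measurements drawn
around a mean that sits above the reference while untreated, is reduced
per therapy line scaled by a patient-specific log-normal responsiveness
(σ = 0.5 — refractory patients exist), and drifts upward with disease
duration; escalation with probability 0.45 per uncontrolled encounter.
Healthy measurements are drawn from normals truncated just below each
diagnostic threshold: a patient who does not have the condition must not
meet its defining criterion, which keeps ground truth and derived presence
consistent.

Event ages are inverse-transform draws from a Weibull baseline on the age
scale (shape 6; scales 120 for ACM and 126 for MCE) conditioned on survival
to follow-up entry, with log-hazard linear in each condition's severity on
the **branch-doubling scale** (0 absent, else 2^(ordinal−1) ∈ {1, 2, 4, 8};
coefficients 0.22/0.16/0.10/0.12 per unit for ACM). Measuring severity on
the doubling scale makes deep uncontrolled states dominate the hazard —
the regime the hierarchy is designed for — and control status reaches the
features only through labs, which the comorbidity+medication feature set
does not see. With the defaults the cohort yields ≈ 9% ACM and ≈ 8% MCE
over follow-up, and the hierarchy feature set outranks the
comorbidity+medication set in held-out AUC at every horizon. Follow-up
ends at the first of ACM, MCE or censoring; analyses of one outcome treat
the other as censoring.

What the generator does **not** emulate: real coding vocabularies and
coding noise, visit-pattern informativeness (encounter timing is
independent of severity), measurement error correlated across labs,
treatment nonadherence, inter-condition causal structure beyond shared
hazard contributions, and informative censoring. Passing tests therefore
show the pipeline recovers a known severity-driven signal under clean
conditions; they do not certify performance on real EHR data.

## Problem sizes

The test suite and examples run the comparison at n = 4000 patients with a
12-strength lasso path and 4 inner folds, the severity-recovery check at
n = 2000, and Monte-Carlo metric checks at n = 5000 — sizes chosen so each
check has clear statistical resolution on a single CPU.

## Known limitations

- Tree structure is configured, not learned; a mis-specified ladder
  degrades the scores silently.
- Medication "active until window end" overstates exposure when therapy is
  stopped; dose decreases are recorded but do not map to a de-escalation
  branch at depth 4.
- The IPCW estimators assume censoring independent of the event given
  entry age; the generator satisfies this, real cohorts may not.
- `most_frequent` comorbidity is computed over encounters, not calendar
  slices; patients with sparse encounters weigh each encounter more.
- With very small folds the penalized fit can sit at the coefficient box
  bound under quasi-separation; the bound is reported via the fitted
  coefficients rather than raised as an error.
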