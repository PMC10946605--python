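# Methods

## The estimation problem

In longitudinal MS registries, treatment decisions respond to the disease:
patients with recent relapses or accumulating disability are more likely to
start a disease-modifying therapy (DMT), and those covariates also predict
the outcomes of interest.  Because such time-varying confounders are
themselves affected by earlier treatment, conditioning on them in an
outcome regression blocks part of the treatment effect, while ignoring them
leaves confounding by indication.  Marginal structural models (MSMs) with
inverse-probability-of-treatment weighting solve this: each 6-month
patient-interval is weighted by the inverse probability of the treatment
state actually observed, given treatment and covariate history, producing a
pseudo-population in which treatment is sequentially unconfounded with
respect to the measured history.  A weighted Cox model on that
pseudo-population then estimates the per-protocol hazard ratio of treated
versus untreated person-time.

The package implements the full chain — registry model, eligibility,
confirmed-event derivation, panel construction under three target-trial
designs, stabilized weights, weighted Cox inference — plus a synthetic
registry generator whose ground truth makes every stage verifiable by
parameter recovery.

## Data model and conventions

Dates are integer days (epoch 2000-01-01); 1 year = 365 days, 6 months =
183 days.  EDSS values live on the ordinal grid {0, 1.0, 1.5, ..., 10.0}
(no 0.5).  Relapses closer than 30 days to the previous one are merged into
a single episode at the earlier onset (a strict-reject policy is available).
Open treatment episodes run through the end of observed follow-up.

Eligibility requires: first-to-last EDSS span of at least 365 days, at
least three EDSS scores, no gap between consecutive scores above 365 days
(the stricter, unambiguous reading of "at least one score per year"), and a
non-missing minimum dataset.  The relapsing cohort excludes patients who
are progressive at their first EDSS visit and censors follow-up at
conversion to secondary progressive MS; the full cohort keeps all
phenotypes, with MS course entering as a time-dependent covariate instead.

## Confirmed disability events

EDSS scores recorded fewer than 30 days after a relapse onset are excluded
before event detection.  Disability worsening is an EDSS increase by one
step (1.5 when the reference is 0; 0.5 above 5.5), improvement the
symmetric decrease (1.5 at or below 1.5; 0.5 above 6).  An event is emitted
at the first score meeting the required step from the current reference,
provided a recorded score at least 365 days after onset exists and every
recorded score up to and including that first distant score holds the
threshold.  No carried-forward values ever enter event detection, and a
trajectory ending within 365 days of a qualifying change yields no event.

The reference is *roving* by default — it resets to the onset score after
each confirmed event, so sequential events are measured from the new
plateau, matching registry practice for recurrent disability endpoints.  A
`fixed_baseline` policy (reference fixed at the first cleaned score,
time-to-first-event semantics per direction) is provided for sensitivity.
An intercurrent relapse between onset and confirmation does not void an
event; only the score-exclusion rule applies.

The detector is a single chronological pass; the test suite holds it
against an independent brute-force checker that enumerates every
(onset, confirmation) pair, exhaustively over all EDSS trajectories of
length up to 6 on an 8-value grid and a fixed date lattice.

## Panels and target-trial designs

Follow-up is divided into half-open 183-day bins; a final fragment shorter
than 15 days is dropped to avoid near-zero at-risk intervals.  A bin is
*treated* when the union of DMT episodes covers at least 15 of its days —
a deliberately conservative classification that counts lingering and
incipient exposure as treated.  Covariates are measured at bin start (age,
MS duration, annualized relapse rates over the prior 12 and 24 months,
fraction of previous bins treated, MRI activity within the past 365 days,
phenotype, pregnancy overlap).  The bin's descriptive EDSS is the last
recorded score on or before bin end, flagged when carried forward from an
earlier bin; a separate `edss_prebin` column holds the last cleaned score on or
before bin *start*, and it is this column the weight models use: the
bin-end value can already contain the bin's own disability outcome (a
worsening onset inside the bin raises the carried score), which must not
feed the weights.

- **Design A** (primary): time zero at the first cleaned EDSS score;
  patients may move untreated → treated once; follow-up is censored at the
  first treatment discontinuation.  The treated indicator is therefore
  non-decreasing within a patient.
- **Design B**: time zero at MS onset; free switching; bins before the
  first EDSS record carry a missing-EDSS marker and contribute to the
  weight models through their non-EDSS covariates plus the missingness
  indicator.
- **Design C**: time zero at the first EDSS score, with the bin clock
  restarting at every change of the episode-level treated state (each
  segment is a new at-risk spell; treatment is constant within a segment).

The previous-state indicator at a patient's very first bin is classified
from the 183 days before time zero, so patients already on therapy at
baseline enter with their true prior state.

## Stabilized weights

For patient *i* and bin *j* the stabilized weight is the running product
over k = 0..j of P(A_k = a_k | A_{k-1}, S) / P(A_k = a_k | A_{k-1}, T_k, S),
where S contains sex, MS duration at first visit and date of birth (plus MS
onset date in the denominator set, to absorb calendar-time trends in DMT
availability) and T the time-dependent covariates (age, pregnancy,
treatment history, relapse history, MS duration, chart EDSS, MS course).
The product restarts per at-risk segment under design C.

Conditioning on the previous state is implemented exactly, by fitting a
separate pooled logistic within each stratum of the previous state; each
patient's first bin forms its own stratum, because the baseline treatment
state is a cross-sectional outcome selected by pre-baseline history and
must be modelled, not passed through.  (The since-onset relapse rate is
deliberately left out of the baseline model: under an effective therapy it
is partly a mediator of pre-baseline treatment.)  Under design A the
previously-treated stratum is structurally constant (treated patients
cannot revert without being censored): it is represented by that constant,
shared by numerator and denominator, so those bins contribute weight
exactly 1.  A stratum whose minority class has fewer than 50 bins is
likewise reduced to its empirical constant — a handful of transitions
carries no usable covariate information, and a shared constant contributes
weight 1 rather than noise.

Numerically, covariates are standardized before fitting, and exactly
collinear columns are removed by pivoted QR — age, MS duration, birth year
and onset year are linearly dependent by construction (age − duration =
onset − birth), as they are in any registry.  Fitted probabilities are
clipped to [0.01, 0.99] before the ratio is formed; weights are winsorized
at their empirical 1st and 99th percentiles by default ((0, 1) disables
truncation).  When a treatment-by-modifier interaction is analysed, the
modifier's columns are removed from both weight models and the resulting
`WeightSet` records the exclusion; the outcome model refuses weights whose
recorded exclusion does not match the requested modifier.

## Outcome models

All outcome models are counting-process Cox regressions on the bin
intervals, time measured from the design's baseline (segment-local under
design C), weighted by the truncated stabilized weights.  Relapses use the
per-bin binary indicator with recurrent at-risk intervals (Andersen–Gill),
so a patient contributes every bin and possibly several event bins.
Disability outcomes use time to the first confirmed event; later bins are
removed from that outcome's risk set.  Interactions enter as
treated × modifier products (EDSS and ARR continuous per-step/per-unit,
MRI activity and phenotype categorical); stratified analyses cut the
modifier at sample quartiles by default and flag unestimable strata rather
than dropping them; the full-cohort three-way model contains
treated × phenotype × prior-ARR with all nested terms.

Point estimates come from lifelines' Cox fitter (Efron ties).  The variance
is a robust sandwich clustered on patient — mandatory, since weighting
induces within-patient dependence — assembled from vectorized
counting-process score residuals in the Breslow form: the cluster-summed
residuals U_g give V = I⁻¹ (Σ_g U_g U_gᵀ) I⁻¹ with I the observed
information.  The implementation agrees with R `survival::coxph(...,
weights=, cluster(id), ties="breslow")` to four decimals on reference data
(a frozen comparison is in the test suite); it exists because the
ready-made robust path in the Python fitter recomputes residuals row by
row and is orders of magnitude too slow for simulation studies.  Estimated
weights are treated as fixed in the variance, the standard MSM practice;
simulation shows this can be mildly anti-conservative here (see
Limitations).  A discrete-time pooled logistic estimator with
cluster-robust variance is provided as a cross-check for the relapse
outcome, and a treated × time trend term serves as the proportional-hazards
diagnostic.

## The synthetic registry

The generator emulates the causal structure the analysis assumes.  Disease
state advances on a 30-day tick; treatment and pregnancy decisions are made
at 183-day epochs anchored at each patient's first visit (the clinic-review
cadence), extending back before baseline so that patients can enter already
treated.  Per tick:

- relapses arrive with intensity
  `baseline_relapse_rate · exp(frailty) · exp(A·log true_hr_relapse)`
  (0.30/year untreated by default); the patient-level frailty (log-normal,
  sd 0.25) makes relapse history genuinely predictive of future relapses,
  so the initiation rule below creates real confounding by indication
  through a fully recorded variable (every relapse since onset is in the
  registry); an optional `relapse_edss_loading` adds a disability term to
  the intensity, off by default because pre-baseline treatment selection
  on EDSS values the registry never records would constitute unmeasured
  confounding for prevalent users, which is outside the assumed causal
  structure;
- the latent EDSS performs a bounded walk on the valid grid whose moves are
  full reference-dependent steps (so one sustained up-move is a confirmable
  worsening and the confirmed-event hazard scales linearly with the
  per-move effect); treatment multiplies the up-move probability by
  `true_hr_worsening` and the down-move probability by
  `true_hr_improvement`;
- each relapse adds a transient +1-step bump to observed scores for a
  random 30–90 days, giving the 30-day post-relapse exclusion rule real
  work to do; visit scores also carry occasional ±0.5-step noise;
- treatment initiation is logistic in relapses of the past year
  (coefficient = `confounding_strength`, default 1.0 in the confounded
  scenarios) and the last recorded EDSS (half that coefficient), with an
  intercept of −3.2 chosen so that roughly 60% of patients are already
  treated at their first visit and about three quarters of follow-up bins
  are treated, matching the registry pattern the analysis targets;
  discontinuation is a constant per-epoch probability (higher during
  pregnancy, when initiation is also penalized);
- CIS converts to RRMS at the first recorded relapse; RRMS converts to
  SPMS by hazard once EDSS ≥ 3; progressive phenotypes accrue disability
  faster and relapse rarely; MRI activity is an annual binary assessment
  correlated with recent relapses, frailty and treatment.

Visit schedules are irregular (normal intervals, mean 180 days, sd 45,
clipped to [30, 330]); follow-up lengths are gamma (mean 8 years, shape 2),
so attrition through the eligibility rules stays below 20%.  The number and
order of random draws per tick does not depend on the evolving state, so
forcing treatment always-on versus always-off replays the identical
randomness: the counterfactual oracle measures the realized per-protocol
effect of a scenario by that paired comparison.  The relapse-rate ratio
recovers `true_hr_relapse` almost exactly; the disability ratios pass
through the confirmation machinery and recover their nominal values
approximately.

Named scenarios: `null` (no effect, confounding on), `protective`
(relapse HR 0.5, worsening 0.55, improvement 1.3, confounding on),
`no_confounding` (the same effects, confounding off), `modified_by_edss`
(the treated log-effect on relapses rises by 0.3 per EDSS step, centred at
2.5 — attenuation with disability), and `phenotype_specific` (25%
progressive patients who derive no treatment benefit).

## What the generator does and does not emulate

It reproduces the longitudinal structure the method needs: irregular
visits, carry-forward gaps, confounding by indication through recorded
history, phenotype transitions, censoring-by-discontinuation, transient
post-relapse EDSS elevation.  It does not model per-DMT heterogeneity
(a single pooled "DMT", as in the analysis it supports), MRI lesion counts
beyond a binary activity flag, center effects or data-quality artifacts,
informative visit timing, or mortality.  Passing recovery tests on this
generator therefore demonstrates the estimator chain is correct under its
stated assumptions — not that those assumptions hold in any particular
registry.

## Numerical and design choices

- Bins of exactly 183 days; last fragment kept if ≥ 15 days.
- Probability floor/ceiling 0.01/0.99; default truncation quantiles
  (0.01, 0.99); both configurable.
- Quartile cut points deduplicate on the discrete EDSS grid, so stratified
  analyses may return fewer than four strata; they are labelled with their
  value ranges.
- The treatment-model separation check operates on standardized
  coefficients (|β| > 15 names the offending covariate); an all-treated or
  all-untreated panel raises a degenerate-model error before fitting.
- Determinism: a single integer seed drives the generator; the pipeline
  writes a manifest of SHA-256 content hashes, and reruns with the same
  configuration reproduce the hashes bit for bit.

## Known limitations

- The weighted partial likelihood leaves a small positive finite-sample
  residual (about +0.02 on the log-HR scale at 1000–2000 patients) when
  confounding is strong, so the Cox-based MSM removes roughly half to
  two-thirds of the naive confounding bias rather than all of it.  An
  extensive simulation audit excluded unmeasured confounding (adding the
  true frailty to the weight model changes nothing), weight truncation and
  clipping, covariate misalignment, censoring channels, baseline-model
  functional form, and tie handling (splitting event bins at the recorded
  event day reproduces the same estimate).  The discriminating observation
  is that the pooled-logistic estimator applied to the *same* stabilized
  weights is essentially unbiased: the weights achieve the intended
  balance, and the residual is a property of the weighted partial
  likelihood with estimated, compounded weights on heavily tied interval
  data.  The pooled-logistic cross-check is therefore the recommended
  sensitivity analysis whenever the two estimators disagree.
- The fixed-weight sandwich variance is mildly anti-conservative for the
  recurrent-relapse outcome under strong confounding (mean estimated SE
  about 0.9 of the Monte-Carlo SD); bootstrap or stacked
  estimating-equation variances would repair this at substantial cost and
  are out of scope.
- Under design A, the marginal standardized mean difference of prior-ARR
  between treated and untreated bins does not vanish after weighting when
  treatment truly reduces relapses: prior ARR over a window overlapping
  treated time is a mediator of past treatment, not a baseline confounder,
  and the weighted pseudo-population is not supposed to balance it.  The
  chart-EDSS difference does balance (|SMD| well under 0.1).
- Design B's onset-anchored bins are offset from the clinic-review epochs
  at which the generator makes decisions, so its weight model sees slightly
  misaligned covariates and retains a small residual confounding that
  designs A and C do not; the design-concordance checks therefore run on
  the confounding-free scenario.
- Inverse-probability-of-censoring weights are not constructed (design A's
  censoring at discontinuation is part of the emulated trial's protocol);
  doubly-robust estimators and per-DMT contrasts are out of scope.
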