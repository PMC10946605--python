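"""Estimate stabilized weights and check covariate balance.

Builds the design-A panel for a confounded synthetic cohort, fits the
numerator/denominator treatment models, and compares treated-vs-untreated
standardized mean differences before and after weighting.  Values near 0
mean the weighted pseudo-population no longer associates the covariate
with treatment.
"""

from msmtrial import (
    build_cohort_panel,
    clean_edss,
    compute_stabilized_weights,
    default_scenarios,
    detect_confirmed_events,
    filter_eligible,
    fit_treatment_models,
    simulate_cohort,
    standardized_mean_difference,
    truncate_weights,
)

params = default_scenarios()["protective"]
params.n_patients = 1500
params.seed = 3

records, _ = simulate_cohort(params)
eligible = filter_eligible(records, "relapsing")
events = {
    r.patient_id: detect_confirmed_events(clean_edss(r.visits, r.relapses))
    for r in eligible.records
}
panel = build_cohort_panel(eligible.records, "A", events, "relapsing")

models = fit_treatment_models(panel)
weights = truncate_weights(compute_stabilized_weights(panel, models))
w = weights.table["w_truncated"].to_numpy()

print(f"bins: {len(panel)}, treated fraction: {panel['treated'].mean():.2f}")
print("weight diagnostics:", {k: round(v, 3) for k, v in weights.diagnostics.items()})
for cov in ("edss_prebin", "arr_since_onset", "arr_prior_12m"):
    before = standardized_mean_difference(panel, cov)
    after = standardized_mean_difference(panel, cov, w)
    print(f"SMD {cov:16s} unweighted {before:+.3f} -> weighted {after:+.3f}")
print(
    "Pre-treatment covariates (chart EDSS, relapse history) balance out; "
    "the 12-month ARR keeps a negative weighted SMD because treatment "
    "itself suppresses relapses in the window - a mediator, not residual "
    "confounding."
)
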