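"""Detect treatment-effect modification by disability level.

In the ``modified_by_edss`` scenario the treated log hazard ratio for
relapses rises by 0.3 per EDSS step (the drug works best in mild
disability).  The weights are re-estimated with EDSS excluded — the
modifier must not sit in the weight model when its interaction is the
estimand — and the interaction plus EDSS-stratified hazard ratios are
reported.
"""

from msmtrial import (
    build_cohort_panel,
    clean_edss,
    compute_stabilized_weights,
    default_scenarios,
    detect_confirmed_events,
    filter_eligible,
    fit_interaction,
    fit_stratified,
    fit_treatment_models,
    simulate_cohort,
    truncate_weights,
)

params = default_scenarios()["modified_by_edss"]
params.n_patients = 3000
params.seed = 9

records, _ = simulate_cohort(params)
eligible = filter_eligible(records, "relapsing")
events = {
    r.patient_id: detect_confirmed_events(clean_edss(r.visits, r.relapses))
    for r in eligible.records
}
panel = build_cohort_panel(eligible.records, "A", events, "relapsing")

models = fit_treatment_models(panel, interacted_modifier="edss")
weights = truncate_weights(compute_stabilized_weights(panel, models))

inter = fit_interaction(panel, weights, "relapse", "edss")
print(
    f"DMT x EDSS interaction: HR {inter.hazard_ratio:.3f} "
    f"({inter.ci_lower:.3f}-{inter.ci_upper:.3f}) per EDSS step, "
    f"p = {inter.p_value:.2g}  [generated with exp(0.3) = 1.35 per step]"
)
print("\nstratified treated-vs-untreated HRs across EDSS quartiles:")
for row in fit_stratified(panel, weights, "relapse", "edss"):
    if row.estimable:
        print(f"  {row.stratum:28s} HR {row.hazard_ratio:.3f} "
              f"({row.ci_lower:.3f}-{row.ci_upper:.3f})")
    else:
        print(f"  {row.stratum:28s} unestimable")
print(
    "\nAn interaction HR above 1 with rising stratum HRs reproduces the "
    "attenuation-with-disability pattern the scenario encodes."
)
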