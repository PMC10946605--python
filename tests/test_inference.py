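"""Weighted Cox inference: identities, sandwich variance, interactions."""

import numpy as np
import pandas as pd
import pytest

from msmtrial.errors import DomainError, EstimationError
from msmtrial.inference import (
    fit_interaction,
    fit_msm,
    fit_pooled_logistic,
    fit_stratified,
    fit_three_way,
    proportional_hazards_trend,
)
from msmtrial.weights import (
    WeightSet,
    compute_stabilized_weights,
    fit_treatment_models,
    truncate_weights,
)


@pytest.fixture(scope="module")
def fitted_weights(protective_panel):
    models = fit_treatment_models(protective_panel)
    return truncate_weights(compute_stabilized_weights(protective_panel, models))


def unit_weights(panel):
    tab = panel[["patient_id", "segment", "bin_index"]].copy()
    tab["p_num"] = 1.0
    tab["p_den"] = 1.0
    tab["w"] = 1.0
    tab["w_truncated"] = 1.0
    return WeightSet(table=tab)


# ---------------------------------------------------------------------------
# Identities and contracts
# ---------------------------------------------------------------------------


def test_unit_weights_equal_unweighted_fit(protective_panel):
    """Weights identically 1 reproduce the naive Cox fit exactly."""
    for outcome in ("relapse", "worsening"):
        w1 = fit_msm(protective_panel, unit_weights(protective_panel), outcome)
        w0 = fit_msm(protective_panel, None, outcome)
        assert w1.log_hr == pytest.approx(w0.log_hr, abs=1e-12)
        assert w1.se == pytest.approx(w0.se, abs=1e-12)


def test_misaligned_weights_rejected(protective_panel, fitted_weights):
    broken = WeightSet(table=fitted_weights.table.iloc[:-10])
    with pytest.raises(DomainError, match="misaligned"):
        fit_msm(protective_panel, broken, "relapse")


def test_zero_events_is_estimation_error(protective_panel):
    quiet = protective_panel[protective_panel["relapse_outcome"] == 0]
    with pytest.raises(EstimationError, match="no relapse events"):
        fit_msm(quiet, None, "relapse")


def test_unknown_outcome_rejected(protective_panel):
    with pytest.raises(DomainError):
        fit_msm(protective_panel, None, "fatigue")


def test_result_invariants(protective_panel, fitted_weights):
    res = fit_msm(protective_panel, fitted_weights, "relapse")
    assert res.ci_lower <= res.hazard_ratio <= res.ci_upper
    assert 0 <= res.p_value <= 1
    assert res.n_events <= int(protective_panel["relapse_outcome"].sum())
    assert res.n_patients == protective_panel["patient_id"].nunique()


# ---------------------------------------------------------------------------
# Robust variance against the reference implementation
# ---------------------------------------------------------------------------


def test_sandwich_matches_r_survival_oracle():
    """Point estimate and clustered sandwich agree with survival::coxph.

    Frozen oracle (R survival 3.8-3) on the deterministic weighted
    mini-panel below:
      coxph(..., weights=w, ties="efron")   -> coef -0.2287235
      coxph(..., weights=w, ties="breslow") -> robust se 0.66186807
    The package fits Efron ties (lifelines) and computes the Breslow-form
    clustered sandwich, so each side is compared with its R counterpart.
    """
    spec = {  # pid -> (treated, event bins, n bins, stabilized weight)
        "p1": (1, [1], 4, 1.4), "p2": (0, [0, 2], 3, 0.8),
        "p3": (1, [], 4, 1.1), "p4": (0, [1], 2, 0.7),
        "p5": (1, [0, 3], 4, 1.9), "p6": (0, [], 3, 1.0),
    }
    rows, wrows = [], []
    for pid, (a, evs, nb, w) in spec.items():
        for k in range(nb):
            rows.append({
                "patient_id": pid, "segment": 0, "bin_index": k,
                "start_date": k * 183, "end_date": (k + 1) * 183,
                "tstart": k * 183.0, "tstop": (k + 1) * 183.0,
                "treated": a, "relapse_outcome": int(k in evs),
            })
            wrows.append({
                "patient_id": pid, "segment": 0, "bin_index": k,
                "p_num": 1.0, "p_den": 1.0, "w": w, "w_truncated": w,
            })
    panel = pd.DataFrame(rows)
    res = fit_msm(panel, WeightSet(table=pd.DataFrame(wrows)), "relapse")
    assert res.log_hr == pytest.approx(-0.2287235, rel=2e-3)
    assert res.se == pytest.approx(0.66186807, rel=2e-2)


def test_pooled_logistic_close_to_cox(protective_panel, fitted_weights):
    """Rare per-bin events: pooled-logistic OR tracks the Cox HR."""
    cox = fit_msm(protective_panel, fitted_weights, "relapse")
    pl = fit_pooled_logistic(protective_panel, fitted_weights, "relapse")
    assert pl.log_hr == pytest.approx(cox.log_hr, abs=0.1)


# ---------------------------------------------------------------------------
# Interactions, strata, three-way
# ---------------------------------------------------------------------------


def test_interaction_requires_modifier_excluded_weights(protective_panel, fitted_weights):
    with pytest.raises(DomainError, match="excluded"):
        fit_interaction(protective_panel, fitted_weights, "relapse", "edss")


def test_interaction_runs_with_contract_weights(protective_panel):
    models = fit_treatment_models(protective_panel, interacted_modifier="edss")
    ws = truncate_weights(compute_stabilized_weights(protective_panel, models))
    res = fit_interaction(protective_panel, ws, "relapse", "edss")
    assert res.term == "treated:edss"
    assert res.ci_lower <= res.hazard_ratio <= res.ci_upper
    assert "EDSS step" in res.interpretation


def test_identical_strata_give_identical_estimates(protective_panel, fitted_weights):
    """Duplicating the cohort into two strata yields equal stratum HRs."""
    a = protective_panel.copy()
    b = protective_panel.copy()
    b["patient_id"] = "dup_" + b["patient_id"]
    a["age"], b["age"] = 30.0, 50.0  # same cohort placed in two age strata
    panel = pd.concat([a, b], ignore_index=True)
    wa = fitted_weights.table.copy()
    wb = fitted_weights.table.copy()
    wb["patient_id"] = "dup_" + wb["patient_id"]
    ws = WeightSet(table=pd.concat([wa, wb], ignore_index=True))
    out = fit_stratified(panel, ws, "relapse", "age", cut_points=[40.0])
    assert len(out) == 2
    assert out[0].hazard_ratio == pytest.approx(out[1].hazard_ratio, rel=1e-10)


def test_stratified_quartiles_cover_all_bins(protective_panel):
    models = fit_treatment_models(protective_panel, interacted_modifier="edss")
    ws = truncate_weights(compute_stabilized_weights(protective_panel, models))
    out = fit_stratified(protective_panel, ws, "relapse", "edss")
    assert 2 <= len(out) <= 4  # duplicate quantiles collapse on the step grid
    assert all(r.stratum is not None for r in out)


def test_stratified_flags_unestimable_stratum():
    """A stratum without events is returned flagged, not dropped."""
    rows = []
    for pid, treated in (("a", 1), ("b", 0), ("c", 1), ("d", 0)):
        for k in range(2):
            rows.append({
                "patient_id": pid, "segment": 0, "bin_index": k,
                "start_date": k * 183, "end_date": (k + 1) * 183,
                "tstart": k * 183.0, "tstop": (k + 1) * 183.0,
                "treated": treated, "age": 30.0 + 20.0 * (pid in "cd"),
                "relapse_outcome": int(pid in "ab" and k == 0),
            })
    panel = pd.DataFrame(rows)
    out = fit_stratified(panel, None, "relapse", "age", cut_points=[40.0])
    assert len(out) == 2
    assert not out[1].estimable
    assert out[1].n_events == 0


def test_three_way_needs_both_phenotype_groups(protective_panel):
    with pytest.raises(DomainError, match="both phenotype"):
        fit_three_way(protective_panel, None, "relapse")


def test_ph_trend_diagnostic_reports_pvalue(protective_panel, fitted_weights):
    out = proportional_hazards_trend(protective_panel, fitted_weights, "relapse")
    assert set(out) == {"trend_coef_per_year", "se", "p_value"}
    assert 0 <= out["p_value"] <= 1
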