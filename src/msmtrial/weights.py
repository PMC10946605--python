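"""Stabilized inverse-probability-of-treatment weights.

For each patient i and 6-month bin j the stabilized weight is

    w_ij = prod_{k=0..j}  P(A_ik = a_ik | A_ik-1, S_i)
                         ------------------------------------
                          P(A_ik = a_ik | A_ik-1, T_ik, S_i)

where A is the treated state, S the fixed/baseline stabilizing variables
(sex, MS duration at first visit, date of birth) and T the time-dependent
covariates (age, pregnancy status, treatment history, history of relapses,
MS duration, EDSS, MS course); MS onset date is included alongside age and
MS duration to absorb calendar-time trends in DMT availability.  Both the
numerator and the denominator are pooled discrete-time logistic models of
the per-bin treated state with the previous state as a covariate.

When a treatment-by-modifier interaction is analysed downstream, the
modifier is removed from both covariate sets (``interacted_modifier``), and
the resulting :class:`WeightSet` records that exclusion so the outcome
model can enforce it.

Fitted probabilities are clipped to a configurable floor/ceiling before the
ratio is formed, and weights can be winsorized at empirical quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, EstimationError

__all__ = [
    "NUMERATOR_COVARIATES",
    "DENOMINATOR_COVARIATES",
    "MODIFIER_COLUMNS",
    "TreatmentModels",
    "WeightSet",
    "fit_treatment_models",
    "compute_stabilized_weights",
    "stabilized_from_probs",
    "truncate_weights",
    "standardized_mean_difference",
]

NUMERATOR_COVARIATES = [
    "prev_treated", "sex", "ms_duration_at_first_visit", "birth_year",
]
# The EDSS entering the treatment models is the level known at bin start
# (edss_prebin): the bin-end carried value can already contain the bin's
# own disability outcome, which must not feed the weights.
DENOMINATOR_COVARIATES = NUMERATOR_COVARIATES + [
    "age", "pregnancy", "prior_treated_fraction", "arr_prior_12m",
    "arr_prior_24m", "ms_duration", "edss_prebin", "course", "onset_year",
]

# Panel columns removed from the weight models when a modifier is interacted
# with treatment in the outcome model.
MODIFIER_COLUMNS = {
    "age": ["age"],
    "ms_duration": ["ms_duration"],
    "edss": ["edss", "edss_prebin"],
    "arr": ["arr_prior_12m", "arr_prior_24m", "arr_since_onset"],
    "mri_activity": ["mri_activity_12m"],
    "phenotype": ["course"],
}

PROB_FLOOR = 0.01
PROB_CEILING = 0.99

# A prev-treated stratum whose minority class is smaller than this is
# modelled by its empirical constant probability: there is no usable
# covariate information in a handful of transitions, and a constant shared
# by numerator and denominator contributes weight exactly 1.
MIN_CLASS_FOR_FIT = 50

# Extra denominator covariates for the baseline (first-bin) stratum.
# Empty by default: the since-onset relapse rate is partly a mediator of
# pre-baseline treatment (therapy suppresses it), so conditioning the
# baseline propensity on it biases effect scenarios.
BASELINE_EXTRA_COVARIATES: list[str] = []


def _prev_strata(panel: pd.DataFrame) -> np.ndarray:
    """Stratum key per bin for the treatment models.

    Each patient's very first bin is its own stratum (-1): the baseline
    treatment state is a cross-sectional outcome — patients already on
    therapy at time zero were selected into it by their pre-baseline
    history, so it must be modelled, not treated as deterministic
    continuation.  Later bins are stratified by the previous state, which
    implements the conditioning on A_{k-1} exactly.
    """
    prev = panel["prev_treated"].to_numpy(float)
    first = ((panel["bin_index"].to_numpy() == 0)
             & (panel["segment"].to_numpy() == 0))
    return np.where(first, -1.0, prev)


def _design_matrix(panel: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Expand panel columns into a numeric design matrix with intercept."""
    X = pd.DataFrame(index=panel.index)
    for cov in covariates:
        if cov == "sex":
            X["sex_female"] = (panel["sex"] == "female").astype(float)
        elif cov == "course":
            for level in sorted(panel["course"].unique())[1:]:
                X[f"course_{level}"] = (panel["course"] == level).astype(float)
        elif cov == "mri_activity_12m":
            X["mri_active"] = (panel["mri_activity_12m"] == "active").astype(float)
            X["mri_not_assessed"] = (panel["mri_activity_12m"] == "not_assessed").astype(float)
        elif cov in ("edss", "edss_prebin"):
            col = panel[cov]
            X[cov] = col.fillna(0.0).astype(float)
            if col.isna().any():
                X[f"{cov}_missing"] = col.isna().astype(float)
        else:
            X[cov] = panel[cov].astype(float)
    # drop constant columns (single-level factors, degenerate covariates)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    return X[keep]


class _StratumGLM:
    """Pooled logistic for one prev-treated stratum.

    Covariates are standardized and exactly collinear columns dropped by
    pivoted QR before fitting (age, MS duration, birth year and onset year
    are linearly dependent by construction); predictions reapply the same
    transform.
    """

    def __init__(self, panel: pd.DataFrame, covs: list, y: np.ndarray):
        from scipy.linalg import qr as _qr

        self.covs = list(covs)
        X = _design_matrix(panel, self.covs)
        self.columns = list(X.columns)
        M = X.to_numpy(float)
        self.mean = M.mean(axis=0)
        sd = M.std(axis=0)
        sd[sd == 0] = 1.0
        self.sd = sd
        Z = np.column_stack([np.ones(len(M)), (M - self.mean) / self.sd])
        _, R, piv = _qr(Z, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        rank = int((diag > max(Z.shape) * np.finfo(float).eps * diag[0] * 100).sum())
        self.keep = np.sort(piv[:rank])
        try:
            self.result = sm.GLM(
                y, Z[:, self.keep], family=sm.families.Binomial()
            ).fit()
        except Exception as exc:  # perfect separation, singular matrix, ...
            raise EstimationError(f"treatment model failed to fit: {exc}") from exc
        if not np.all(np.isfinite(self.result.params)) or np.abs(self.result.params).max() > 15:
            j = int(np.nanargmax(np.abs(self.result.params)))
            names = ["const"] + self.columns
            offender = names[int(self.keep[j])]
            raise EstimationError(
                f"treatment model shows separation on covariate {offender!r}"
            )

    def predict_p1(self, panel: pd.DataFrame) -> np.ndarray:
        X = _design_matrix(panel, self.covs)
        M = X.reindex(columns=self.columns, fill_value=0.0).to_numpy(float)
        Z = np.column_stack([np.ones(len(M)), (M - self.mean) / self.sd])
        return np.asarray(self.result.predict(Z[:, self.keep]))


@dataclass
class TreatmentModels:
    """Fitted numerator/denominator treatment-probability models.

    Conditioning on the previous treated state A_{k-1} is implemented
    exactly: a separate pooled logistic is fitted within each
    ``prev_treated`` stratum (initiation model among previously untreated
    bins, continuation model among previously treated ones).  A stratum in
    which the current state is structurally constant — design A: once
    treated, a patient stays treated until censoring, so
    P(A=1 | A_prev=1) = 1 — is represented by that constant probability;
    numerator and denominator then agree there and the bin's weight
    contribution is exactly 1.

    ``num_models``/``den_models`` map the previous state (0.0/1.0) to
    either a fitted GLM result or a constant probability of being treated.
    """

    numerator_covs: list[str]
    denominator_covs: list[str]
    num_models: dict
    den_models: dict
    interacted_modifier: str | None = None
    prob_floor: float = PROB_FLOOR
    prob_ceiling: float = PROB_CEILING

    def predict_probs(self, panel: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
        """(p_num, p_den) of the *observed* state per bin, plus #clipped."""
        a = panel["treated"].to_numpy(float)
        strata = _prev_strata(panel)
        lo, hi = self.prob_floor, self.prob_ceiling
        clipped = 0
        out = []
        for covs, models in ((self.numerator_covs, self.num_models),
                             (self.denominator_covs, self.den_models)):
            p1 = np.empty(len(panel))
            fitted = np.zeros(len(panel), bool)
            for s, mdl in models.items():
                mask = strata == s
                if not mask.any():
                    continue
                if isinstance(mdl, float):
                    # constant stratum: shared by numerator and denominator,
                    # so these bins contribute weight ratio exactly 1
                    p1[mask] = mdl
                else:
                    p1[mask] = mdl.predict_p1(panel[mask])
                    fitted[mask] = True
            clipped += int((fitted & ((p1 < lo) | (p1 > hi))).sum())
            p1 = np.clip(p1, lo, hi)
            out.append(np.where(a == 1.0, p1, 1.0 - p1))
        return out[0], out[1], clipped


@dataclass
class WeightSet:
    """Per-bin stabilized weights with their probability components."""

    table: pd.DataFrame  # patient_id, segment, bin_index, p_num, p_den, w, w_truncated
    interacted_modifier: str | None = None
    truncation_bounds: tuple[float, float] | None = None
    diagnostics: dict = field(default_factory=dict)


def fit_treatment_models(
    panel: pd.DataFrame,
    numerator_covs: list[str] | None = None,
    denominator_covs: list[str] | None = None,
    interacted_modifier: str | None = None,
    prob_floor: float = PROB_FLOOR,
    prob_ceiling: float = PROB_CEILING,
) -> TreatmentModels:
    """Fit the pooled logistic numerator and denominator models.

    If ``interacted_modifier`` is given, its panel columns are removed from
    both covariate sets before fitting (the modifier must not appear in the
    model of weights when its interaction with treatment is analysed).
    """
    num_covs = list(NUMERATOR_COVARIATES if numerator_covs is None else numerator_covs)
    den_covs = list(DENOMINATOR_COVARIATES if denominator_covs is None else denominator_covs)
    augment_baseline = denominator_covs is None  # extras belong to the default set
    dropped: set = set()
    if interacted_modifier is not None:
        if interacted_modifier not in MODIFIER_COLUMNS:
            raise DomainError(f"unknown modifier {interacted_modifier!r}")
        dropped = set(MODIFIER_COLUMNS[interacted_modifier])
        num_covs = [c for c in num_covs if c not in dropped]
        den_covs = [c for c in den_covs if c not in dropped]

    a = panel["treated"].to_numpy(float)
    if len(panel) == 0 or a.min() == a.max():
        raise EstimationError(
            "treatment model is degenerate: all panel bins are "
            + ("treated" if len(panel) and a.min() == 1.0 else "untreated")
        )

    strata = _prev_strata(panel)
    fitted = []
    for which, covs in (("num", num_covs), ("den", den_covs)):
        models: dict[float, object] = {}
        for s in sorted(np.unique(strata)):
            stratum = panel[strata == s]
            a_s = stratum["treated"].to_numpy(float)
            minority = min(int(a_s.sum()), int(len(a_s) - a_s.sum()))
            if minority < MIN_CLASS_FOR_FIT:
                models[s] = float(a_s.mean())  # (near-)constant stratum
                continue
            covs_s = list(covs)
            if which == "den" and s == -1.0 and augment_baseline:
                # The baseline state summarises all pre-baseline decisions,
                # so its denominator additionally conditions on the full
                # recorded relapse history (rate since onset) rather than
                # the per-decision windows alone.
                covs_s += [c for c in BASELINE_EXTRA_COVARIATES
                           if c not in covs_s and c not in dropped
                           and c in panel.columns]
            models[s] = _StratumGLM(stratum, covs_s, a_s)
        fitted.append(models)

    return TreatmentModels(
        numerator_covs=num_covs,
        denominator_covs=den_covs,
        num_models=fitted[0],
        den_models=fitted[1],
        interacted_modifier=interacted_modifier,
        prob_floor=prob_floor,
        prob_ceiling=prob_ceiling,
    )


def stabilized_from_probs(
    keys: pd.DataFrame, p_num: np.ndarray, p_den: np.ndarray
) -> pd.DataFrame:
    """Cumulative-product weights from per-bin probability components.

    ``keys`` must hold patient_id, segment and bin_index sorted in
    chronological order within each (patient_id, segment); the running
    product restarts at every new at-risk segment.
    """
    out = keys[["patient_id", "segment", "bin_index"]].copy()
    out["p_num"] = np.asarray(p_num, float)
    out["p_den"] = np.asarray(p_den, float)
    ratio = out["p_num"] / out["p_den"]
    out["w"] = ratio.groupby(
        [out["patient_id"], out["segment"]], sort=False
    ).cumprod()
    out["w_truncated"] = out["w"]
    return out


def compute_stabilized_weights(
    panel: pd.DataFrame, models: TreatmentModels
) -> WeightSet:
    """Stabilized weights for every bin of ``panel`` under fitted models."""
    p_num, p_den, n_clipped = models.predict_probs(panel)
    table = stabilized_from_probs(panel, p_num, p_den)
    w = table["w"].to_numpy()
    diagnostics = {
        "mean": float(w.mean()),
        "sd": float(w.std(ddof=1)) if len(w) > 1 else 0.0,
        "min": float(w.min()),
        "max": float(w.max()),
        "n_bins": int(len(w)),
        "n_prob_clipped": int(n_clipped),
    }
    return WeightSet(
        table=table,
        interacted_modifier=models.interacted_modifier,
        diagnostics=diagnostics,
    )


def truncate_weights(
    weights: WeightSet, lower_q: float = 0.01, upper_q: float = 0.99
) -> WeightSet:
    """Winsorize the weights at empirical quantiles; (0, 1) is the identity."""
    if not (0.0 <= lower_q < upper_q <= 1.0):
        raise DomainError("require 0 <= lower_q < upper_q <= 1")
    w = weights.table["w"].to_numpy()
    lo = float(np.quantile(w, lower_q))
    hi = float(np.quantile(w, upper_q))
    table = weights.table.copy()
    table["w_truncated"] = np.clip(w, lo, hi)
    diagnostics = dict(weights.diagnostics)
    diagnostics["n_truncated"] = int(((w < lo) | (w > hi)).sum())
    return replace(
        weights, table=table, truncation_bounds=(lo, hi), diagnostics=diagnostics
    )


def standardized_mean_difference(
    panel: pd.DataFrame, column: str, weights: np.ndarray | None = None
) -> float:
    """SMD of ``column`` between treated and untreated bins.

    Weighted means and variances when ``weights`` is given; the denominator
    is the pooled standard deviation sqrt((v1 + v0)/2).
    """
    x = panel[column].to_numpy(float)
    a = panel["treated"].to_numpy(float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    ok = np.isfinite(x)
    x, a, w = x[ok], a[ok], w[ok]
    stats = []
    for grp in (1.0, 0.0):
        m = a == grp
        ww, xx = w[m], x[m]
        mean = np.average(xx, weights=ww)
        var = np.average((xx - mean) ** 2, weights=ww)
        stats.append((mean, var))
    (m1, v1), (m0, v0) = stats
    pooled = np.sqrt((v1 + v0) / 2.0)
    return float((m1 - m0) / pooled) if pooled > 0 else 0.0
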