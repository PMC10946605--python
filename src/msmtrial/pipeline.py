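"""End-to-end analysis orchestration.

:func:`run_analysis` sequences the whole pipeline — simulate or load a
registry, apply eligibility, derive confirmed disability events, build the
panel for the chosen design, estimate stabilized weights (re-estimated with
the modifier excluded for every interaction analysis), fit the marginal
structural Cox models, and write a tidy results table, diagnostics, a
weight histogram and a plain-text forest-style report with a content-hash
manifest.  Everything is deterministic given the configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError
from .events import clean_edss, detect_confirmed_events
from .inference import (
    OUTCOMES,
    ModelResult,
    fit_interaction,
    fit_msm,
    fit_stratified,
    fit_three_way,
    proportional_hazards_trend,
)
from .panel import build_cohort_panel, carried_fraction
from .registry import filter_eligible, read_registry, to_iso
from .simulate import default_scenarios, simulate_cohort
from .weights import (
    WeightSet,
    compute_stabilized_weights,
    fit_treatment_models,
    standardized_mean_difference,
    truncate_weights,
)

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis", "load_config"]

log = logging.getLogger("msmtrial")

VALID_MODIFIERS = ("age", "ms_duration", "edss", "arr", "mri_activity", "phenotype")


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run."""

    scenario: str | None = "protective"      # named synthetic scenario ...
    input_paths: dict | None = None          # ... or registry table paths
    n_patients: int | None = None            # override scenario size
    cohort_kind: str = "relapsing"
    design: str = "A"
    outcomes: tuple = OUTCOMES
    modifiers: tuple = ()
    reference_policy: str = "roving"
    relapse_policy: str = "merge"
    truncation: tuple = (0.01, 0.99)
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if self.design not in ("A", "B", "C"):
            raise DomainError(f"unknown design {self.design!r}")
        if self.cohort_kind not in ("relapsing", "full"):
            raise DomainError(f"unknown cohort_kind {self.cohort_kind!r}")
        for m in self.modifiers:
            if m not in VALID_MODIFIERS:
                raise DomainError(f"unknown modifier {m!r}")
        if "phenotype" in self.modifiers and self.cohort_kind == "relapsing":
            raise DomainError(
                "modifier 'phenotype' needs the full cohort: the relapsing "
                "cohort has a single phenotype group"
            )
        for oc in self.outcomes:
            if oc not in OUTCOMES:
                raise DomainError(f"unknown outcome {oc!r}")
        if self.scenario is None and not self.input_paths:
            raise DomainError("either a scenario or input_paths is required")


@dataclass
class AnalysisResult:
    """Bundle returned by :func:`run_analysis`."""

    panel: pd.DataFrame
    weights: WeightSet
    results: pd.DataFrame
    diagnostics: dict
    exclusions: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def load_config(path) -> AnalysisConfig:
    """Read a YAML key-value configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in AnalysisConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise DomainError(f"unknown configuration keys: {sorted(unknown)}")
    for key in ("outcomes", "modifiers", "truncation"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return AnalysisConfig(**raw)


def _load_cohort(config: AnalysisConfig):
    if config.input_paths:
        log.info("reading registry tables: %s", sorted(config.input_paths))
        return read_registry(config.input_paths, relapse_policy=config.relapse_policy)
    scenarios = default_scenarios()
    if config.scenario not in scenarios:
        raise DomainError(
            f"unknown scenario {config.scenario!r}; available: {sorted(scenarios)}"
        )
    params = scenarios[config.scenario]
    if config.n_patients is not None:
        params.n_patients = config.n_patients
    params.seed = config.seed
    log.info("simulating scenario %r with %d patients (seed %d)",
             config.scenario, params.n_patients, params.seed)
    records, _ = simulate_cohort(params)
    return records


def run_analysis(config: AnalysisConfig) -> AnalysisResult:
    """Run the full pipeline described by ``config``.

    Every modifier analysis re-estimates the weights with that modifier
    excluded from the weight model before fitting the interaction and the
    stratified models.
    """
    config.validate()
    records = _load_cohort(config)
    elig = filter_eligible(records, config.cohort_kind)
    log.info("eligibility: %d retained, %d excluded", len(elig.records), len(elig.exclusions))

    events = {}
    n_events = {"worsening": 0, "improvement": 0}
    for rec in elig.records:
        evs = detect_confirmed_events(
            clean_edss(rec.visits, rec.relapses), config.reference_policy
        )
        events[rec.patient_id] = evs
        for e in evs:
            n_events[e.kind] += 1
    log.info("confirmed events: %s", n_events)

    panel = build_cohort_panel(elig.records, config.design, events, config.cohort_kind)
    if len(panel) == 0:
        raise DomainError("panel is empty after eligibility and binning")
    log.info("panel: %d bins, %.0f%% treated, %.0f%% EDSS carried forward",
             len(panel), 100 * panel["treated"].mean(), 100 * carried_fraction(panel))

    models = fit_treatment_models(panel)
    weights = truncate_weights(
        compute_stabilized_weights(panel, models), *config.truncation
    )
    log.info("stabilized weights: %s", weights.diagnostics)

    rows: list[ModelResult] = []
    for outcome in config.outcomes:
        rows.append(fit_msm(panel, weights, outcome, config.design))
        naive = fit_msm(panel, None, outcome, config.design)
        naive.term = "treated (unweighted)"
        rows.append(naive)

    for modifier in config.modifiers:
        m_models = fit_treatment_models(panel, interacted_modifier=modifier)
        m_weights = truncate_weights(
            compute_stabilized_weights(panel, m_models), *config.truncation
        )
        for outcome in config.outcomes:
            rows.append(fit_interaction(panel, m_weights, outcome, modifier))
            rows += fit_stratified(panel, m_weights, outcome, modifier)
        if modifier == "phenotype" and config.cohort_kind == "full":
            for outcome in config.outcomes:
                rows.append(fit_three_way(panel, m_weights, outcome, config.design))

    results = pd.DataFrame([r.to_dict() for r in rows])
    w = weights.table["w_truncated"].to_numpy()
    diagnostics = {
        "n_patients": int(panel["patient_id"].nunique()),
        "n_excluded": int(len(elig.exclusions)),
        "n_bins": int(len(panel)),
        "treated_bin_fraction": float(panel["treated"].mean()),
        "edss_carried_fraction": float(carried_fraction(panel)),
        "n_worsening_events": n_events["worsening"],
        "n_improvement_events": n_events["improvement"],
        "weights": weights.diagnostics,
        "smd_arr_prior_12m_unweighted": standardized_mean_difference(panel, "arr_prior_12m"),
        "smd_arr_prior_12m_weighted": standardized_mean_difference(panel, "arr_prior_12m", w),
        "smd_edss_unweighted": standardized_mean_difference(panel, "edss"),
        "smd_edss_weighted": standardized_mean_difference(panel, "edss", w),
        "ph_trend_relapse": proportional_hazards_trend(panel, weights, "relapse"),
    }

    result = AnalysisResult(
        panel=panel, weights=weights, results=results,
        diagnostics=diagnostics, exclusions=elig.exclusions,
    )
    if config.output_dir:
        result.manifest = _write_outputs(config, result)
    return result


# ---------------------------------------------------------------------------
# Output artifacts
# ---------------------------------------------------------------------------


def _forest_report(results: pd.DataFrame, diagnostics: dict) -> str:
    """Plain-text forest-style report grouped per outcome."""
    lines = ["Marginal structural Cox model results", "=" * 60]
    for outcome, grp in results.groupby("outcome", sort=False):
        lines.append(f"\nOutcome: {outcome}")
        lines.append("-" * 60)
        for _, r in grp.iterrows():
            label = r["term"] if r["stratum"] is None else f"  {r['stratum']}"
            if r["term"] == "treated" and r["stratum"] is None:
                label = "Overall (treated vs untreated)"
            if not r["estimable"]:
                lines.append(f"{label:<44s} unestimable (events={r['n_events']})")
                continue
            lines.append(
                f"{label:<44s} HR {r['hazard_ratio']:6.3f} "
                f"({r['ci_lower']:6.3f}-{r['ci_upper']:6.3f})  p={r['p_value']:.3g}"
            )
    lines.append("\nDiagnostics")
    lines.append("-" * 60)
    for key, val in diagnostics.items():
        lines.append(f"{key}: {val}")
    return "\n".join(lines) + "\n"


def _write_outputs(config: AnalysisConfig, result: AnalysisResult) -> dict:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    paths = {}

    panel_out = result.panel.copy()
    for col in ("start_date", "end_date"):
        panel_out[col] = panel_out[col].map(to_iso)
    panel_out.to_csv(os.path.join(out, "panel.csv"), index=False)
    paths["panel.csv"] = None

    result.weights.table.to_csv(os.path.join(out, "weights.csv"), index=False)
    paths["weights.csv"] = None
    result.results.to_csv(os.path.join(out, "results.csv"), index=False)
    paths["results.csv"] = None
    result.exclusions.to_csv(os.path.join(out, "exclusions.csv"), index=False)
    paths["exclusions.csv"] = None

    with open(os.path.join(out, "diagnostics.json"), "w") as fh:
        json.dump(result.diagnostics, fh, indent=2, default=float)
    paths["diagnostics.json"] = None

    with open(os.path.join(out, "report.txt"), "w") as fh:
        fh.write(_forest_report(result.results, result.diagnostics))
    paths["report.txt"] = None

    _weight_histogram(result.weights, os.path.join(out, "weights_hist.png"))
    paths["weights_hist.png"] = None

    manifest = {}
    for name in paths:
        with open(os.path.join(out, name), "rb") as fh:
            manifest[name] = hashlib.sha256(fh.read()).hexdigest()
    manifest["config"] = {k: list(v) if isinstance(v, tuple) else v
                          for k, v in asdict(config).items()}
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _weight_histogram(weights: WeightSet, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(weights.table["w_truncated"], bins=60, color="steelblue", edgecolor="none")
    ax.set_xlabel("truncated stabilized weight")
    ax.set_ylabel("bins")
    ax.set_title("Distribution of stabilized weights")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
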