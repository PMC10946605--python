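"""Shared fixtures: small handmade cohorts and simulated panels."""

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from msmtrial.events import clean_edss, detect_confirmed_events
from msmtrial.panel import build_cohort_panel
from msmtrial.registry import filter_eligible, write_registry
from msmtrial.simulate import default_scenarios, simulate_cohort


@pytest.fixture(scope="session")
def protective_cohort():
    """Small protective-scenario cohort shared across statistical tests."""
    params = default_scenarios()["protective"]
    params.n_patients = 800
    params.seed = 42
    records, truth = simulate_cohort(params)
    return records, truth


@pytest.fixture(scope="session")
def protective_panel(protective_cohort):
    records, _ = protective_cohort
    elig = filter_eligible(records, "relapsing")
    events = {
        r.patient_id: detect_confirmed_events(clean_edss(r.visits, r.relapses))
        for r in elig.records
    }
    return build_cohort_panel(elig.records, "A", events, "relapsing")


@pytest.fixture()
def registry_dir(tmp_path, protective_cohort):
    """Protective cohort written out as the delimited table set."""
    records, _ = protective_cohort
    paths = write_registry(records[:50], tmp_path / "registry")
    return paths
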