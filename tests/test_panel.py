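"""Panel construction: treatment classification, binning, designs A/B/C."""

import numpy as np
import pytest

from msmtrial.errors import DomainError
from msmtrial.events import ConfirmedEvent, clean_edss, detect_confirmed_events
from msmtrial.panel import build_cohort_panel, build_panel, classify_treatment_status
from msmtrial.registry import TreatmentEpisode, filter_eligible

from helpers import Y, make_patient


def ep(start, stop=None):
    return TreatmentEpisode("DMT", start, stop)


# ---------------------------------------------------------------------------
# classify_treatment_status
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "episodes, expected",
    [
        ([ep(0, 20)], 1),            # 20 covered days
        ([ep(0, 14)], 0),            # 14 days: below the 15-day rule
        ([ep(0, 15)], 1),            # boundary: exactly 15
        ([ep(0, 8), ep(50, 58)], 1), # union 8+8 = 16 days
        ([ep(0, 8), ep(50, 56)], 0), # union 8+6 = 14 days
        ([], 0),
        ([ep(-100, None)], 1),       # open episode spans the bin
        ([ep(170, 200)], 0),         # only 13 days fall inside the bin
    ],
)
def test_fifteen_day_rule(episodes, expected):
    assert classify_treatment_status(0, 183, episodes) == expected


# ---------------------------------------------------------------------------
# build_panel basics
# ---------------------------------------------------------------------------


def never_treated_patient(years=3.0):
    days = int(years * Y)
    visits = tuple((d, 2.0) for d in range(0, days + 1, 120))
    return make_patient(visits=visits)


def test_three_years_never_treated_gives_six_bins():
    rec = never_treated_patient(3.0)  # 1095 days of follow-up
    rows = build_panel(rec, "A", [])
    assert len(rows) == 6
    assert all(r["treated"] == 0 for r in rows)
    assert rows[-1]["end_date"] - rows[0]["start_date"] == 1080
    assert [r["bin_index"] for r in rows] == list(range(6))


def test_design_a_censors_at_discontinuation():
    """Follow-up ends with the last treated bin once the DMT stops."""
    visits = tuple((d, 2.0) for d in range(0, 2000, 120))
    rec = make_patient(visits=visits, treatments=((0, 800),))
    rows = build_panel(rec, "A", [])
    # bins 0-3 treated (800/183 = 4.37 -> bin 4 has 68 treated days -> treated)
    assert [r["treated"] for r in rows] == [1, 1, 1, 1, 1]
    assert rows[-1]["censor_reason"] == "treatment_discontinuation"


def test_design_a_treated_indicator_nondecreasing(protective_panel):
    for _, grp in protective_panel.groupby("patient_id"):
        a = grp.sort_values("bin_index")["treated"].to_numpy()
        assert (np.diff(a) >= 0).all()


def test_design_c_rebaselines_at_state_change():
    """Starting a DMT at day 400 opens a new segment with bin clock at 0."""
    visits = tuple((d, 2.0) for d in range(0, 1500, 120))
    rec = make_patient(visits=visits, treatments=((400, None),))
    rows = build_panel(rec, "C", [])
    segments = {r["segment"] for r in rows}
    assert segments == {0, 1}
    seg1 = [r for r in rows if r["segment"] == 1]
    assert seg1[0]["bin_index"] == 0
    assert seg1[0]["start_date"] == 400
    assert all(r["treated"] == 1 for r in seg1)
    assert all(r["treated"] == 0 for r in rows if r["segment"] == 0)


def test_design_b_starts_at_onset_with_missing_edss_markers():
    visits = tuple((d + 500, 2.0) for d in range(0, 1200, 120))
    rec = make_patient(visits=visits)
    rows = build_panel(rec, "B", [])
    assert rows[0]["start_date"] == 0  # MS onset
    assert rows[0]["edss_missing"]
    late = [r for r in rows if r["start_date"] >= 500 + 183]
    assert all(not r["edss_missing"] for r in late)


def test_unknown_design_rejected():
    with pytest.raises(DomainError):
        build_panel(never_treated_patient(), "D", [])


# ---------------------------------------------------------------------------
# Carry-forward and covariates
# ---------------------------------------------------------------------------


def test_edss_carry_forward_flags():
    visits = ((0, 3.0), (400, 4.0), (800, 4.0))
    rec = make_patient(visits=visits)
    rows = build_panel(rec, "A", [])
    # bin 1 (183-366) has no in-bin score: carries 3.0 from day 0
    assert rows[1]["edss"] == 3.0 and rows[1]["edss_carried"]
    assert rows[0]["edss"] == 3.0 and not rows[0]["edss_carried"]
    # bin 2 (366-549) contains the day-400 score
    assert rows[2]["edss"] == 4.0 and not rows[2]["edss_carried"]


def test_relapse_counts_and_binary_outcome():
    visits = tuple((d, 2.0) for d in range(0, 800, 120))
    rec = make_patient(visits=visits, relapses=(50, 100, 400))
    rows = build_panel(rec, "A", [])
    assert rows[0]["relapses_in_bin"] == 2 and rows[0]["relapse_outcome"] == 1
    assert rows[1]["relapses_in_bin"] == 0 and rows[1]["relapse_outcome"] == 0
    assert rows[2]["relapses_in_bin"] == 1
    # ARR window before bin 2 start (366): relapses at 50, 100 inside 1..366
    assert rows[2]["arr_prior_12m"] == pytest.approx(2.0)


def test_pregnancy_overlap_flag():
    visits = tuple((d, 2.0) for d in range(0, 800, 120))
    rec = make_patient(visits=visits, pregnancies=((200, 470),))
    rows = build_panel(rec, "A", [])
    assert [r["pregnancy"] for r in rows] == [0, 1, 1, 0]


def test_mri_recency_window():
    visits = tuple((d, 2.0) for d in range(0, 1000, 120))
    rec = make_patient(visits=visits, mri=((10, "active"),))
    rows = build_panel(rec, "A", [])
    assert rows[1]["mri_activity_12m"] == "active"      # 173 days before bin 1
    assert rows[3]["mri_activity_12m"] == "not_assessed"  # >365 days stale


def test_event_onset_maps_to_exactly_one_bin():
    visits = ((0, 2.0), (200, 3.0), (600, 3.0), (900, 3.0))
    rec = make_patient(visits=visits)
    events = detect_confirmed_events(clean_edss(rec.visits, rec.relapses))
    assert len(events) == 1
    rows = build_panel(rec, "A", events)
    flags = [r["worsening_event"] for r in rows]
    assert sum(flags) == 1
    hit = rows[flags.index(1)]
    assert hit["start_date"] <= events[0].onset_day < hit["end_date"]


# ---------------------------------------------------------------------------
# Conservation invariants on a simulated cohort
# ---------------------------------------------------------------------------


def test_person_time_conserved(protective_panel):
    """Bin lengths tile follow-up: contiguous, non-overlapping, 183 days."""
    for _, grp in protective_panel.groupby(["patient_id", "segment"]):
        g = grp.sort_values("bin_index")
        starts = g["start_date"].to_numpy()
        ends = g["end_date"].to_numpy()
        assert (starts[1:] == ends[:-1]).all()
        lengths = ends - starts
        assert (lengths[:-1] == 183).all()
        assert lengths[-1] >= 15


def test_relapse_sum_matches_followed_time(protective_cohort, protective_panel):
    records, _ = protective_cohort
    by_id = {r.patient_id: r for r in records}
    for pid, grp in protective_panel.groupby("patient_id"):
        lo = grp["start_date"].min()
        hi = grp["end_date"].max()
        expected = sum(1 for d in by_id[pid].relapses if lo <= d < hi)
        assert grp["relapses_in_bin"].sum() == expected


def test_spms_conversion_censors_relapsing_panel():
    visits = tuple((d, 3.0) for d in range(0, 2000, 150))
    rec = make_patient(visits=visits, courses=(("RRMS", 0), ("SPMS", 700)))
    rows = build_panel(rec, "A", [], cohort_kind="relapsing")
    assert rows[-1]["end_date"] <= 700
    assert rows[-1]["censor_reason"] == "spms_conversion"
    rows_full = build_panel(rec, "A", [], cohort_kind="full")
    assert rows_full[-1]["end_date"] > 700
    assert rows_full[-1]["course"] == "SPMS"
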