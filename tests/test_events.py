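"""Disability-event derivation: cleaning, step rules, confirmation, ARR."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msmtrial.errors import DomainError
from msmtrial.events import (
    annualized_relapse_rate,
    clean_edss,
    detect_confirmed_events,
    required_step,
)
from msmtrial.registry import EdssScore


def scores(*pairs):
    return [EdssScore(d, v) for d, v in pairs]


# ---------------------------------------------------------------------------
# Independent brute-force oracle: literally checks every (onset, confirmation)
# pair against the definition, resolving the sequence in onset order.
# ---------------------------------------------------------------------------


def brute_force_events(traj, policy="roving"):
    n = len(traj)
    days = [s.day for s in traj]
    vals = [s.value for s in traj]
    events = []
    ref = vals[0] if traj else None
    done = set()
    i = 1
    while i < n:
        found = None
        for kind in ("worsening", "improvement"):
            if policy == "fixed_baseline" and kind in done:
                continue
            delta = required_step(ref, kind)
            change = vals[i] - ref if kind == "worsening" else ref - vals[i]
            if change < delta:
                continue
            # every j at least a year out; confirmed iff some j has all
            # intermediate scores holding the threshold
            for j in range(i + 1, n):
                if days[j] - days[i] < 365:
                    continue
                holds = all(
                    (vals[k] - ref if kind == "worsening" else ref - vals[k]) >= delta
                    for k in range(i + 1, j + 1)
                )
                if holds:
                    found = (kind, days[i], ref, vals[i], days[j])
                    break
            if found:
                break
        if found:
            events.append(found)
            if policy == "roving":
                ref = found[3]
            else:
                done.add(found[0])
        i += 1
    return events


def as_tuples(evs):
    return [(e.kind, e.onset_day, e.reference_edss, e.onset_edss, e.confirmation_day)
            for e in evs]


# ---------------------------------------------------------------------------
# clean_edss
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "visit_day, relapse_day, kept",
    [(110, 100, False), (130, 100, True), (129, 100, False), (90, 100, True)],
)
def test_post_relapse_exclusion_boundary(visit_day, relapse_day, kept):
    """Scores <30 days after a relapse are dropped; day 30 itself is kept."""
    out = clean_edss(scores((visit_day, 3.0)), [relapse_day])
    assert (len(out) == 1) == kept


def test_clean_edss_no_relapses_is_identity():
    traj = scores((0, 1.0), (100, 2.0))
    assert clean_edss(traj, []) == traj


@given(
    days=st.lists(st.integers(0, 2000), min_size=0, max_size=15, unique=True),
    relapses=st.lists(st.integers(0, 2000), min_size=0, max_size=5, unique=True),
)
@settings(max_examples=200, deadline=None)
def test_clean_edss_keeps_exactly_the_distant_scores(days, relapses):
    """A score survives iff it is >=30 days after every earlier relapse."""
    traj = scores(*[(d, 2.0) for d in sorted(days)])
    out = clean_edss(traj, sorted(relapses))
    expected = [
        v for v in traj
        if all(v.day - r >= 30 for r in relapses if r <= v.day)
    ]
    assert out == expected


# ---------------------------------------------------------------------------
# required_step
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ref, kind, expected",
    [
        (0.0, "worsening", 1.5),
        (1.0, "worsening", 1.0),
        (5.5, "worsening", 1.0),
        (6.0, "worsening", 0.5),
        (0.0, "improvement", 1.5),
        (1.5, "improvement", 1.5),
        (2.0, "improvement", 1.0),
        (6.0, "improvement", 1.0),
        (6.5, "improvement", 0.5),
    ],
)
def test_required_step_reference_dependence(ref, kind, expected):
    assert required_step(ref, kind) == expected


def test_required_step_rejects_invalid_edss():
    with pytest.raises(DomainError):
        required_step(0.5, "worsening")
    with pytest.raises(DomainError):
        required_step(3.0, "sideways")


# ---------------------------------------------------------------------------
# detect_confirmed_events
# ---------------------------------------------------------------------------


def test_simple_confirmed_worsening():
    """A 1-step rise held for >=365 days confirms at the first distant score."""
    evs = detect_confirmed_events(scores((0, 2.0), (180, 3.0), (560, 3.0)))
    assert as_tuples(evs) == [("worsening", 180, 2.0, 3.0, 560)]


def test_broken_confirmation_window_yields_no_event():
    """A dip below threshold before the 12-month mark voids the candidate."""
    evs = detect_confirmed_events(
        scores((0, 2.0), (180, 3.0), (300, 2.0), (600, 3.0))
    )
    assert evs == []


def test_constant_trajectory_and_short_input():
    assert detect_confirmed_events(scores((0, 2.0), (400, 2.0))) == []
    assert detect_confirmed_events(scores((0, 2.0))) == []
    assert detect_confirmed_events([]) == []


def test_trajectory_ending_early_gives_no_event():
    """No extrapolation: a rise <365 days before the end is unconfirmed."""
    evs = detect_confirmed_events(scores((0, 2.0), (180, 3.5), (400, 3.5)))
    assert evs == []


def test_roving_reference_resets_after_event():
    """After a confirmed worsening the reference moves to the onset score."""
    traj = scores((0, 2.0), (180, 3.0), (560, 3.0), (740, 4.0), (1200, 4.0))
    evs = detect_confirmed_events(traj, "roving")
    assert [(e.kind, e.reference_edss, e.onset_edss) for e in evs] == [
        ("worsening", 2.0, 3.0),
        ("worsening", 3.0, 4.0),
    ]


def test_fixed_baseline_reports_single_worsening():
    """Under fixed_baseline the second rise is not a new event."""
    traj = scores((0, 2.0), (180, 3.0), (560, 3.0), (740, 4.0), (1200, 4.0))
    evs = detect_confirmed_events(traj, "fixed_baseline")
    assert len([e for e in evs if e.kind == "worsening"]) == 1


def test_improvement_detected_symmetrically():
    evs = detect_confirmed_events(scores((0, 4.0), (180, 3.0), (560, 3.0)))
    assert as_tuples(evs) == [("improvement", 180, 4.0, 3.0, 560)]


@given(
    vals=st.lists(
        st.sampled_from([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]),
        min_size=2, max_size=6,
    ),
    policy=st.sampled_from(["roving", "fixed_baseline"]),
)
@settings(max_examples=400, deadline=None)
def test_matches_brute_force_oracle(vals, policy):
    """Single-pass detector equals the exhaustive pair-checking oracle."""
    lattice = [0, 120, 260, 430, 640, 830]
    traj = scores(*zip(lattice[: len(vals)], vals))
    assert as_tuples(detect_confirmed_events(traj, policy)) == brute_force_events(
        traj, policy
    )


@given(
    vals=st.lists(
        st.sampled_from([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]),
        min_size=2, max_size=6,
    ),
    shift=st.integers(-5000, 5000),
)
@settings(max_examples=200, deadline=None)
def test_translation_invariance(vals, shift):
    """Shifting every date shifts every event by the same amount."""
    lattice = [0, 120, 260, 430, 640, 830]
    traj = scores(*zip(lattice[: len(vals)], vals))
    shifted = scores(*[(s.day + shift, s.value) for s in traj])
    base = detect_confirmed_events(traj)
    moved = detect_confirmed_events(shifted)
    assert [(e.kind, e.onset_day + shift, e.confirmation_day + shift) for e in base] == [
        (e.kind, e.onset_day, e.confirmation_day) for e in moved
    ]


@given(
    vals=st.lists(
        st.sampled_from([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]),
        min_size=3, max_size=6,
    ),
)
@settings(max_examples=200, deadline=None)
def test_removing_trailing_scores_never_creates_events(vals):
    """Truncating the future can only destroy events, never add earlier ones."""
    lattice = [0, 120, 260, 430, 640, 830]
    traj = scores(*zip(lattice[: len(vals)], vals))
    full = as_tuples(detect_confirmed_events(traj))
    trunc = as_tuples(detect_confirmed_events(traj[:-1]))
    assert set(trunc) <= set(full)


def test_worsening_and_improvement_mutually_exclusive_at_onset():
    """One score cannot be both a worsening and an improvement onset."""
    traj = scores((0, 3.0), (180, 4.0), (560, 4.0), (700, 2.0), (1100, 2.0))
    evs = detect_confirmed_events(traj)
    onsets = [e.onset_day for e in evs]
    assert len(onsets) == len(set(onsets))


# ---------------------------------------------------------------------------
# annualized_relapse_rate
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "relapses, start, end, expected",
    [
        ([50], 0, 183, 365 / 183),
        ([], 0, 183, 0.0),
        ([10, 200, 700], 0, 730, 1.5),
        ([0, 183], 0, 183, 365 / 183),  # half-open window: end excluded
    ],
)
def test_annualized_relapse_rate_arithmetic(relapses, start, end, expected):
    assert annualized_relapse_rate(relapses, start, end) == pytest.approx(expected)


def test_annualized_relapse_rate_rejects_empty_window():
    with pytest.raises(DomainError):
        annualized_relapse_rate([], 100, 100)
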