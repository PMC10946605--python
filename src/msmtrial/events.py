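"""Confirmed disability events and relapse rates from EDSS trajectories.

Disability worsening is an EDSS increase by one step — 1.5 steps when the
reference is 0, 0.5 steps when it exceeds 5.5 — sustained by every
subsequent recorded score up to and including the first score at least 365
days after onset.  Improvement is the symmetric decrease (1.5 steps when the
reference is <= 1.5, 0.5 steps above 6).  Scores recorded fewer than 30 days
after a relapse onset are excluded before event detection, and only recorded
(never carried-forward) scores participate.

The reference score is "roving" by default: after each confirmed event it
resets to the score at that event's onset, so sequential events are measured
from the new plateau.  A ``fixed_baseline`` policy measures every change
against the first cleaned score and reports at most one worsening and one
improvement (time-to-first-event semantics).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

from .errors import DomainError
from .registry import VALID_EDSS, YEAR_DAYS, EdssScore

__all__ = [
    "ConfirmedEvent",
    "clean_edss",
    "required_step",
    "detect_confirmed_events",
    "annualized_relapse_rate",
]

CONFIRMATION_DAYS = YEAR_DAYS  # ">= 12 months" operationalised as >= 365 days
POST_RELAPSE_EXCLUSION_DAYS = 30


@dataclass(frozen=True)
class ConfirmedEvent:
    """A 12-month-confirmed disability worsening or improvement."""

    kind: str  # "worsening" | "improvement"
    onset_day: int
    reference_edss: float
    onset_edss: float
    confirmation_day: int
    patient_id: str | None = None


def clean_edss(visits: list[EdssScore], relapses: list[int]) -> list[EdssScore]:
    """Drop scores recorded <30 days after a relapse onset.

    A score is retained iff its date is at least 30 days after every
    preceding relapse; order is preserved.  ``relapses`` must be sorted.
    """
    if not relapses:
        return list(visits)
    out = []
    for v in visits:
        i = bisect_right(relapses, v.day)
        if i == 0 or v.day - relapses[i - 1] >= POST_RELAPSE_EXCLUSION_DAYS:
            out.append(v)
    return out


def required_step(reference_edss: float, kind: str) -> float:
    """Minimum EDSS change that counts as an event, given the reference."""
    if reference_edss not in VALID_EDSS:
        raise DomainError(f"invalid EDSS reference {reference_edss}")
    if kind == "worsening":
        if reference_edss == 0.0:
            return 1.5
        return 0.5 if reference_edss > 5.5 else 1.0
    if kind == "improvement":
        if reference_edss <= 1.5:
            return 1.5
        return 0.5 if reference_edss > 6.0 else 1.0
    raise DomainError(f"unknown event kind {kind!r}")


def _qualifies(value: float, ref: float, kind: str) -> bool:
    if kind == "worsening":
        return value - ref >= required_step(ref, "worsening")
    return ref - value >= required_step(ref, "improvement")


def detect_confirmed_events(
    cleaned_scores: list[EdssScore], reference_policy: str = "roving"
) -> list[ConfirmedEvent]:
    """Single chronological pass emitting confirmed worsening/improvement.

    An event is emitted at the first score meeting the required step from
    the current reference, provided a score dated >= 365 days after onset
    exists and every recorded score between onset and that first >=365-day
    score (inclusive) meets the same threshold.  A trajectory ending less
    than 365 days after a qualifying change yields no event.
    """
    if reference_policy not in ("roving", "fixed_baseline"):
        raise DomainError(f"unknown reference_policy {reference_policy!r}")
    n = len(cleaned_scores)
    if n < 2:
        return []
    days = [s.day for s in cleaned_scores]
    vals = [s.value for s in cleaned_scores]
    ref = vals[0]
    events: list[ConfirmedEvent] = []
    done = {"worsening": False, "improvement": False}  # fixed_baseline only
    for i in range(1, n):
        kind = None
        if _qualifies(vals[i], ref, "worsening"):
            kind = "worsening"
        elif _qualifies(vals[i], ref, "improvement"):
            kind = "improvement"
        if kind is None or (reference_policy == "fixed_baseline" and done[kind]):
            continue
        # first score >= 365 days after onset (bisect on the sorted days)
        j = bisect_left(days, days[i] + CONFIRMATION_DAYS, i + 1)
        if j == n:
            continue  # trajectory ends <365 days after the change: no event
        if all(_qualifies(vals[k], ref, kind) for k in range(i + 1, j + 1)):
            events.append(
                ConfirmedEvent(
                    kind=kind,
                    onset_day=days[i],
                    reference_edss=ref,
                    onset_edss=vals[i],
                    confirmation_day=days[j],
                )
            )
            if reference_policy == "roving":
                ref = vals[i]
            else:
                done[kind] = True
    return events


def annualized_relapse_rate(
    relapse_days: list[int], window_start: int, window_end: int
) -> float:
    """Relapses with onset in [window_start, window_end), scaled to per-year."""
    if window_end <= window_start:
        raise DomainError("annualized_relapse_rate: window must have positive length")
    count = sum(1 for d in relapse_days if window_start <= d < window_end)
    return count * YEAR_DAYS / (window_end - window_start)
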