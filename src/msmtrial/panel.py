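"""Patient x 6-month panels under the three target-trial designs.

Each eligible patient is converted into contiguous half-open 183-day bins
carrying the treatment state, time-dependent covariates measured at bin
start, and per-bin outcomes:

- **Design A** — time zero at the first (cleaned) EDSS visit; a single
  untreated -> treated transition is allowed and follow-up is censored at
  the first treatment discontinuation.
- **Design B** — time zero at MS onset; free switching between states, no
  rebaselining.  Bins before the first EDSS record carry a missing-EDSS
  marker.
- **Design C** — time zero at the first EDSS visit, with the bin clock
  restarting at k = 0 at every change of treatment state (new at-risk
  segment).

A bin counts as treated when the union of treatment episodes covers at
least 15 days of it.  The final partial bin is retained when it is at least
15 days long.  EDSS is carried forward from the last recorded (cleaned)
score; carried values are flagged and never feed confirmed-event detection,
which happens upstream on recorded scores only.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right

import numpy as np
import pandas as pd

from .errors import DomainError
from .events import ConfirmedEvent, clean_edss
from .registry import (
    BIN_DAYS,
    RELAPSING_PHENOTYPES,
    YEAR_DAYS,
    PatientRecord,
    TreatmentEpisode,
)

__all__ = [
    "PANEL_COLUMNS",
    "classify_treatment_status",
    "build_panel",
    "build_cohort_panel",
    "carried_fraction",
]

MIN_BIN_DAYS = 15
TREATED_MIN_DAYS = 15

PANEL_COLUMNS = [
    "patient_id", "segment", "bin_index", "start_date", "end_date",
    "tstart", "tstop", "treated", "prev_treated", "edss", "edss_carried",
    "edss_missing", "edss_prebin", "age", "ms_duration", "course", "course_group",
    "pregnancy", "relapses_in_bin", "relapse_outcome", "arr_prior_12m",
    "arr_prior_24m", "arr_since_onset", "prior_treated_fraction", "mri_activity_12m",
    "first_relapse_day", "worsening_event", "worsening_onset_day",
    "improvement_event", "improvement_onset_day", "censored", "censor_reason",
    "sex", "ms_duration_at_first_visit", "birth_year", "onset_year",
]


def classify_treatment_status(
    start: int, end: int, episodes: list[TreatmentEpisode]
) -> int:
    """1 iff the union of episode-bin intersections covers >= 15 days.

    The bin is the half-open interval [start, end); an open episode
    (stop None) extends beyond any bin.  Episodes must be non-overlapping,
    so intersection lengths simply add.
    """
    covered = 0
    for ep in episodes:
        stop = end if ep.stop is None else min(ep.stop, end)
        covered += max(0, stop - max(ep.start, start))
        if covered >= TREATED_MIN_DAYS:
            return 1
    return 0


def _treated_state_changes(
    episodes: list[TreatmentEpisode], t0: int, t1: int
) -> list[int]:
    """Days in (t0, t1) where the episode-level treated state flips."""
    days = set()
    for ep in episodes:
        if t0 < ep.start < t1:
            days.add(ep.start)
        if ep.stop is not None and t0 < ep.stop < t1:
            days.add(ep.stop)
    return sorted(days)


def _in_episode(day: int, episodes: list[TreatmentEpisode]) -> bool:
    for ep in episodes:
        if ep.start <= day and (ep.stop is None or day < ep.stop):
            return True
    return False


def build_panel(
    patient: PatientRecord,
    design: str,
    events: list[ConfirmedEvent],
    cohort_kind: str = "relapsing",
) -> list[dict]:
    """Build the bin rows for one patient; see the module docstring.

    ``events`` are the patient's confirmed disability events, precomputed
    from cleaned recorded scores.  Returns a list of row dicts with the
    :data:`PANEL_COLUMNS` keys (empty when follow-up is too short).
    """
    if design not in ("A", "B", "C"):
        raise DomainError(f"unknown design {design!r}")
    cleaned = clean_edss(patient.visits, patient.relapses)
    if not cleaned:
        return []
    # study baseline: the first visit with usable disability information
    # (the first cleaned score); follow-up runs to the last recorded EDSS
    t0 = patient.onset if design == "B" else cleaned[0].day
    end = cleaned[-1].day
    censor_reason = "end_of_followup"
    if cohort_kind == "relapsing":
        spms = patient.spms_day()
        if spms is not None and spms < end:
            end = spms
            censor_reason = "spms_conversion"
    if end - t0 < MIN_BIN_DAYS:
        return []

    score_days = [s.day for s in cleaned]
    score_vals = [s.value for s in cleaned]
    relapses = patient.relapses
    mri_days = [d for d, _ in patient.mri]
    worsening_days = sorted(e.onset_day for e in events if e.kind == "worsening")
    improvement_days = sorted(e.onset_day for e in events if e.kind == "improvement")

    if design == "C":
        bounds = [t0] + _treated_state_changes(patient.treatments, t0, end) + [end]
        segments = list(zip(bounds[:-1], bounds[1:]))
    else:
        segments = [(t0, end)]

    baseline_prev = classify_treatment_status(t0 - BIN_DAYS, t0, patient.treatments)
    ms_duration_fv = (cleaned[0].day - patient.onset) / YEAR_DAYS
    birth_year = 2000.0 + patient.birth / 365.25
    onset_year = 2000.0 + patient.onset / 365.25

    rows: list[dict] = []
    hist_states: list[int] = []
    seen_treated = False
    stop_all = False
    for seg_idx, (s0, s1) in enumerate(segments):
        if stop_all:
            break
        seg_state = _in_episode(s0, patient.treatments) if design == "C" else None
        cur = s0
        k = 0
        while cur < s1:
            bstart, bend = cur, min(cur + BIN_DAYS, s1)
            if bend - bstart < MIN_BIN_DAYS:
                break  # drop a too-short final fragment
            if design == "C":
                treated = int(seg_state)
            else:
                treated = classify_treatment_status(bstart, bend, patient.treatments)
            if design == "A" and treated == 0 and seen_treated:
                if rows:
                    rows[-1]["censored"] = True
                    rows[-1]["censor_reason"] = "treatment_discontinuation"
                censor_reason = "treatment_discontinuation"
                stop_all = True
                break
            seen_treated = seen_treated or treated == 1
            prev = hist_states[-1] if hist_states else baseline_prev

            # EDSS: last recorded score on/before bin end (exclusive)
            si = bisect_left(score_days, bend) - 1
            if si < 0:
                edss_val, carried, missing = np.nan, False, True
            else:
                edss_val = score_vals[si]
                carried = score_days[si] < bstart
                missing = False
            # EDSS known at bin start (last cleaned score on/before it):
            # the pre-treatment disability level for this bin's state
            pi = bisect_right(score_days, bstart) - 1
            edss_prebin = score_vals[pi] if pi >= 0 else np.nan

            r_lo = bisect_left(relapses, bstart)
            r_hi = bisect_left(relapses, bend)
            n_rel = r_hi - r_lo
            first_rel = relapses[r_lo] if n_rel else -1
            arr12 = (r_lo - bisect_left(relapses, bstart - YEAR_DAYS)) * 1.0
            arr24 = (r_lo - bisect_left(relapses, bstart - 2 * YEAR_DAYS)) / 2.0
            # full relapse history since MS onset (every relapse is recorded)
            dur = bstart - patient.onset
            arr_onset = (r_lo * YEAR_DAYS / dur) if dur > 0 else 0.0

            course = patient.phenotype_at(bstart) or "CIS"
            pregnancy = int(any(s < bend and e > bstart for s, e in patient.pregnancies))

            mi = bisect_left(mri_days, bstart) - 1
            if mi >= 0 and bstart - mri_days[mi] <= YEAR_DAYS:
                mri_status = patient.mri[mi][1]
            else:
                mri_status = "not_assessed"

            w_lo = bisect_left(worsening_days, bstart)
            wor = int(bisect_left(worsening_days, bend) > w_lo)
            wor_day = worsening_days[w_lo] if wor else -1
            i_lo = bisect_left(improvement_days, bstart)
            imp = int(bisect_left(improvement_days, bend) > i_lo)
            imp_day = improvement_days[i_lo] if imp else -1

            rows.append({
                "patient_id": patient.patient_id,
                "segment": seg_idx,
                "bin_index": k,
                "start_date": bstart,
                "end_date": bend,
                "tstart": float(bstart - s0),
                "tstop": float(bend - s0),
                "treated": treated,
                "prev_treated": prev,
                "edss": edss_val,
                "edss_carried": carried,
                "edss_missing": missing,
                "edss_prebin": edss_prebin,
                "age": (bstart - patient.birth) / YEAR_DAYS,
                "ms_duration": (bstart - patient.onset) / YEAR_DAYS,
                "course": course,
                "course_group": "relapsing" if course in RELAPSING_PHENOTYPES else "progressive",
                "pregnancy": pregnancy,
                "relapses_in_bin": n_rel,
                "relapse_outcome": int(n_rel >= 1),
                "first_relapse_day": first_rel,
                "arr_prior_12m": arr12,
                "arr_prior_24m": arr24,
                "arr_since_onset": arr_onset,
                "prior_treated_fraction": (sum(hist_states) / len(hist_states)) if hist_states else 0.0,
                "mri_activity_12m": mri_status,
                "worsening_event": wor,
                "worsening_onset_day": wor_day,
                "improvement_event": imp,
                "improvement_onset_day": imp_day,
                "censored": False,
                "censor_reason": "",
                "sex": patient.sex,
                "ms_duration_at_first_visit": ms_duration_fv,
                "birth_year": birth_year,
                "onset_year": onset_year,
            })
            hist_states.append(treated)
            k += 1
            cur = bend
    if rows and not rows[-1]["censored"]:
        rows[-1]["censored"] = True
        rows[-1]["censor_reason"] = censor_reason
    return rows


def build_cohort_panel(
    records: list[PatientRecord],
    design: str,
    events_by_patient: dict[str, list[ConfirmedEvent]],
    cohort_kind: str = "relapsing",
) -> pd.DataFrame:
    """Concatenate per-patient panels into one long-format table."""
    rows: list[dict] = []
    for rec in records:
        rows += build_panel(rec, design, events_by_patient.get(rec.patient_id, []),
                            cohort_kind=cohort_kind)
    if not rows:
        return pd.DataFrame(columns=PANEL_COLUMNS)
    return pd.DataFrame.from_records(rows, columns=PANEL_COLUMNS)


def carried_fraction(panel: pd.DataFrame) -> float:
    """Diagnostic: fraction of bins whose EDSS was carried forward."""
    if len(panel) == 0:
        return float("nan")
    return float(panel["edss_carried"].mean())
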