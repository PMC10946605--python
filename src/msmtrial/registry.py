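"""Registry data model: patient records, tabular IO, validation, eligibility.

A cohort is a list of :class:`PatientRecord`, one per patient, assembled from
five (optionally six) delimited tables: ``patients``, ``courses``, ``visits``,
``relapses``, ``treatments``, ``mri`` and optionally ``pregnancies``.  Dates
are ISO-8601 in the files and integer days since 2000-01-01 internally; all
durations are in days, with 1 year = 365 days and 6 months = 183 days.

Eligibility implements the registry minimum-data rules: follow-up of at least
one year between first and last EDSS score, at least three EDSS scores, no
gap between consecutive scores longer than a year, and a non-missing minimum
dataset.  The relapsing cohort additionally drops patients who are already
progressive at their first EDSS visit and records a censoring date at
conversion to secondary progressive MS for converters.  Follow-up is trimmed
to the span from the first to the last recorded EDSS.
"""

from __future__ import annotations

import datetime as _dt
from bisect import bisect_left
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "EPOCH",
    "VALID_EDSS",
    "PHENOTYPES",
    "RELAPSING_PHENOTYPES",
    "PROGRESSIVE_PHENOTYPES",
    "to_day",
    "to_iso",
    "EdssScore",
    "TreatmentEpisode",
    "PatientRecord",
    "EligibilityResult",
    "read_registry",
    "write_registry",
    "filter_eligible",
]

EPOCH = _dt.date(2000, 1, 1).toordinal()

# EDSS step grid: 0.0 then half-steps from 1.0 to 10.0 (no 0.5).
VALID_EDSS = frozenset([0.0] + [x / 2 for x in range(2, 21)])

PHENOTYPES = ("CIS", "RRMS", "SPMS", "PPMS", "PRMS")
RELAPSING_PHENOTYPES = frozenset({"CIS", "RRMS"})
PROGRESSIVE_PHENOTYPES = frozenset({"SPMS", "PPMS", "PRMS"})

MIN_RELAPSE_GAP_DAYS = 30
YEAR_DAYS = 365
BIN_DAYS = 183


def to_day(iso: str) -> int:
    """ISO-8601 date string -> integer days since 2000-01-01."""
    return _dt.date.fromisoformat(str(iso)).toordinal() - EPOCH


def to_iso(day: int) -> str:
    """Integer day -> ISO-8601 date string."""
    return _dt.date.fromordinal(int(day) + EPOCH).isoformat()


@dataclass(frozen=True, order=True)
class EdssScore:
    """A single recorded EDSS assessment."""

    day: int
    value: float


@dataclass(frozen=True)
class TreatmentEpisode:
    """One DMT exposure episode; ``stop`` of None means ongoing."""

    dmt_name: str
    start: int
    stop: int | None = None


@dataclass
class PatientRecord:
    """One subject's complete longitudinal history.

    All event containers are kept chronologically sorted by
    :meth:`validated`.  ``course_history`` is a list of
    ``(phenotype, start_day)`` transitions; ``mri`` a list of
    ``(day, activity)`` with activity in {"active", "not_active"};
    ``pregnancies`` a list of ``(start_day, end_day)`` intervals.
    """

    patient_id: str
    sex: str
    birth: int
    onset: int
    course_history: list[tuple[str, int]] = field(default_factory=list)
    visits: list[EdssScore] = field(default_factory=list)
    relapses: list[int] = field(default_factory=list)
    treatments: list[TreatmentEpisode] = field(default_factory=list)
    mri: list[tuple[int, str]] = field(default_factory=list)
    pregnancies: list[tuple[int, int]] = field(default_factory=list)

    # -- derived accessors -------------------------------------------------
    def phenotype_at(self, day: int) -> str | None:
        """MS course in force on ``day`` (latest transition on/before it)."""
        current = None
        for phen, start in self.course_history:
            if start <= day:
                current = phen
            else:
                break
        return current

    def spms_day(self) -> int | None:
        """Day of conversion to SPMS, if recorded."""
        for phen, start in self.course_history:
            if phen == "SPMS":
                return start
        return None

    def first_edss_day(self) -> int | None:
        return self.visits[0].day if self.visits else None

    def last_edss_day(self) -> int | None:
        return self.visits[-1].day if self.visits else None

    # -- validation --------------------------------------------------------
    def validated(self, relapse_policy: str = "merge") -> "PatientRecord":
        """Return a sorted, invariant-checked copy of this record.

        ``relapse_policy`` controls relapses closer than 30 days apart:
        ``"merge"`` collapses them onto the earlier onset (the clinical
        definition counts them as one episode); ``"strict"`` raises
        :class:`ValidationError`.
        """
        pid = self.patient_id
        if self.sex not in ("female", "male"):
            raise ValidationError(f"patient {pid}: sex must be female/male, got {self.sex!r}")
        if self.onset < self.birth:
            raise ValidationError(f"patient {pid}: ms_onset_date precedes birth_date")

        visits = sorted(self.visits)
        for v in visits:
            if v.value not in VALID_EDSS:
                raise ValidationError(
                    f"patient {pid}: invalid EDSS value {v.value} on {to_iso(v.day)}"
                )

        courses = sorted(self.course_history, key=lambda c: c[1])
        seen_spms = False
        prev_phen = None
        for phen, start in courses:
            if phen not in PHENOTYPES:
                raise ValidationError(f"patient {pid}: unknown phenotype {phen!r}")
            if phen == prev_phen:
                raise ValidationError(f"patient {pid}: repeated phenotype {phen} in course history")
            if seen_spms and phen != "SPMS":
                raise ValidationError(f"patient {pid}: course reverts after SPMS")
            seen_spms = seen_spms or phen == "SPMS"
            prev_phen = phen

        relapses = sorted(self.relapses)
        cleaned_relapses: list[int] = []
        for day in relapses:
            if cleaned_relapses and day - cleaned_relapses[-1] < MIN_RELAPSE_GAP_DAYS:
                if relapse_policy == "merge":
                    continue  # merged into the earlier onset
                raise ValidationError(
                    f"patient {pid}: relapses on {to_iso(cleaned_relapses[-1])} and "
                    f"{to_iso(day)} are <30 days apart"
                )
            cleaned_relapses.append(day)

        episodes = sorted(self.treatments, key=lambda e: e.start)
        for i, ep in enumerate(episodes):
            if ep.stop is not None and ep.stop < ep.start:
                raise ValidationError(f"patient {pid}: treatment episode stops before it starts")
            if i + 1 < len(episodes):
                if ep.stop is None or episodes[i + 1].start < ep.stop:
                    raise ValidationError(f"patient {pid}: overlapping treatment episodes")

        return replace(
            self,
            visits=visits,
            course_history=courses,
            relapses=cleaned_relapses,
            treatments=episodes,
            mri=sorted(self.mri),
            pregnancies=sorted(self.pregnancies),
        )


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "patients": ["patient_id", "sex", "birth_date", "ms_onset_date"],
    "courses": ["patient_id", "phenotype", "start_date"],
    "visits": ["patient_id", "date", "edss"],
    "relapses": ["patient_id", "date"],
    "treatments": ["patient_id", "dmt_name", "start_date", "stop_date"],
    "mri": ["patient_id", "date", "activity"],
    "pregnancies": ["patient_id", "start_date", "end_date"],
}

_REQUIRED_TABLES = ("patients", "courses", "visits", "relapses", "treatments", "mri")


def _read_table(name: str, path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _SCHEMAS[name]:
        if col not in df.columns:
            raise SchemaError(f"table {name!r}: missing required column {col!r}")
    return df


def read_registry(
    paths_by_table: dict, relapse_policy: str = "merge"
) -> list[PatientRecord]:
    """Read the delimited registry tables into validated patient records.

    ``paths_by_table`` maps table names (``patients``, ``courses``,
    ``visits``, ``relapses``, ``treatments``, ``mri`` and optionally
    ``pregnancies``) to file paths.
    """
    for name in _REQUIRED_TABLES:
        if name not in paths_by_table:
            raise SchemaError(f"missing required table {name!r}")
    tables = {name: _read_table(name, path) for name, path in paths_by_table.items()}

    def grouped(name: str):
        df = tables.get(name)
        if df is None or df.empty:
            return {}
        return dict(tuple(df.groupby("patient_id", sort=False)))

    courses_by, visits_by = grouped("courses"), grouped("visits")
    relapses_by, treat_by = grouped("relapses"), grouped("treatments")
    mri_by, preg_by = grouped("mri"), grouped("pregnancies")

    records = []
    for row in tables["patients"].itertuples(index=False):
        pid = row.patient_id
        visits = [
            EdssScore(to_day(r.date), float(r.edss))
            for r in visits_by.get(pid, pd.DataFrame(columns=_SCHEMAS["visits"])).itertuples()
        ]
        courses = [
            (r.phenotype, to_day(r.start_date))
            for r in courses_by.get(pid, pd.DataFrame(columns=_SCHEMAS["courses"])).itertuples()
        ]
        relapses = [
            to_day(r.date)
            for r in relapses_by.get(pid, pd.DataFrame(columns=_SCHEMAS["relapses"])).itertuples()
        ]
        treatments = [
            TreatmentEpisode(r.dmt_name, to_day(r.start_date),
                             None if r.stop_date == "" else to_day(r.stop_date))
            for r in treat_by.get(pid, pd.DataFrame(columns=_SCHEMAS["treatments"])).itertuples()
        ]
        mri = [
            (to_day(r.date), r.activity)
            for r in mri_by.get(pid, pd.DataFrame(columns=_SCHEMAS["mri"])).itertuples()
        ]
        pregnancies = [
            (to_day(r.start_date), to_day(r.end_date))
            for r in preg_by.get(pid, pd.DataFrame(columns=_SCHEMAS["pregnancies"])).itertuples()
        ]
        rec = PatientRecord(
            patient_id=pid,
            sex=row.sex,
            birth=to_day(row.birth_date),
            onset=to_day(row.ms_onset_date),
            course_history=courses,
            visits=visits,
            relapses=relapses,
            treatments=treatments,
            mri=mri,
            pregnancies=pregnancies,
        )
        records.append(rec.validated(relapse_policy=relapse_policy))
    return records


def write_registry(records: list[PatientRecord], out_dir) -> dict:
    """Write the cohort back to the delimited table format.

    Returns the mapping of table name -> written path, suitable for
    :func:`read_registry` (round-trip identity on validated cohorts).
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    rows: dict[str, list] = {name: [] for name in _SCHEMAS}
    for rec in records:
        rows["patients"].append(
            (rec.patient_id, rec.sex, to_iso(rec.birth), to_iso(rec.onset))
        )
        rows["courses"] += [(rec.patient_id, p, to_iso(d)) for p, d in rec.course_history]
        rows["visits"] += [(rec.patient_id, to_iso(v.day), v.value) for v in rec.visits]
        rows["relapses"] += [(rec.patient_id, to_iso(d)) for d in rec.relapses]
        rows["treatments"] += [
            (rec.patient_id, ep.dmt_name, to_iso(ep.start),
             "" if ep.stop is None else to_iso(ep.stop))
            for ep in rec.treatments
        ]
        rows["mri"] += [(rec.patient_id, to_iso(d), a) for d, a in rec.mri]
        rows["pregnancies"] += [
            (rec.patient_id, to_iso(s), to_iso(e)) for s, e in rec.pregnancies
        ]
    paths = {}
    for name, cols in _SCHEMAS.items():
        path = os.path.join(out_dir, f"{name}.csv")
        pd.DataFrame(rows[name], columns=cols).to_csv(path, index=False)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------


@dataclass
class EligibilityResult:
    """Outcome of :func:`filter_eligible`.

    ``records`` are the retained patients; ``exclusions`` is a DataFrame with
    columns (patient_id, reason_code, detail), one row per excluded patient;
    ``spms_censor`` maps patient_id -> censoring day for relapsing-cohort
    patients who convert to SPMS during follow-up.
    """

    records: list[PatientRecord]
    exclusions: pd.DataFrame
    spms_censor: dict


_EXCLUSION_COLUMNS = ["patient_id", "reason_code", "detail"]


def filter_eligible(
    records: list[PatientRecord], cohort_kind: str = "relapsing"
) -> EligibilityResult:
    """Apply the minimum-data eligibility rules.

    Retains patients with: first-to-last EDSS span >= 365 days, >= 3 EDSS
    scores, no inter-score gap > 365 days, and non-missing minimum dataset
    (sex, dates, course history).  ``cohort_kind="relapsing"`` additionally
    excludes patients whose phenotype at their first EDSS visit is
    progressive, and records an SPMS-conversion censoring day for patients
    converting during follow-up.  ``cohort_kind="full"`` keeps all
    phenotypes with no conversion censoring.
    """
    if cohort_kind not in ("relapsing", "full"):
        raise ValidationError(f"unknown cohort_kind {cohort_kind!r}")
    kept: list[PatientRecord] = []
    excluded: list[tuple] = []
    spms_censor: dict = {}
    for rec in records:
        pid = rec.patient_id
        if not rec.course_history:
            excluded.append((pid, "missing_minimum_data", "no MS course recorded"))
            continue
        if len(rec.visits) < 3:
            excluded.append((pid, "lt_3_edss", f"{len(rec.visits)} EDSS scores"))
            continue
        span = rec.visits[-1].day - rec.visits[0].day
        if span < YEAR_DAYS:
            excluded.append(
                (pid, "followup_lt_1y", f"{span / YEAR_DAYS:.2f} years between first and last EDSS")
            )
            continue
        gaps = [b.day - a.day for a, b in zip(rec.visits, rec.visits[1:])]
        if max(gaps) > YEAR_DAYS:
            excluded.append(
                (pid, "edss_gap_gt_1y", f"largest inter-score gap {max(gaps)} days")
            )
            continue
        baseline_phen = rec.phenotype_at(rec.visits[0].day)
        if baseline_phen is None:
            excluded.append((pid, "missing_minimum_data", "no course at first EDSS visit"))
            continue
        if cohort_kind == "relapsing":
            if baseline_phen in PROGRESSIVE_PHENOTYPES:
                excluded.append(
                    (pid, "progressive_at_baseline", f"phenotype {baseline_phen} at first EDSS")
                )
                continue
            spms = rec.spms_day()
            if spms is not None and spms <= rec.visits[-1].day:
                spms_censor[pid] = max(spms, rec.visits[0].day)
        kept.append(rec)
    exclusions = pd.DataFrame(excluded, columns=_EXCLUSION_COLUMNS)
    return EligibilityResult(records=kept, exclusions=exclusions, spms_censor=spms_censor)
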