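"""Cohort eligibility, policy-period assignment, and the model-ready table.

The study population is long-stay nursing-home residents with dementia, aged
65+ at admission, continuously enrolled in fee-for-service Medicare Parts
A/B/D, without exclusionary diagnoses (Huntington's disease, schizophrenia,
Tourette syndrome), who newly initiate an antipsychotic.  Episodes are
assigned to one of three federal policy periods by their initiation date:

* ``pre_partnership``   — through 2012-03-31,
* ``post_partnership``  — 2012-04-01 .. 2014-12-31 (National Partnership to
  Improve Dementia Care in force),
* ``post_five_star``    — from 2015-01-01 (antipsychotic measures in the
  Five Star Quality Rating System).

Facility covariates are categorized at the fixed study cutpoints (percent
Black residents <5 / 5-15 / >15; percent Medicaid <=62.5 / >62.5; summed
nurse staffing hours per resident day <3 / 3-4.1 / >4.1) with the reference
levels used in the adjusted model: low percent Black, lower percent
Medicaid, for-profit ownership, lower staffing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataInconsistencyError
from .exposure import EpisodeRules

log = logging.getLogger(__name__)

PARTNERSHIP_START = date(2012, 4, 1)
FIVE_STAR_START = date(2015, 1, 1)

POLICY_PERIODS = ("pre_partnership", "post_partnership", "post_five_star")

#: Category labels, reference level first.
CATEGORY_LEVELS = {
    "period": list(POLICY_PERIODS),
    "pct_black_cat": ["low", "intermediate", "high"],
    "pct_medicaid_cat": ["low", "high"],
    "ownership": ["for_profit", "nonprofit_or_government"],
    "staffing_cat": ["low", "mid", "high"],
}

#: Columns of the model-ready analysis table.
ANALYSIS_COLUMNS = [
    "person_id", "index_date", "outcome", "event_day", "duration_days",
    "time", "event", "competing", "period", "quarters_after_first",
    "age", "comorbidity_score", "anxiety", "bipolar", "depression",
    "physical_aggression", "facility_id", "pct_black_cat",
    "pct_medicaid_cat", "ownership", "staffing_cat",
]

#: Clinical/demographic covariates required on the resident record.
_RESIDENT_COVARIATES = ["comorbidity_score", "anxiety", "bipolar", "depression",
                        "physical_aggression"]


@dataclass(frozen=True)
class StayInterval:
    """A nursing-home stay, half-open on days: present on entry .. exit-1."""

    person_id: str
    facility_id: str
    entry_date: date
    exit_date: date

    def __post_init__(self):
        if self.exit_date < self.entry_date:
            raise ValueError(f"stay exit {self.exit_date} precedes entry {self.entry_date}")


@dataclass(frozen=True)
class FacilityYear:
    facility_id: str
    year: int
    pct_black: float
    pct_medicaid: float
    ownership: str  # for_profit | nonprofit_or_government
    staffing_hours_per_resident_day: float
    beds: int = 0
    urban: bool = True

    def __post_init__(self):
        for name in ("pct_black", "pct_medicaid"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"FacilityYear.{name} must be a percent in [0, 100], got {v}")
        if self.staffing_hours_per_resident_day < 0:
            raise ValueError("FacilityYear.staffing_hours_per_resident_day must be >= 0")
        if self.ownership not in CATEGORY_LEVELS["ownership"]:
            raise ValueError(f"FacilityYear.ownership must be one of {CATEGORY_LEVELS['ownership']}")


def qualify_long_stay(stays: Sequence[StayInterval], rules: EpisodeRules | None = None) -> date | None:
    """First date by which a resident attains long-stay status, or ``None``.

    Scanning calendar days from first entry, long-stay status is attained on
    the day cumulative nursing-home days *exceed* ``long_stay_min_days``
    (default 100) while cumulative days outside the facility since first
    entry remain at most ``long_stay_max_outside`` (default 10).  Days
    between stays — including hospital days — count as outside.
    """
    rules = rules or EpisodeRules()
    if not stays:
        return None
    ordered = sorted(stays, key=lambda s: s.entry_date)
    for a, b in zip(ordered, ordered[1:]):
        if b.entry_date < a.exit_date:
            raise DataInconsistencyError(
                f"overlapping stays for {a.person_id}: {a.entry_date}..{a.exit_date} and "
                f"{b.entry_date}..{b.exit_date}"
            )
    need = rules.long_stay_min_days + 1
    nh_days = 0
    outside = 0
    prev_exit: date | None = None
    for st in ordered:
        if prev_exit is not None:
            outside += (st.entry_date - prev_exit).days
            if outside > rules.long_stay_max_outside:
                return None
        stay_len = (st.exit_date - st.entry_date).days
        if nh_days + stay_len >= need:
            return date.fromordinal(st.entry_date.toordinal() + (need - nh_days) - 1)
        nh_days += stay_len
        prev_exit = st.exit_date
    return None


def assign_policy_period(index_date: date,
                         study_start: date = date(2010, 1, 1),
                         study_end: date = date(2017, 12, 31)) -> str:
    """Policy period in force at an episode's initiation date."""
    if not (study_start <= index_date <= study_end):
        raise ValueError(f"index date {index_date} outside study window {study_start}..{study_end}")
    if index_date < PARTNERSHIP_START:
        return "pre_partnership"
    if index_date < FIVE_STAR_START:
        return "post_partnership"
    return "post_five_star"


def derive_facility_covariates(fy: FacilityYear) -> dict[str, str]:
    """Categorize a facility-year at the study cutpoints."""
    if fy.pct_black < 5.0:
        black = "low"
    elif fy.pct_black <= 15.0:
        black = "intermediate"
    else:
        black = "high"
    medicaid = "low" if fy.pct_medicaid <= 62.5 else "high"
    staffing = fy.staffing_hours_per_resident_day
    if staffing < 3.0:
        staff = "low"
    elif staffing <= 4.1:
        staff = "mid"
    else:
        staff = "high"
    return {
        "pct_black_cat": black,
        "pct_medicaid_cat": medicaid,
        "ownership": fy.ownership,
        "staffing_cat": staff,
    }


def _spans_cover(spans: Iterable[tuple[date, date]], lo: date, hi: date) -> bool:
    """True when the union of half-open spans [start, end) covers [lo, hi]."""
    pos = lo.toordinal()
    stop = hi.toordinal()
    for start, end in sorted(spans):
        s, e = start.toordinal(), end.toordinal()
        if s > pos:
            return False
        pos = max(pos, e)
        if pos > stop:
            return True
    return pos > stop


def apply_eligibility(
    resident: Mapping,
    enrollment_spans: Mapping[str, Sequence[tuple[date, date]]],
    index_date: date,
    rules: EpisodeRules,
    admission_date: date,
    long_stay_date: date | None,
) -> tuple[bool, list[str]]:
    """Evaluate every eligibility criterion; returns (eligible, failed reasons).

    ``resident`` is a mapping with ``birth_date``, ``dementia_onset_date``,
    ``exclusionary_dx`` and ``medicare_advantage`` entries.
    ``enrollment_spans`` maps part labels (``"AB"``, ``"D"``) to half-open
    date spans; continuous enrollment is required from ``washout_days``
    before the index through the index date.
    """
    reasons: list[str] = []
    birth = resident.get("birth_date")
    if birth is None or (isinstance(birth, float) and math.isnan(birth)):
        raise ValueError(f"missing birth_date for resident {resident.get('person_id')}")
    age_at_admission = (admission_date - birth).days / 365.25
    if age_at_admission < 65:
        reasons.append("age_under_65")
    onset = resident.get("dementia_onset_date")
    if onset is None or (isinstance(onset, float) and math.isnan(onset)) or onset > index_date:
        reasons.append("no_dementia_by_index")
    if bool(resident.get("exclusionary_dx")):
        reasons.append("exclusionary_diagnosis")
    if bool(resident.get("medicare_advantage")):
        reasons.append("medicare_advantage")
    window_lo = date.fromordinal(index_date.toordinal() - rules.washout_days)
    for part in ("AB", "D"):
        if not _spans_cover(enrollment_spans.get(part, ()), window_lo, index_date):
            reasons.append("enrollment_gap")
            break
    if long_stay_date is None or not (long_stay_date < index_date):
        reasons.append("not_long_stay_by_index")
    return (not reasons, reasons)


def quarters_between(study_start: date, index_date: date) -> int:
    """Whole calendar quarters from the study window's first quarter."""
    q0 = study_start.year * 4 + (study_start.month - 1) // 3
    q1 = index_date.year * 4 + (index_date.month - 1) // 3
    return q1 - q0


def _stays_by_person(stays: pd.DataFrame) -> dict[str, list[StayInterval]]:
    out: dict[str, list[StayInterval]] = {}
    for row in stays.itertuples(index=False):
        out.setdefault(row.person_id, []).append(
            StayInterval(row.person_id, row.facility_id, row.entry_date, row.exit_date)
        )
    return out


def _enrollment_by_person(enrollment: pd.DataFrame) -> dict[str, dict[str, list[tuple[date, date]]]]:
    out: dict[str, dict[str, list[tuple[date, date]]]] = {}
    for row in enrollment.itertuples(index=False):
        out.setdefault(row.person_id, {}).setdefault(row.part, []).append(
            (row.start_date, row.end_date)
        )
    return out


def assemble_analysis_table(
    episodes: pd.DataFrame,
    residents: pd.DataFrame,
    stays: pd.DataFrame,
    facility_years: pd.DataFrame,
    enrollment: pd.DataFrame,
    rules: EpisodeRules | None = None,
    study_start: date = date(2010, 1, 1),
    study_end: date = date(2017, 12, 31),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join classified episodes to covariates, keeping eligible episodes only.

    Returns the analysis table (one row per eligible episode, columns in
    :data:`ANALYSIS_COLUMNS`) and a drop log mapping reason codes to counts.
    The result is deterministic and independent of input row order.
    """
    rules = rules or EpisodeRules()
    drop: dict[str, int] = {}

    def dropped(reason: str):
        drop[reason] = drop.get(reason, 0) + 1

    res_by_id = {r["person_id"]: r for r in residents.to_dict("records")}
    stays_by_person = _stays_by_person(stays)
    enroll_by_person = _enrollment_by_person(enrollment)
    fy_by_key = {(r["facility_id"], int(r["year"])): r for r in facility_years.to_dict("records")}

    rows: list[dict] = []
    ordered = episodes.sort_values(["person_id", "index_date"], kind="mergesort")
    for ep in ordered.to_dict("records"):
        pid = ep["person_id"]
        resident = res_by_id.get(pid)
        person_stays = stays_by_person.get(pid, [])
        if resident is None or not person_stays:
            dropped("missing_resident_or_stays")
            continue
        idx: date = ep["index_date"]
        admission = min(s.entry_date for s in person_stays)
        long_stay_date = qualify_long_stay(person_stays, rules)
        ok, reasons = apply_eligibility(
            resident, enroll_by_person.get(pid, {}), idx, rules, admission, long_stay_date
        )
        if not ok:
            dropped("ineligible:" + reasons[0])
            continue
        stay_at_index = next(
            (s for s in person_stays if s.entry_date <= idx < s.exit_date), None
        )
        if stay_at_index is None:
            dropped("no_stay_at_index")
            continue
        fy = fy_by_key.get((stay_at_index.facility_id, idx.year))
        if fy is None:
            dropped("missing_facility_year")
            continue
        try:
            fac_cats = derive_facility_covariates(FacilityYear(
                facility_id=fy["facility_id"], year=int(fy["year"]),
                pct_black=float(fy["pct_black"]), pct_medicaid=float(fy["pct_medicaid"]),
                ownership=str(fy["ownership"]),
                staffing_hours_per_resident_day=float(fy["staffing_hours_per_resident_day"]),
            ))
        except (ValueError, TypeError):
            dropped("invalid_facility_year")
            continue
        clinical = {k: resident.get(k) for k in _RESIDENT_COVARIATES}
        if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in clinical.values()):
            dropped("missing_covariates")
            continue
        age = (idx - resident["birth_date"]).days / 365.25
        rows.append({
            "person_id": pid,
            "index_date": idx,
            "outcome": ep["outcome"],
            "event_day": int(ep["event_day"]),
            "duration_days": int(ep["duration_days"]),
            "time": int(ep["event_day"]),
            "event": int(ep["outcome"] == "discontinued"),
            "competing": int(ep["outcome"] == "died"),
            "period": assign_policy_period(idx, study_start, study_end),
            "quarters_after_first": quarters_between(study_start, idx),
            "age": age,
            "comorbidity_score": float(clinical["comorbidity_score"]),
            "anxiety": int(clinical["anxiety"]),
            "bipolar": int(clinical["bipolar"]),
            "depression": int(clinical["depression"]),
            "physical_aggression": int(clinical["physical_aggression"]),
            "facility_id": stay_at_index.facility_id,
            **fac_cats,
        })

    if drop:
        log.info("assemble_analysis_table dropped %d episode(s): %s", sum(drop.values()), drop)
    table = pd.DataFrame(rows, columns=ANALYSIS_COLUMNS)
    return table, drop
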