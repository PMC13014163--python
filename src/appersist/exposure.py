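"""Daily drug availability and treatment-episode construction from dispensing claims.

This module turns a stream of pharmacy fills (person, date, drug code, days
supply) into the analysis units of a new-user persistence study:

* :func:`build_availability` converts fills into merged intervals of days with
  drug on hand, applying the stockpiling rule (overlapping refills of the
  *same* drug carry remaining supply forward) and the restart rule (a fill of
  a *different* drug in the class replaces whatever supply remained).
* :func:`find_new_use_episodes` locates treatment initiations: interval starts
  preceded by at least ``washout_days`` (default 90) uncovered days.
* :func:`classify_episode_end` scans forward from an initiation and decides,
  under a fixed precedence, whether the episode ended in discontinuation
  (a gap of ``gap_days``, default 30, without drug on hand), death, or one of
  the censoring events (nursing-home discharge, fee-for-service or Part D
  disenrollment, or reaching the ``horizon_days`` = 180-day administrative
  boundary).

Day convention: a fill on day ``d`` with supply ``s`` covers the closed run of
integer days ``d .. d+s-1``.  A discontinuation is dated at the first
uncovered day of the qualifying gap, so the event day equals the days of
follow-up during which medication could have been in hand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

from .errors import DataInconsistencyError

log = logging.getLogger(__name__)

#: Recognised episode outcomes.
OUTCOMES = (
    "discontinued",
    "died",
    "censored_discharge",
    "censored_ffs_disenroll",
    "censored_partd_disenroll",
    "censored_admin",
)

#: Tie-break precedence when several terminating events are decided on the
#: same day: discontinuation (whose event day, the gap start, precedes its
#: decision day) beats death, death beats any censoring, and specific
#: censoring events beat the administrative boundary.
PRECEDENCE = {name: rank for rank, name in enumerate(OUTCOMES)}


@dataclass(frozen=True)
class EpisodeRules:
    """Tunable constants of the episode algorithm.

    Defaults are the study definitions: 90-day washout for new use, 30-day
    gap for discontinuation, 180-day follow-up horizon, and the long-stay
    qualification (>100 nursing-home days with at most 10 days outside).
    """

    washout_days: int = 90
    gap_days: int = 30
    horizon_days: int = 180
    long_stay_min_days: int = 100  # exclusive threshold: needs *more* than this
    long_stay_max_outside: int = 10

    def __post_init__(self):
        for name in ("washout_days", "gap_days", "horizon_days",
                     "long_stay_min_days", "long_stay_max_outside"):
            value = getattr(self, name)
            if not isinstance(value, int) or value <= 0:
                raise ValueError(f"EpisodeRules.{name} must be a positive integer, got {value!r}")


@dataclass(frozen=True)
class DispensingClaim:
    """One pharmacy fill (a Part-D-style prescription drug event)."""

    person_id: str
    dispense_date: date
    drug_code: str
    days_supply: int


@dataclass
class CoverageIntervalSet:
    """Merged closed intervals of day ordinals during which drug is on hand."""

    person_id: str
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def total_covered_days(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    def covered_days_in(self, start: int, stop: int) -> int:
        """Covered days with ordinal in the half-open window [start, stop)."""
        total = 0
        for s, e in self.intervals:
            total += max(0, min(e, stop - 1) - max(s, start) + 1)
        return total

    def normalized(self) -> "CoverageIntervalSet":
        """Sorted, merged (overlapping or adjacent runs joined) copy; idempotent."""
        return CoverageIntervalSet(self.person_id, normalize_intervals(self.intervals))


@dataclass(frozen=True)
class ExposureEpisode:
    """A classified new-use episode.

    ``event_day`` counts days since the index fill (the index day is day 0 of
    coverage; the event day is in 1..horizon).  ``duration_days`` is the
    number of covered days credited within ``[index, index + event_day)``.
    """

    person_id: str
    index_date: date
    outcome: str
    event_day: int
    duration_days: int


def normalize_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge closed integer intervals; adjacent runs are joined."""
    ordered = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in ordered:
        if e < s:
            raise ValueError(f"interval end {e} precedes start {s}")
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_availability(claims: Sequence[DispensingClaim]) -> CoverageIntervalSet:
    """Convert one person's fills into merged coverage intervals.

    Rules applied fill-by-fill in (date, drug, supply) order:

    * no drug on hand on the fill date -> a fresh run of ``days_supply`` days;
    * same drug refilled while supply remains -> stockpiling, the run is
      extended by the full new supply (remaining days carry forward);
    * a *different* drug filled while supply remains -> restart, coverage
      from the fill date runs exactly the new supply (remainder discarded).

    Exact duplicate claims are processed once (logged).  Supplies below one
    day are rejected.
    """
    if not claims:
        return CoverageIntervalSet(person_id="", intervals=[])
    person_ids = {c.person_id for c in claims}
    if len(person_ids) != 1:
        raise ValueError(f"build_availability expects claims for one person, got {sorted(person_ids)}")
    for c in claims:
        if c.days_supply < 1:
            raise ValueError(
                f"days_supply must be >= 1, got {c.days_supply} for {c.person_id} on {c.dispense_date}"
            )

    unique = sorted(set(claims), key=lambda c: (c.dispense_date, c.drug_code, c.days_supply))
    n_dupes = len(claims) - len(unique)
    if n_dupes:
        log.warning("dropped %d exact duplicate dispensing claim(s) for person %s",
                    n_dupes, claims[0].person_id)

    intervals: list[list[int]] = []
    cov_end: int | None = None
    current_drug: str | None = None
    for c in unique:
        d = c.dispense_date.toordinal()
        s = c.days_supply
        if cov_end is None or d > cov_end:
            intervals.append([d, d + s - 1])
            cov_end = d + s - 1
        elif c.drug_code == current_drug:
            cov_end += s
            intervals[-1][1] = cov_end
        else:
            cov_end = d + s - 1
            intervals[-1][1] = cov_end
        current_drug = c.drug_code

    return CoverageIntervalSet(
        person_id=unique[0].person_id,
        intervals=normalize_intervals(intervals),
    )


def find_new_use_episodes(
    coverage: CoverageIntervalSet,
    rules: EpisodeRules,
    eligibility_window: tuple[date | None, date | None] = (None, None),
) -> list[date]:
    """Index dates of new-use episodes.

    An interval start qualifies when the ``washout_days`` days immediately
    before it are fully uncovered (the first interval trivially qualifies:
    there is no prior coverage) and the date lies inside the eligibility
    window (inclusive bounds; ``None`` leaves a side open).
    """
    lo, hi = eligibility_window
    lo_ord = lo.toordinal() if lo is not None else None
    hi_ord = hi.toordinal() if hi is not None else None
    indexes: list[date] = []
    prev_end: int | None = None
    for s, e in normalize_intervals(coverage.intervals):
        qualifies = prev_end is None or (s - prev_end - 1) >= rules.washout_days
        in_window = (lo_ord is None or s >= lo_ord) and (hi_ord is None or s <= hi_ord)
        if qualifies and in_window:
            indexes.append(date.fromordinal(s))
        prev_end = e
    return indexes


def classify_episode_end(
    coverage: CoverageIntervalSet,
    index_date: date,
    rules: EpisodeRules,
    death_date: date | None = None,
    discharge_date: date | None = None,
    ffs_end: date | None = None,
    partd_end: date | None = None,
) -> ExposureEpisode:
    """Classify how an episode beginning at ``index_date`` ends.

    Candidate terminating events, each with a *decision day* (days since
    index) at which it is established:

    * discontinuation: the first uncovered run of at least ``gap_days`` days
      that completes within the horizon; decided on the gap's ``gap_days``-th
      uncovered day, dated at the gap's first uncovered day;
    * death at its day; censoring (discharge, FFS disenrollment, Part D
      disenrollment) at their days; the administrative boundary at
      ``horizon_days``.

    The earliest decision wins; same-day ties follow :data:`PRECEDENCE`.
    Events dated on the index day itself are counted at day 1 (the minimum
    possible event day, since the index day is covered by construction).
    """
    idx = index_date.toordinal()
    horizon = rules.horizon_days
    intervals = normalize_intervals(coverage.intervals)
    if not any(s == idx for s, _ in intervals):
        raise ValueError(f"{index_date} is not the start of a coverage interval")
    if death_date is not None and death_date < index_date:
        raise DataInconsistencyError(
            f"death date {death_date} precedes episode index {index_date} for {coverage.person_id}"
        )

    # Coverage runs relative to index, clipped to the follow-up window [0, horizon).
    rel = [(max(s, idx) - idx, min(e, idx + horizon - 1) - idx)
           for s, e in intervals if e >= idx and s < idx + horizon]

    # (decision_day, precedence, event_day, outcome); the smallest tuple wins.
    candidates: list[tuple[int, int, int, str]] = []

    gap_starts = []
    for (s1, e1), (s2, _) in zip(rel, rel[1:]):
        gap_starts.append((e1 + 1, s2 - e1 - 1))  # (first uncovered day, run length)
    last_end = rel[-1][1]
    if last_end + 1 < horizon:
        gap_starts.append((last_end + 1, horizon - last_end - 1))
    for g, run in gap_starts:
        if run >= rules.gap_days and g + rules.gap_days <= horizon:
            candidates.append((g + rules.gap_days - 1, PRECEDENCE["discontinued"], g, "discontinued"))
            break

    def event_offset(d: date | None) -> int | None:
        if d is None:
            return None
        off = d.toordinal() - idx
        if off < 0:
            raise DataInconsistencyError(
                f"event date {d} precedes episode index {index_date} for {coverage.person_id}"
            )
        return max(off, 1)

    death_off = event_offset(death_date)
    if death_off is not None:
        candidates.append((death_off, PRECEDENCE["died"], death_off, "died"))
    for d, outcome in ((discharge_date, "censored_discharge"),
                      (ffs_end, "censored_ffs_disenroll"),
                      (partd_end, "censored_partd_disenroll")):
        off = event_offset(d)
        if off is not None:
            candidates.append((off, PRECEDENCE[outcome], off, outcome))
    candidates.append((horizon, PRECEDENCE["censored_admin"], horizon, "censored_admin"))

    _, _, event_day, outcome = min(candidates)
    duration = sum(max(0, min(e, event_day - 1) - s + 1) for s, e in rel)
    return ExposureEpisode(
        person_id=coverage.person_id,
        index_date=index_date,
        outcome=outcome,
        event_day=int(event_day),
        duration_days=int(duration),
    )


def episodes_for_person(
    claims: Sequence[DispensingClaim],
    rules: EpisodeRules,
    eligibility_window: tuple[date | None, date | None] = (None, None),
    death_date: date | None = None,
    discharge_date: date | None = None,
    ffs_end: date | None = None,
    partd_end: date | None = None,
) -> list[ExposureEpisode]:
    """Build availability, locate new-use indexes, and classify each episode."""
    coverage = build_availability(claims)
    if not coverage.intervals:
        return []
    episodes = []
    for index_date in find_new_use_episodes(coverage, rules, eligibility_window):
        episodes.append(
            classify_episode_end(
                coverage, index_date, rules,
                death_date=death_date, discharge_date=discharge_date,
                ffs_end=ffs_end, partd_end=partd_end,
            )
        )
    return episodes
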