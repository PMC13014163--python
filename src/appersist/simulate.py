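"""Synthetic nursing-home claims with known ground-truth hazards.

Every downstream stage (exposure engine, cohort builder, competing-risks
estimation) is testable against this generator because the data-generating
process is fully specified:

* time is discrete in whole days, and every event process (discontinuation,
  death, discharge, disenrollment, initiation) is a daily Bernoulli hazard;
* the per-day discontinuation hazard of an episode is the configured
  baseline multiplied by the policy-period multiplier in force at the
  episode's index date and by ``exp(covariate effects)``;
* fills follow the configured days-supply and refill-delay distributions,
  and the *final* fill of an episode is truncated so that drug-on-hand ends
  exactly on the latent stop day — the latent discontinuation time is
  therefore identifiable from the claims through the 30-day-gap rule, and
  parameter-recovery experiments measure estimator error rather than
  supply-grid rounding;
* a configurable fraction of residents contributes a second (and rarely a
  third) episode after a fresh 90-day washout, and a small fraction
  initiates before attaining long-stay status, exercising the cohort
  builder's exclusion paths.

Outputs are plain pandas tables (facility-years, residents, stays,
enrollment spans, deaths, dispensings) with ISO dates at the I/O boundary.
Fixing the seed makes every table byte-identical across runs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from datetime import date
import numpy as np
import pandas as pd

from .cohort import FIVE_STAR_START, PARTNERSHIP_START, POLICY_PERIODS
from .errors import ConfigError
from .exposure import EpisodeRules, OUTCOMES

_BIG = 10 ** 7  # sentinel "never happens" day ordinal / offset
_NONPROFIT_P = 0.28  # facility nonprofit/government share (stable over years)
_SPLIT_STAY_P = 0.06  # residents with a mid-stay hospital interruption
_EARLY_INITIATOR_P = 0.02  # residents who initiate before long-stay qualification
_FILL_PAD_DAYS = 10  # fills are materialized a little past the 180-day horizon

_RESIDENT_FLAG_DEFAULTS = {
    "anxiety": 0.78,
    "depression": 0.91,
    "bipolar": 0.15,
    "physical_aggression": 0.30,
    "verbal_aggression": 0.38,
}


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic world.

    Hazards are per-day probabilities in [0, 1).  ``period_disc_multipliers``
    are the true post-Partnership and post-Five-Star hazard ratios on
    discontinuation, applied by the episode's index date.
    ``covariate_effects`` maps resident flags (or ``"nonprofit"``) to true
    log hazard ratios; ``covariate_prevalences`` gives each flag's Bernoulli
    probability.  ``period_interaction`` optionally multiplies the two
    post-period hazard ratios for episodes carrying a given flag (used for
    interaction / subgroup experiments).
    """

    seed: int = 0
    n_facilities: int = 60
    n_residents: int = 2000
    study_start: date = date(2010, 1, 1)
    study_end: date = date(2017, 12, 31)
    baseline_disc_hazard: float = 0.0037
    period_disc_multipliers: tuple[float, float] = (1.17, 1.19)
    death_hazard: float = 0.0010
    discharge_hazard: float = 0.0008
    ffs_disenroll_hazard: float = 0.0002
    partd_disenroll_hazard: float = 0.0002
    initiation_hazard: float = 0.010
    supply_lengths: tuple[int, ...] = (28, 30, 60, 90)
    supply_probs: tuple[float, ...] = (0.15, 0.70, 0.10, 0.05)
    refill_delays: tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3)
    refill_delay_probs: tuple[float, ...] = (0.03, 0.05, 0.10, 0.62, 0.12, 0.05, 0.03)
    second_episode_fraction: float = 0.12
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"anxiety": -0.152, "bipolar": -0.156})
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(_RESIDENT_FLAG_DEFAULTS))
    period_interaction: dict[str, tuple[float, float]] = field(default_factory=dict)
    drug_codes: tuple[str, ...] = ("AP01", "AP02", "AP03", "AP04", "AP05")

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        for name in ("n_facilities", "n_residents"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.study_start >= self.study_end:
            raise ConfigError("study_start must precede study_end")
        if (self.study_end - self.study_start).days < 600:
            raise ConfigError("study_start..study_end must span at least 600 days")
        for name in ("baseline_disc_hazard", "death_hazard", "discharge_hazard",
                     "ffs_disenroll_hazard", "partd_disenroll_hazard",
                     "initiation_hazard"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigError(f"{name} must be a per-day hazard in [0, 1), got {v}")
        if len(self.period_disc_multipliers) != 2 or any(
                m <= 0 for m in self.period_disc_multipliers):
            raise ConfigError("period_disc_multipliers must be a pair of positive reals")
        for dist, probs, name in (
                (self.supply_lengths, self.supply_probs, "supply_length_dist"),
                (self.refill_delays, self.refill_delay_probs, "refill_delay_dist")):
            if len(dist) != len(probs) or not dist:
                raise ConfigError(f"{name} values and probabilities must align and be non-empty")
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"{name} probabilities must be non-negative and sum to 1")
        if any(int(s) < 1 for s in self.supply_lengths):
            raise ConfigError("supply_length_dist values must be >= 1 day")
        if max(self.refill_delays) >= EpisodeRules().gap_days:
            raise ConfigError("refill_delay_dist offsets must stay below the 30-day gap")
        if not (0.0 <= self.second_episode_fraction <= 1.0):
            raise ConfigError("second_episode_fraction must be in [0, 1]")
        allowed = set(self.covariate_prevalences) | {"nonprofit"}
        unknown = set(self.covariate_effects) - allowed
        if unknown:
            raise ConfigError(
                f"covariate_effects names {sorted(unknown)} lack a prevalence "
                "in covariate_prevalences (or are not 'nonprofit')")
        for k, p in self.covariate_prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"covariate_prevalences[{k!r}] must be a probability")
        for k, pair in self.period_interaction.items():
            if k not in allowed:
                raise ConfigError(f"period_interaction key {k!r} is not a known covariate")
            if len(pair) != 2 or any(m <= 0 for m in pair):
                raise ConfigError(f"period_interaction[{k!r}] must be a pair of positive reals")


@dataclass
class GroundTruth:
    """True parameters implied by a :class:`SimulationConfig`."""

    period_log_hr: dict[str, float]
    covariate_log_hr: dict[str, float]
    rmst_days: dict[str, float]


@dataclass
class World:
    """Generated tables plus the per-resident arrays the episode draw uses."""

    config: SimulationConfig
    tables: dict[str, pd.DataFrame]
    entry: np.ndarray
    death: np.ndarray          # day ordinal of death, _BIG if none in window
    stay1_exit: np.ndarray
    stay2_entry: np.ndarray    # _BIG when there is no second stay
    stay2_exit: np.ndarray
    qual: np.ndarray           # long-stay qualification ordinal, _BIG if never
    ffs_span_end: np.ndarray
    partd_span_end: np.ndarray
    partd_raw: np.ndarray      # latent Part D disenrollment ordinal
    flags: dict[str, np.ndarray]
    nonprofit: np.ndarray
    facility_idx: np.ndarray
    early_initiator: np.ndarray


@dataclass
class EpisodeDraws:
    """Per-episode latent draws plus materialized fills (internal)."""

    resident: np.ndarray       # row index into the resident arrays
    index_ord: np.ndarray
    period_idx: np.ndarray
    hazard: np.ndarray
    t_disc: np.ndarray
    gap_start: np.ndarray      # first day offset with no drug on hand
    outcome_idx: np.ndarray    # index into exposure.OUTCOMES
    event_day: np.ndarray
    fill_ep: np.ndarray        # fills: episode row
    fill_off: np.ndarray       # fills: day offset from index
    fill_sup: np.ndarray       # fills: days supply
    drug: np.ndarray           # per-episode drug code index


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _geometric(rng: np.random.Generator, p, size) -> np.ndarray:
    """Daily-Bernoulli first-success times; zero hazard maps to 'never'."""
    p = np.broadcast_to(np.asarray(p, dtype=float), size if np.ndim(size) == 0 else size)
    out = np.full(p.shape, _BIG, dtype=np.int64)
    mask = p > 0
    if mask.any():
        out[mask] = rng.geometric(p[mask])
    return out


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

def _empty_tables() -> dict[str, pd.DataFrame]:
    return {
        "facility_years": pd.DataFrame(columns=[
            "facility_id", "year", "pct_black", "pct_medicaid", "ownership",
            "staffing_hours_per_resident_day", "beds", "urban"]),
        "residents": pd.DataFrame(columns=[
            "person_id", "birth_date", "sex", "race", "dual_eligible", "region",
            "dementia_onset_date", "death_date", "exclusionary_dx",
            "medicare_advantage", "comorbidity_score", "adl_score",
            "anxiety", "depression", "bipolar", "physical_aggression",
            "verbal_aggression"]),
        "stays": pd.DataFrame(columns=["person_id", "facility_id", "entry_date", "exit_date"]),
        "enrollment": pd.DataFrame(columns=["person_id", "part", "start_date", "end_date"]),
        "deaths": pd.DataFrame(columns=["person_id", "death_date"]),
    }


def generate_world(config: SimulationConfig) -> World:
    """Generate the facility, resident, stay, enrollment, and death tables."""
    config.validate()
    rng = _rng(config, 0)
    start = config.study_start.toordinal()
    end = config.study_end.toordinal()
    years = list(range(config.study_start.year, config.study_end.year + 1))
    nf, n = config.n_facilities, config.n_residents

    # facilities: a mixture over the three percent-Black strata, roughly the
    # observed marginal distribution of US nursing homes
    fac_ids = np.array([f"F{i:04d}" for i in range(nf)])
    stratum = rng.choice(3, size=nf, p=(0.45, 0.30, 0.25))
    pct_black = np.where(
        stratum == 0, rng.uniform(0.0, 5.0, nf),
        np.where(stratum == 1, rng.uniform(5.0, 15.0, nf), rng.uniform(15.0, 80.0, nf)))
    pct_medicaid = np.clip(rng.normal(62.5, 18.0, nf), 0.0, 100.0)
    nonprofit = rng.random(nf) < _NONPROFIT_P
    staffing = np.clip(rng.normal(3.55, 0.70, nf), 0.5, 8.0)
    beds = np.clip(np.rint(rng.normal(130, 71, nf)), 20, 500).astype(int)
    urban = rng.random(nf) < 0.70

    fy_rows = []
    for year in years:
        jb = np.clip(pct_black + rng.normal(0.0, 0.6, nf), 0.0, 100.0)
        jm = np.clip(pct_medicaid + rng.normal(0.0, 0.8, nf), 0.0, 100.0)
        js = np.clip(staffing + rng.normal(0.0, 0.05, nf), 0.5, 8.0)
        fy_rows.append(pd.DataFrame({
            "facility_id": fac_ids, "year": year,
            "pct_black": np.round(jb, 2), "pct_medicaid": np.round(jm, 2),
            "ownership": np.where(nonprofit, "nonprofit_or_government", "for_profit"),
            "staffing_hours_per_resident_day": np.round(js, 2),
            "beds": beds, "urban": urban,
        }))
    facility_years = (pd.concat(fy_rows, ignore_index=True)
                      if fy_rows else _empty_tables()["facility_years"])

    if n == 0 or nf == 0:
        tables = _empty_tables()
        tables["facility_years"] = facility_years
        z = np.zeros(0, dtype=np.int64)
        return World(config, tables, z, z, z, z, z, z, z, z, z,
                     {k: np.zeros(0, bool) for k in config.covariate_prevalences},
                     np.zeros(0, bool), z, np.zeros(0, bool))

    pids = np.array([f"P{i:06d}" for i in range(n)])
    facility_idx = rng.integers(0, nf, n)
    entry = start + rng.integers(0, max(end - start - 420, 1), n)
    age_at_entry = np.clip(rng.normal(85.0, 7.3, n), 62.0, 105.0)
    birth = entry - np.rint(age_at_entry * 365.25).astype(np.int64)
    sex = rng.choice(np.array(["F", "M"]), size=n, p=(0.73, 0.27))
    race = rng.choice(np.array(["nh_white", "nh_black", "hispanic", "other"]),
                      size=n, p=(0.830, 0.095, 0.052, 0.023))
    dual = rng.random(n) < 0.50
    region = rng.choice(np.array(["northeast", "south", "midwest", "west"]),
                        size=n, p=(0.20, 0.45, 0.26, 0.09))
    onset = entry - rng.integers(30, 1500, n)
    flags = {k: rng.random(n) < p for k, p in config.covariate_prevalences.items()}
    comorbidity = np.clip(np.rint(rng.normal(5.4, 3.4, n)), 0, 20).astype(int)
    adl = np.clip(np.rint(rng.normal(17.5, 6.2, n)), 0, 28).astype(int)
    ma = rng.random(n) < 0.04
    exclusionary = rng.random(n) < 0.05

    death = entry + _geometric(rng, config.death_hazard, n)
    discharge = entry + _geometric(rng, config.discharge_hazard, n)
    split = rng.random(n) < _SPLIT_STAY_P
    cut = rng.integers(30, 90, n)
    hosp_gap = rng.integers(2, 15, n)
    ffs_raw = entry + _geometric(rng, config.ffs_disenroll_hazard, n)
    partd_raw = entry + _geometric(rng, config.partd_disenroll_hazard, n)
    early = rng.random(n) < _EARLY_INITIATOR_P

    exit_final = np.minimum.reduce([discharge, death + 1, np.full(n, end + 1)])
    stay2_entry_cand = entry + cut + hosp_gap
    has2 = split & (entry + cut < exit_final) & (stay2_entry_cand < exit_final)
    stay1_exit = np.where(split, np.minimum(entry + cut, exit_final), exit_final)
    stay2_entry = np.where(has2, stay2_entry_cand, _BIG)
    stay2_exit = np.where(has2, exit_final, _BIG)

    # long-stay qualification: >100 cumulative NH days with <=10 outside
    rules = EpisodeRules()
    need = rules.long_stay_min_days + 1
    len1 = stay1_exit - entry
    len2 = np.where(has2, stay2_exit - stay2_entry, 0)
    qual = np.full(n, _BIG, dtype=np.int64)
    in1 = len1 >= need
    qual[in1] = entry[in1] + need - 1
    ok2 = (~in1) & has2 & (hosp_gap <= rules.long_stay_max_outside) & (len2 >= need - len1)
    qual[ok2] = stay2_entry[ok2] + (need - len1[ok2]) - 1

    death_in_window = death <= end
    death_vis = np.where(death_in_window, death, _BIG)
    ffs_span_end = np.minimum.reduce([ffs_raw, death + 1, np.full(n, end + 1)])
    partd_span_end = np.minimum.reduce([partd_raw, death + 1, np.full(n, end + 1)])

    def d(o):
        return [date.fromordinal(int(v)) for v in o]

    residents = pd.DataFrame({
        "person_id": pids, "birth_date": d(birth), "sex": sex, "race": race,
        "dual_eligible": dual, "region": region,
        "dementia_onset_date": d(onset),
        "death_date": [date.fromordinal(int(v)) if w else None
                       for v, w in zip(death, death_in_window)],
        "exclusionary_dx": exclusionary, "medicare_advantage": ma,
        "comorbidity_score": comorbidity, "adl_score": adl,
        **{k: v for k, v in flags.items()},
    })
    stay_rows = [pd.DataFrame({"person_id": pids, "facility_id": fac_ids[facility_idx],
                               "entry_date": d(entry), "exit_date": d(stay1_exit)})]
    if has2.any():
        stay_rows.append(pd.DataFrame({
            "person_id": pids[has2], "facility_id": fac_ids[facility_idx[has2]],
            "entry_date": d(stay2_entry[has2]), "exit_date": d(stay2_exit[has2])}))
    stays = (pd.concat(stay_rows, ignore_index=True)
             .sort_values(["person_id", "entry_date"], kind="mergesort")
             .reset_index(drop=True))
    span_start = entry - 400
    enrollment = pd.concat([
        pd.DataFrame({"person_id": pids, "part": "AB",
                      "start_date": d(span_start), "end_date": d(ffs_span_end)}),
        pd.DataFrame({"person_id": pids, "part": "D",
                      "start_date": d(span_start), "end_date": d(partd_span_end)}),
    ], ignore_index=True).sort_values(["person_id", "part"], kind="mergesort").reset_index(drop=True)
    deaths = pd.DataFrame({
        "person_id": pids[death_in_window],
        "death_date": d(death[death_in_window]),
    }).reset_index(drop=True)

    tables = {"facility_years": facility_years, "residents": residents,
              "stays": stays, "enrollment": enrollment, "deaths": deaths}
    return World(config, tables, entry.astype(np.int64), death_vis.astype(np.int64),
                 stay1_exit.astype(np.int64), stay2_entry.astype(np.int64),
                 stay2_exit.astype(np.int64), qual, ffs_span_end.astype(np.int64),
                 partd_span_end.astype(np.int64), partd_raw.astype(np.int64),
                 flags, nonprofit[facility_idx], facility_idx, early)


# ---------------------------------------------------------------------------
# Episode draws and claims
# ---------------------------------------------------------------------------

def _period_index(index_ord: np.ndarray) -> np.ndarray:
    bounds = np.array([PARTNERSHIP_START.toordinal(), FIVE_STAR_START.toordinal()])
    return np.searchsorted(bounds, index_ord, side="right")


def _episode_hazard(config: SimulationConfig, world: World,
                    resident: np.ndarray, period_idx: np.ndarray) -> np.ndarray:
    mult = np.array([1.0, *config.period_disc_multipliers])[period_idx]
    loghr = np.zeros(len(resident))
    for name, beta in config.covariate_effects.items():
        flag = world.nonprofit if name == "nonprofit" else world.flags[name]
        loghr += beta * flag[resident]
    h = config.baseline_disc_hazard * mult * np.exp(loghr)
    for name, pair in config.period_interaction.items():
        flag = world.nonprofit if name == "nonprofit" else world.flags[name]
        extra = np.array([1.0, pair[0], pair[1]])[period_idx]
        h *= np.where(flag[resident], extra, 1.0)
    return np.clip(h, 1e-12, 0.95)


def _valid_index(world: World, resident: np.ndarray, cand: np.ndarray,
                 rules: EpisodeRules):
    """Apply index-date constraints; hospital-gap candidates move to the
    second stay's entry.  Returns (valid mask, adjusted index ordinals)."""
    config = world.config
    start = config.study_start.toordinal()
    end = config.study_end.toordinal()
    idx = cand.copy()
    in_gap = (idx >= world.stay1_exit[resident]) & (idx < world.stay2_entry[resident]) \
        & (world.stay2_entry[resident] < _BIG)
    idx[in_gap] = world.stay2_entry[resident][in_gap]
    in_stay = ((idx >= world.entry[resident]) & (idx < world.stay1_exit[resident])) | (
        (idx >= world.stay2_entry[resident]) & (idx < world.stay2_exit[resident]))
    valid = (
        in_stay
        & (idx >= start + rules.washout_days)
        & (idx <= end - rules.horizon_days)
        & (idx < world.death[resident])
        & (idx < world.partd_raw[resident])
    )
    return valid, idx


def _materialize_fills(config: SimulationConfig, rng: np.random.Generator,
                       t_end: np.ndarray):
    """Tile coverage over [0, t_end) per episode; returns fills and the
    first day offset with no drug on hand."""
    n = len(t_end)
    supply_vals = np.asarray(config.supply_lengths, dtype=np.int64)
    delay_vals = np.asarray(config.refill_delays, dtype=np.int64)
    k_max = int(math.ceil((EpisodeRules().horizon_days + _FILL_PAD_DAYS)
                          / supply_vals.min())) + 2
    supplies = rng.choice(supply_vals, size=(n, k_max), p=config.supply_probs)
    delays = rng.choice(delay_vals, size=(n, k_max), p=config.refill_delay_probs)

    cov_end = np.full(n, -1, dtype=np.int64)
    last_fill = np.full(n, -1, dtype=np.int64)
    done = np.zeros(n, dtype=bool)
    fill_ep, fill_off, fill_sup = [], [], []
    for k in range(k_max):
        if k == 0:
            d = np.zeros(n, dtype=np.int64)
            fill_now = np.ones(n, dtype=bool)
        else:
            need = ~done & (cov_end + 1 < t_end)
            done |= ~need & ~done
            d = np.maximum(cov_end + 1 + delays[:, k], last_fill + 1)
            fill_now = need & (d < t_end)
            done |= need & ~fill_now  # scheduled refill falls at/after the stop day
        if not fill_now.any():
            if done.all():
                break
            continue
        s = supplies[:, k].astype(np.int64)
        early_fill = fill_now & (d <= cov_end)
        new_end = np.where(early_fill, cov_end + s, d + s - 1)
        over = new_end - (t_end - 1)
        s = np.where(over > 0, s - over, s)
        new_end = np.minimum(new_end, t_end - 1)
        rows = np.nonzero(fill_now)[0]
        fill_ep.append(rows)
        fill_off.append(d[rows])
        fill_sup.append(s[rows])
        cov_end[fill_now] = new_end[fill_now]
        last_fill[fill_now] = d[fill_now]
        done |= fill_now & (cov_end + 1 >= t_end)
    gap_start = cov_end + 1
    if fill_ep:
        return (np.concatenate(fill_ep), np.concatenate(fill_off),
                np.concatenate(fill_sup), gap_start)
    return (np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0, np.int64), gap_start)


_OUT_IDX = {name: i for i, name in enumerate(OUTCOMES)}


def _classify(world: World, resident: np.ndarray, index_ord: np.ndarray,
              gap_start: np.ndarray, rules: EpisodeRules):
    """Mirror the exposure engine's precedence on the latent event offsets."""
    end = world.config.study_end.toordinal()
    horizon, gap = rules.horizon_days, rules.gap_days
    n = len(resident)

    def offset(abs_day, cond):
        off = np.where(cond, np.maximum(abs_day - index_ord, 1), _BIG)
        return off.astype(np.int64)

    death_abs = world.death[resident]
    death_off = offset(death_abs, death_abs <= end)

    in1 = (index_ord >= world.entry[resident]) & (index_ord < world.stay1_exit[resident])
    stay_exit = np.where(in1, world.stay1_exit[resident], world.stay2_exit[resident])
    real_discharge = (stay_exit <= end) & (death_abs >= stay_exit)
    dis_off = offset(stay_exit, real_discharge)

    ffs_end = world.ffs_span_end[resident]
    ffs_off = offset(ffs_end, (ffs_end <= end) & (ffs_end > index_ord))
    partd_end = world.partd_span_end[resident]
    partd_off = offset(partd_end, (partd_end <= end) & (partd_end > index_ord))

    disc_decision = np.where(gap_start <= horizon - gap, gap_start + gap - 1, _BIG)
    admin = np.full(n, horizon, dtype=np.int64)

    decisions = np.stack([disc_decision, death_off, dis_off, ffs_off, partd_off, admin])
    event_days = np.stack([np.minimum(gap_start, _BIG), death_off, dis_off,
                           ffs_off, partd_off, admin])
    ranks = np.arange(6)[:, None]
    winner = np.argmin(decisions * 8 + ranks, axis=0)
    event_day = np.take_along_axis(event_days, winner[None, :], axis=0)[0]
    return winner.astype(np.int64), event_day.astype(np.int64)


def _draw_episodes(config: SimulationConfig, world: World) -> EpisodeDraws:
    rng = _rng(config, 1)
    rules = EpisodeRules()
    n = config.n_residents

    parts: list[dict] = []

    def run_round(resident: np.ndarray, cand: np.ndarray) -> dict:
        valid, idx = _valid_index(world, resident, cand, rules)
        resident, idx = resident[valid], idx[valid]
        period_idx = _period_index(idx)
        hazard = _episode_hazard(config, world, resident, period_idx)
        t_disc = _geometric(rng, hazard, len(resident))

        death_off = np.maximum(world.death[resident] - idx, 1)
        in1 = (idx >= world.entry[resident]) & (idx < world.stay1_exit[resident])
        stay_exit = np.where(in1, world.stay1_exit[resident], world.stay2_exit[resident])
        dis_off = np.maximum(stay_exit - idx, 1)
        partd_off = np.maximum(world.partd_span_end[resident] - idx, 1)
        pad = rules.horizon_days + _FILL_PAD_DAYS
        t_end = np.minimum.reduce([t_disc, death_off, dis_off, partd_off,
                                   np.full(len(resident), pad, dtype=np.int64)])
        fill_ep, fill_off, fill_sup, gap_start = _materialize_fills(config, rng, t_end)
        outcome_idx, event_day = _classify(world, resident, idx, gap_start, rules)
        drug = rng.integers(0, len(config.drug_codes), len(resident))
        return dict(resident=resident, index_ord=idx, period_idx=period_idx,
                    hazard=hazard, t_disc=t_disc, gap_start=gap_start,
                    outcome_idx=outcome_idx, event_day=event_day,
                    fill_ep=fill_ep, fill_off=fill_off, fill_sup=fill_sup, drug=drug)

    if n > 0:
        # round 1: post-qualification new users
        all_res = np.arange(n)
        base = all_res[(world.qual < _BIG) & ~world.early_initiator]
        wait = _geometric(rng, config.initiation_hazard, len(base))
        parts.append(run_round(base, world.qual[base] + wait))

        # repeat episodes after a fresh washout (a shrinking fraction)
        prev = parts[0]
        for _ in range(2):
            if not len(prev["resident"]):
                break
            again = rng.random(len(prev["resident"])) < config.second_episode_fraction
            res = prev["resident"][again]
            last_covered = prev["index_ord"][again] + prev["gap_start"][again] - 1
            wait = _geometric(rng, config.initiation_hazard, len(res))
            cand = last_covered + 1 + rules.washout_days + wait
            nxt = run_round(res, cand)
            parts.append(nxt)
            prev = nxt

        # pre-qualification initiators (excluded later by the cohort builder)
        eres = all_res[world.early_initiator]
        cand = world.entry[eres] + rng.integers(10, 61, len(eres))
        parts.append(run_round(eres, cand))

    if not parts:
        empty = np.zeros(0, dtype=np.int64)
        return EpisodeDraws(empty, empty, empty, empty.astype(float), empty, empty,
                            empty, empty, empty, empty, empty, empty)

    cat = {k: np.concatenate([p[k] for p in parts]) for k in parts[0]}
    # stable ordering by (resident, index date) with episode-level fills remapped
    order = np.lexsort((cat["index_ord"], cat["resident"]))
    remap = np.empty(len(order), dtype=np.int64)
    remap[order] = np.arange(len(order))
    offsets = np.cumsum([0] + [len(p["resident"]) for p in parts[:-1]])
    fill_ep_global = np.concatenate(
        [p["fill_ep"] + off for p, off in zip(parts, offsets)]) if parts else np.zeros(0, np.int64)
    return EpisodeDraws(
        resident=cat["resident"][order], index_ord=cat["index_ord"][order],
        period_idx=cat["period_idx"][order], hazard=cat["hazard"][order],
        t_disc=cat["t_disc"][order], gap_start=cat["gap_start"][order],
        outcome_idx=cat["outcome_idx"][order], event_day=cat["event_day"][order],
        fill_ep=remap[fill_ep_global], fill_off=cat["fill_off"], fill_sup=cat["fill_sup"],
        drug=cat["drug"][order],
    )


def generate_dispensings(config: SimulationConfig, world: World) -> pd.DataFrame:
    """The Part-D-style dispensing table implied by the latent episode draws."""
    draws = _draw_episodes(config, world)
    pids = world.tables["residents"]["person_id"].to_numpy()
    drugs = np.asarray(config.drug_codes)
    df = pd.DataFrame({
        "person_id": pids[draws.resident[draws.fill_ep]],
        "dispense_date": [date.fromordinal(int(v)) for v in
                          draws.index_ord[draws.fill_ep] + draws.fill_off],
        "drug_code": drugs[draws.drug[draws.fill_ep]],
        "days_supply": draws.fill_sup.astype(int),
    })
    return (df.sort_values(["person_id", "dispense_date", "drug_code"], kind="mergesort")
            .reset_index(drop=True))


def simulate_episode_table(config: SimulationConfig, world: World | None = None) -> pd.DataFrame:
    """Episode-level outcomes straight from the latent draws.

    Produces exactly the episodes (index dates, event days, outcomes) that
    the exposure engine recovers from :func:`generate_dispensings` output —
    an identity that is itself under test — without materializing claims.
    """
    if world is None:
        world = generate_world(config)
    draws = _draw_episodes(config, world)
    pids = world.tables["residents"]["person_id"].to_numpy() if len(
        world.tables["residents"]) else np.array([], dtype=object)
    outcome = np.asarray(OUTCOMES, dtype=object)[draws.outcome_idx] if len(
        draws.outcome_idx) else np.array([], dtype=object)
    df = pd.DataFrame({
        "person_id": pids[draws.resident] if len(draws.resident) else [],
        "index_date": [date.fromordinal(int(v)) for v in draws.index_ord],
        "period": np.asarray(POLICY_PERIODS, dtype=object)[draws.period_idx] if len(
            draws.period_idx) else np.array([], dtype=object),
        "outcome": outcome,
        "time": draws.event_day.astype(int),
        "event": (outcome == "discontinued").astype(int) if len(outcome) else [],
        "competing": (outcome == "died").astype(int) if len(outcome) else [],
    })
    for name in config.covariate_prevalences:
        df[name] = world.flags[name][draws.resident].astype(int) if len(
            draws.resident) else []
    df["nonprofit"] = world.nonprofit[draws.resident].astype(int) if len(
        draws.resident) else []
    return df


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def _true_rmst(config: SimulationConfig, mult: float,
               horizon: int = 180) -> float:
    """Restricted mean on-treatment days for one period: the step-function
    integral of the covariate-mixture survival of exit (discontinuation or
    death) under the configured daily hazards."""
    keys = sorted(config.covariate_effects)
    prev = {k: (_NONPROFIT_P if k == "nonprofit" else config.covariate_prevalences[k])
            for k in keys}
    t = np.arange(horizon)
    total = np.zeros(horizon)
    for bits in itertools.product((0, 1), repeat=len(keys)):
        pi = 1.0
        loghr = 0.0
        for k, b in zip(keys, bits):
            pi *= prev[k] if b else 1.0 - prev[k]
            loghr += config.covariate_effects[k] * b
        h = float(np.clip(config.baseline_disc_hazard * mult * math.exp(loghr),
                          1e-12, 0.95))
        total += pi * ((1.0 - h) * (1.0 - config.death_hazard)) ** t
    return float(total.sum())


def ground_truth(config: SimulationConfig) -> GroundTruth:
    """True log hazard ratios and per-period restricted mean durations."""
    config.validate()
    m1, m2 = config.period_disc_multipliers
    rmst = {
        "pre_partnership": _true_rmst(config, 1.0),
        "post_partnership": _true_rmst(config, m1),
        "post_five_star": _true_rmst(config, m2),
    }
    return GroundTruth(
        period_log_hr={"post_partnership": math.log(m1),
                       "post_five_star": math.log(m2)},
        covariate_log_hr=dict(config.covariate_effects),
        rmst_days=rmst,
    )
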