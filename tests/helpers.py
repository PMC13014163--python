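"""Independent brute-force oracles used to check the package's algorithms.

Everything here deliberately re-derives results the slow, obvious way
(day-by-day walks, direct likelihood evaluation with generic optimizers) so
tests compare two genuinely different routes to the same answer.
"""

from __future__ import annotations

import math
from datetime import date

import numpy as np
from scipy import optimize

from appersist.exposure import DispensingClaim, EpisodeRules


# ---------------------------------------------------------------------------
# day-by-day coverage oracle (explicit carried-supply counter)
# ---------------------------------------------------------------------------

def day_coverage_oracle(claims: list[DispensingClaim]) -> set[int]:
    """Simulate drug-on-hand one day at a time with a supply counter."""
    fills = sorted(set(claims), key=lambda c: (c.dispense_date, c.drug_code, c.days_supply))
    if not fills:
        return set()
    by_day: dict[int, list[DispensingClaim]] = {}
    for c in fills:
        by_day.setdefault(c.dispense_date.toordinal(), []).append(c)
    start = min(by_day)
    end = max(by_day) + sum(c.days_supply for c in fills) + 5
    covered: set[int] = set()
    counter = 0
    current_drug: str | None = None
    for day in range(start, end + 1):
        for c in by_day.get(day, []):
            if counter > 0 and c.drug_code != current_drug:
                counter = c.days_supply  # new drug: discard remaining supply
            else:
                counter += c.days_supply  # same drug (or nothing on hand): stockpile
            current_drug = c.drug_code
        if counter > 0:
            covered.add(day)
            counter -= 1
    return covered


def episode_indexes_oracle(covered: set[int], rules: EpisodeRules) -> list[int]:
    """Scan the daily coverage array for starts preceded by >=washout bare days."""
    if not covered:
        return []
    lo, hi = min(covered), max(covered)
    indexes = []
    for day in range(lo, hi + 1):
        if day not in covered:
            continue
        if (day - 1) in covered:
            continue  # not a run start
        bare = 0
        d = day - 1
        while d >= lo and d not in covered:
            bare += 1
            d -= 1
        if d < lo:
            bare = rules.washout_days  # nothing before the first run
        if bare >= rules.washout_days:
            indexes.append(day)
    return indexes


def classify_oracle(covered: set[int], index_ord: int, rules: EpisodeRules,
                    death: int | None = None, discharge: int | None = None,
                    ffs: int | None = None, partd: int | None = None):
    """Day-walking state machine over the follow-up window.

    Walks decision days 1..horizon; at each day collects the decisions that
    fire (gap reaching ``gap_days`` uncovered days, death, censorings, the
    administrative boundary) and resolves the first day's decisions by the
    fixed precedence.  Returns (outcome, event_day, duration_days).
    """
    H, G = rules.horizon_days, rules.gap_days

    def off(v):
        return None if v is None else max(v - index_ord, 1)

    death_o, dis_o, ffs_o, partd_o = off(death), off(discharge), off(ffs), off(partd)
    run = 0
    gap_start = None
    for t in range(1, H + 1):
        fired: list[tuple[int, str, int]] = []
        if t < H:
            if (index_ord + t) in covered:
                run, gap_start = 0, None
            else:
                if run == 0:
                    gap_start = t
                run += 1
                if run == G:
                    fired.append((0, "discontinued", gap_start))
        if death_o == t:
            fired.append((1, "died", t))
        if dis_o == t:
            fired.append((2, "censored_discharge", t))
        if ffs_o == t:
            fired.append((3, "censored_ffs_disenroll", t))
        if partd_o == t:
            fired.append((4, "censored_partd_disenroll", t))
        if t == H:
            fired.append((5, "censored_admin", H))
        if fired:
            _, outcome, event_day = min(fired)
            duration = sum(1 for u in range(event_day) if (index_ord + u) in covered)
            return outcome, event_day, duration
    raise AssertionError("unreachable: the administrative boundary always fires")


def long_stay_oracle(stays, rules: EpisodeRules):
    """Day-walk the stay calendar from first entry."""
    if not stays:
        return None
    ordered = sorted(stays, key=lambda s: s.entry_date)
    first = ordered[0].entry_date.toordinal()
    last = max(s.exit_date.toordinal() for s in ordered)
    nh = out = 0
    for day in range(first, last):
        in_nh = any(s.entry_date.toordinal() <= day < s.exit_date.toordinal()
                    for s in ordered)
        if in_nh:
            nh += 1
        else:
            out += 1
        if out > rules.long_stay_max_outside:
            return None
        if in_nh and nh > rules.long_stay_min_days:
            return date.fromordinal(day)
    return None


# ---------------------------------------------------------------------------
# brute-force Cox partial likelihood
# ---------------------------------------------------------------------------

def cox_loglik_direct(beta, times, events, X, ties="breslow") -> float:
    """Breslow/Efron log partial likelihood written out with explicit loops."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    times = np.asarray(times)
    events = np.asarray(events)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    ll = 0.0
    for u in sorted(set(times[events == 1])):
        D = [i for i in range(len(times)) if times[i] == u and events[i]]
        R = [i for i in range(len(times)) if times[i] >= u]
        ll += sum(float(X[i] @ beta) for i in D)
        risk = [math.exp(float(X[j] @ beta)) for j in R]
        if ties == "breslow":
            ll -= len(D) * math.log(sum(risk))
        else:
            tied = sum(math.exp(float(X[i] @ beta)) for i in D)
            for k in range(len(D)):
                ll -= math.log(sum(risk) - k / len(D) * tied)
    return ll


def cox_mle_bruteforce(times, events, X, ties="breslow") -> np.ndarray:
    """Maximize the written-out partial likelihood with generic optimizers.

    One covariate: golden-section search on a wide bracket.  Two covariates:
    quasi-Newton with numerical gradients from several starts, polished by
    Nelder-Mead.  Independent of the analytic Newton-Raphson under test.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    p = X.shape[1]

    def neg(beta):
        return -cox_loglik_direct(beta, times, events, X, ties)

    if p == 1:
        res = optimize.minimize_scalar(lambda b: neg([b]), bounds=(-15.0, 15.0),
                                       method="bounded", options={"xatol": 1e-12})
        return np.array([res.x])
    best = None
    for x0 in (np.zeros(p), np.full(p, 0.5), np.full(p, -0.5)):
        r = optimize.minimize(neg, x0, method="BFGS",
                              options={"gtol": 1e-11, "maxiter": 500})
        r = optimize.minimize(neg, r.x, method="Nelder-Mead",
                              options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        if best is None or r.fun < best.fun:
            best = r
    return np.asarray(best.x)


# ---------------------------------------------------------------------------
# random inputs
# ---------------------------------------------------------------------------

def random_claims(rng: np.random.Generator, n_max: int = 12,
                  window_days: int = 2000) -> list[DispensingClaim]:
    """A random per-person claim set over a multi-year window."""
    n = int(rng.integers(1, n_max + 1))
    base = date(2010, 1, 1).toordinal()
    claims = []
    for _ in range(n):
        claims.append(DispensingClaim(
            person_id="p",
            dispense_date=date.fromordinal(base + int(rng.integers(0, window_days))),
            drug_code=f"AP{int(rng.integers(1, 4))}",
            days_supply=int(rng.integers(1, 95)),
        ))
    return claims


def random_toy_survival(rng: np.random.Generator, n: int, p: int):
    """A tiny untied survival dataset for oracle comparisons."""
    while True:
        times = rng.choice(np.arange(1, 40), size=n, replace=False)
        events = (rng.random(n) < 0.7).astype(int)
        X = np.round(rng.normal(0, 1, size=(n, p)), 2)
        if events.sum() >= 3 and len(set(times[events == 1])) >= 2:
            centered = X - X.mean(axis=0)
            if np.linalg.matrix_rank(centered) == p and np.abs(X).sum() > 0:
                return times, events, X
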