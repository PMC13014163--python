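"""Competing-risks estimation: cumulative incidence, restricted mean
on-treatment duration, and the cause-specific proportional-hazards model.

Discontinuation and death compete; discharge, disenrollment and the 180-day
boundary censor.  Estimators:

* :func:`estimate_cif` — the Aalen–Johansen estimator on an integer-day grid.
  At each event day the cause-specific hazard is events / at-risk and the
  cumulative incidence increment is the event-free survival just before the
  day times that hazard, so ``CIF_disc + CIF_death + S = 1`` holds exactly.
  When both causes occur on the same day, discontinuations are processed
  before deaths in the risk-set update (equivalent to a refined time grid,
  so additivity is preserved).
* :func:`restricted_mean_duration` — the exact step-function integral of the
  on-treatment survival over [0, tau]; with tau = 180 this is the expected
  number of days on drug within six months.
* :func:`fit_cox` / :func:`fit_discontinuation_model` — Cox partial
  likelihood for the cause-specific hazard, censoring competing events at
  their times.  Breslow tie handling by default (Efron behind a flag),
  Newton-Raphson with analytic gradient and Hessian, standard errors from
  the inverse observed information, Wald chi-square inference, and an
  optional cluster-robust sandwich variance for residents contributing
  several episodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CATEGORY_LEVELS
from .errors import ConvergenceError, RankDeficiencyError

log = logging.getLogger(__name__)

CAUSE_DISCONTINUED = 1
CAUSE_DIED = 2

#: Covariate specification mirroring the adjusted discontinuation model.
DEFAULT_COVARIATES = [
    "period", "quarters_after_first", "age", "comorbidity_score",
    "anxiety", "bipolar", "depression", "physical_aggression",
    "pct_black_cat", "pct_medicaid_cat", "ownership", "staffing_cat",
]

OUTCOME_TO_CAUSE = {"discontinued": CAUSE_DISCONTINUED, "died": CAUSE_DIED}


def status_from_outcomes(outcomes: Sequence[str]) -> np.ndarray:
    """Map outcome labels to status codes (0 censored, 1 discontinued, 2 died)."""
    return np.array([OUTCOME_TO_CAUSE.get(o, 0) for o in outcomes], dtype=int)


# ---------------------------------------------------------------------------
# Aalen-Johansen cumulative incidence
# ---------------------------------------------------------------------------

@dataclass
class CIFEstimate:
    """Cumulative incidence functions on the integer-day grid 0..tau.

    ``surv[t]``, ``cif_disc[t]`` and ``cif_death[t]`` are the values just
    after all events at day ``t`` are processed; the functions are step
    functions constant on [t, t+1).
    """

    grid: np.ndarray
    surv: np.ndarray
    cif_disc: np.ndarray
    cif_death: np.ndarray
    n_at_risk: np.ndarray
    n_subjects: int
    var_disc: np.ndarray | None = None
    var_death: np.ndarray | None = None

    def band(self, cause: int = CAUSE_DISCONTINUED, z: float = 1.959963984540054):
        """Pointwise plain-scale 95% band (clipped to [0, 1])."""
        cif = self.cif_disc if cause == CAUSE_DISCONTINUED else self.cif_death
        var = self.var_disc if cause == CAUSE_DISCONTINUED else self.var_death
        if var is None:
            raise ValueError("variance was not computed; pass compute_variance=True")
        half = z * np.sqrt(np.maximum(var, 0.0))
        return np.clip(cif - half, 0.0, 1.0), np.clip(cif + half, 0.0, 1.0)


def estimate_cif(time: Sequence[int], status: Sequence[int], tau: int = 180,
                 compute_variance: bool = False) -> CIFEstimate:
    """Aalen-Johansen estimator for discontinuation under competing death.

    ``time`` holds integer event/censoring days in 1..tau; ``status`` is 0
    for censored, 1 for discontinuation, 2 for death.  An all-censored
    sample is valid (both CIFs identically zero); an empty sample is not.
    """
    time = np.asarray(time, dtype=int)
    status = np.asarray(status, dtype=int)
    if time.size == 0:
        raise ValueError("estimate_cif requires a non-empty stratum")
    if time.min() < 1 or time.max() > tau:
        raise ValueError(f"event days must lie in 1..{tau}")
    if not np.isin(status, (0, 1, 2)).all():
        raise ValueError("status codes must be 0 (censored), 1 (discontinued) or 2 (died)")

    grid = np.arange(tau + 1)
    surv = np.ones(tau + 1)
    cif1 = np.zeros(tau + 1)
    cif2 = np.zeros(tau + 1)
    # at-risk counts just before each grid day
    n_at_risk = np.array([(time >= max(t, 1)).sum() for t in grid])

    # refined step list for the variance: (day, cause, d_events, n_at_risk, S_before)
    steps: list[tuple[int, int, int, int, float]] = []
    s = 1.0
    for t in np.unique(time):
        n = int((time >= t).sum())
        for cause, cif in ((CAUSE_DISCONTINUED, cif1), (CAUSE_DIED, cif2)):
            d = int(((time == t) & (status == cause)).sum())
            if d == 0:
                continue
            inc = s * d / n
            cif[t:] += inc
            steps.append((int(t), cause, d, n, s))
            s *= 1.0 - d / n
            n -= d
        surv[t:] = s

    # floating accumulation can overshoot the [0, 1] range by ~1e-16
    np.clip(cif1, 0.0, 1.0, out=cif1)
    np.clip(cif2, 0.0, 1.0, out=cif2)
    np.clip(surv, 0.0, 1.0, out=surv)

    var1 = var2 = None
    if compute_variance:
        var1 = _aalen_cif_variance(steps, cif1, CAUSE_DISCONTINUED, tau)
        var2 = _aalen_cif_variance(steps, cif2, CAUSE_DIED, tau)

    return CIFEstimate(grid=grid, surv=surv, cif_disc=cif1, cif_death=cif2,
                       n_at_risk=n_at_risk, n_subjects=int(time.size),
                       var_disc=var1, var_death=var2)


def _aalen_cif_variance(steps, cif_k: np.ndarray, cause: int, tau: int) -> np.ndarray:
    """Pointwise Aalen-type variance of one cumulative incidence function.

    Standard delta-method estimator over the (refined, tie-broken) step
    sequence; terms with a vanished risk set are set to zero by convention.
    """
    var = np.zeros(tau + 1)
    if not steps:
        return var
    days = np.array([s[0] for s in steps])
    causes = np.array([s[1] for s in steps])
    d_all = np.array([s[2] for s in steps], dtype=float)
    n_all = np.array([s[3] for s in steps], dtype=float)
    s_before = np.array([s[4] for s in steps])
    f_at_step = cif_k[days]  # CIF_k at the step's day (post-update)
    d_k = np.where(causes == cause, d_all, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        term_a_w = np.where(n_all > d_all, d_all / (n_all * (n_all - d_all)), 0.0)
    term_b = s_before ** 2 * np.where(n_all > 0, (n_all - d_k) / n_all * d_k / n_all ** 2, 0.0)
    term_c_w = s_before * np.where(n_all > 0, d_k / n_all ** 2, 0.0)

    for t in range(1, tau + 1):
        mask = days <= t
        if not mask.any():
            continue
        diff = cif_k[t] - f_at_step[mask]
        var[t] = (diff ** 2 * term_a_w[mask]).sum() + term_b[mask].sum() \
            - 2.0 * (diff * term_c_w[mask]).sum()
    return np.maximum(var, 0.0)


def restricted_mean_duration(cif: CIFEstimate, tau: int = 180) -> float:
    """Area under the on-treatment survival curve over [0, tau], in days."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if tau > len(cif.surv) - 1:
        raise ValueError(f"tau={tau} exceeds the estimated grid 0..{len(cif.surv) - 1}")
    return float(np.sum(cif.surv[:tau]))


def duration_summary(table: pd.DataFrame, tau: int = 180,
                     estimand: str = "on_treatment") -> pd.DataFrame:
    """Restricted mean on-treatment days within tau, by policy period.

    ``estimand="on_treatment"`` (default) integrates the event-free survival,
    treating both discontinuation and death as exits from treatment;
    ``estimand="net_of_discontinuation"`` integrates ``1 - CIF_disc``,
    counting days not yet discontinued regardless of vital status.
    """
    if estimand not in ("on_treatment", "net_of_discontinuation"):
        raise ValueError(f"unknown duration estimand {estimand!r}")
    rows = []
    for period in CATEGORY_LEVELS["period"]:
        sub = table[table["period"] == period]
        if sub.empty:
            continue
        status = sub["event"].to_numpy() * CAUSE_DISCONTINUED \
            + sub["competing"].to_numpy() * CAUSE_DIED
        cif = estimate_cif(sub["time"].to_numpy(), status, tau=tau)
        if estimand == "on_treatment":
            mean_days = restricted_mean_duration(cif, tau=tau)
        else:
            mean_days = float(np.sum(1.0 - cif.cif_disc[:tau]))
        rows.append({
            "period": period,
            "n_episodes": int(len(sub)),
            "mean_on_treatment_days": mean_days,
        })
    return pd.DataFrame(rows, columns=["period", "n_episodes", "mean_on_treatment_days"])


# ---------------------------------------------------------------------------
# Cause-specific Cox model
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted cause-specific proportional-hazards model."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n: int
    n_events: int
    tie_method: str
    robust: bool = False

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def wald_chi2(self) -> np.ndarray:
        return (self.coef / self.se) ** 2

    @property
    def p(self) -> np.ndarray:
        return stats.chi2.sf(self.wald_chi2, df=1)

    def ci(self, z: float = 1.96) -> tuple[np.ndarray, np.ndarray]:
        return np.exp(self.coef - z * self.se), np.exp(self.coef + z * self.se)

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci()
        return pd.DataFrame({
            "covariate": self.names,
            "coef": self.coef,
            "se": self.se,
            "chi_square": self.wald_chi2,
            "p_value": self.p,
            "hazard_ratio": self.hr,
            "hr_ci_low": lo,
            "hr_ci_high": hi,
        })


def _breslow_quantities(t, e, X, beta):
    """Log partial likelihood, score and information under Breslow ties.

    Rows must be sorted by ascending time; risk sets are suffixes.
    """
    n, p = X.shape
    eta = X @ beta
    shift = eta.max() if n else 0.0
    w = np.exp(eta - shift)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    s2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1], axis=0)[::-1]

    uniq, first = np.unique(t, return_index=True)
    inv = np.searchsorted(uniq, t)
    d = np.bincount(inv, weights=e, minlength=len(uniq))
    has_event = d > 0
    fi = first[has_event]
    du = d[has_event]

    ll = float(e @ eta - du @ (np.log(s0[fi]) + shift))
    rbar = s1[fi] / s0[fi, None]
    score = (e[:, None] * X).sum(axis=0) - (du[:, None] * rbar).sum(axis=0)
    info = np.einsum("u,uij->ij", du, s2[fi] / s0[fi, None, None]
                     - rbar[:, :, None] * rbar[:, None, :])
    return ll, score, info


def _efron_quantities(t, e, X, beta):
    """Log partial likelihood, score and information under Efron ties."""
    n, p = X.shape
    eta = X @ beta
    shift = eta.max() if n else 0.0
    w = np.exp(eta - shift)
    wx = w[:, None] * X
    wxx = w[:, None, None] * (X[:, :, None] * X[:, None, :])
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = float(e @ eta)
    score = (e[:, None] * X).sum(axis=0).astype(float)
    info = np.zeros((p, p))
    for u in np.unique(t):
        mask_t = t == u
        ev = mask_t & (e > 0)
        d = int(ev.sum())
        if d == 0:
            continue
        i0 = int(np.argmax(mask_t))
        w0, w1, w2 = w[ev].sum(), wx[ev].sum(axis=0), wxx[ev].sum(axis=0)
        for k in range(d):
            f = k / d
            a0 = s0[i0] - f * w0
            a1 = s1[i0] - f * w1
            a2 = s2[i0] - f * w2
            ll -= np.log(a0) + shift
            r = a1 / a0
            score -= r
            info += a2 / a0 - np.outer(r, r)
    return ll, score, info


def fit_cox(
    time: Sequence[int] | np.ndarray,
    event: Sequence[int] | np.ndarray,
    X: np.ndarray,
    names: Sequence[str] | None = None,
    tie_method: str = "breslow",
    cluster: Sequence | None = None,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    loglik_rtol: float = 1e-10,
) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton-Raphson.

    ``event`` is 1 for the cause of interest and 0 otherwise (competing
    events and censorings enter as censored at their times).  Convergence
    requires the maximum absolute score component below ``score_tol`` or the
    relative log-likelihood change below ``loglik_rtol``.  A coefficient
    diverging past +-20 is flagged as monotone likelihood (separation).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != t.size:
        raise ValueError("X rows must match the number of subjects")
    n, p = X.shape
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    if e.sum() < 2 or len(np.unique(t[e > 0])) < 2:
        raise ValueError("need at least 2 distinct event times to fit the model")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
        raise RankDeficiencyError(f"design matrix is rank deficient (columns: {names})")
    if tie_method not in ("breslow", "efron"):
        raise ValueError("tie_method must be 'breslow' or 'efron'")

    order = np.argsort(t, kind="mergesort")
    t, e, X = t[order], e[order], X[order]
    quantities = _breslow_quantities if tie_method == "breslow" else _efron_quantities

    beta = np.zeros(p)
    ll, score, info = quantities(t, e, X, beta)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "singular information matrix during Newton-Raphson",
                {"iteration": n_iter, "beta": beta.tolist()},
            ) from exc
        new_beta = beta + step
        new_ll, new_score, new_info = quantities(t, e, X, new_beta)
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            if halvings >= 20:
                break
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = quantities(t, e, X, new_beta)
            halvings += 1
        delta_ll = abs(new_ll - ll)
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if np.abs(beta).max() > 20.0:
            raise ConvergenceError(
                "diverging coefficient suggests monotone likelihood (separation)",
                {"iteration": n_iter, "beta": beta.tolist(), "names": names},
            )
        if np.abs(score).max() < score_tol or delta_ll < loglik_rtol * max(abs(ll), 1.0):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations",
            {"final_score_max": float(np.abs(score).max()), "beta": beta.tolist()},
        )

    cov = np.linalg.inv(info)
    robust = cluster is not None
    if robust:
        cl = np.asarray(cluster)[order]
        cov = _cluster_robust_cov(t, e, X, beta, cov, cl)
    se = np.sqrt(np.diag(cov))
    return CoxFit(names=names, coef=beta, se=se, cov=cov, loglik=ll,
                  n_iter=n_iter, converged=converged, n=n, n_events=int(e.sum()),
                  tie_method=tie_method, robust=robust)


def _cluster_robust_cov(t, e, X, beta, naive_cov, cluster) -> np.ndarray:
    """Sandwich variance from cluster-summed score residuals (Breslow weights)."""
    eta = X @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]

    uniq, first = np.unique(t, return_index=True)
    inv = np.searchsorted(uniq, t)
    d = np.bincount(inv, weights=e, minlength=len(uniq))
    rbar_u = s1[first] / s0[first, None]
    # cumulative hazard-type sums over event times u <= t_i
    a_u = np.cumsum(d / s0[first] * np.exp(-shift))
    b_u = np.cumsum((d / s0[first] ** 2)[:, None] * s1[first] * np.exp(-shift), axis=0)
    a_i = a_u[inv]
    b_i = b_u[inv]
    resid = e[:, None] * (X - rbar_u[inv]) - (w * np.exp(shift))[:, None] * (X * a_i[:, None] - b_i)

    groups = pd.Series(range(len(cluster))).groupby(np.asarray(cluster)).indices
    meat = np.zeros((X.shape[1], X.shape[1]))
    for idxs in groups.values():
        u = resid[idxs].sum(axis=0)
        meat += np.outer(u, u)
    return naive_cov @ meat @ naive_cov


# ---------------------------------------------------------------------------
# Design-matrix construction and the high-level model interface
# ---------------------------------------------------------------------------

def build_design_matrix(table: pd.DataFrame,
                        covariates: Sequence[str] = DEFAULT_COVARIATES
                        ) -> tuple[np.ndarray, list[str]]:
    """Expand a covariate list into a numeric design matrix.

    Categorical covariates (see :data:`appersist.cohort.CATEGORY_LEVELS`) are
    dummy-coded against their reference level (the first listed); numeric
    covariates enter as is.  Column names are ``name`` or ``name:level``.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov in CATEGORY_LEVELS:
            levels = CATEGORY_LEVELS[cov]
            values = table[cov].astype(str)
            unknown = set(values.unique()) - set(levels)
            if unknown:
                raise ValueError(f"unknown levels {sorted(unknown)} for covariate {cov}")
            for level in levels[1:]:
                cols.append((values == level).to_numpy(dtype=float))
                names.append(f"{cov}:{level}")
        else:
            cols.append(table[cov].to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(cols) if cols else np.empty((len(table), 0))
    return X, names


def fit_discontinuation_model(
    table: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    cause: str = "discontinued",
    tie_method: str = "breslow",
    cluster_col: str | None = None,
) -> CoxFit:
    """Cause-specific Cox model on an analysis table.

    ``cause`` selects the modelled event ("discontinued" or "died"); the
    other cause and all censorings are treated as censored at their times.
    """
    X, names = build_design_matrix(table, covariates)
    event = (table["outcome"] == cause).to_numpy(dtype=int)
    cluster = table[cluster_col].to_numpy() if cluster_col else None
    return fit_cox(table["time"].to_numpy(), event, X, names,
                   tie_method=tie_method, cluster=cluster)


@dataclass
class InteractionTest:
    """Wald tests for period-by-characteristic product terms."""

    characteristic: str
    term_names: list[str]
    term_p: np.ndarray
    joint_chi2: float
    joint_df: int
    joint_p: float
    fit: CoxFit
    dropped_terms: list[str] = field(default_factory=list)


def test_interactions(
    table: pd.DataFrame,
    base_covariates: Sequence[str],
    characteristic: str,
    cause: str = "discontinued",
    tie_method: str = "breslow",
) -> InteractionTest:
    """Refit with period x characteristic product terms and Wald-test them.

    Returns per-term Wald p-values and a joint Wald test across all product
    terms (alpha = 0.05, two-sided).  Product columns that are collinear
    with the base design are dropped with a warning; a characteristic that
    is constant raises :class:`RankDeficiencyError`.
    """
    covs = list(base_covariates)
    if characteristic not in covs:
        covs.append(characteristic)
    if "period" not in covs:
        covs.insert(0, "period")
    X, names = build_design_matrix(table, covs)

    period_cols = [i for i, nm in enumerate(names) if nm.startswith("period:")]
    if characteristic in CATEGORY_LEVELS:
        char_cols = [i for i, nm in enumerate(names) if nm.startswith(f"{characteristic}:")]
    else:
        char_cols = [names.index(characteristic)]
    if not char_cols or all(np.ptp(X[:, j]) == 0 for j in char_cols):
        raise RankDeficiencyError(
            f"characteristic {characteristic!r} is constant; interaction is not estimable"
        )

    prod_cols, prod_names, dropped = [], [], []
    for i in period_cols:
        for j in char_cols:
            col = X[:, i] * X[:, j]
            name = f"{names[i]}*{names[j]}"
            trial = np.column_stack([X] + prod_cols + [col])
            if np.linalg.matrix_rank(trial - trial.mean(axis=0)) < trial.shape[1]:
                dropped.append(name)
                warnings.warn(f"dropping rank-deficient interaction term {name}")
                continue
            prod_cols.append(col)
            prod_names.append(name)
    if not prod_cols:
        raise RankDeficiencyError(
            f"all period x {characteristic} product terms are collinear with the base design"
        )

    X_full = np.column_stack([X] + prod_cols)
    event = (table["outcome"] == cause).to_numpy(dtype=int)
    fit = fit_cox(table["time"].to_numpy(), event, X_full, names + prod_names,
                  tie_method=tie_method)

    k = len(prod_names)
    idx = np.arange(len(names), len(names) + k)
    beta_i = fit.coef[idx]
    cov_i = fit.cov[np.ix_(idx, idx)]
    joint_chi2 = float(beta_i @ np.linalg.solve(cov_i, beta_i))
    joint_p = float(stats.chi2.sf(joint_chi2, df=k))
    return InteractionTest(
        characteristic=characteristic,
        term_names=prod_names,
        term_p=fit.p[idx],
        joint_chi2=joint_chi2,
        joint_df=k,
        joint_p=joint_p,
        fit=fit,
        dropped_terms=dropped,
    )


def subgroup_fit(
    table: pd.DataFrame,
    subgroup_flag: str = "bipolar",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    cause: str = "discontinued",
    tie_method: str = "breslow",
) -> dict[bool, CoxFit]:
    """Fit the model separately within and outside a binary subgroup.

    The subgroup flag itself is removed from the covariate list (it is
    constant within each stratum).  Both strata must be non-empty and must
    contain events of the modelled cause.
    """
    covs = [c for c in covariates if c != subgroup_flag]
    fits: dict[bool, CoxFit] = {}
    for value in (True, False):
        sub = table[table[subgroup_flag].astype(bool) == value]
        if sub.empty:
            raise ValueError(f"subgroup {subgroup_flag}={value} is empty")
        if (sub["outcome"] == cause).sum() == 0:
            raise ValueError(f"subgroup {subgroup_flag}={value} has no {cause} events")
        fits[value] = fit_discontinuation_model(sub, covs, cause=cause, tie_method=tie_method)
    return fits
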