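"""End-to-end orchestration: simulate -> episodes -> cohort -> analyze.

Each stage reads and writes delimited tables so intermediate results are
inspectable, and a JSON manifest records seed, config hash, per-stage row
counts and every dropped record's reason.  Re-running with the same
configuration reproduces identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .cohort import CATEGORY_LEVELS, assemble_analysis_table
from .errors import AppersistError, ConfigError
from .exposure import EpisodeRules, classify_episode_end, build_availability, \
    find_new_use_episodes, DispensingClaim
from .simulate import SimulationConfig, generate_world, generate_dispensings
from .survival import (CAUSE_DIED, CAUSE_DISCONTINUED, DEFAULT_COVARIATES,
                       duration_summary, estimate_cif, fit_discontinuation_model,
                       subgroup_fit, test_interactions)

log = logging.getLogger(__name__)

INPUT_TABLES = ("dispensings", "residents", "stays", "enrollment", "deaths",
                "facility_years")


class StageError(AppersistError, RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs."""

    out_dir: Path
    synthetic: bool = True
    sim: SimulationConfig | None = None
    inputs: dict[str, Path] = field(default_factory=dict)
    rules: EpisodeRules = field(default_factory=EpisodeRules)
    study_start: date = date(2010, 1, 1)
    study_end: date = date(2017, 12, 31)
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    tie_method: str = "breslow"
    cluster_episodes_within_resident: bool = False
    duration_estimand: str = "on_treatment"
    run_interactions: bool = True
    run_subgroup: bool = True
    make_plot: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.synthetic:
            if self.sim is None:
                self.sim = SimulationConfig(seed=self.seed)
            self.sim.validate()
            self.study_start = self.sim.study_start
            self.study_end = self.sim.study_end
        else:
            missing = [t for t in INPUT_TABLES if t not in self.inputs]
            if missing:
                raise ConfigError(f"non-synthetic run is missing input paths for: {missing}")
            for t, p in self.inputs.items():
                if not Path(p).exists():
                    raise ConfigError(f"input table {t!r} not found at {p}")
        if self.tie_method not in ("breslow", "efron"):
            raise ConfigError("tie_method must be 'breslow' or 'efron'")
        if self.duration_estimand not in ("on_treatment", "net_of_discontinuation"):
            raise ConfigError("duration_estimand must be 'on_treatment' or "
                              "'net_of_discontinuation'")


def extract_episodes(
    dispensings: pd.DataFrame,
    stays: pd.DataFrame,
    deaths: pd.DataFrame,
    enrollment: pd.DataFrame,
    rules: EpisodeRules,
    study_start: date,
    study_end: date,
) -> pd.DataFrame:
    """Run the exposure engine over a dispensing table.

    New-use indexes are searched inside the window
    ``[study_start + washout, study_end - horizon]`` so that every episode
    has a fully observable washout and 180-day follow-up.  Per episode, the
    censoring dates are resolved from the person's stay containing the
    index (discharge), and the enrollment spans covering the index (FFS and
    Part D ends); span or stay ends at the data boundary are administrative,
    not censoring events.
    """
    window = (date.fromordinal(study_start.toordinal() + rules.washout_days),
              date.fromordinal(study_end.toordinal() - rules.horizon_days))
    death_by_person = dict(zip(deaths["person_id"], deaths["death_date"]))
    stays_by_person: dict[str, list] = {}
    for row in stays.itertuples(index=False):
        stays_by_person.setdefault(row.person_id, []).append(row)
    spans_by_person: dict[str, dict[str, list]] = {}
    for row in enrollment.itertuples(index=False):
        spans_by_person.setdefault(row.person_id, {}).setdefault(row.part, []).append(row)

    records = []
    for pid, group in dispensings.groupby("person_id", sort=True):
        claims = [DispensingClaim(pid, r.dispense_date, r.drug_code, int(r.days_supply))
                  for r in group.itertuples(index=False)]
        coverage = build_availability(claims)
        death = death_by_person.get(pid)
        for index_date in find_new_use_episodes(coverage, rules, window):
            discharge = None
            for st in stays_by_person.get(pid, []):
                if st.entry_date <= index_date < st.exit_date:
                    if st.exit_date <= study_end and (death is None or death >= st.exit_date):
                        discharge = st.exit_date
                    break
            ends = {}
            for part in ("AB", "D"):
                ends[part] = None
                for sp in spans_by_person.get(pid, {}).get(part, []):
                    if sp.start_date <= index_date < sp.end_date:
                        if sp.end_date <= study_end:
                            ends[part] = sp.end_date
                        break
            ep = classify_episode_end(
                coverage, index_date, rules,
                death_date=death if (death is None or death >= index_date) else None,
                discharge_date=discharge,
                ffs_end=ends["AB"], partd_end=ends["D"],
            )
            records.append({
                "person_id": pid, "index_date": index_date, "outcome": ep.outcome,
                "event_day": ep.event_day, "duration_days": ep.duration_days,
            })
    return pd.DataFrame(records, columns=["person_id", "index_date", "outcome",
                                          "event_day", "duration_days"])


def make_descriptive_tables(
    analysis: pd.DataFrame,
    residents: pd.DataFrame,
    facility_years: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Year-by-year cohort and facility summaries in tidy long format.

    Resident rows summarize the residents initiating an episode each year
    (demographics, clinical covariates); facility rows summarize the
    facilities contributing at least one episode (including the 1 / 2 / 3+
    residents-per-facility distribution).  Percent variables within a block
    share a ``pct:`` prefix and sum to 100 up to rounding.
    """
    res_rows: list[dict] = []
    fac_rows: list[dict] = []
    if analysis.empty:
        return {"residents_by_year": pd.DataFrame(columns=["year", "variable", "value"]),
                "facilities_by_year": pd.DataFrame(columns=["year", "variable", "value"])}

    tab = analysis.copy()
    tab["year"] = tab["index_date"].map(lambda d: d.year)
    res_cov = residents.set_index("person_id")
    fy = facility_years.set_index(["facility_id", "year"])

    def pct(rows, year, block, series):
        counts = series.value_counts()
        total = counts.sum()
        for level, c in sorted(counts.items()):
            rows.append({"year": year, "variable": f"pct:{block}:{level}",
                         "value": round(100.0 * c / total, 1)})

    for year, sub in tab.groupby("year"):
        first = sub.sort_values("index_date").drop_duplicates("person_id")
        people = res_cov.loc[first["person_id"]]
        res_rows.append({"year": year, "variable": "n_residents", "value": len(first)})
        res_rows.append({"year": year, "variable": "age_mean",
                         "value": round(float(first["age"].mean()), 1)})
        res_rows.append({"year": year, "variable": "age_sd",
                         "value": round(float(first["age"].std(ddof=1)), 1) if len(first) > 1 else 0.0})
        pct(res_rows, year, "sex", people["sex"])
        pct(res_rows, year, "race", people["race"])
        pct(res_rows, year, "region", people["region"])
        for flag in ("dual_eligible", "anxiety", "depression", "bipolar",
                     "physical_aggression", "verbal_aggression"):
            res_rows.append({"year": year, "variable": f"share:{flag}",
                             "value": round(100.0 * float(people[flag].mean()), 1)})
        for num, label in (("comorbidity_score", "comorbidity"), ("adl_score", "adl")):
            res_rows.append({"year": year, "variable": f"{label}_mean",
                             "value": round(float(people[num].mean()), 1)})
            res_rows.append({"year": year, "variable": f"{label}_sd",
                             "value": round(float(people[num].std(ddof=1)), 1) if len(people) > 1 else 0.0})

        per_fac = sub.groupby("facility_id")["person_id"].nunique()
        fac_rows.append({"year": year, "variable": "n_facilities", "value": len(per_fac)})
        binned = per_fac.map(lambda k: "1" if k == 1 else ("2" if k == 2 else "3+"))
        pct(fac_rows, year, "residents_per_facility", binned)
        keys = [(f, year) for f in per_fac.index if (f, year) in fy.index]
        if keys:
            chars = fy.loc[keys]
            for num in ("pct_black", "pct_medicaid", "staffing_hours_per_resident_day", "beds"):
                fac_rows.append({"year": year, "variable": f"{num}_mean",
                                 "value": round(float(chars[num].mean()), 1)})
                fac_rows.append({"year": year, "variable": f"{num}_sd",
                                 "value": round(float(chars[num].std(ddof=1)), 1) if len(chars) > 1 else 0.0})
            fac_rows.append({"year": year, "variable": "share:nonprofit_or_government",
                             "value": round(100.0 * float(
                                 (chars["ownership"] == "nonprofit_or_government").mean()), 1)})
            fac_rows.append({"year": year, "variable": "share:urban",
                             "value": round(100.0 * float(chars["urban"].astype(bool).mean()), 1)})
            staff_cat = chars["staffing_hours_per_resident_day"].map(
                lambda h: "low" if h < 3.0 else ("mid" if h <= 4.1 else "high"))
            pct(fac_rows, year, "staffing_cat", staff_cat)
    return {
        "residents_by_year": pd.DataFrame(res_rows, columns=["year", "variable", "value"]),
        "facilities_by_year": pd.DataFrame(fac_rows, columns=["year", "variable", "value"]),
    }


def plot_cif(curves: pd.DataFrame, path: Path) -> None:
    """Cumulative-incidence-of-discontinuation figure, one line per period."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = {"pre_partnership": "tab:blue", "post_partnership": "tab:red",
              "post_five_star": "tab:green"}
    for period, sub in curves.groupby("period"):
        ax.step(sub["day"], sub["cif_disc"], where="post",
                label=period, color=colors.get(period))
    ax.set_xlabel("Days since antipsychotic initiation")
    ax.set_ylabel("Cumulative incidence of discontinuation")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write all outputs, and return the run manifest."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    cfg_dict.pop("out_dir", None)  # the hash identifies the run, not its location
    manifest: dict = {
        "seed": int(config.seed),
        "config_hash": tio.config_hash(cfg_dict),
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:  # halt with the stage name and cause
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
                raise StageError(name, exc) from exc
            return result
        return wrap

    # ---- stage: simulate or load -----------------------------------------
    if config.synthetic:
        def _simulate():
            world = generate_world(config.sim)
            dispensings = generate_dispensings(config.sim, world)
            tables = dict(world.tables)
            tables["dispensings"] = dispensings
            for name, df in tables.items():
                tio.write_table(df, out / f"{name}.tsv")
            manifest["stages"]["simulate"] = {
                "status": "ok", **{f"n_{k}": int(len(v)) for k, v in tables.items()}}
            return tables
        tables = stage("simulate")(_simulate)
    else:
        def _load():
            tables = {name: tio.read_table(config.inputs[name], kind=name)
                      for name in INPUT_TABLES}
            manifest["stages"]["load"] = {
                "status": "ok", **{f"n_{k}": int(len(v)) for k, v in tables.items()}}
            return tables
        tables = stage("load")(_load)

    # ---- stage: episodes --------------------------------------------------
    def _episodes():
        eps = extract_episodes(tables["dispensings"], tables["stays"], tables["deaths"],
                               tables["enrollment"], config.rules,
                               config.study_start, config.study_end)
        tio.write_table(eps, out / "episodes.tsv")
        counts = eps["outcome"].value_counts().to_dict()
        manifest["stages"]["episodes"] = {
            "status": "ok", "n_episodes": int(len(eps)),
            "outcomes": {k: int(v) for k, v in sorted(counts.items())}}
        return eps
    episodes = stage("episodes")(_episodes)

    # ---- stage: cohort ----------------------------------------------------
    def _cohort():
        table, drops = assemble_analysis_table(
            episodes, tables["residents"], tables["stays"], tables["facility_years"],
            tables["enrollment"], config.rules, config.study_start, config.study_end)
        tio.write_table(table, out / "analysis.tsv")
        manifest["stages"]["cohort"] = {
            "status": "ok", "episodes_in": int(len(episodes)),
            "eligible": int(len(table)),
            "dropped": {k: int(v) for k, v in sorted(drops.items())},
            "n_dropped": int(sum(drops.values()))}
        return table
    analysis = stage("cohort")(_cohort)

    # ---- stage: analyze ---------------------------------------------------
    def _analyze():
        info: dict = {"status": "ok"}
        curves_rows = []
        for period in CATEGORY_LEVELS["period"]:
            sub = analysis[analysis["period"] == period]
            if sub.empty:
                continue
            status = sub["event"].to_numpy() * CAUSE_DISCONTINUED \
                + sub["competing"].to_numpy() * CAUSE_DIED
            cif = estimate_cif(sub["time"].to_numpy(), status,
                               tau=config.rules.horizon_days, compute_variance=True)
            curves_rows.append(pd.DataFrame({
                "period": period, "day": cif.grid, "surv": cif.surv,
                "cif_disc": cif.cif_disc, "cif_death": cif.cif_death,
                "var_disc": cif.var_disc, "n_at_risk": cif.n_at_risk}))
        curves = pd.concat(curves_rows, ignore_index=True) if curves_rows else \
            pd.DataFrame(columns=["period", "day", "surv", "cif_disc", "cif_death",
                                  "var_disc", "n_at_risk"])
        tio.write_table(curves, out / "cif_curves.tsv")

        durations = duration_summary(analysis, tau=config.rules.horizon_days,
                                     estimand=config.duration_estimand)
        tio.write_table(durations, out / "duration_summary.tsv")

        fit = fit_discontinuation_model(
            analysis, config.covariates, tie_method=config.tie_method,
            cluster_col="person_id" if config.cluster_episodes_within_resident else None)
        summary = fit.summary()
        tio.write_table(summary, out / "model_summary.tsv")
        (out / "model_summary.json").write_text(json.dumps({
            "loglik": fit.loglik, "n": fit.n, "n_events": fit.n_events,
            "n_iter": fit.n_iter, "tie_method": fit.tie_method,
            "robust": fit.robust,
            "coefficients": summary.to_dict("records")}, indent=2, sort_keys=True))
        info["n_model_rows"] = fit.n
        info["n_discontinuations"] = fit.n_events

        if config.run_interactions:
            inter_rows = []
            for char in ("pct_black_cat", "pct_medicaid_cat", "ownership", "staffing_cat"):
                try:
                    res = test_interactions(analysis, config.covariates, char,
                                            tie_method=config.tie_method)
                    inter_rows.append({"characteristic": char,
                                       "joint_chi2": res.joint_chi2,
                                       "joint_df": res.joint_df,
                                       "joint_p": res.joint_p})
                except AppersistError as exc:
                    inter_rows.append({"characteristic": char, "joint_chi2": np.nan,
                                       "joint_df": 0, "joint_p": np.nan})
                    log.warning("interaction test for %s skipped: %s", char, exc)
            tio.write_table(pd.DataFrame(inter_rows), out / "interaction_tests.tsv")

        if config.run_subgroup:
            try:
                fits = subgroup_fit(analysis, "bipolar", config.covariates,
                                    tie_method=config.tie_method)
                sub_rows = []
                for flag, f in fits.items():
                    s = f.summary()
                    s.insert(0, "bipolar", int(flag))
                    s.insert(1, "n_episodes", f.n)
                    sub_rows.append(s)
                tio.write_table(pd.concat(sub_rows, ignore_index=True),
                                out / "subgroup_bipolar.tsv")
            except (AppersistError, ValueError) as exc:
                log.warning("bipolar subgroup analysis skipped: %s", exc)
                info["subgroup_skipped"] = str(exc)

        if config.make_plot and not curves.empty:
            plot_cif(curves, out / "cif_by_period.png")

        descr = make_descriptive_tables(analysis, tables["residents"],
                                        tables["facility_years"])
        tio.write_table(descr["residents_by_year"], out / "table1_residents_by_year.tsv")
        tio.write_table(descr["facilities_by_year"], out / "table2_facilities_by_year.tsv")
        manifest["stages"]["analyze"] = info
        return durations
    stage("analyze")(_analyze)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
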