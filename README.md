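# appersist

Antipsychotic (AP) treatment **persistence and discontinuation analysis** for
nursing-home pharmacy claims.

Federal initiatives — the 2012 CMS National Partnership to Improve Dementia
Care and the 2015 inclusion of AP measures in the Nursing Home Five Star
Rating System — targeted how *many* long-stay residents with dementia receive
antipsychotics. Whether they also shortened how *long* new users stay on the
drug is a question about treatment duration, which requires rebuilding
exposure episodes from dispensing claims and estimating time-to-discontinuation
under the competing risk of death. `appersist` implements that pipeline for
pharmacoepidemiologists, and ships a synthetic claims generator with known
ground-truth hazards so every stage can be validated without access to
restricted Medicare data.

## What it computes

1. **Daily drug availability** from Part-D-style fills. A fill on day *d*
   with days supply *s* covers days *d..d+s−1*; overlapping refills of the
   same drug stockpile (the remainder carries forward); a fill of a
   *different* AP restarts the supply from the switch date.
2. **New-use episodes**: a fill preceded by ≥ 90 days with no AP on hand
   starts an episode; residents may contribute several.
3. **Episode outcomes** within a 180-day horizon: *discontinuation* when an
   uncovered run reaches 30 days (dated at the first uncovered day, so the
   event day equals the days of follow-up with drug in hand); *death* as the
   competing event; censoring at nursing-home discharge, fee-for-service or
   Part D disenrollment, or day 180.
4. **Cohort construction**: long-stay qualification (> 100 nursing-home days
   with ≤ 10 days outside), age ≥ 65 at admission, dementia before index,
   exclusionary diagnoses, continuous Parts A/B/D enrollment, policy-period
   assignment (through 2012-03 / 2012-04–2014-12 / from 2015-01), and
   facility covariates at the standard cutpoints (percent Black residents
   < 5 / 5–15 / > 15; percent Medicaid ≤ 62.5 / > 62.5; summed nurse staffing
   < 3 / 3–4.1 / > 4.1 h per resident-day).
5. **Competing-risks estimation.** With cause-specific hazards
   λ_k(t), the Aalen–Johansen estimator gives cumulative incidences
   F̂_k(t) = Σ_{t_j ≤ t} Ŝ(t_j−) d_kj / n_j with
   F̂_disc + F̂_death + Ŝ = 1 exactly; mean on-treatment days within τ = 180
   is the step integral ∫₀^τ Ŝ(t) dt; and the cause-specific Cox model
   λ_disc(t | x) = λ₀(t) exp(x'β) is fit by Newton–Raphson on the partial
   likelihood (Breslow ties by default, Efron optional), with Wald
   chi-square inference, period × facility interaction tests, and subgroup
   fits (e.g. bipolar disorder).

## Worked example

```bash
cat > demo.cfg <<EOF
seed = 20
n_residents = 12000
n_facilities = 200
EOF
appersist run-all --config demo.cfg --out demo_out
```

prints

```
pipeline complete; manifest at demo_out/manifest.json (7188 eligible episodes)
```

The simulated world yields 8 411 new-use episodes, of which 7 188 survive
eligibility (the manifest itemizes every drop: 420 exclusionary diagnoses,
305 Medicare Advantage, 308 enrollment gaps, 165 initiations before
long-stay qualification, 25 under-65 admissions). `duration_summary.tsv`
shows the mean on-treatment days within 180 by policy period:

```
period           n_episodes  mean_on_treatment_days
pre_partnership        1750               126.8
post_partnership       2930               123.4
post_five_star         2508               121.2
```

i.e. roughly five days less time on drug after the policy changes — the
generator's defaults place true per-period means near 126/121/120 days.
`model_summary.tsv` holds the adjusted cause-specific model; at this sample
size the post-Partnership hazard ratio for discontinuation is estimated at
1.16 (95% CI 0.98–1.36) against a configured truth of 1.17. The parameter-
recovery test in `tests/test_acceptance.py` repeats this experiment over
100 replicates of ~20 000 episodes and checks bias (< 2%) and 95% CI
coverage.

Other outputs in `demo_out/`: `cif_curves.tsv` (per-period cumulative
incidence of discontinuation and death with pointwise variance, plus the
figure `cif_by_period.png`), `interaction_tests.tsv`,
`subgroup_bipolar.tsv`, and Table-1/2-style descriptives by initiation year.

As a library:

```python
from appersist import (DispensingClaim, EpisodeRules, build_availability,
                       classify_episode_end, find_new_use_episodes)
from datetime import date

rules = EpisodeRules()                  # washout 90, gap 30, horizon 180
fills = [DispensingClaim("r1", date(2011, 6, 1), "AP01", 30),
         DispensingClaim("r1", date(2011, 7, 1), "AP01", 15)]
cov = build_availability(fills)         # one interval: 45 covered days
index = find_new_use_episodes(cov, rules)[0]
episode = classify_episode_end(cov, index, rules)
print(episode.outcome, episode.event_day, episode.duration_days)
# discontinued 45 45
```

## Layout

- `src/appersist/exposure.py` — interval algebra, washout, gap rule
- `src/appersist/cohort.py` — eligibility, periods, covariate categories
- `src/appersist/survival.py` — Aalen–Johansen, restricted means, Cox
- `src/appersist/simulate.py` — synthetic world with known hazards
- `src/appersist/pipeline.py`, `cli.py` — orchestration, manifest, CLI
- `docs/methods.md` — modelling assumptions and design choices
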