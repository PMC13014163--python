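# Methods

This note records the models, conventions and design choices behind
`appersist`, in the order data flows through the pipeline. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Exposure construction

**Day convention.** Time is discrete in whole days, matching days-supply
granularity. A fill on day *d* with supply *s* covers the closed run
*d..d+s−1*. Coverage intervals are merged when overlapping or adjacent.

**Stockpiling and restart.** A refill of the *same* drug while supply
remains extends coverage by the full new supply (the remainder carries
forward). A fill of a *different* antipsychotic while supply remains
replaces it: coverage from the switch date runs exactly the new fill's days
supply. A consequence worth noting: total covered days are monotone in the
claim stream only within one drug — a switch fill can *shorten* coverage by
discarding a large remainder, and the property tests assert exactly that.
All AP drug codes form a single exposure class for washout and gap
purposes; concurrent APs are not modelled as separate exposures.

**New use.** An interval start is an episode index when the 90 days
immediately before it are fully uncovered (the first-ever interval
qualifies trivially; callers restrict the eligibility window so that at
least 90 days of data precede any index — the pipeline uses
`[study_start + 90, study_end − 180]`, which also guarantees a fully
observable 180-day follow-up).

**Episode classification.** Candidate terminating events carry a *decision
day*: a gap decides on its 30th uncovered day but is *dated* at its first
uncovered day, so the event day equals days of follow-up with drug on hand
(a 45-day run followed by a 31-day gap is a discontinuation at day 45 with
45 days of exposure; a 29-day stop resumed on day 30 of the gap leaves an
ongoing user). Death, discharge, and disenrollments decide at their own
days; the administrative boundary decides at day 180. The earliest decision
wins; same-day ties resolve discontinuation > death > discharge > FFS
disenrollment > Part D disenrollment > administrative. Hence a death during
a gap that has not yet reached 30 days is a death — the discontinuation was
never confirmed — and a gap starting after day 150 cannot qualify within
follow-up, yielding administrative censoring. Events dated on the index day
are counted at day 1, the minimum event day (the index day itself is
covered by construction). Same-drug refills that do not literally overlap
existing coverage start new intervals; only the 30-day rule decides whether
the intervening gap ends the episode.

## Cohort

**Long-stay qualification** scans calendar days from first nursing-home
entry: the qualification date is the first day on which cumulative NH days
exceed 100 while cumulative days outside (hospital days included) remain at
most 10. Stays are half-open `[entry, exit)`. Long-stay status must be
attained strictly before the episode index.

**Eligibility** additionally requires age ≥ 65 at first admission, dementia
onset on or before the index, no exclusionary diagnosis (Huntington's,
schizophrenia, Tourette), no Medicare Advantage enrollment, and continuous
Parts A/B and D enrollment over `[index − 90, index]`. Disenrollment *after*
the index is not an exclusion; it censors the episode. Every failed
criterion is reported by reason code, and the pipeline manifest conserves
counts (episodes in = eligible + dropped).

**Policy periods** are assigned by index date: through 2012-03-31
(pre-Partnership), 2012-04-01..2014-12-31 (post-Partnership), from
2015-01-01 (post-Five-Star). `quarters_after_first` counts whole calendar
quarters from the study window's first quarter — a global secular-trend
clock rather than a within-period one, the simpler of the two defensible
readings.

**Facility covariates** come from the facility-year record of the index
year; resident clinical covariates from the resident record supplied for
the cohort (one record per resident in the synthetic world). Missing
required covariates drop the episode with a logged count (complete-case).

## Estimation

**Aalen–Johansen.** At each event day, the cause-specific hazard is
events/at-risk and the CIF increment is Ŝ(t−) times that hazard. When both
causes occur on the same day, discontinuations are processed before deaths
in the risk-set update — equivalent to refining the time grid — so the
identity CIF_disc + CIF_death + S = 1 holds to machine precision (asserted
at 1e−10). The optional pointwise variance is the standard Aalen/delta-method
estimator evaluated over the refined step sequence; in the no-censoring,
no-competing-risk special case it tracks the binomial variance of the
sample proportion, which the tests check.

**Restricted mean duration.** The estimand is expected days on treatment
within τ = 180: the exact step integral of the event-free ("on-treatment")
survival, treating both discontinuation and death as exits and censoring as
non-informative. The alternative reading — integrating 1 − CIF_disc, which
counts days not yet discontinued regardless of vital status — is available
via `duration_summary(..., estimand="net_of_discontinuation")`; it is never
smaller. With no censoring and no competing deaths the estimator reduces
exactly to the sample mean of min(T, τ).

**Cause-specific Cox model.** Competing deaths and censorings enter as
censored at their times. Breslow tie handling is the default (the
historical default of the mainframe statistical stacks these analyses were
run on); Efron is available behind `tie_method="efron"` and is
cross-checked against lifelines. Newton–Raphson uses the analytic gradient
and observed information with step-halving; convergence requires max |score|
< 1e−8 or relative log-likelihood change < 1e−10 (50 iterations maximum).
Standard errors come from the inverse observed information; hazard ratios
and 95% CIs are Wald on the log scale at 1.96; Wald chi-square = (β̂/SE)².
A coefficient passing |β| > 20 aborts with a monotone-likelihood
(separation) diagnosis; a rank-deficient design is rejected up front.
Multiple episodes per resident are treated as independent rows with naive
SEs by default, matching the analysis convention for this design; a
cluster-robust sandwich variance (score residuals summed within resident)
is available via `cluster_col`. Interaction tests refit with period ×
characteristic product terms and report per-term and joint Wald tests at
α = 0.05 two-sided, dropping collinear products with a warning.

## Synthetic data generator

The generator emulates the data sources of a claims-based nursing-home
study: facility-years (percent Black residents drawn from a three-stratum
mixture averaging ≈ 12%, percent Medicaid ≈ N(62.5, 18), 28% nonprofit,
staffing ≈ N(3.55, 0.7) h/day), residents (age at entry ≈ N(85, 7.3)
truncated at 62 so a few admissions fail the 65+ rule, 73% female,
psychiatric comorbidity flags at their configured prevalences, 4% Medicare
Advantage, 5% exclusionary diagnoses), stays (6% with a 2–14-day hospital
interruption, exercising the days-outside rule), enrollment spans, and
deaths. All event processes are daily Bernoulli hazards; with the seed
fixed, every output table is byte-identical across runs.

**Episode process.** After long-stay qualification a resident initiates
with a daily hazard (default 0.01/day); the episode's latent
discontinuation day is geometric with hazard
`baseline × period multiplier × exp(covariate effects)`, with the period
multiplier fixed by the *index* date. Fills follow the configured
days-supply distribution (28/30/60/90 days, mostly 30) with refill-delay
jitter (−3..+3 days; early refills exercise stockpiling), and the final
fill is truncated so drug-on-hand ends exactly on the latent stop day.
Short final fills are common in nursing-home pharmacy cycles, and this
choice makes the latent time identifiable through the 30-day gap rule:
parameter-recovery experiments then measure estimator error, not
supply-grid rounding. One drug code is used per episode (a mid-episode
switch with an early refill would truncate coverage through the restart
rule and break identifiability); the restart rule is exercised directly by
the exposure-engine tests. 12% of completed episodes are followed by a
fresh initiation after a new 90-day washout (so ~1.4% of residents reach a
third episode), and 2% of residents initiate before qualifying as
long-stay, feeding the cohort builder's exclusion paths.

Defaults were chosen so the *true* per-period restricted means sit on the
reported 120–126-day scale: baseline discontinuation hazard 0.0037/day,
period multipliers (1.17, 1.19), death 0.001/day, discharge 0.0008/day,
disenrollment 0.0002/day per part, anxiety and bipolar log-HRs −0.152 and
−0.156. `ground_truth()` returns the exact implied quantities: period and
covariate log-HRs, and per-period restricted means computed by enumerating
covariate profiles and summing the discrete survival
Σ_t Π(1 − h)ᵗ — cross-checked in tests against high-n Monte Carlo and, for
constant hazards, against the geometric closed form
(1 − qᵀ)/(1 − q), which approaches (1 − e^{−λT})/λ for small hazards.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: realistic NDC/ICD vocabularies, dose and
gradual dose reduction, PRN versus scheduled dispensing, seasonal or
facility-level prescribing trends beyond the period multipliers,
within-facility correlation of outcomes, informative censoring (discharge
and disenrollment are independent of the discontinuation process by
construction), and measurement error in days supply. The identity between
the claims path and the latent episode table (tested exactly) shows the
*engine* is faithful; it cannot show that real claims satisfy the
generator's assumptions.

**A measurement property worth knowing.** The gap rule is a coarse
instrument near boundaries: a latent stop whose 30-day confirmation window
is interrupted by death or censoring is recorded as that competing event,
and a stop after day 150 cannot be confirmed within follow-up. These are
properties of the estimand itself (shared by any study using the rule).
They attenuate absolute discontinuation rates slightly but cancel in
period hazard *ratios*, which is what the recovery experiments verify
(mean HR bias below 2%, CI coverage within [0.90, 0.99] at ~20 000 episodes
per replicate).

## Problem sizes in the tests

Unit tests run worlds of a few hundred residents; the recovery experiment
uses 100 replicates of ~29 000 residents (~20 500 episodes each); the
closed-form restricted-mean check draws 50 000 exit times; the interval
algebra is compared to the day-by-day oracle on 500 random claim sets over
a 2000-day window. The full suite completes in a few minutes on one CPU.

## Known limitations

- The Residential History File construction, ICD-based phenotyping, and
  comorbidity scoring are out of scope: stays, diagnosis flags and scores
  are inputs.
- Fine–Gray subdistribution modelling, frailty terms, time-varying
  covariates and penalized fits are not implemented.
- The CIF variance is pointwise (no simultaneous bands), and the
  cluster-robust variance option is first-order (no small-sample
  correction).
- `quarters_after_first` and the duration estimand each have one documented
  alternative reading; both are switchable but the defaults above are what
  the pipeline reports.
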