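# Methods

This note documents the model implemented in `wardsim`: its assumptions,
the parameters that matter, how the synthetic data generator is built and
calibrated, the numerical and design choices made where the design was
genuinely open, and the limits of what the simulation can show.

## 1. Scope and structure

The package simulates inpatient nursing units ("wards") that move between
understaffed, adequately staffed and overstaffed states as stochastic
demand for care meets stochastic staff supply, under three baseline roster
plans and four temporary-staff availability scenarios, and then evaluates
the staffing cost and mortality consequences of each plan. Units are the
agents; days are sampled independently (no serial correlation, no
patient-level admission/discharge trajectories); each day has three
shifts (early, late, night).

Pipeline: `synthetic_hospital` (units, scenarios) → `demand_model`
(required hours) → `roster_planner` (baseline headcounts) →
`shift_engine` (absence, floating, hiring, achieved hours) → `economics`
(costs, exposure, deaths, cost per life saved) → `experiments`/`cli`
(grids and reports).

## 2. Synthetic hospital generator

No unit-level hospital data ships with the package; the generator
replaces it with a synthetic system whose statistical structure matches
what year-long acuity/dependency audits of general medical/surgical units
show.

Defaults (all in `GeneratorConfig`):

| parameter | default | meaning |
|---|---|---|
| hospitals × units | 3 × 27 | 81 units total |
| specialty groups | 3 per hospital (9 units each) | float-pool boundaries |
| beds | uniform 22–30 | ward size |
| occupancy | Normal(0.88, 0.05), clipped [0.65, 0.97] | census = Binomial(beds, occupancy) |
| base acuity mix | (0.36, 0.27, 0.18, 0.12, 0.07) over levels 0/1a/1b/2/3 | per-unit Dirichlet around this |
| care hours per level | 3.0 / 4.5 / 5.5 / 9.0 / 14.0 h/patient/day | illustrative, configurable |
| specialing rate | uniform 0–0.4 patients/day, 24 h each | 1:1 care demand |
| RN skill mix | Normal(0.51, 0.05), clipped [0.35, 0.70] | share of hours assigned to RNs |
| shift weights | Dirichlet around (0.40, 0.35, 0.25) | early/late/night split |

The binomial census keeps census ≤ beds by construction and is
under-dispersed relative to Poisson, as a sum of bed-occupancy indicators
should be. Mean census ≈ 22.7 per unit-day, so a default year produces
≈ 678k patient days over 29,565 unit days.

### Demand-shape calibration

The calibration targets are cross-unit distributional shape statistics of
daily required hours: median per-unit sample skewness ≈ 0.6 with ~16% of
units above 1, and median excess kurtosis ≈ 0.7.

Mechanism. Each unit draws a skewness target from
LogNormal(ln 0.6, 0.514) across units (median 0.6; ~16% above 1). The
day-to-day control is a mean-one acuity factor g applied to the unit's
care-level mix: target per-patient hours μ = clip(h̄·g, h_lo, h_hi),
where h̄ is the base-mix per-patient hours, h_lo the all-level-0 floor
and h_hi a high-acuity anchor mix (0, 0, 0, 0.25, 0.75 → 11.75 h). The
day's level proportions interpolate between the base mix and the
appropriate anchor so that the multinomial census split has expectation
μ per patient.

The factor g = exp(σZ)/E[exp(σZ)] uses a log-normal bulk — σ set by
inverting the log-normal skewness function at the unit's target — plus a
symmetric scale mixture: with probability 0.028 a day is a
"high-variability day" and Z is widened 3.5×. The mixture exists because
the care-level mix is bounded above by the anchor, which truncates
exactly the tail mass that carries fourth-moment weight: a pure
log-normal factor can reach the skewness target but plateaus well short
of the kurtosis target. Rare symmetric wide days restore the tail weight
while adding little additional asymmetry.

One global constant (`SHAPE_INFLATION` = 0.455) rescales the per-unit σ to
account for everything else that contributes shape — census noise,
multinomial sampling of the level mix, Poisson specialing jumps, the
anchor clip and the mixture itself. It was fixed once against the default
configuration (81 units × 365 days, independent replicate seeds) so that
the population means of the two medians sit at ≈ 0.61 (skewness) and
≈ 0.70 (excess kurtosis), with ~13–15% of units above skewness 1.
Single-replicate medians scatter with sd ≈ 0.03 (skewness) and ≈ 0.11
(kurtosis); the acceptance script therefore averages 40 replicate seeds.

What the generator does **not** emulate: seasonal or serially correlated
demand, admission/discharge dynamics within a day, unit closures or bed
reconfigurations, correlated demand across units (outbreaks), or any real
hospital's absolute levels. Passing tests show the pipeline behaves
correctly under realistically-shaped stochastic demand; they say nothing
about any specific hospital's numbers.

### Availability scenarios

Bank/agency request-fulfilment probabilities by (source, role, shift,
weekday). Presets: `none` (all 0), `limited` (a packaged synthetic table,
0.15–0.40, higher on weekday early shifts, lower at night and on
weekends, bank above agency, assistants above RNs — an emulation of
empirically observed availability, all entries < 0.5), `higher` (0.5
everywhere) and `unlimited` (bank 0.5, agency 1.0). The packaged
`limited` table is a constructed fixture, not observed data.

## 3. Rosters

The establishment statistic is computed on the 20 daily totals of a
dedicated per-unit sample stream (disjoint from simulation demand), then
split by role and shift: flexible = 0.8 × mean, standard = mean,
resilient = 90th percentile by the nearest-rank method
(⌈0.9 n⌉-th order statistic — reproducible and conservative at n = 20).
Headcounts are rounded to the nearest 0.5 person, ties up, so rosters
share the half-shift currency of floats and hires; rounding error per
shift-role is at most a quarter shift. WTE establishment reporting
inverts daily worked hours through contracted weekly hours and an uplift
fraction; uplift never enters bedside demand.

## 4. Shift engine

Per unit-shift-role: absence is binomial over the 2 × headcount
half-person slots (RN 3%, NA 4%), reconciling fractional rosters with
whole-person sickness. Status: understaffed iff
(required − available)/required > 0.15; overstaffed iff available >
required; adequate otherwise; zero demand is never understaffed.

Fill rules (role-matched, half-shift blocks):

1. **Floating** within the specialty group: recipients in descending
   shortfall order, donors in descending current whole-block surplus,
   ties by position; donors never drop below their own requirement.
2. **Bank**, then **agency**: the residual gap is covered by
   ⌈gap/block⌉ requested blocks; each block fills with the scenario's
   bank probability, declined blocks go once to the agency. No retries.

**Fill target.** Triggered units are filled back up to the tolerance
boundary, (1 − 0.15) × required, not to the full requirement (the final
block may overshoot the boundary). This is a deliberate design choice:
the tolerance defines the band of adequate staffing, so a ward requests
cover for the part of the shortfall that lies outside the band. The
alternative — filling to the full requirement — makes a low-baseline
plan with certain agency fulfilment effectively demand-matched on the
majority of shifts it triggers, producing the paradox that the cheapest
roster buys the best outcomes at high availability; boundary-filling
preserves the characteristic trade-off (lower baselines are cheaper and
worse, less so as availability rises) that the whole evaluation is
designed to study, and matches the observed "trigger effect" whereby
moderate shortfalls persist.

**Common random numbers.** One master seed spawns named sub-streams:
structure, establishment, demand (per unit), absence (per unit, a fixed
table of per-slot uniforms so larger rosters extend rather than reshuffle
the smaller roster's draws), and fulfilment (counter-based uniforms keyed
by unit, day, shift, role, block and source). Consequences, exploited by
the tests: demand and absence are identical across plans and scenarios;
with no fill channels, a higher-baseline plan's achieved hours dominate a
lower one's unit by unit; raising any fulfilment probability weakly
raises every unit's achieved hours. Under active filling, per-unit
dominance between plans is only typical, not guaranteed — the threshold
trigger is non-monotone (a plan sitting just inside the band receives
nothing while a worse-off plan is topped up past it) — so plan ordering
under fills is asserted on per-shift aggregates.

Accounting identities, checked exactly on every run: achieved = rostered
− absent − floated out + floated in + bank + agency; float hours net to
zero within each shift-role; every fill is a whole number of blocks.

## 5. Economics

**Costing.** Worked substantive hours are rostered − absent (floating
relocates staff without changing the pay bill; absent staff are not
paid in this model — sick pay is treated as part of the employer on-cost
baked into the hourly rate). Bank and agency hours are priced at their
own rates. Default rates (£/h, 2017-era, illustrative): RN 27/25/35 and
NA 17/16/22 for substantive/bank/agency; unsocial multipliers 1.3
(weekday night), 1.35 (weekend day), 1.6 (weekend night). Bank below
substantive reflects reduced pension contributions; agency reflects a
capped framework rate.

**Exposure.** Judged per unit-day, weighted by patient days, against the
unit's mean achieved HPPD under the standard plan at the same
availability (the reference scenario). Both thresholds are strict: low
iff HPPD < unit mean; high-temporary iff temporary HPPD > 1.5. Exposure
days per admission = proportion × baseline length of stay (default
5 days); admissions = patient days / baseline LOS.

**Outcomes.** Default linear excess-risk form: Δdeaths = baseline risk ×
admissions × (RR − 1) × Δexposure days, summed over the low-staffing term
and, in the secondary-analysis variant, the high-temporary term;
Δbed-days = admissions × LOS × (%ΔLOS per low day / 100) × Δexposure
days. A compact "literal" evaluation of the published-style expression
((Δexposure × RR × risk × population) − baseline deaths) is retained
behind a flag for audit only; it is dimensionally inconsistent as a
delta and is not used in reports. Effect defaults (illustrative, in the
magnitude range of longitudinal staffing-outcome studies): mortality RR
1.03 (CI 1.01–1.05) per low-staffed day, +0.3% LOS per low-staffed day,
RR 1.02 per high-temporary day, baseline mortality risk 0.035 per
admission.

**Cost-effectiveness.** NNT = 1/ARR (or NNH = 1/ARI) with an explicit
no-effect marker when Δdeaths = 0; net cost per life saved =
(Δstaff cost + Δbed days × £337)/|Δdeaths|, so shorter stays offset
staff cost. Cross-hospital averages are unweighted: deltas are averaged
(equivalently pooled) across hospitals before ratios are taken.

**Sensitivity grid** (for the resilient-vs-standard comparison): mortality
RR at either CI bound, bed-day cost +25%, agency +25%, agency = bank,
bank = substantive, all costs +25%, and no-floating. All but the last are
pure recostings of the stored hours-by-cell ledgers (bit-identical when
unperturbed); no-floating re-simulates with the same seeds and re-derives
its reference levels from its own standard run, so the perturbed world is
internally consistent.

## 6. Numerical choices and degenerate inputs

- Tolerance comparisons use a 1e-9 guard; a shortfall of exactly 15% does
  not trigger, and hours exactly at a threshold are not flagged.
- Half-rounding of headcounts is floor(2x + 0.5)/2 (ties up).
- Degenerate inputs are first-class: zero census, zero demand, empty
  availability, singleton specialty groups (floating vacuous, warned at
  generation), all-absent rosters.
- Sample skewness is the adjusted Fisher–Pearson statistic and kurtosis
  is bias-corrected excess kurtosis (scipy, `bias=False`); units with
  under 3 days or zero variance are excluded from shape summaries with a
  warning.
- Seeds are organised so that adding or removing trailing units does not
  reshuffle other units' streams.

## 7. Problem sizes used in the test suite

The packaged tests run the generator at its full default scale (81 units
× 365 days, 5 seeds) for calibration checks, one 27-unit hospital × 365
days × all 12 plan/availability cells for accounting identities, the full
3-hospital default grid for the qualitative cost/outcome patterns, a
10-unit hospital × 100 days for coupling (dominance/monotonicity)
properties, and 1,000 randomized ≤3-unit instances for equivalence
against a straight-line reimplementation of the fill rules. These sizes
keep the whole suite around a minute on one CPU while exercising the
study-scale configuration end to end.

## 8. Known limitations

- Temporary and floated staff are assumed as productive as home-unit
  substantive staff; quality penalties from heavy temporary use enter
  only through the secondary analysis's mortality term.
- Absence is short-notice sickness only; longer-term absence is assumed
  rostered around and so lives in the uplift, not the simulation.
- The economic perspective is narrow: staff cost plus a national excess
  bed-day reference cost; no QALYs, discounting, or adverse-event costs.
- Costs use one representative pay rate per role and source, not a band
  mix.
- Effect estimates, care-hour multipliers and the `limited` availability
  table are illustrative stand-ins, clearly labelled; absolute cost and
  NNT levels produced by the defaults are internally consistent but not
  estimates for any real hospital system. Qualitative contrasts between
  plans and availability scenarios are the object of study.
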