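# Methods

`olfthresh` estimates animal odor-detection thresholds from adaptive
staircase sessions on a flow-dilution olfactometer and analyzes how those
thresholds respond to environmental conditions, behavioral state and odor
availability. This note records the models, the conventions adopted where
the procedure underdetermines them, the synthetic-data generator's
assumptions, and the package's known limitations.

## Stimulus model

The olfactometer mixes an odor line (metered in cc/min) into a clean
dilution line (L/min). Stimulus intensity is the unitless odor fraction

    c = q_odor / (q_odor + 1000 · q_clean),

the 1000 converting L/min to cc/min. The default five-step ladder
(80, 50, 25, 12, 3 %) reproduces the instrument's printed labels after
rounding to integer percent; the flow-derived value of the 12 % step is
11.96 %. All threshold arithmetic uses the nominal fractions — the
imputation rules are defined at the nominal 0.03 and 0.80, and mixing
nominal and flow-exact values would introduce spurious 0.004 offsets.
Percent appears only at I/O; internally everything is a fraction in (0, 1],
logged base 10.

## Staircase

Sessions are three-alternative forced choice (3-AFC, chance = 1/3) driven by
a 3-down-1-up rule: three consecutive correct responses step the
concentration down one rung, any error steps it up one. A *reversal* is any
change in the direction of adjustment. Sessions end at a required reversal
count (7 for the single-session protocol, 4 for the daily acclimatization
protocol), by clearing the floor (three consecutive correct at the lowest
step), at a 40-minute cap, or by welfare criteria (five consecutive
no-search trials, or one under overt heat stress), checked in the priority
order welfare > floor > reversals > time.

Conventions the rule set does not pin down, fixed here and exposed as
options where an alternative is defensible:

- **Reversal concentration** — the fraction presented on the trial that
  *triggered* the turn. This is symmetric between up- and down-turns;
  the post-change convention is available via `reversal_at_new_step`.
- **Counter resets** — the correct-counter resets on every realized step
  change and on every error; streaks never carry across steps.
- **Top clamp** — an error at the highest step moves nothing and records
  nothing: an unrealized movement has no direction.
- **First movement** — sets the direction; it is never itself a reversal.
- **No-search trials** — freeze the staircase entirely (no movement, the
  correct streak survives) and count only toward the welfare criteria.
- **Floor vs. reversal tie** — when the floor rule and the reversal count
  fire on the same trial, the floor wins; floor sessions are imputed, so
  the tie-break decides the imputation provenance, not the data.

### Equilibrium

Descent requires three straight hits (probability p³), ascent one miss.
These balance where p³ = ½, i.e. p\* = 0.5^(1/3) ≈ 0.794, so the staircase
oscillates around the concentration at which the observer is 79.4 % correct.
The acceptance suite verifies this by simulation: 500 sessions on a finely
spaced ladder (0.05 log₁₀ steps), 30 reversals each with the first six
discarded, put the accuracy at the mean reversal concentration within ±0.02
of p\*.

The 7-reversal field protocol, started at the ladder top, does **not**
measure this equilibrium unbiasedly: the descent transient leaves its first
reversals above threshold, lapses inject spuriously high reversals in
proportion to the descent length, and the coarse ladder quantizes the
oscillation. These are properties of the instrument protocol, reproduced
faithfully by the simulator, and they matter when interpreting planted-truth
recovery (below).

## Threshold statistic and imputation

A session's detection threshold is the geometric mean of its reversal
fractions; on the log₁₀ scale, the arithmetic mean of log₁₀ reversals.
Incomplete sessions are padded to the required reversal count before
averaging: floor terminations with the lowest ladder fraction (0.03 —
the subject out-ran the dilution range), welfare terminations with 0.80
(failure to perform). Time-cap sessions are padded like welfare ones by
default; the protocol's imputation rules name only floor and welfare, so
this is a package decision, configurable (`time_cap_as_fail`) and recorded
in each record's provenance fields. A non-imputed variant averages the
observed reversals only and flags sessions with none as missing.

Useful fixed points: an all-floor session gives log₁₀ 0.03 = −1.523, an
all-fail session −0.097. Welfare imputation can only raise, floor imputation
only lower, the non-imputed estimate — a monotonicity the test suite holds
as an invariant.

## Mixed-effects analysis

All inferential models are linear mixed models with a random intercept per
dog, fit by REML (statsmodels `MixedLM`). The main threshold model is

    log10 threshold ~ breed + condition + odor + condition:odor + (1 | dog)

with the standard condition and alphabetical factor levels as reference.
Fixed terms are tested with joint Wald chi-squares on a sum-contrast coding;
on the balanced designs this package generates these coincide with
classical Type-II tests. Because the study scale is small (handfuls of
dogs), the Wald table also carries a small-sample p-value, `p_f`, referring
chi²/df to F(df, n − k_fe): the asymptotic chi-square is anti-conservative
at this scale, and the package's null-calibration test (400 simulated null
experiments at 4 dogs × 2 odors × 3 conditions) holds the F variant to the
nominal 5 % ± 2 %. Reports should quote the chi-square (the field's
convention) alongside `p_f` when n is small.

Post-hoc condition-vs-standard contrasts within each odor are estimated
marginal mean differences — design rows averaged over the remaining factors
with equal weights — signed condition − standard so positive means poorer
detection. p-values are reported unadjusted and Holm-adjusted within each
odor's family; repeated contrasts invite multiplicity correction but no
single adjustment is canonical for this design, so both are emitted.
`fold_change(δ) = 10^δ` converts log₁₀ differences to fold changes.

Covariate models (`log10 threshold ~ covariate × odor + (1 | dog)`) accept
session mean subcutaneous temperature (restricted to the standard and hot
conditions — cold-condition readings are sensor artefacts and arrive flagged
invalid), mean searched-trial latency, and mean inter-box interval. Under
sum-coded odor the covariate main effect is the across-odor average slope.
Session-mean latency averages searched trials only (no-search trials have no
latency); the alternative is a caller-side filter. The acclimatization model
predicts test-day outcomes by treatment group with the dog intercept, and is
reused for the behavioral/physiological responses.

VOC (odor availability) regressions are simple per-odor OLS fits of log
threshold on condition-mean total VOC, joined at the condition level because
headspace sampling was per condition, not per session; the standard
condition carries no VOC sample and is excluded. Instrument responses
convert to concentrations by response-factor division (calibration slope;
curves must satisfy the r² > 0.98 linearity criterion). Fewer than three
distinct condition means makes the slope unidentifiable and flags the odor
as degenerate rather than erroring the batch.

## Synthetic-data generator

The generator exists so every stage — session logs, temperature series,
threshold tables, model fits — is testable at desk scale. It emulates:

- a logistic 3-AFC psychometric observer,
  P(correct) = γ + (1 − γ − λ)·F((log₁₀ c − α)/β), γ = 1/3. Logistic rather
  than Weibull because any sigmoid serves the staircase and the logistic's
  closed-form midpoint anchors tests;
- session observer midpoints α = baseline(odor) + δ(odor, condition) +
  dog effect + session noise, with optional mediated pathways (a
  temperature slope, used by recovery scenarios) kept separate from δ so a
  planted contrast is never double-counted;
- the two study designs: 8 dogs (4 + 4 by breed) × 4 odorants × 5
  temperature/humidity conditions with counterbalanced condition orders, and
  a 22-day two-group daily protocol whose acclimatization arm ramps to
  40 °C / 70 % RH over six days, with hot test days 11 and 22 for both
  groups and a planted group effect on those days;
- subcutaneous temperature trajectories T(t) = T_asym − (T_asym − T₀)e^(−t/τ)
  read every 5 minutes with noise, T_asym ordered hot-humid > hot-dry >
  standard; cold conditions emit physiologically implausible, `valid=False`
  series (the real sensor artefact);
- lognormal latencies and inter-box intervals whose log-location shifts
  with a 0–1 condition heat index and with the observer's performance
  deficit, so covariate analyses have signal; per-trial duration adds a 20 s
  purge interval, which is what makes 40-minute caps binding;
- no-search probabilities rising with heat, so welfare terminations occur.

Defaults: β = 0.15 log₁₀ units, λ₀ = 0.02 (+0.02/°C above 39.5 °C session
mean), σ_dog = 0.15, σ_session = 0.10; baselines per odor span the observed
range of the instrument (the most detectable odorant is placed below the
dilution floor, so its sessions floor out and impute — reproducing the
real censoring); condition shifts plant hot-condition decrements of
≈ 0.4–0.5 log₁₀ for the headline odorant. One master seed drives a
`SeedSequence` tree; every session owns a child seed and is reproducible in
isolation.

What it does **not** emulate: order/startup effects, learning or fatigue
within sessions, sniffing-vs-panting physiology, airflow or plume structure,
odorant chemistry, handler behavior. Passing tests therefore certify the
pipeline's arithmetic and inference, not any claim about real dogs.

### Planted-truth recovery and instrument bias

Recovery scenarios (acceptance tests and script) plant a 0.47 log₁₀
hot-condition contrast and a 0.21 log₁₀/°C temperature slope, then refit
them. They run on a finely spaced ladder (0.1 log₁₀ steps) with lapse-free
observers: on the instrument's own 5-step ladder the non-uniform spacing
(0.12 → 0.03 is 0.6 log₁₀) quantizes the measurement, and with λ > 0 the
descent from the ladder top injects high early reversals in proportion to
descent length, attenuating measured contrasts by roughly 10–20 %. Those
biases are real features of the field protocol — the simulator reproduces
them, and the acceptance script's acclimatization quantity deliberately
reports the floor-censored group difference under the instrument ladder —
but a recovery test run under them would measure the instrument, not the
statistics. CI coverage of planted values is asserted at ≥ 85 % over 40
replicates, the exact binomial band around a nominal 95 %.

## Numerical choices

- Geometric means are computed in log space; exactness to 1e−12 on
  hand-computed cases is asserted.
- REML fits that fail the default optimizer retry with Powell and mark the
  summary unconverged; singular fits flag rather than raise.
- CSV round-trips use `float_precision="round_trip"` and `repr`-serialized
  list fields so a written session reads back identically.
- Problem sizes in the test suite and acceptance script (400 null
  replicates at 24 observations each; 40 recovery replicates at 16 dogs;
  500 convergence sessions) were chosen to put Monte-Carlo error comfortably
  inside the asserted tolerances while keeping a full run in tens of
  seconds.

## Limitations

- Thresholds are censored by the dilution range: subjects below 3 % or
  above 80 % produce imputed, biased-toward-the-boundary records. Group
  differences that straddle the floor are attenuated (the acceptance
  script's acclimatization quantity shows this).
- The asymptotic chi-square p-values are anti-conservative below ~30
  observations; use `p_f`.
- The staircase estimator (all seven reversals, started at the top) is
  upward-biased relative to the 79.4 % point; comparisons between
  conditions share the bias, absolute thresholds carry it.
- `MixedLM` offers no Kenward–Roger correction; `p_f`'s residual df is a
  pragmatic, calibration-verified stand-in.
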