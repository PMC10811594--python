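# Methods

## The measurement problem

Rhythmic-training serious games for children with reading and related
neurodevelopmental disorders measure sensorimotor synchronization: how
precisely a child taps, claps, shakes, sings or punches in time with an
expected beat.  This package implements the full measurement and analysis
chain for such telemetry: the expected-input beat grids of six game
tasks, the timing-tolerance classification and normalized scoring of raw
input events, the difficulty curriculum that schedules levels, a
synthetic cohort generator, and the longitudinal mixed models used to
quantify progress — together with parameter-recovery experiments that
validate the estimation pipeline, since the original raw game logs are
not public.

## Scoring model

Each level defines expected-input times T on a 4/4 beat grid at the
level's tempo.  A player input at time t (after latency correction, see
below) has signed asynchrony `delta_tap = t − T`.  Task-specific nested
tolerance windows `t_perfect < t_good < t_correct` grade each input into
four levels of acceptance; an input is *acceptable* iff
`|delta_tap| ≤ t_correct`, with all interval boundaries closed.  Each
expected input also receives a normalized performance score

    score(δ) = (−100 / threshold)·|δ| + 100   if |δ| ≤ threshold
             = 0                              otherwise,

with `threshold = t_correct`.  Note one deliberate literalism: an input
exactly at `|δ| = t_correct` classifies as *correct* yet scores 0 — both
published rules are applied as printed.

Session aggregation uses the number of expected inputs as denominator:
misses count as non-acceptable with score 0, while spurious (unmatched)
events are counted and reported but never enter the ratio or the mean —
this keeps both statistics well defined for players who under- or
over-respond.  Stars follow the acceptable-input ratio: ≥50% → 1,
≥75% → 2, ≥90% → 3.

Sing Lab is the exception: a sung note is credited iff its onset falls
within `min(0.15 s, 0.30 × note duration)` of the expected onset and the
note was sung for at least 60% of its duration; credited notes score
100, uncredited 0.  The published onset rule ("0.15 s … and up to 30% of
the note duration") is ambiguous; we read the duration fraction as a cap
on the window for short notes.

**Latency.** Devices report an input after the player's action; a
standard 20 ms latency is subtracted (configurable per device profile)
and timestamps clip at 0.

**Matching.** Raw events are matched to expected times by an exact
one-to-one assignment (`scipy.optimize.linear_sum_assignment`) that
first maximizes the number of matched pairs within `t_correct` and then
minimizes the total `|delta_tap|`; exact ties go to the earlier event
via an infinitesimal rank penalty (10⁻⁹ s per event rank, far below
timestamp resolution).  A greedy nearest-pair matcher was considered and
rejected: the Hungarian solution is guaranteed optimal, which the test
suite verifies against an exhaustive bitmask-DP oracle on thousands of
small instances.

## Beat schedules

Response types map to grid patterns: continuous tapping fills every
pattern slot; *last-beat* tasks answer once per measure on beat 3
(1-indexed), after two demonstration beats; *call-and-response* tasks
alternate one demonstration measure with one response measure (a
configuration default — phase lengths are not published) and only
response measures carry expected inputs.  Rhythmic density is one input
per beat, an "eighth" pattern of 3 evenly spaced inputs per 2 beats
(the published gloss, kept over standard music notation), or half-time
(one per 2 beats).  Mid-task rhythm changes regenerate the grid from the
first measure boundary at or after the change point.  Generated levels
in the curriculum run 80–100 s; `build_schedule` itself accepts any
positive duration so short grids can be built for tests and fixtures.

## Curriculum

12 chapters × 6 levels.  Tasks are introduced one at a time, each
practiced twice (optionally three times) before the next appears; after
the introduction phase every chapter contains each task once.  Tempo
rises linearly 90 → 132 BPM across chapters (published direction, not
values; configurable), density switches to the eighth pattern from
chapter 7 for the task types that support it, and from chapter 10 a
mid-task change to half-time is inserted.  Entry pathways: dyspraxia
advances Sing Lab before River Splash and Karate Fruits; dyslexia
advances River Splash before Sing Lab.  The two rules conflict when both
flags are declared; motor accessibility (the dyspraxia rule) takes
precedence, applied as rule order in the default pathway table.  Daily
missions pick 4 previously played tasks by ascending stars then
ascending mean score (latest session per task), cycling when fewer than
4 distinct tasks were played.

## Synthetic cohort

The generator emulates the usability-study conditions: 98 players, ages
Normal(9.05, 2.4²) truncated to [6, 14] (the published "SE 2.4" is read
as an SD — with n = 98 an SE of 2.4 would imply an implausible age SD of
~24 years); independent diagnosis flags with prevalences dyslexia 0.23
and ADHD 0.18 (published declaration rates) and 0.10 for the others
(unpublished; configurable); games-played per player lognormal with
median 42 and log-SD 0.728, calibrated to the published engagement
median 42 and mean 54.77.  Diagnosis co-occurrence is independent by
default; joint rates are not published.

Session scores follow the published fixed-effect predictor (intercept
37.83; age 1.08/yr; dyslexia +2.81; ADHD +4.16; dysgraphia −2.06;
executive impairment −3.26; dyscalculia −0.43; dysphasia −0.51; time
slope 0.02/level with interactions +0.06 ADHD, −0.06 dyslexia, −0.03
executive, −0.01 dysphasia, +0.05 dyscalculia, 0.00 dysgraphia) plus
random intercepts and Gaussian residual, clipped to [0, 100].  The
random-effect SDs are not published; defaults are player 6, game 3,
level 2, residual 15 score points, which reproduce the order of
magnitude of the published test statistics.  The clipping rate is
reported (`records.attrs["clip_rate"]`, ~0.5% under defaults) so
recovery experiments can bound attenuation bias.

Two random-effect layouts are supported (`CohortConfig.re_structure`):
`"nested"` draws player, game-within-player and level-within-game
intercepts (the progress-model structure) and `"game_level"` draws game
and level intercepts shared across players (the diagnosis/interaction
model structure).  Each recovery experiment generates under the
structure of the model it fits — the standard parameter-recovery design.

**Event-level path.** The same predictor drives an event-level
realization: for a target mean session score m and task threshold c, the
per-input Gaussian jitter SD σ solves

    E[score(δ)] = 100·[(2Φ(u) − 1) − (2/u)(φ(0) − φ(u))] = m,  u = c/σ,

a closed form in folded-normal moments, inverted by Brent root-finding.
Misses (default rate 0.05) score zero, so the matched-input target is
inflated by 1/(1 − miss rate), saturating near 100; spurious events are
added at 0.02 per expected input, uniform over the level.  Scoring the
simulated events through the engine therefore reproduces the intended
mean — the key cross-module consistency test.

What the generator does *not* emulate: device heterogeneity and
per-tablet latency, dropout mechanisms, diagnosis comorbidity structure,
within-session fatigue or learning, and any dependence of engagement on
performance.  Passing recovery tests therefore demonstrate that the
estimation pipeline retrieves known effects under the study's design and
noise scale — not that the published coefficients are correct for real
children.

## Longitudinal models

Three REML linear mixed models, one record per game played:

* progress: `score ~ time + (1 | player/game/level)`
* diagnosis: `score ~ age + dyscalculia + dysgraphia + dyslexia +
  dysphasia + ADHD + executive impairment + (1 | game/level)`
* interaction (per diagnosis): `score ~ time × diagnosis + (1 | game/level)`

The default backend is statsmodels `MixedLM`, with the inner grouping
factors expressed as variance components; an R/lme4 (lmerTest) backend
run through `Rscript` serves as an independent cross-check and agrees
with the default within a fraction of a standard error.  Players with
fewer than 15 games (inclusive bound, configurable) are removed first.
Wald 95% intervals use the normal critical value; reported degrees of
freedom are residual-based for the default backend (Satterthwaite under
lme4) and are used only for order-of-magnitude sanity, not validation.
Diagnosis indicator columns with no variation are dropped with a
warning.  Non-convergence is flagged on the fit, never silently
discarded; on the progress model the flag trips in a large minority of
replicates because the level-within-player variance component is weakly
identified (most (player, level) cells hold a single observation) —
fixed effects and their SEs are unaffected, with measured 95% CI
coverage of 0.98 across replicates.

**Recovery precision.** At study scale the sampling SD of the recovered
time slope is ~0.006/level (the published fit's own SE is 0.0075), so a
single replicate determines the 250-level predicted gain of 5 points
only to ±1.5 at one SD.  Recovery experiments therefore aggregate over
replicates: the acceptance script reports the mean predicted change over
60 seeds (SE ≈ 0.2) and mean recovered coefficients over 30 seeds for
the diagnosis model.

## Numerical choices and degenerate inputs

* Closed tolerance intervals; comparisons use exact arithmetic on floats
  with 10⁻¹² guards only where grid positions are derived.
* Empty event list → all misses; zero expected inputs → error; negative
  latency, non-positive tempo/duration/threshold → validation errors.
* `expected_score_to_jitter` rejects targets outside (0, 100); its
  bracket grows geometrically until it straddles the root.
* Root seeds are split per stage with `numpy.random.SeedSequence`; every
  derived seed stays below 2³¹.
* Pipeline artifacts embed the game version, a SHA-256 hash of the run
  configuration (excluding the output directory) and the root seed.

## Known limitations

* The curriculum's tempi, durations, call-and-response phase lengths and
  change-point placement are configuration defaults, not published
  facts.
* The diagnosis and interaction models omit a player intercept (as
  published); applying them to data with real player heterogeneity
  underestimates SEs of player-level contrasts.
* Sing Lab scoring covers rhythm and duration only — no pitch.
* The v2 "simplified calculation" (acceptable ratio as headline measure)
  and the 0–100 score are both always computed; the package does not
  model which one a given game build displayed.
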