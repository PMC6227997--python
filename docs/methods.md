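# Methods

## Model

The pipeline estimates per-individual daytime cumulative activity budgets
for a bay-resting dolphin population by fusing three observation streams
that each cover a different axis of the problem: photo-identification tells
us *who* uses *which bays* and how often; daily acoustic presence calls tell
us *whether a bay held dolphins at all* on a given day; scan-sampled focal
follows tell us *what dolphins do* inside each bay and outside, and how long
follows actually spend inside a bay.

For individual *i* on day *d* the simulation proceeds:

1. **Bay allocation.**  A bay is drawn from π\_i, the individual's sighting
   counts normalised across bays.  Every individual is allocated to some bay
   every day; "outside" arises only through the acoustic gate (step 2).
   This is the most literal reading of the allocation procedure, which
   offers no direct-to-outside path.
2. **Acoustic gate.**  The (bay, day) call confirms the visit.  `ABSENT`
   re-allocates the individual outside the bays (not to a second bay — the
   record supports removal to outside only).  `MISSING` imputes presence by
   one Bernoulli draw at the bay's observed presence rate,
   #present / #non-missing days.
3. **Time inside.**  For a confirmed visit, the daytime fraction *a* ∈ [0,1]
   is resampled uniformly from the bay's empirical per-follow sample
   (10 min × inside-scan count / 720 min, clipped to 1).  Outside days have
   *a* = 0, and *b* = 1 − *a* always.
4. **Daily budget.**  One bootstrap replicate budget is drawn for the bay
   and one for outside — per individual-day, since the uncertainty is
   allocated per dolphin — and mixed componentwise:
   *a*·(inside budget) + *b*·(outside budget).  The mixture of two points on
   the 2-simplex stays on the simplex, so every daily budget is valid by
   construction.

The cumulative budget is the mean of the daily budgets (all days share the
same 720-minute daytime window, so the duration-weighted sum normalised by
total minutes reduces to the plain mean; this identity is asserted in
tests).

Stratum budgets are estimated from scans as state-count ratios — each
instantaneous scan stands for one 10-minute window — and their uncertainty
as a nonparametric bootstrap over scan states (B = 1000 by default).
Resampling ignores within-follow autocorrelation; see Limitations.
Boat- and land-based scans are pooled within a stratum; a platform filter
exists for sensitivity analyses.

## Exposure metrics

A scan is *approached* when ≥ 1 boat, kayak or swimmer is within 100 m,
else *unapproached* (control).  Maximal same-state runs within a follow form
intervals of duration 10 min × scan count (not last-minus-first timestamps,
so a single-scan run is 10 min).  A within-follow gap > 1.5× the nominal
spacing breaks the run and censors the abutting ends, so continuity is never
fabricated across dropouts.  Follow-boundary intervals are flagged
left-/right-censored; medians include censored intervals by default (the
simplest treatment; exclusion is one flag away).  Even-count medians are the
mean of the two middle values.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| bays | Makako, Kealakekua, Honaunau, Kauhako | configured bay identifiers; `OUTSIDE` is reserved |
| daytime window | 06:00–18:00 (720 min) | daylight period the budgets describe |
| scan interval | 10 min | instantaneous sampling grid; 1 scan = 10 min of time |
| bootstrap B | 1000 | replicates per stratum budget distribution |
| approach threshold | 100 m | impact criterion for boats/kayaks/swimmers |
| study scale | 235 individuals × 601 days | default simulation scope |

## Synthetic-data generator

The generator emulates the study's structure with explicit truth:

* **Bay affinities**: Dirichlet(2.0, 0.8, 0.7, 0.5) per individual — skewed
  so most individuals favour the first bay, with heterogeneous multi-bay
  use, mirroring the concentration of real catalogues in one favoured
  resting bay.
* **Bay-day presence**: Bernoulli with per-bay rates 0.90 / 0.65 / 0.37 /
  0.51 (the published per-bay acoustic presence rates, used as generating
  parameters).
* **Direct-outside days**: with probability 0.10 an individual skips the
  bays entirely.  The estimator never allocates outside except via the
  acoustic gate — a deliberate generator/model mismatch kept so tests can
  quantify the estimator's occupancy bias rather than hide it.
* **True budgets**: rest/social/travel = (0.726, 0.190, 0.084) in the
  first bay (the published Makako point budget, used as a default), ~(0.62,
  0.33, 0.05) in the other bays, (0.35, 0.35, 0.30) outside — resting
  dominates inside bays, travelling is mostly an outside activity.
* **Time inside**: Beta draws per bay-day (means 0.8, 0.7, 0.6, 0.7);
  follow scan counts are the Beta draw × 72 slots, rounded, so the
  empirical per-follow sample recovers the Beta mean up to grid
  quantisation (< 0.01).
* **Approach process**: a two-state Markov chain over scans with stay
  probabilities 0.9 (approached) and 0.5 (unapproached); its stationary
  approached fraction is 0.5/0.6 ≈ 0.833, matching the heavy exposure
  regime the method is meant for.  Activity states are i.i.d. within a
  follow by default — the analysis model treats scans as exchangeable
  within strata — with an optional persistence switch to probe the
  bootstrap's autocorrelation blind spot.
* **Survey design**: 2/4/2/4 survey days per month per bay (the study's
  cadence), one follow per surveyed bay-day with probability 0.4 plus
  outside follows (probability 0.15 per survey day, log-normal length),
  and a flat photographic detection probability of 0.9.  Acoustic records
  go missing at rate 0.107 (the fraction of bay-days without usable
  recordings implied by the published recording-day totals).

What the generator does **not** emulate: spatial movement within bays,
photographic misidentification, group structure (follows sample a group,
but sightings are per-individual), platform-specific approach dynamics, and
seasonal or diel non-stationarity.  Passing recovery tests therefore show
the estimator is consistent under its own assumptions plus mild violations
(direct-outside days, Markov exposure), not that field estimates are
unbiased.

## Numerical and design choices

* **Draw order.**  One `numpy` PCG64 generator seeded from the study
  config; per individual, draws are vectorised across the day axis in the
  fixed order: bay allocation, presence imputation uniforms, time-inside
  uniforms, bay replicate indices, outside replicate indices.  Identical
  config + seed ⇒ byte-identical outputs.
* **Empirical resampling** uses floor(u · n) indexing of a uniform u, so a
  single uniform stream drives draws from samples of different sizes.
* **Rounding** of reported whole percentages is half-up (36.5 → 37), which
  reproduces conventional rounded field summaries; unrounded values are
  reported alongside.
* **Duplicate sightings** (same individual, day, bay) collapse to one
  sighting-day with a warning — a dolphin photographed twice in a bay in
  one day is one occurrence.
* **Degenerate inputs**: empty strata, all-missing acoustic series, bays
  with no touching follows, and B < 1 raise typed errors
  (`ValidationError`, `CoverageError`, `ConfigError`) before any simulation
  work; the CLI maps them to exit codes 3, 4 and 2.
* **Time-inside unit**: per-follow values (follows are the observation
  unit), not per-day aggregates; a follow contributes one value per bay it
  touches.

## Problem sizes in tests

Unit tests run on a committed 5-individual, 12-day toy fixture whose
expected tallies were counted by hand.  Recovery and oracle tests use
moderate scales chosen for tight Monte Carlo error at low cost: the
closed-form linearity oracle at 60 individuals × 200 days (12,000
individual-days, 3 s.e. tolerance), parameter recovery and the scale check
at the full default 235 × 601 with B = 1000, which completes in seconds on
one CPU.

## Limitations

* The bootstrap treats scans as exchangeable within strata; within-follow
  behavioural autocorrelation deflates replicate spread.  The generator's
  persistence option exists precisely to measure this.
* Time-inside distributions inherit follow-duration biases: follows
  truncated by observation logistics shorten the empirical sample.
* The acoustic gate is bay-level: one ABSENT call empties a bay for all
  allocated individuals that day.
* No multi-bay days, no night-time (foraging) budget, no travel-time
  accounting between strata: the daily mixture has exactly two terms.
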