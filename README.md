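# baybudgets

Cumulative daytime activity budgets and human-exposure metrics for
bay-resting dolphin populations.

Hawaiian spinner dolphins (*Stenella longirostris*) forage offshore at night
and rest during the day inside a handful of sheltered coastal bays, where
they are also repeatedly approached by boats, kayaks and swimmers.  Because
no single sampling method follows an individual dolphin through a whole
study period, estimating how much of its daytime an individual spends
resting, socialising and travelling requires fusing three partial data
streams:

1. **photo-identification** sighting histories (which individuals use which
   bays, and how often),
2. **passive acoustic monitoring** (were dolphins in a bay at all on a given
   day: present / absent / recorder down), and
3. **scan-sampled focal follows** (the predominant group activity every
   10 minutes, plus counts of boats, kayaks and swimmers within 100 m).

`baybudgets` implements the full fusion model as a reusable, seeded
pipeline, together with a synthetic-data generator with known ground truth
so every stage can be tested without field data.

## The model

For each individual *i* and study day *d*:

* *i* is allocated to one bay, drawn from its relative occurrence
  probabilities (per-individual photo-ID sighting counts, normalised);
* the bay-day acoustic call gates the visit: `ABSENT` re-allocates *i*
  outside the bays, `MISSING` imputes presence by a Bernoulli draw at the
  bay's observed presence rate (#present days / #non-missing days);
* the fraction *a* of the 06:00–18:00 daytime spent inside the bay is
  resampled from the bay's empirical per-follow distribution, and the daily
  budget is the convex mixture

  daily budget = *a* · (budget inside bay *i*) + *b* · (budget outside bays),
  with *b* = 1 − *a*;

* the inside/outside budgets are drawn per individual-day from bootstrap
  density distributions (B = 1000 resamples of the observed scan states per
  stratum), propagating estimation uncertainty.

The cumulative activity budget of an individual is the duration-weighted
mean of its daily budgets over the study period (default 601 days).
Exposure metrics come from the same scans: a scan is *approached* when any
boat, kayak or swimmer is within 100 m, maximal same-state runs form
approached/unapproached intervals (10 min per scan), and medians and
histograms summarise their durations.

## Worked example

```python
import baybudgets as bb
from baybudgets.budgets import bootstrap_budget, time_inside_distribution
from baybudgets.cumulative import StudyConfig, simulate_study
from baybudgets.synthetic import GeneratorConfig, generate

cfg = GeneratorConfig(seed=7)                      # 235 individuals, 601 days
sightings, acoustic, scans, truth = generate(cfg)

bays = list(cfg.bays)
matrix = bb.occurrence_matrix(sightings, bays)
budget_dists = {s: bootstrap_budget(scans, s, B=1000, seed=i)
                for i, s in enumerate(bays + [bb.OUTSIDE])}
time_dists = {b: time_inside_distribution(scans, b) for b in bays}

study = StudyConfig(study_days=cfg.study_days,
                    individuals=matrix.individuals, seed=11)
budgets, log = simulate_study(study, matrix, acoustic,
                              budget_dists, time_dists)
print(bb.summarize_population(budgets))
```

prints

```
    state   mean_pct    sd_pct    min_pct    max_pct
0    rest  53.826948  3.982747  44.416317  63.071916
1  social  30.036777  2.535329  24.105277  34.838335
2  travel  16.136274  1.542438  12.822808  20.745348
```

i.e. under the generator's default conditions the average simulated
individual spends ~54% of its daytime resting (individuals range 44–63%),
~30% socialising and ~16% travelling.  The same scan table gives
`bb.exposure_proportion(scans) ≈ 0.839`: dolphins are within 100 m of human
activity for ~84% of observed time, close to the generating approach
chain's stationary fraction of 5/6.

The same pipeline is available from the shell:

```
baybudgets synth --out-dir data --seed 7
baybudgets run-all --config run.cfg      # flat key = value config
baybudgets report --manifest out/manifest.json
```

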