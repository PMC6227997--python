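"""Monte Carlo simulation of per-individual cumulative daytime activity budgets.

The model fuses three data streams.  For each individual and each study day:

1. **Allocation** — the individual is allocated to one bay, drawn from its
   relative-occurrence probabilities (photo-ID sighting counts normalised per
   individual).  An individual visits at most one bay per day.
2. **Acoustic gating** — the bay-day acoustic call confirms the visit.  If
   the bay was ABSENT that day the individual is instead placed outside the
   bays.  If the call is MISSING, presence is imputed by a Bernoulli draw
   with the bay's observed presence rate.
3. **Time inside** — for a confirmed bay visit, the fraction ``a`` of the
   12-hour daytime spent inside the bay is drawn from the bay's empirical
   per-follow distribution; ``b = 1 - a`` is spent outside.  Outside days
   have ``a = 0``.
4. **Daily budget** — one bootstrap replicate budget is drawn for the bay
   and one for outside, and combined as the convex mixture
   ``a * (budget inside bay) + b * (budget outside bays)``.

The cumulative activity budget of an individual is the duration-weighted sum
of its daily budgets over the study period, normalised by total daytime
minutes; with a constant daytime window this is the plain mean of the daily
budgets.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .budgets import ActivityBudget, BudgetDistribution, TimeInsideDistribution
from .core import DAYTIME_MINUTES, OUTSIDE, CoverageError, ValidationError
from .ingest import OccurrenceMatrix


def default_study_days(
    start: _dt.date = _dt.date(2011, 1, 1), n_days: int = 601
) -> list[_dt.date]:
    """Consecutive calendar days; the study default is 601 days."""
    return [start + _dt.timedelta(days=i) for i in range(n_days)]


@dataclass(frozen=True)
class StudyConfig:
    """Scope and reproducibility parameters of one simulation run."""

    study_days: list[_dt.date]
    individuals: list[str]
    seed: int = 0
    n_bootstrap: int = 1000
    daytime_minutes: int = DAYTIME_MINUTES

    def __post_init__(self):
        if not self.study_days:
            raise ValidationError("StudyConfig: study_days is empty")
        if any(
            b <= a for a, b in zip(self.study_days, self.study_days[1:])
        ):
            raise ValidationError("StudyConfig: study_days not strictly increasing")
        if not self.individuals:
            raise ValidationError("StudyConfig: individuals is empty")


@dataclass
class DailyAllocation:
    """Where one individual spent one day, and how much of it inside.

    ``a`` is the daytime fraction inside the allocated bay (0 when the
    stratum is outside); ``b = 1 - a`` exactly.
    """

    individual_id: str
    date: _dt.date
    stratum: str
    a: float | None = None

    @property
    def b(self) -> float | None:
        return None if self.a is None else 1.0 - self.a


@dataclass(frozen=True)
class CumulativeBudget:
    """One individual's activity budget integrated over the study period."""

    individual_id: str
    p_rest: float
    p_social: float
    p_travel: float
    total_minutes: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_rest, self.p_social, self.p_travel], float)


def allocate_day(
    individual: str,
    date: _dt.date,
    matrix: OccurrenceMatrix,
    acoustic_status: dict[tuple[str, _dt.date], str],
    presence_probs: dict[str, float],
    rng: np.random.Generator,
) -> DailyAllocation:
    """Draw the day's bay and apply the acoustic gate.

    The bay is drawn from the individual's allocation probabilities, then the
    (bay, date) acoustic status is consulted: ABSENT sends the individual
    outside; MISSING triggers a Bernoulli presence draw at the bay's
    observed presence rate.  ``a`` is left unset.
    """
    if individual not in matrix.probs.index:
        raise ValidationError(f"allocate_day: unknown individual {individual!r}")
    probs = matrix.probs.loc[individual].to_numpy(float)
    bay = matrix.bays[rng.choice(len(probs), p=probs)]
    status = acoustic_status.get((bay, date), "MISSING")
    if status == "ABSENT":
        return DailyAllocation(individual, date, OUTSIDE)
    if status == "MISSING" and rng.random() >= presence_probs[bay]:
        return DailyAllocation(individual, date, OUTSIDE)
    return DailyAllocation(individual, date, bay)


def draw_time_inside(
    allocation: DailyAllocation,
    dist: TimeInsideDistribution | None,
    rng: np.random.Generator,
) -> DailyAllocation:
    """Fill ``a`` by resampling the bay's empirical time-inside sample.

    Outside allocations get ``a = 0`` and need no distribution.
    """
    if allocation.stratum == OUTSIDE:
        allocation.a = 0.0
        return allocation
    if dist is None or len(dist.values) == 0:
        raise CoverageError(
            f"draw_time_inside: no time-inside distribution for bay "
            f"{allocation.stratum!r}"
        )
    allocation.a = float(dist.values[rng.integers(0, len(dist.values))])
    return allocation


def daily_budget(
    allocation: DailyAllocation,
    bay_budget_draw: ActivityBudget,
    outside_budget_draw: ActivityBudget,
) -> ActivityBudget:
    """Mix the bay and outside budget draws by time shares:
    ``a * bay + b * outside`` componentwise (a convex combination, so the
    result is itself a valid budget)."""
    if allocation.a is None:
        raise ValidationError("daily_budget: allocation has no time-inside draw")
    a = allocation.a
    mixed = a * bay_budget_draw.as_array() + (1.0 - a) * outside_budget_draw.as_array()
    return ActivityBudget.from_array(mixed)


def _check_coverage(
    matrix: OccurrenceMatrix,
    budget_dists: dict[str, BudgetDistribution],
    time_dists: dict[str, TimeInsideDistribution],
) -> None:
    reachable = [b for b in matrix.bays if (matrix.counts[b] > 0).any()]
    missing_budget = [b for b in reachable if b not in budget_dists]
    missing_time = [b for b in reachable if b not in time_dists]
    problems = []
    if OUTSIDE not in budget_dists:
        problems.append(f"no budget distribution for {OUTSIDE}")
    if missing_budget:
        problems.append(f"no budget distribution for reachable bay(s) {missing_budget}")
    if missing_time:
        problems.append(
            f"no time-inside distribution for reachable bay(s) {missing_time}"
        )
    if problems:
        raise CoverageError("simulate_study: " + "; ".join(problems))


def simulate_study(
    config: StudyConfig,
    matrix: OccurrenceMatrix,
    acoustic: pd.DataFrame,
    budget_dists: dict[str, BudgetDistribution],
    time_dists: dict[str, TimeInsideDistribution],
    presence_probs: dict[str, float] | None = None,
    return_daily: bool = True,
) -> tuple[list[CumulativeBudget], pd.DataFrame | None]:
    """Run the full allocation-gating-mixing chain for every individual-day.

    Draws are vectorised per individual across the day axis, in a fixed
    order (bay allocation, presence imputation, time inside, bay replicate
    index, outside replicate index), so a given (config, seed) always
    produces byte-identical output.

    Returns the per-individual cumulative budgets and, unless
    ``return_daily=False``, a log with one row per individual-day
    (stratum, a, b and the mixed daily budget).
    """
    from .ingest import presence_probability

    _check_coverage(matrix, budget_dists, time_dists)
    bays = matrix.bays
    n_days = len(config.study_days)
    day_index = {d: j for j, d in enumerate(config.study_days)}

    # (bay, day) status codes: 1 PRESENT, 0 ABSENT, -1 MISSING
    code = {"PRESENT": 1, "ABSENT": 0, "MISSING": -1}
    status = np.full((len(bays), n_days), -1, dtype=np.int8)
    bay_row = {b: i for i, b in enumerate(bays)}
    for b, d, s in acoustic[["bay", "date", "status"]].itertuples(index=False):
        j = day_index.get(d)
        if j is not None and b in bay_row:
            status[bay_row[b], j] = code[s]

    if presence_probs is None:
        presence_probs = {b: presence_probability(acoustic, b) for b in bays}
    p_present = np.array([presence_probs[b] for b in bays], float)

    # pre-fetch per-bay empirical samples and replicate arrays
    a_samples = [
        time_dists[b].values if b in time_dists else np.empty(0) for b in bays
    ]
    bay_reps = [
        budget_dists[b].replicates if b in budget_dists else np.empty((0, 3))
        for b in bays
    ]
    out_reps = budget_dists[OUTSIDE].replicates

    rng = np.random.default_rng(config.seed)
    days_arange = np.arange(n_days)
    results: list[CumulativeBudget] = []
    log_frames = []
    total_minutes = float(n_days * config.daytime_minutes)

    for ind in config.individuals:
        if ind not in matrix.probs.index:
            raise ValidationError(f"simulate_study: unknown individual {ind!r}")
        probs = matrix.probs.loc[ind].to_numpy(float)
        bay_idx = rng.choice(len(bays), size=n_days, p=probs)
        u_presence = rng.random(n_days)
        u_a = rng.random(n_days)
        u_bay_rep = rng.random(n_days)
        u_out_rep = rng.random(n_days)

        st = status[bay_idx, days_arange]
        present = (st == 1) | ((st == -1) & (u_presence < p_present[bay_idx]))

        a = np.zeros(n_days)
        daily = np.empty((n_days, 3))
        out_draw = out_reps[(u_out_rep * len(out_reps)).astype(int)]
        daily[:] = out_draw  # a=0 rows are pure outside budget
        for bi in np.unique(bay_idx[present]):
            sel = present & (bay_idx == bi)
            sample = a_samples[bi]
            reps = bay_reps[bi]
            a[sel] = sample[(u_a[sel] * len(sample)).astype(int)]
            bay_draw = reps[(u_bay_rep[sel] * len(reps)).astype(int)]
            daily[sel] = (
                a[sel, None] * bay_draw + (1.0 - a[sel, None]) * out_draw[sel]
            )

        # every daily budget is a convex mixture of valid budgets
        assert np.allclose(daily.sum(axis=1), 1.0, atol=1e-9)
        cum = daily.mean(axis=0)
        results.append(
            CumulativeBudget(ind, cum[0], cum[1], cum[2], total_minutes)
        )
        if return_daily:
            strata = np.where(present, np.asarray(bays, object)[bay_idx], OUTSIDE)
            log_frames.append(
                pd.DataFrame(
                    {
                        "individual_id": ind,
                        "date": config.study_days,
                        "stratum": strata,
                        "a": a,
                        "b": 1.0 - a,
                        "p_rest": daily[:, 0],
                        "p_social": daily[:, 1],
                        "p_travel": daily[:, 2],
                    }
                )
            )

    daily_log = pd.concat(log_frames, ignore_index=True) if return_daily else None
    return results, daily_log


def summarize_population(budgets: list[CumulativeBudget]) -> pd.DataFrame:
    """Across-individual mean, sample s.d., min and max per activity state,
    as percentages of daytime."""
    if len(budgets) < 2:
        raise ValidationError("summarize_population: need at least 2 individuals")
    arr = np.stack([b.as_array() for b in budgets]) * 100.0
    return pd.DataFrame(
        {
            "state": ["rest", "social", "travel"],
            "mean_pct": arr.mean(axis=0),
            "sd_pct": arr.std(axis=0, ddof=1),
            "min_pct": arr.min(axis=0),
            "max_pct": arr.max(axis=0),
        }
    )


def cumulative_table(budgets: list[CumulativeBudget]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [b.individual_id for b in budgets],
            "p_rest": [b.p_rest for b in budgets],
            "p_social": [b.p_social for b in budgets],
            "p_travel": [b.p_travel for b in budgets],
        }
    )
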