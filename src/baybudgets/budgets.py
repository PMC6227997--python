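"""Stratum activity budgets from scan samples.

An activity budget is the proportion of observation time a dolphin group
spends resting, socialising and travelling.  Because scans are instantaneous
samples on a fixed 10-minute grid, every "proportion of time" here is a
scan-count ratio.  Uncertainty is carried as a nonparametric bootstrap: the
observed activity states in a stratum are resampled with replacement and the
budget recomputed, B times (default 1000), giving a density distribution of
budgets per stratum from which the simulation later draws.

The same scan data also yield, per bay, the empirical distribution of the
proportion of daytime a followed group spent inside the bay (one value per
follow touching the bay).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ACTIVITY_STATES,
    DAYTIME_MINUTES,
    OUTSIDE,
    SCAN_INTERVAL_MIN,
    ValidationError,
)

_STATE_INDEX = {s: i for i, s in enumerate(ACTIVITY_STATES)}


@dataclass(frozen=True)
class ActivityBudget:
    """Proportions of time in each activity state; components sum to 1."""

    p_rest: float
    p_social: float
    p_travel: float

    def __post_init__(self):
        arr = self.as_array()
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValidationError(f"budget components outside [0,1]: {arr}")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValidationError(f"budget components sum to {arr.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_rest, self.p_social, self.p_travel], float)

    @classmethod
    def from_array(cls, arr) -> "ActivityBudget":
        return cls(float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass(frozen=True)
class BudgetDistribution:
    """Bootstrap density distribution of a stratum's activity budget.

    ``replicates`` is a (B, 3) array of [rest, social, travel] proportions,
    each row a valid budget; ``n_scans`` is the source sample size.
    """

    stratum: str
    replicates: np.ndarray
    n_scans: int

    @property
    def B(self) -> int:
        return self.replicates.shape[0]

    def point(self) -> ActivityBudget:
        return ActivityBudget.from_array(self.replicates.mean(axis=0))


@dataclass(frozen=True)
class TimeInsideDistribution:
    """Empirical sample of the daytime fraction spent inside one bay.

    One value per focal follow that touched the bay:
    ``10 min x (scans located inside) / daytime_minutes``, clipped to [0, 1].
    """

    bay: str
    values: np.ndarray

    def __post_init__(self):
        if len(self.values) == 0:
            raise ValidationError(f"time-inside sample for {self.bay!r} is empty")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValidationError(f"time-inside values outside [0,1] for {self.bay!r}")

    def mean(self) -> float:
        return float(self.values.mean())


def _stratum_scans(
    scans: pd.DataFrame, stratum: str, platform: str | None = None
) -> pd.DataFrame:
    sub = scans[scans["location"] == stratum]
    if platform is not None:
        sub = sub[sub["platform"] == platform]
    return sub


def point_budget(
    scans: pd.DataFrame, stratum: str, platform: str | None = None
) -> ActivityBudget:
    """Point estimate of the stratum budget: state counts / total scans.

    ``platform`` optionally restricts to BOAT or LAND scans; by default
    platforms are pooled within the stratum.
    """
    sub = _stratum_scans(scans, stratum, platform)
    if len(sub) == 0:
        raise ValidationError(f"point_budget: no scans in stratum {stratum!r}")
    counts = sub["activity"].value_counts()
    total = len(sub)
    return ActivityBudget(
        *(counts.get(s, 0) / total for s in ACTIVITY_STATES)
    )


def bootstrap_budget(
    scans: pd.DataFrame,
    stratum: str,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    platform: str | None = None,
) -> BudgetDistribution:
    """Bootstrap the stratum budget: resample the n observed activity states
    with replacement, recompute the budget, repeat B times."""
    if B < 1:
        raise ValidationError(f"bootstrap_budget: B must be >= 1, got {B}")
    sub = _stratum_scans(scans, stratum, platform)
    n = len(sub)
    if n == 0:
        raise ValidationError(f"bootstrap_budget: no scans in stratum {stratum!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    states = sub["activity"].map(_STATE_INDEX).to_numpy()
    draws = rng.integers(0, n, size=(B, n))
    resampled = states[draws]  # (B, n) state indices
    replicates = np.stack(
        [(resampled == i).mean(axis=1) for i in range(len(ACTIVITY_STATES))],
        axis=1,
    )
    return BudgetDistribution(stratum=stratum, replicates=replicates, n_scans=n)


def time_inside_distribution(
    scans: pd.DataFrame, bay: str, daytime_minutes: int = DAYTIME_MINUTES
) -> TimeInsideDistribution:
    """Per-follow daytime fractions spent inside ``bay``.

    Each follow with at least one scan located inside the bay contributes
    one value: its inside-scan count x 10 min over the daytime window,
    clipped to 1 if a follow ran longer than the window.  Follows that never
    touched the bay contribute nothing.
    """
    if bay == OUTSIDE:
        raise ValidationError("time_inside_distribution is defined per bay only")
    inside = scans[scans["location"] == bay]
    if len(inside) == 0:
        raise ValidationError(
            f"time_inside_distribution: no follow touches bay {bay!r}; "
            "supply a configured fallback sample"
        )
    per_follow = inside.groupby("follow_id").size()
    values = np.clip(
        per_follow.to_numpy(float) * SCAN_INTERVAL_MIN / daytime_minutes, 0.0, 1.0
    )
    return TimeInsideDistribution(bay=bay, values=values)


def budget_table(dists: dict[str, BudgetDistribution]) -> pd.DataFrame:
    """Flatten point estimates of per-stratum distributions for CSV output."""
    rows = []
    for stratum, dist in dists.items():
        b = dist.point()
        rows.append(
            {
                "stratum": stratum,
                "p_rest": b.p_rest,
                "p_social": b.p_social,
                "p_travel": b.p_travel,
                "n_scans": dist.n_scans,
            }
        )
    return pd.DataFrame(rows)


def replicate_table(dists: dict[str, BudgetDistribution]) -> pd.DataFrame:
    """All bootstrap replicates, one row per (stratum, replicate)."""
    frames = []
    for stratum, dist in dists.items():
        frames.append(
            pd.DataFrame(
                {
                    "stratum": stratum,
                    "replicate": np.arange(dist.B),
                    "p_rest": dist.replicates[:, 0],
                    "p_social": dist.replicates[:, 1],
                    "p_travel": dist.replicates[:, 2],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
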