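"""Human-exposure metrics from focal-follow scans.

Each scan is classified *approached* if any boat, kayak or swimmer is within
100 m of the focal group (the impact criterion), otherwise *unapproached*
(control).  Within each follow, maximal runs of identical exposure state
form intervals; their durations (10 min per scan) are the basis for the
frequency histograms and medians of approached / unapproached situation
lengths.  A gap of more than 1.5x the nominal scan spacing inside a follow
breaks the run, so continuity is never fabricated across observation
dropouts; boundary runs are flagged as censored because the true situation
extended beyond the observation window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SCAN_INTERVAL_MIN, ValidationError

APPROACHED = "APPROACHED"
UNAPPROACHED = "UNAPPROACHED"

#: a within-follow time gap above this multiple of the nominal interval
#: breaks a run into censored pieces
GAP_BREAK_FACTOR = 1.5


@dataclass(frozen=True)
class ExposureInterval:
    """A maximal run of scans in one exposure state within one follow."""

    follow_id: str
    state: str
    n_scans: int
    left_censored: bool
    right_censored: bool

    @property
    def duration_minutes(self) -> int:
        return self.n_scans * SCAN_INTERVAL_MIN


def classify_scan(n_boats: int, n_kayaks: int, n_swimmers: int) -> str:
    """APPROACHED iff at least one boat, kayak or swimmer is within 100 m."""
    if min(n_boats, n_kayaks, n_swimmers) < 0:
        raise ValidationError("classify_scan: negative count")
    return APPROACHED if (n_boats + n_kayaks + n_swimmers) >= 1 else UNAPPROACHED


def _scan_states(scans: pd.DataFrame) -> np.ndarray:
    total = (
        scans["n_boats"].to_numpy()
        + scans["n_kayaks"].to_numpy()
        + scans["n_swimmers"].to_numpy()
    )
    return np.where(total >= 1, APPROACHED, UNAPPROACHED)


def extract_runs(scans: pd.DataFrame, follow_id: str) -> list[ExposureInterval]:
    """Run-length encode one follow's exposure states in timestamp order.

    The follow's first and last intervals are left-/right-censored; a
    within-follow gap larger than 1.5x the nominal spacing also censors the
    abutting interval ends.
    """
    sub = scans[scans["follow_id"] == follow_id].sort_values("timestamp")
    if len(sub) == 0:
        raise ValidationError(f"extract_runs: unknown follow {follow_id!r}")
    states = _scan_states(sub)
    times = sub["timestamp"].to_numpy()
    gap_limit = np.timedelta64(
        int(GAP_BREAK_FACTOR * SCAN_INTERVAL_MIN * 60), "s"
    )
    # boundaries where state changes or the record gaps out
    breaks_gap = np.zeros(len(sub), bool)
    if len(sub) > 1:
        breaks_gap[1:] = np.diff(times) > gap_limit
    new_run = np.zeros(len(sub), bool)
    new_run[0] = True
    new_run[1:] = (states[1:] != states[:-1]) | breaks_gap[1:]

    starts = np.flatnonzero(new_run)
    ends = np.append(starts[1:], len(sub))
    intervals = []
    for k, (s, e) in enumerate(zip(starts, ends)):
        left = (k == 0) or breaks_gap[s]
        right = (e == len(sub)) or breaks_gap[e] if e < len(sub) else True
        intervals.append(
            ExposureInterval(
                follow_id=follow_id,
                state=str(states[s]),
                n_scans=int(e - s),
                left_censored=bool(left),
                right_censored=bool(right),
            )
        )
    return intervals


def extract_all_runs(scans: pd.DataFrame) -> pd.DataFrame:
    """Intervals for every follow, flattened to a DataFrame with the
    follow's platform attached."""
    platform = scans.groupby("follow_id")["platform"].first()
    rows = []
    for fid in scans["follow_id"].unique():
        for iv in extract_runs(scans, fid):
            rows.append(
                {
                    "follow_id": iv.follow_id,
                    "platform": platform[fid],
                    "state": iv.state,
                    "n_scans": iv.n_scans,
                    "duration_minutes": iv.duration_minutes,
                    "left_censored": iv.left_censored,
                    "right_censored": iv.right_censored,
                }
            )
    return pd.DataFrame(rows)


def exposure_proportion(
    scans: pd.DataFrame, platform_filter: str | None = None
) -> float:
    """Fraction of scans with any human activity within 100 m."""
    sub = scans if platform_filter is None else scans[scans["platform"] == platform_filter]
    if len(sub) == 0:
        raise ValidationError("exposure_proportion: empty scan selection")
    return float((_scan_states(sub) == APPROACHED).mean())


def control_fraction(scans: pd.DataFrame, platform: str) -> float:
    """Fraction of a platform's scans that are unapproached (control data)."""
    sub = scans[scans["platform"] == platform]
    if len(sub) == 0:
        raise ValidationError(f"control_fraction: no scans on platform {platform!r}")
    return float((_scan_states(sub) == UNAPPROACHED).mean())


def interval_summary(
    intervals: pd.DataFrame, include_censored: bool = True
) -> pd.DataFrame:
    """Median interval duration per (state, platform) cell.

    Cells with no intervals are simply absent from the output.  Even-count
    medians are the mean of the two middle values.  ``include_censored=False``
    drops intervals that abut a follow boundary or an observation gap.
    """
    sub = intervals
    if not include_censored:
        sub = sub[~(sub["left_censored"] | sub["right_censored"])]
    if len(sub) == 0:
        return pd.DataFrame(
            columns=["state", "platform", "n_intervals", "median_minutes"]
        )
    out = (
        sub.groupby(["state", "platform"])["duration_minutes"]
        .agg(n_intervals="size", median_minutes="median")
        .reset_index()
    )
    return out


def duration_histogram(
    intervals: pd.DataFrame, bin_minutes: int = SCAN_INTERVAL_MIN
) -> pd.DataFrame:
    """Histogram counts of interval durations at 10-minute bins, per
    (state, platform)."""
    df = intervals.copy()
    # left-closed bins [k*bin, (k+1)*bin); durations are exact multiples of
    # the scan interval, so with the default bin width each duration maps to
    # its own bin
    df["bin_start_min"] = (df["duration_minutes"] // bin_minutes) * bin_minutes
    out = (
        df.groupby(["state", "platform", "bin_start_min"])
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def per_type_exposure(scans: pd.DataFrame) -> pd.DataFrame:
    """Descriptive per-activity-type exposure: fraction of scans with at
    least one boat / kayak / swimmer, per location."""
    rows = []
    for loc, sub in scans.groupby("location"):
        rows.append(
            {
                "location": loc,
                "n_scans": len(sub),
                "frac_boats": float((sub["n_boats"] >= 1).mean()),
                "frac_kayaks": float((sub["n_kayaks"] >= 1).mean()),
                "frac_swimmers": float((sub["n_swimmers"] >= 1).mean()),
            }
        )
    return pd.DataFrame(rows)
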