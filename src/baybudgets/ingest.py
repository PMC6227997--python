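"""Reading and validating the three input data streams.

Three tabular streams feed the cumulative-budget model:

* **sightings** — photo-identification records, one row per
  (individual, date, bay): which catalogued individuals were photographed in
  which bay on which survey day.
* **acoustic** — daily presence calls from bottom-mounted recorders, one row
  per (bay, date) with a tri-state status (PRESENT / ABSENT / MISSING).
* **scans** — instantaneous scan samples from group focal follows, one row
  per 10-minute scan with the predominant group activity and counts of
  boats, kayaks and swimmers within 100 m.

All three are plain UTF-8 CSV with a mandatory header row and are held
in-memory as pandas DataFrames.  This module also derives the two summaries
of the sighting data that parameterise the simulation: the per-individual
occurrence matrix (bay-allocation probabilities) and per-bay presence
probabilities from the acoustic record.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ACOUSTIC_STATUSES,
    ACTIVITY_STATES,
    OUTSIDE,
    PLATFORMS,
    ValidationError,
    logger,
    round_half_up,
)

SIGHTING_COLUMNS = ["individual_id", "date", "bay"]
ACOUSTIC_COLUMNS = ["bay", "date", "status"]
SCAN_COLUMNS = [
    "follow_id",
    "timestamp",
    "platform",
    "location",
    "activity",
    "n_boats",
    "n_kayaks",
    "n_swimmers",
]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}")


def _parse_dates(series: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    if parsed.isna().any():
        bad = series[parsed.isna()].iloc[0]
        raise ValidationError(f"{what}: unparseable ISO date {bad!r}")
    return parsed.dt.date


def read_sightings(path, bays: Sequence[str]) -> pd.DataFrame:
    """Read and validate a photo-ID sighting table.

    Parameters
    ----------
    path
        CSV with columns ``individual_id,date,bay``.
    bays
        The configured bay identifiers; any other bay value (including the
        reserved outside sentinel) is a hard error.

    Returns
    -------
    DataFrame with columns individual_id (str), date (datetime.date), bay
    (str), deduplicated on all three columns and sorted.  A dolphin
    photographed twice in the same bay on the same day is one sighting-day.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, SIGHTING_COLUMNS, "sightings")
    df = df[SIGHTING_COLUMNS].copy()
    bays = list(bays)
    bad = ~df["bay"].isin(bays)
    if bad.any():
        row = df[bad].iloc[0]
        raise ValidationError(
            f"sightings: unknown bay {row['bay']!r} "
            f"(individual {row['individual_id']!r}, date {row['date']!r}); "
            f"configured bays: {bays}"
        )
    df["date"] = _parse_dates(df["date"], "sightings")
    n_before = len(df)
    df = df.drop_duplicates(SIGHTING_COLUMNS, ignore_index=True)
    if len(df) < n_before:
        logger.warning(
            "sightings: collapsed %d duplicate (individual, date, bay) rows",
            n_before - len(df),
        )
    return df.sort_values(SIGHTING_COLUMNS, ignore_index=True)


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Per-individual bay sighting counts and derived allocation probabilities.

    ``counts`` and ``probs`` are DataFrames indexed by individual_id with one
    column per configured bay.  Each row of ``probs`` is
    ``count / row total`` — the relative occurrence of that individual across
    bays, used as its daily bay-allocation distribution.  Rows sum to 1; a
    probability is 0 exactly when the count is 0.
    """

    counts: pd.DataFrame
    probs: pd.DataFrame

    @property
    def individuals(self) -> list[str]:
        return list(self.counts.index)

    @property
    def bays(self) -> list[str]:
        return list(self.counts.columns)


def occurrence_matrix(sightings: pd.DataFrame, bays: Sequence[str]) -> OccurrenceMatrix:
    """Tally sighting-days per (individual, bay) and normalise to probabilities."""
    if len(sightings) == 0:
        raise ValidationError("occurrence_matrix: empty sighting table")
    counts = (
        sightings.groupby(["individual_id", "bay"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(bays), fill_value=0)
    )
    counts.columns.name = None
    totals = counts.sum(axis=1)
    probs = counts.div(totals, axis=0)
    return OccurrenceMatrix(counts=counts, probs=probs)


def bay_use_summary(matrix: OccurrenceMatrix) -> pd.DataFrame:
    """Percentage of catalogued individuals documented at least once per bay.

    Returns one row per bay with the individual count, the unrounded
    percentage and the half-up-rounded percentage.  Percentages need not sum
    to 100 because individuals use multiple bays.
    """
    n_total = len(matrix.counts)
    n_per_bay = (matrix.counts >= 1).sum(axis=0)
    pct = 100.0 * n_per_bay / n_total
    return pd.DataFrame(
        {
            "bay": matrix.bays,
            "n_individuals": n_per_bay.to_numpy(),
            "pct": pct.to_numpy(),
            "pct_rounded": [round_half_up(p) for p in pct],
        }
    )


def read_acoustic(
    path, bays: Sequence[str], study_days: Sequence[_dt.date]
) -> pd.DataFrame:
    """Read daily acoustic presence calls and fill gaps with MISSING.

    Every (bay, study day) pair resolves to exactly one of
    PRESENT / ABSENT / MISSING; days absent from the file are MISSING (the
    recorder produced nothing usable that day).
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ACOUSTIC_COLUMNS, "acoustic")
    df = df[ACOUSTIC_COLUMNS].copy()
    bays = list(bays)
    bad = ~df["bay"].isin(bays)
    if bad.any():
        raise ValidationError(
            f"acoustic: unknown bay {df[bad].iloc[0]['bay']!r}; configured bays: {bays}"
        )
    bad_status = ~df["status"].isin(ACOUSTIC_STATUSES)
    if bad_status.any():
        raise ValidationError(
            f"acoustic: unknown status token {df[bad_status].iloc[0]['status']!r}; "
            f"expected one of {ACOUSTIC_STATUSES}"
        )
    df["date"] = _parse_dates(df["date"], "acoustic")
    dup = df.duplicated(["bay", "date"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"acoustic: duplicate record for bay {row['bay']!r} on {row['date']}"
        )
    full = pd.MultiIndex.from_product(
        [bays, list(study_days)], names=["bay", "date"]
    ).to_frame(index=False)
    out = full.merge(df, on=["bay", "date"], how="left")
    out["status"] = out["status"].fillna("MISSING")
    return out.sort_values(["bay", "date"], ignore_index=True)


def presence_probability(acoustic: pd.DataFrame, bay: str) -> float:
    """Observed daily presence rate for a bay: #PRESENT / #non-MISSING days.

    Used to impute presence by a Bernoulli draw on days with no usable
    recording.
    """
    sub = acoustic.loc[acoustic["bay"] == bay, "status"]
    n_obs = int((sub != "MISSING").sum())
    if n_obs == 0:
        raise ValidationError(
            f"presence_probability: bay {bay!r} has no non-MISSING days; "
            "supply a prior presence probability via configuration"
        )
    return float((sub == "PRESENT").sum()) / n_obs


def read_scans(path, bays: Sequence[str]) -> pd.DataFrame:
    """Read and validate focal-follow scan samples.

    Scans are sorted by (follow_id, timestamp).  Timestamps must be strictly
    increasing within a follow; gaps larger than the nominal 10-minute
    spacing are allowed here (run extraction treats large gaps as breaks).
    Single-scan follows are retained with a log message.
    """
    df = pd.read_csv(
        path,
        dtype={
            "follow_id": str,
            "platform": str,
            "location": str,
            "activity": str,
        },
    )
    _require_columns(df, SCAN_COLUMNS, "scans")
    df = df[SCAN_COLUMNS].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce")
    if df["timestamp"].isna().any():
        raise ValidationError("scans: unparseable timestamp")

    valid_locations = set(bays) | {OUTSIDE}
    bad = ~df["location"].isin(valid_locations)
    if bad.any():
        raise ValidationError(
            f"scans: unknown location {df[bad].iloc[0]['location']!r}; "
            f"expected a configured bay or {OUTSIDE!r}"
        )
    bad = ~df["activity"].isin(ACTIVITY_STATES)
    if bad.any():
        raise ValidationError(
            f"scans: unknown activity token {df[bad].iloc[0]['activity']!r}; "
            f"expected one of {ACTIVITY_STATES}"
        )
    bad = ~df["platform"].isin(PLATFORMS)
    if bad.any():
        raise ValidationError(
            f"scans: unknown platform {df[bad].iloc[0]['platform']!r}"
        )
    for col in ("n_boats", "n_kayaks", "n_swimmers"):
        counts = pd.to_numeric(df[col], errors="coerce")
        if counts.isna().any() or (counts < 0).any() or (counts % 1 != 0).any():
            raise ValidationError(f"scans: {col} must be a non-negative integer")
        df[col] = counts.astype(int)

    df = df.sort_values(["follow_id", "timestamp"], ignore_index=True)
    # strictly increasing timestamps within each follow
    deltas = df.groupby("follow_id")["timestamp"].diff()
    if (deltas <= pd.Timedelta(0)).any():
        fid = df.loc[deltas <= pd.Timedelta(0), "follow_id"].iloc[0]
        raise ValidationError(
            f"scans: non-increasing timestamps within follow {fid!r}"
        )
    sizes = df.groupby("follow_id").size()
    singletons = sizes[sizes == 1]
    if len(singletons):
        logger.info(
            "scans: retained %d single-scan follow(s): %s",
            len(singletons),
            list(singletons.index[:5]),
        )
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write any of the three tables back to CSV (round-trip safe)."""
    df.to_csv(path, index=False)
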