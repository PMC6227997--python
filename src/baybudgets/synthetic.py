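"""Synthetic three-stream datasets with known ground truth.

The generator emulates the structure of the field study — a closed catalogue
of individuals with heterogeneous bay affinities, four resting bays
monitored acoustically every day, and boat-/land-based focal follows
producing 10-minute scan samples — while keeping every generating parameter
explicit, so the whole estimation pipeline can be tested for parameter
recovery without any field data.

Latent truth per day: each individual either skips the bays entirely (with a
small direct-outside probability) or picks a bay from its personal affinity
vector; if the chosen bay has no dolphins that day (bay-day presence is
Bernoulli per bay), the individual ends up outside.  Surveyed bay-days then
yield photo-ID sightings (flat detection probability), every bay-day yields
an acoustic call (with a configurable missing-data rate), and follows yield
scans whose activity states are drawn from the stratum's true budget and
whose approached/unapproached sequence follows a two-state Markov chain.

The direct-outside days are a deliberate mismatch with the estimation model,
which only ever places individuals outside via the acoustic gate; tests use
it to quantify the resulting occupancy bias.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .budgets import ActivityBudget
from .core import (
    ACTIVITY_STATES,
    DAYTIME_MINUTES,
    DEFAULT_BAYS,
    OUTSIDE,
    SCAN_INTERVAL_MIN,
    ConfigError,
)

#: bays with clifftop vantage points allowing land-based (theodolite) follows
LAND_CAPABLE_BAYS = ("Kealakekua", "Kauhako")

_DEFAULT_TRUE_BUDGETS = {
    "Makako": (0.726, 0.190, 0.084),
    "Kealakekua": (0.62, 0.33, 0.05),
    "Honaunau": (0.61, 0.34, 0.05),
    "Kauhako": (0.63, 0.32, 0.05),
    OUTSIDE: (0.35, 0.35, 0.30),
}

_DEFAULT_TIME_INSIDE_BETA = {
    "Makako": (8.0, 2.0),
    "Kealakekua": (7.0, 3.0),
    "Honaunau": (6.0, 4.0),
    "Kauhako": (7.0, 3.0),
}


@dataclass
class GeneratorConfig:
    """All generating parameters, defaulting to the study's scale.

    Defaults: 235 catalogued individuals, 4 bays, 601 consecutive study
    days, per-bay daily presence probabilities 0.90/0.65/0.37/0.51, a
    monthly survey cadence of 2/4/2/4 days per bay, and an approach chain
    whose stationary approached fraction is
    ``(1-q_u) / ((1-q_u) + (1-q_a))`` for stay probabilities ``q_a``
    (approached) and ``q_u`` (unapproached) — 0.833 at the defaults.
    """

    n_individuals: int = 235
    bays: tuple[str, ...] = DEFAULT_BAYS
    n_days: int = 601
    start_date: _dt.date = _dt.date(2011, 1, 1)
    seed: int = 0

    #: Dirichlet concentrations for per-individual bay affinities; the
    #: skewed defaults make most individuals favour the first bay, mirroring
    #: the observed concentration of the catalogue in one bay.
    affinity_alpha: tuple[float, ...] = (2.0, 0.8, 0.7, 0.5)
    #: probability an individual skips the bays entirely on a given day
    p_outside_day: float = 0.10
    #: per-bay daily probability that any dolphins are present
    presence_probs: tuple[float, ...] = (0.90, 0.65, 0.37, 0.51)
    #: per-stratum true activity budgets (rest, social, travel)
    true_budgets: dict = field(
        default_factory=lambda: dict(_DEFAULT_TRUE_BUDGETS)
    )
    #: per-bay Beta(alpha, beta) for the daytime fraction spent inside
    time_inside_beta: dict = field(
        default_factory=lambda: dict(_DEFAULT_TIME_INSIDE_BETA)
    )
    #: approach-chain stay probabilities
    stay_approached: float = 0.9
    stay_unapproached: float = 0.5
    #: optional activity-state persistence (stay probability of a two-state
    #: "repeat last state" mixture); None = states i.i.d. within a follow
    activity_persistence: float | None = None

    #: survey days per month per bay (same cadence every month)
    survey_days_per_month: dict = field(
        default_factory=lambda: {
            "Makako": 2,
            "Kealakekua": 4,
            "Honaunau": 2,
            "Kauhako": 4,
        }
    )
    #: probability a surveyed bay-day also yields a focal follow
    p_follow_per_survey_day: float = 0.4
    #: probability a surveyed day yields an additional follow outside bays
    p_outside_follow_per_survey_day: float = 0.15
    #: lognormal parameters (of scan count) for outside-follow length
    outside_follow_lognorm: tuple[float, float] = (2.9, 0.5)
    #: probability an individual present in a surveyed bay is photographed
    detection_prob: float = 0.9
    #: probability a bay-day acoustic record is unusable (MISSING)
    missing_rate: float = 0.107

    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_days < 1:
            raise ConfigError("n_individuals and n_days must be positive")
        if len(self.presence_probs) != len(self.bays) or len(
            self.affinity_alpha
        ) != len(self.bays):
            raise ConfigError(
                "presence_probs and affinity_alpha must match the bay list"
            )
        probs = list(self.presence_probs) + [
            self.p_outside_day,
            self.stay_approached,
            self.stay_unapproached,
            self.detection_prob,
            self.missing_rate,
            self.p_follow_per_survey_day,
            self.p_outside_follow_per_survey_day,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        for stratum in list(self.bays) + [OUTSIDE]:
            if stratum not in self.true_budgets:
                raise ConfigError(f"true_budgets missing stratum {stratum!r}")
            ActivityBudget(*self.true_budgets[stratum])  # validates
        for bay in self.bays:
            a, b = self.time_inside_beta[bay]
            if a <= 0 or b <= 0:
                raise ConfigError(f"Beta parameters for {bay!r} must be positive")

    @property
    def study_days(self) -> list[_dt.date]:
        return [
            self.start_date + _dt.timedelta(days=i) for i in range(self.n_days)
        ]

    @property
    def exposure_stationary(self) -> float:
        p_enter = 1.0 - self.stay_unapproached  # U -> A
        p_leave = 1.0 - self.stay_approached  # A -> U
        return p_enter / (p_enter + p_leave)


@dataclass(frozen=True)
class GroundTruth:
    """The generating quantities the pipeline should recover."""

    allocation_probs: pd.DataFrame  # individuals x bays, rows sum to 1
    true_budgets: dict
    mean_time_inside: dict  # bay -> Beta mean
    exposure_stationary: float
    presence_probs: dict
    p_outside_day: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "allocation_probs": {
                    ind: [float(x) for x in row]
                    for ind, row in self.allocation_probs.iterrows()
                },
                "true_budgets": {
                    k: list(map(float, v)) for k, v in self.true_budgets.items()
                },
                "mean_time_inside": {
                    k: float(v) for k, v in self.mean_time_inside.items()
                },
                "exposure_stationary": self.exposure_stationary,
                "presence_probs": {
                    k: float(v) for k, v in self.presence_probs.items()
                },
                "p_outside_day": self.p_outside_day,
            },
            indent=2,
        )


def _survey_calendar(config: GeneratorConfig) -> list[tuple[str, _dt.date]]:
    """Fixed monthly cadence: each bay surveyed on the same evenly spaced
    days-of-month, every month of the study period."""
    days = config.study_days
    by_month: dict[tuple[int, int], list[_dt.date]] = {}
    for d in days:
        by_month.setdefault((d.year, d.month), []).append(d)
    calendar = []
    for _, month_days in sorted(by_month.items()):
        for bay in config.bays:
            k = config.survey_days_per_month.get(bay, 0)
            if k < 1 or not month_days:
                continue
            idx = np.linspace(0, len(month_days) - 1, num=k).round().astype(int)
            for i in sorted(set(idx)):
                calendar.append((bay, month_days[i]))
    return calendar


def _markov_states(
    rng: np.random.Generator, n: int, p_start: float, stay_a: float, stay_u: float
) -> np.ndarray:
    """Boolean approached-sequence from the two-state chain, started from a
    Bernoulli(p_start) draw (the stationary distribution by default)."""
    out = np.empty(n, bool)
    u = rng.random(n)
    out[0] = u[0] < p_start
    for i in range(1, n):
        p_app = stay_a if out[i - 1] else (1.0 - stay_u)
        out[i] = u[i] < p_app
    return out


def _draw_activities(
    rng: np.random.Generator,
    n: int,
    budget: tuple[float, float, float],
    persistence: float | None,
) -> np.ndarray:
    p = np.asarray(budget, float)
    states = rng.choice(len(ACTIVITY_STATES), size=n, p=p)
    if persistence:
        repeat = rng.random(n) < persistence
        for i in range(1, n):
            if repeat[i]:
                states[i] = states[i - 1]
    return np.asarray(ACTIVITY_STATES, object)[states]


def _approach_counts(
    rng: np.random.Generator, approached: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(approached)
    boats = np.where(approached, rng.poisson(0.8, n), 0)
    kayaks = np.where(approached, rng.poisson(0.5, n), 0)
    swimmers = np.where(approached, rng.poisson(1.0, n), 0)
    # the approached criterion requires at least one platform within 100 m
    empty = approached & ((boats + kayaks + swimmers) == 0)
    swimmers = np.where(empty, 1, swimmers)
    return boats, kayaks, swimmers


def generate(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (sightings, acoustic, scans, ground truth) under ``config``.

    Fully reproducible: the same config (including its seed) always yields
    byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bays = list(config.bays)
    n_bays = len(bays)
    days = config.study_days
    n_days = config.n_days
    individuals = [f"ID{i + 1:04d}" for i in range(config.n_individuals)]

    # --- latent truth -----------------------------------------------------
    affinities = rng.dirichlet(config.affinity_alpha, size=config.n_individuals)
    bay_day_present = (
        rng.random((n_bays, n_days))
        < np.asarray(config.presence_probs)[:, None]
    )

    # per individual-day latent location: -1 = outside, else bay index
    latent = np.empty((config.n_individuals, n_days), dtype=np.int16)
    for i in range(config.n_individuals):
        u_out = rng.random(n_days)
        bay_choice = rng.choice(n_bays, size=n_days, p=affinities[i])
        loc = bay_choice.copy()
        loc[u_out < config.p_outside_day] = -1
        chosen_present = bay_day_present[bay_choice, np.arange(n_days)]
        loc[(loc >= 0) & ~chosen_present] = -1
        latent[i] = loc

    # --- photo-ID sightings ----------------------------------------------
    calendar = _survey_calendar(config)
    day_index = {d: j for j, d in enumerate(days)}
    srows = []
    for bay, date in calendar:
        j = day_index[date]
        bi = bays.index(bay)
        here = np.flatnonzero(latent[:, j] == bi)
        detected = here[rng.random(len(here)) < config.detection_prob]
        for i in detected:
            srows.append((individuals[i], date.isoformat(), bay))
    sightings = pd.DataFrame(srows, columns=["individual_id", "date", "bay"])
    sightings["date"] = pd.to_datetime(sightings["date"]).dt.date

    # --- acoustic calls ---------------------------------------------------
    arows = []
    for bi, bay in enumerate(bays):
        miss = rng.random(n_days) < config.missing_rate
        for j, d in enumerate(days):
            status = (
                "MISSING"
                if miss[j]
                else ("PRESENT" if bay_day_present[bi, j] else "ABSENT")
            )
            arows.append((bay, d, status))
    acoustic = pd.DataFrame(arows, columns=["bay", "date", "status"])

    # --- focal-follow scans ----------------------------------------------
    max_slots = DAYTIME_MINUTES // SCAN_INTERVAL_MIN  # 72
    q_a, q_u = config.stay_approached, config.stay_unapproached
    p_stat = config.exposure_stationary
    follow_counter = 0
    frames = []

    def _emit_follow(date, location, platform, n_scans, start_slot):
        nonlocal follow_counter
        follow_counter += 1
        fid = f"F{follow_counter:04d}"
        t0 = _dt.datetime.combine(date, _dt.time(6, 0)) + _dt.timedelta(
            minutes=SCAN_INTERVAL_MIN * start_slot
        )
        times = [
            t0 + _dt.timedelta(minutes=SCAN_INTERVAL_MIN * k)
            for k in range(n_scans)
        ]
        activities = _draw_activities(
            rng, n_scans, config.true_budgets[location], config.activity_persistence
        )
        approached = _markov_states(rng, n_scans, p_stat, q_a, q_u)
        boats, kayaks, swimmers = _approach_counts(rng, approached)
        frames.append(
            pd.DataFrame(
                {
                    "follow_id": fid,
                    "timestamp": times,
                    "platform": platform,
                    "location": location,
                    "activity": activities,
                    "n_boats": boats,
                    "n_kayaks": kayaks,
                    "n_swimmers": swimmers,
                }
            )
        )

    for bay, date in calendar:
        if rng.random() < config.p_follow_per_survey_day:
            a_beta, b_beta = config.time_inside_beta[bay]
            a_true = rng.beta(a_beta, b_beta)
            n_scans = int(np.clip(round(a_true * max_slots), 1, max_slots))
            start_slot = int(rng.integers(0, max_slots - n_scans + 1))
            platform = (
                "LAND"
                if bay in LAND_CAPABLE_BAYS and rng.random() < 0.5
                else "BOAT"
            )
            _emit_follow(date, bay, platform, n_scans, start_slot)
        if rng.random() < config.p_outside_follow_per_survey_day:
            mu, sigma = config.outside_follow_lognorm
            n_scans = int(np.clip(round(rng.lognormal(mu, sigma)), 1, max_slots))
            start_slot = int(rng.integers(0, max_slots - n_scans + 1))
            _emit_follow(date, OUTSIDE, "BOAT", n_scans, start_slot)

    scans = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "follow_id",
                "timestamp",
                "platform",
                "location",
                "activity",
                "n_boats",
                "n_kayaks",
                "n_swimmers",
            ]
        )
    )

    truth = GroundTruth(
        allocation_probs=pd.DataFrame(
            affinities, index=individuals, columns=bays
        ),
        true_budgets=dict(config.true_budgets),
        mean_time_inside={
            bay: ab[0] / (ab[0] + ab[1])
            for bay, ab in config.time_inside_beta.items()
        },
        exposure_stationary=p_stat,
        presence_probs=dict(zip(bays, config.presence_probs)),
        p_outside_day=config.p_outside_day,
    )
    return sightings, acoustic, scans, truth


def small_fixture() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """The deterministic toy dataset shipped with the package: 5 individuals,
    4 bays, 12 study days, 3 follows.  Used by unit tests and docs; its
    occurrence tallies are committed alongside as a hand-checked JSON."""
    base = resources.files("baybudgets").joinpath("data")
    from .ingest import read_acoustic, read_scans, read_sightings

    days = [_dt.date(2011, 1, 1) + _dt.timedelta(days=i) for i in range(12)]
    with resources.as_file(base.joinpath("fixture_sightings.csv")) as p:
        sightings = read_sightings(p, DEFAULT_BAYS)
    with resources.as_file(base.joinpath("fixture_acoustic.csv")) as p:
        acoustic = read_acoustic(p, DEFAULT_BAYS, days)
    with resources.as_file(base.joinpath("fixture_scans.csv")) as p:
        scans = read_scans(p, DEFAULT_BAYS)
    return sightings, acoustic, scans


def fixture_hand_tally() -> dict:
    """The committed hand tally for the toy dataset (occurrence counts and
    derived probabilities, counted manually from the CSV)."""
    base = resources.files("baybudgets").joinpath("data")
    return json.loads(base.joinpath("fixture_hand_tally.json").read_text())
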