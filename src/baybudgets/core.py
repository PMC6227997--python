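"""Shared constants, error classes and small helpers.

The package models daytime habitat use of a bay-resting dolphin population:
individuals rest in a handful of sheltered bays during the day and forage
offshore at night.  Everything downstream is organised around a small set of
strata — the configured bays plus a single "outside" stratum — and a fixed
instantaneous scan-sampling interval.
"""

from __future__ import annotations

import logging
import math

logger = logging.getLogger("baybudgets")

#: Reserved stratum for time spent outside any configured bay.  Never a valid
#: value in sighting or acoustic tables.
OUTSIDE = "OUTSIDE"

#: Default bay identifiers (Kona coast resting bays).
DEFAULT_BAYS = ("Makako", "Kealakekua", "Honaunau", "Kauhako")

#: Behavioural states recorded at each scan.
ACTIVITY_STATES = ("REST", "SOCIAL", "TRAVEL")

#: Observation platforms.
PLATFORMS = ("BOAT", "LAND")

#: Acoustic day statuses.
ACOUSTIC_STATUSES = ("PRESENT", "ABSENT", "MISSING")

#: Nominal scan-sampling interval in minutes: each instantaneous scan stands
#: for one 10-minute window.
SCAN_INTERVAL_MIN = 10

#: Daytime observation window, 06:00-18:00.
DAYTIME_MINUTES = 720


class BayBudgetsError(Exception):
    """Base class for all package errors."""


class ConfigError(BayBudgetsError):
    """Bad or unresolvable configuration (CLI exit code 2)."""


class ValidationError(BayBudgetsError):
    """An input table violates its contract (CLI exit code 3)."""


class CoverageError(BayBudgetsError):
    """A stratum reachable by the simulation lacks a required empirical
    distribution (CLI exit code 4)."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going away from zero.

    Used for reported whole-number percentages; Python's built-in ``round``
    rounds half to even, which would turn e.g. 36.5 into 36.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
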