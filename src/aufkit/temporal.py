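"""Temporal behaviour of the AUF for a single app under market events.

Simulates a two-year daily trajectory of one app's user base.  Each day
the active-user count drifts by a uniform draw whose bounds depend on
the governing market event (baseline fluctuation, publicity waves,
version-upgrade migration), the daily-use figure is drawn uniformly,
and the AUF is recorded.  The logarithm damps the raw usage noise,
which is the property the metric is valued for; the lag estimator
quantifies how long after a perturbation the score takes to settle.

Per-day update order: (1) any user-count reset whose start day is
today; (2) one drift draw from the governing event (events replace, not
add to, the baseline fluctuation); (3) clamp to the user floor;
(4) draw the day's uses; (5) record the AUF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidParameterError


@dataclass(frozen=True)
class MarketEvent:
    """A market perturbation: a day range with its own drift bounds and/or a user reset.

    ``drift_min``/``drift_max`` bound the uniform daily change in active
    users while the event governs; both ``None`` makes the event
    reset-only.  ``reset_users`` (if set) replaces the user count at the
    start of ``day_start``.
    """

    name: str
    day_start: int
    day_end: int
    drift_min: float | None = None
    drift_max: float | None = None
    reset_users: float | None = None

    def __post_init__(self) -> None:
        if self.day_start < 1 or self.day_end < self.day_start:
            raise InvalidParameterError(
                f"event {self.name!r}: need 1 <= day_start <= day_end, "
                f"got {self.day_start}..{self.day_end}"
            )
        if (self.drift_min is None) != (self.drift_max is None):
            raise InvalidParameterError(
                f"event {self.name!r}: drift_min and drift_max must be set together"
            )
        if self.has_drift and self.drift_min > self.drift_max:
            raise InvalidParameterError(
                f"event {self.name!r}: drift_min {self.drift_min} > drift_max {self.drift_max}"
            )
        if self.drift_min is None and self.reset_users is None:
            raise InvalidParameterError(
                f"event {self.name!r}: must carry drift bounds, a reset, or both"
            )
        if self.reset_users is not None and self.reset_users <= 0:
            raise InvalidParameterError(
                f"event {self.name!r}: reset_users must be > 0, got {self.reset_users!r}"
            )

    @property
    def has_drift(self) -> bool:
        return self.drift_min is not None

    def covers(self, day: int) -> bool:
        return self.day_start <= day <= self.day_end


@dataclass(frozen=True)
class TemporalConfig:
    """Full specification of a single-app temporal run.

    Defaults mirror the reference market schedule: a two-year (730-day)
    horizon, launch with 50 users, daily uses uniform on [10, 20], and a
    baseline user drift uniform on [-50, 50] on days no event covers.
    ``users_floor`` keeps the logarithm defined if drift would push the
    user count to zero or below.
    """

    duration_days: int = 730
    initial_users: float = 50.0
    uses_min: float = 10.0
    uses_max: float = 20.0
    baseline_drift: tuple[float, float] = (-50.0, 50.0)
    events: tuple[MarketEvent, ...] = field(default_factory=tuple)
    users_floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_days < 1:
            raise InvalidParameterError(f"duration_days must be >= 1, got {self.duration_days!r}")
        if self.uses_min > self.uses_max or self.uses_min < 0:
            raise InvalidParameterError(
                f"need 0 <= uses_min <= uses_max, got {self.uses_min}..{self.uses_max}"
            )
        if self.baseline_drift[0] > self.baseline_drift[1]:
            raise InvalidParameterError(f"baseline_drift bounds out of order: {self.baseline_drift}")
        if not self.users_floor > 0:
            raise InvalidParameterError(f"users_floor must be > 0, got {self.users_floor!r}")
        if self.initial_users < self.users_floor:
            raise InvalidParameterError(
                f"initial_users {self.initial_users} below users_floor {self.users_floor}"
            )
        _check_overlaps(self.events)


def _check_overlaps(events: tuple[MarketEvent, ...]) -> None:
    """Reject ambiguous schedules: two drift events overlapping from the same start day.

    Overlap with distinct start days is legal — the later-starting event
    governs the shared days.
    """
    drifting = [e for e in events if e.has_drift]
    for i, a in enumerate(drifting):
        for b in drifting[i + 1:]:
            lo = max(a.day_start, b.day_start)
            hi = min(a.day_end, b.day_end)
            if lo <= hi and a.day_start == b.day_start:
                raise ConfigurationError(
                    f"events {a.name!r} and {b.name!r} overlap on days {lo}..{hi} "
                    "with equal start days; priority is undefined"
                )


@dataclass(frozen=True)
class DayState:
    """One day of the trajectory: the user count after update, the day's uses, the AUF."""

    day: int
    active_users: float
    daily_uses: float
    auf: float


def default_market_schedule(seed: int = 0) -> TemporalConfig:
    """The reference two-year event schedule used for temporal validation.

    Launch on day 1 with 50 users; positive media publicity on days
    100-110 (drift uniform on [50, 500]); negative publicity on days
    350-360 (uniform [-500, 50]); an app/OS version update on day 501
    that resets the user base to 500; user migration to the new version
    over days 500-650 (uniform [-20, 250]).  All other days fluctuate
    uniformly on [-50, 50]; daily uses are uniform on [10, 20] throughout.
    """
    events = (
        MarketEvent("positive-publicity", 100, 110, 50.0, 500.0),
        MarketEvent("upgrade-migration", 500, 650, -20.0, 250.0),
        MarketEvent("version-update-reset", 501, 501, reset_users=500.0),
        MarketEvent("negative-publicity", 350, 360, -500.0, 50.0),
    )
    return TemporalConfig(events=events, seed=seed)


def _governing_drift(config: TemporalConfig, day: int) -> tuple[float, float]:
    governing = None
    for ev in config.events:
        if ev.has_drift and ev.covers(day):
            if governing is None or ev.day_start > governing.day_start:
                governing = ev
    if governing is None:
        return config.baseline_drift
    return (governing.drift_min, governing.drift_max)


def simulate_timeseries(config: TemporalConfig) -> pd.DataFrame:
    """Run the daily simulation, returning a (day, active_users, daily_uses, auf) table.

    Seeded and reproducible: identical config gives an identical table.
    Days are 1-based; event ranges are inclusive.
    """
    rng = np.random.default_rng(config.seed)
    users = float(config.initial_users)
    days = np.arange(1, config.duration_days + 1)
    out_users = np.empty(len(days))
    out_uses = np.empty(len(days))
    for i, day in enumerate(days):
        for ev in config.events:
            if ev.reset_users is not None and ev.day_start == day:
                users = float(ev.reset_users)
        lo, hi = _governing_drift(config, int(day))
        users += rng.uniform(lo, hi)
        users = max(users, config.users_floor)
        out_users[i] = users
        out_uses[i] = rng.uniform(config.uses_min, config.uses_max)
    return pd.DataFrame(
        {
            "day": days,
            "active_users": out_users,
            "daily_uses": out_uses,
            "auf": np.log10(out_users * out_uses),
        }
    )


def day_states(series: pd.DataFrame) -> list[DayState]:
    """View a simulated table as a list of :class:`DayState` objects."""
    return [
        DayState(int(r.day), float(r.active_users), float(r.daily_uses), float(r.auf))
        for r in series.itertuples(index=False)
    ]


def estimate_stabilization_lag(
    series: pd.DataFrame,
    event_day: int,
    tolerance_band: float = 0.4,
    window: int = 30,
) -> int | None:
    """Smallest lag L after ``event_day`` at which the AUF has settled.

    "Settled" means the AUF range (max - min) over the inclusive day span
    ``[event_day + L, event_day + L + window]`` is at most
    ``tolerance_band``.  Returns ``None`` if no such span fits inside the
    series.
    """
    if window < 1:
        raise InvalidParameterError(f"window must be >= 1, got {window!r}")
    if not (tolerance_band > 0 and math.isfinite(tolerance_band)):
        raise InvalidParameterError(f"tolerance_band must be finite and > 0, got {tolerance_band!r}")
    days = series["day"].to_numpy(int)
    if not (days[0] <= event_day <= days[-1]):
        raise InvalidParameterError(
            f"event_day {event_day} outside series days {days[0]}..{days[-1]}"
        )
    auf = series["auf"].to_numpy(float)
    start_idx = int(np.searchsorted(days, event_day))
    span = window + 1  # inclusive endpoints
    s = pd.Series(auf[start_idx:])
    rng_roll = (s.rolling(span).max() - s.rolling(span).min()).to_numpy()
    settled = np.flatnonzero(rng_roll[span - 1:] <= tolerance_band)
    return int(settled[0]) if settled.size else None
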