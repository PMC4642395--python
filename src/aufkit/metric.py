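"""The app usage factor (AUF) and its inverse equivalence scale.

The AUF scores the population impact of a mobile app as

    AUF = log10(A_u * D_u)

where ``A_u`` is the number of active users within a stable measurement
window and ``D_u`` the app's median number of daily uses.  Like the
Richter scale, each unit increase corresponds to a ten-fold larger
daily-action footprint: an AUF of 6 means one million "equivalent
active-user daily actions" market-wide.

The module also implements the regulatory-screening rule built on the
metric: apps whose AUF lies more than ``k`` sample standard deviations
above the ecosystem mean (default ``k = 2``, upper tail only) are
flagged for case-by-case assessment.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientSampleError, InvalidInputError, InvalidParameterError

#: Default measurement window (days) over which A_u and D_u are assumed stable.
DEFAULT_WINDOW_DAYS = 30


@dataclass(frozen=True)
class UsageRecord:
    """One app's usage observation within a measurement window.

    Parameters
    ----------
    app_id : str
        Opaque app identifier.
    active_users : float
        Number of active users, ``A_u`` (>= 0).  Real-valued so that
        simulation output is admissible.
    daily_uses : float
        Median number of daily uses, ``D_u`` (>= 0).
    window_days : int
        Length of the measurement window the figures are stable over;
        carried as metadata only.
    """

    app_id: str
    active_users: float
    daily_uses: float
    window_days: int = DEFAULT_WINDOW_DAYS

    def __post_init__(self) -> None:
        if not math.isfinite(self.active_users) or self.active_users < 0:
            raise InvalidInputError(
                f"active_users must be finite and >= 0, got {self.active_users!r}"
            )
        if not math.isfinite(self.daily_uses) or self.daily_uses < 0:
            raise InvalidInputError(
                f"daily_uses must be finite and >= 0, got {self.daily_uses!r}"
            )
        if self.window_days < 1:
            raise InvalidInputError(f"window_days must be >= 1, got {self.window_days!r}")

    @property
    def product(self) -> float:
        """Equivalent active-user daily actions, ``A_u * D_u``."""
        return self.active_users * self.daily_uses


@dataclass(frozen=True)
class AufScore:
    """An evaluated AUF: the log10 score and the linear-scale product behind it."""

    value: float
    product: float


def compute_auf(active_users: float, daily_uses: float) -> AufScore:
    """Compute the app usage factor ``log10(active_users * daily_uses)``.

    The score is only defined for a strictly positive product; a zero or
    negative factor signals an unused or malformed record and raises
    :class:`~aufkit.errors.InvalidInputError` naming the offending factor.
    No presentation rounding is applied here.

    Examples
    --------
    >>> compute_auf(600, 1).value  # doctest: +ELLIPSIS
    2.778151...
    >>> compute_auf(100_000, 10).value
    6.0
    """
    for name, value in (("active_users", active_users), ("daily_uses", daily_uses)):
        if not math.isfinite(value):
            raise InvalidInputError(f"{name} must be finite, got {value!r}")
        if value <= 0:
            raise InvalidInputError(
                f"AUF undefined: {name} = {value!r} is not strictly positive"
            )
    product = active_users * daily_uses
    return AufScore(value=math.log10(product), product=product)


def equivalent_daily_actions(auf_value: float) -> float:
    """Invert the AUF back to equivalent active-user daily actions, ``10**AUF``.

    Strictly increasing; the exact inverse of :func:`compute_auf` up to
    floating-point tolerance.

    >>> equivalent_daily_actions(6)
    1000000.0
    """
    if not math.isfinite(auf_value):
        raise InvalidInputError(f"auf_value must be finite, got {auf_value!r}")
    return 10.0 ** auf_value


def score_records(records: pd.DataFrame) -> pd.DataFrame:
    """Score a table of usage records, appending an ``auf`` column.

    ``records`` must have ``app_id``, ``active_users`` and ``daily_uses``
    columns; every row needs a strictly positive product.
    """
    required = {"app_id", "active_users", "daily_uses"}
    missing = required - set(records.columns)
    if missing:
        raise InvalidInputError(f"records table missing columns: {sorted(missing)}")
    product = records["active_users"].to_numpy(float) * records["daily_uses"].to_numpy(float)
    bad = np.flatnonzero(~(product > 0))
    if bad.size:
        raise InvalidInputError(
            f"AUF undefined for {bad.size} record(s) with non-positive "
            f"active_users*daily_uses (first offending row index: {bad[0]})"
        )
    out = records.copy()
    out["auf"] = np.log10(product)
    return out


@dataclass(frozen=True)
class FlagReport:
    """Outcome of the mean + k*SD screening rule over an AUF sample."""

    k: float
    mean: float
    sd: float
    threshold: float
    flagged_ids: tuple[str, ...]
    n_flagged: int
    n_total: int
    proportion: float
    two_sided: bool = False
    threshold_lower: float | None = None
    flagged_ids_lower: tuple[str, ...] = field(default=())


def _as_score_series(scores) -> pd.Series:
    if isinstance(scores, pd.DataFrame):
        missing = {"app_id", "auf"} - set(scores.columns)
        if missing:
            raise InvalidInputError(f"scores table missing columns: {sorted(missing)}")
        return pd.Series(scores["auf"].to_numpy(float), index=scores["app_id"].astype(str))
    if isinstance(scores, pd.Series):
        return scores.astype(float)
    if isinstance(scores, Mapping):
        return pd.Series({str(k): float(v) for k, v in scores.items()})
    if isinstance(scores, Sequence):
        # bare values: synthesize positional ids
        vals = [s.value if isinstance(s, AufScore) else float(s) for s in scores]
        return pd.Series(vals, index=[str(i) for i in range(len(vals))])
    raise InvalidInputError(f"unsupported scores container: {type(scores).__name__}")


def flag_high_impact(scores, k: float = 2.0, *, two_sided: bool = False) -> FlagReport:
    """Flag apps whose AUF exceeds the ecosystem mean by more than ``k`` SDs.

    Computes the sample mean ``m`` and sample standard deviation ``s``
    (n-1 denominator) of the supplied AUF values and flags every app with
    AUF *strictly* greater than ``m + k*s``.  The rule is one-sided by
    default: on the left-skewed ecosystem AUF distribution only the upper
    tail identifies unusually high population impact.  Set
    ``two_sided=True`` to additionally report apps below ``m - k*s``.

    Parameters
    ----------
    scores
        A DataFrame with ``app_id``/``auf`` columns, a Series indexed by
        app id, a mapping id -> AUF, or a plain sequence of scores.
    k : float
        Number of standard deviations above the mean (>= 0).
    """
    if k < 0:
        raise InvalidParameterError(f"k must be >= 0, got {k!r}")
    series = _as_score_series(scores)
    n = len(series)
    if n < 2:
        raise InsufficientSampleError(
            f"flagging needs >= 2 scores for a sample SD, got {n}"
        )
    values = series.to_numpy(float)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    threshold = mean + k * sd
    upper = series.index[values > threshold]
    lower_threshold = mean - k * sd if two_sided else None
    lower = series.index[values < lower_threshold] if two_sided else pd.Index([])
    n_flagged = len(upper) + len(lower)
    return FlagReport(
        k=float(k),
        mean=mean,
        sd=sd,
        threshold=threshold,
        flagged_ids=tuple(str(i) for i in upper),
        n_flagged=n_flagged,
        n_total=n,
        proportion=n_flagged / n,
        two_sided=two_sided,
        threshold_lower=lower_threshold,
        flagged_ids_lower=tuple(str(i) for i in lower),
    )
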