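"""Stability surface of the AUF over an (A_u, D_u) rectangle.

Evaluates the metric on a linearly spaced grid (200x200 over
0 < A_u < 100,000 and 0 < D_u < 50 by default) and extracts the AUF = 0
boundary, the hyperbola ``D_u = 1/A_u``.  Above that contour an app
clears the minimum-use bar (product of users and daily uses above one
action per day — roughly "used once a month by 50 people"); below it the
score is negative and the app is essentially unused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError
from .metric import UsageRecord

STABLE = "stable"
BELOW_MINIMUM_USE = "below-minimum-use"


@dataclass(frozen=True)
class StabilityGrid:
    """Evaluated AUF surface plus its analytic zero contour.

    ``surface[i, j] = log10(users_axis[i] * uses_axis[j])``;
    ``zero_contour`` holds (A_u, 1/A_u) pairs sampled along the users axis.
    """

    users_axis: np.ndarray
    uses_axis: np.ndarray
    surface: np.ndarray
    zero_contour: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format (users, uses, auf) table of the surface."""
        uu, dd = np.meshgrid(self.users_axis, self.uses_axis, indexing="ij")
        return pd.DataFrame(
            {"users": uu.ravel(), "uses": dd.ravel(), "auf": self.surface.ravel()}
        )

    def contour_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.zero_contour, columns=["users", "uses"])


def build_stability_grid(
    users_max: float = 100_000.0,
    uses_max: float = 50.0,
    resolution: int = 200,
) -> StabilityGrid:
    """Evaluate the AUF on a ``resolution x resolution`` open-interval grid.

    The axes span the open intervals (0, users_max] and (0, uses_max]:
    linear spacing starts one step (max/resolution) above zero so the
    logarithm stays defined everywhere.  Deterministic.
    """
    if not users_max > 0 or not uses_max > 0:
        raise InvalidParameterError(
            f"grid bounds must be > 0, got users_max={users_max!r}, uses_max={uses_max!r}"
        )
    if resolution < 2:
        raise InvalidParameterError(f"resolution must be >= 2, got {resolution!r}")
    users_axis = np.linspace(users_max / resolution, users_max, resolution)
    uses_axis = np.linspace(uses_max / resolution, uses_max, resolution)
    surface = np.log10(users_axis[:, None] * uses_axis[None, :])
    contour_uses = 1.0 / users_axis
    keep = contour_uses <= uses_max
    zero_contour = np.column_stack([users_axis[keep], contour_uses[keep]])
    return StabilityGrid(
        users_axis=users_axis,
        uses_axis=uses_axis,
        surface=surface,
        zero_contour=zero_contour,
    )


def classify_stability(record: UsageRecord) -> str:
    """Classify a record as ``stable`` (A_u * D_u > 1) or ``below-minimum-use``.

    A product of exactly 1 (AUF = 0) falls below the bar: the stability
    criterion is strict.
    """
    product = record.product
    if product <= 0:
        raise InvalidInputError(
            f"stability undefined for non-positive product {product!r}"
        )
    return STABLE if product > 1 else BELOW_MINIMUM_USE
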