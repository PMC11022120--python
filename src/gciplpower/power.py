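"""Two-sided normal-approximation power for the two-sample comparison.

For arm sizes n_test and n_gc, mean difference delta and common known
standard deviation sigma, the standardized effect is

    Z = delta / (sigma * sqrt(1/n_gc + 1/n_test))

and the two-sided power at level alpha is

    power = Phi(Z - z_{1-alpha/2}) + Phi(-Z - z_{1-alpha/2})

Both additive terms are kept.  The far-tail second term matters only at
tiny Z (it makes the null power exactly alpha, not alpha/2) and is below
1e-6 in every design regime this package targets, so the closed-form
sample-size inversion in :mod:`gciplpower.design`, which drops it, agrees
with this function to that tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import norm

from .errors import InvalidDispersionError


@dataclass(frozen=True)
class PowerResult:
    """Standardized effect and the resulting two-sided power."""

    z_stat: float
    power: float
    n_test: int | None = None
    n_gc: int | None = None


def power(
    n_test: int,
    n_gc: int,
    delta: float,
    sigma: float,
    alpha: float = 0.05,
) -> PowerResult:
    """Exact two-term normal-approximation power at given arm sizes.

    At ``delta = 0`` this returns exactly ``alpha`` (the test is unbiased
    under the normal model), and it is symmetric in the sign of *delta*.
    """
    if sigma <= 0:
        raise InvalidDispersionError(f"sigma must be positive, got {sigma}")
    if n_test < 1 or n_gc < 1:
        raise ValueError("arm sizes must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    z_crit = norm.ppf(1 - alpha / 2)
    z = delta / (sigma * math.sqrt(1.0 / n_gc + 1.0 / n_test))
    p = norm.cdf(z - z_crit) + norm.cdf(-z - z_crit)
    return PowerResult(z_stat=float(z), power=float(p), n_test=n_test, n_gc=n_gc)


def power_curve(
    delta: float,
    sigma: float,
    n_grid: Sequence[int],
    alpha: float = 0.05,
    kappa: float = 1.0,
) -> list[PowerResult]:
    """Power along an increasing grid of test-arm sizes.

    The control arm is sized ``ceil(kappa * n)`` for each ``n`` in the
    grid.  Power is non-decreasing along the curve and flat at *alpha*
    when ``delta`` is zero.
    """
    if len(n_grid) == 0:
        raise ValueError("n_grid must be non-empty")
    if any(b <= a for a, b in zip(n_grid, n_grid[1:])):
        raise ValueError("n_grid must be strictly increasing")
    return [
        power(n, max(1, math.ceil(kappa * n)), delta, sigma, alpha) for n in n_grid
    ]
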