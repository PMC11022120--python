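"""Per-arm and total sample size for the two-arm parallel design.

The closed form for the test-drug arm, with matching ratio
kappa = n_gc / n_test, mean difference delta and common SD sigma, is

    n_test = (1 + 1/kappa) * (sigma * (z_{1-alpha/2} + z_{1-power}) / delta)**2

Method A draws sigma from the control arm's follow-up values, Method B
from the per-eye baseline-minus-follow-up change scores; delta comes from
the protective-effect model either way.  Raw sizes are ceiled per arm,
each arm separately, which is the conservative convention: the achieved
analytic power at the integer sizes is then always at least the target.
Normal quantiles are used at full double precision (z_{0.975} =
1.959964...), never the textbook 1.96.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import norm

from . import effects
from .cohort import EyeRecord, FOLLOWUPS, METRICS, summarize, summarize_change
from .effects import METHODS, EffectSpec
from .errors import InfiniteSampleSizeError, InvalidDispersionError
from .power import power as analytic_power

#: Default protective-effect grid (fractions of control-arm loss prevented).
DEFAULT_EFFECTS = (0.20, 0.30, 0.40, 0.50, 0.60)
#: Default power targets.
DEFAULT_POWERS = (0.80, 0.90, 0.95)


@dataclass(frozen=True)
class DesignSpec:
    """Design parameters for one sample-size estimate."""

    effect_size: float
    method: str
    metric: str
    followup: str
    alpha: float = 0.05
    power: float = 0.80
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise ValueError(f"power must be in (0, 1), got {self.power}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.followup not in FOLLOWUPS:
            raise ValueError(f"followup must be one of {FOLLOWUPS}")


@dataclass(frozen=True)
class SampleSizeResult:
    """A sample-size estimate with the inputs it used and the power it buys."""

    design: DesignSpec
    delta: float
    sigma: float
    n_test_raw: float
    n_test: int
    n_gc: int
    n_total: int
    achieved_power: float

    def to_dict(self) -> dict:
        d = {
            "method": self.design.method,
            "metric": self.design.metric,
            "followup": self.design.followup,
            "effect_size": self.design.effect_size,
            "alpha": self.design.alpha,
            "power": self.design.power,
            "kappa": self.design.kappa,
            "delta": self.delta,
            "sigma": self.sigma,
            "n_test_raw": self.n_test_raw,
            "n_test": self.n_test,
            "n_gc": self.n_gc,
            "n_total": self.n_total,
            "achieved_power": self.achieved_power,
        }
        return d


def n_per_arm_raw(
    delta: float,
    sigma: float,
    alpha: float = 0.05,
    power: float = 0.80,
    kappa: float = 1.0,
) -> float:
    """Unrounded test-arm size from the closed-form normal approximation.

    Raises
    ------
    InfiniteSampleSizeError
        If ``delta`` is zero — no finite trial detects no difference.
    InvalidDispersionError
        If ``sigma`` is not positive.
    """
    if sigma <= 0:
        raise InvalidDispersionError(f"sigma must be positive, got {sigma}")
    if delta == 0:
        raise InfiniteSampleSizeError("delta is zero; required sample size is infinite")
    z = norm.ppf(1 - alpha / 2) + norm.ppf(power)
    return float((1 + 1 / kappa) * (sigma * z / delta) ** 2)


def _design_inputs(
    records: Sequence[EyeRecord], spec: DesignSpec
) -> tuple[float, float]:
    """(delta, sigma) for the design, from unrounded cohort statistics."""
    baseline = summarize(records, spec.metric, "baseline")
    followup = summarize(records, spec.metric, spec.followup)
    eff = EffectSpec(
        effect_size=spec.effect_size,
        mean_baseline=baseline.mean,
        mean_followup_gc=followup.mean,
        method=spec.method,
    )
    d = effects.delta(eff)
    if spec.method == "A":
        sigma = followup.sd
    else:
        sigma = summarize_change(records, spec.metric, spec.followup).sd
    return d, sigma


def estimate(records: Sequence[EyeRecord], spec: DesignSpec) -> SampleSizeResult:
    """Sample-size estimate for one design, parameterized by a pilot cohort.

    Statistics are taken unrounded from the records; per-arm sizes are
    ceiled separately (``n_gc = ceil(kappa * n_test_raw)``) and the
    achieved analytic power at the integer sizes is reported.
    """
    d, sigma = _design_inputs(records, spec)
    return from_parameters(
        delta=d,
        sigma=sigma,
        alpha=spec.alpha,
        power=spec.power,
        kappa=spec.kappa,
        design=spec,
    )


def from_parameters(
    delta: float,
    sigma: float,
    alpha: float = 0.05,
    power: float = 0.80,
    kappa: float = 1.0,
    design: DesignSpec | None = None,
) -> SampleSizeResult:
    """Sample-size estimate straight from (delta, sigma), no cohort needed."""
    raw = n_per_arm_raw(delta, sigma, alpha=alpha, power=power, kappa=kappa)
    n_test = math.ceil(raw)
    n_gc = math.ceil(kappa * raw)
    achieved = analytic_power(n_test, n_gc, delta, sigma, alpha).power
    if design is None:
        design = DesignSpec(
            effect_size=1.0, method="A", metric="volume", followup="m2",
            alpha=alpha, power=power, kappa=kappa,
        )
    return SampleSizeResult(
        design=design,
        delta=delta,
        sigma=sigma,
        n_test_raw=raw,
        n_test=n_test,
        n_gc=n_gc,
        n_total=n_test + n_gc,
        achieved_power=achieved,
    )


def grid(
    records: Sequence[EyeRecord],
    effects_grid: Iterable[float] = DEFAULT_EFFECTS,
    powers: Iterable[float] = DEFAULT_POWERS,
    methods: Iterable[str] = METHODS,
    metrics: Iterable[str] = METRICS,
    followups: Iterable[str] = FOLLOWUPS,
    alphas: Iterable[float] = (0.05,),
    kappa: float = 1.0,
) -> list[SampleSizeResult]:
    """Cartesian product of designs, one :class:`SampleSizeResult` per cell.

    The default grids span 5 effect sizes x 3 powers x 2 methods x
    2 metrics x 2 follow-ups = 120 cells (60 per follow-up visit).
    """
    grids = [list(g) for g in (effects_grid, powers, methods, metrics, followups, alphas)]
    if any(len(g) == 0 for g in grids):
        raise ValueError("all grids must be non-empty")
    results = []
    for effect, pw, method, metric, followup, alpha in product(*grids):
        spec = DesignSpec(
            effect_size=effect, method=method, metric=metric, followup=followup,
            alpha=alpha, power=pw, kappa=kappa,
        )
        results.append(estimate(records, spec))
    return results


def grid_frame(results: Iterable[SampleSizeResult]) -> pd.DataFrame:
    """Tidy one-row-per-cell DataFrame of grid results."""
    return pd.DataFrame([r.to_dict() for r in results])


def table_layout(results: Iterable[SampleSizeResult]) -> pd.DataFrame:
    """Wide layout: rows = (follow-up, effect size), columns = power x method x metric.

    Mirrors the conventional presentation of such grids; cells hold the
    total N over both arms.
    """
    frame = grid_frame(results)
    wide = frame.pivot_table(
        index=["followup", "effect_size"],
        columns=["power", "method", "metric"],
        values="n_total",
    )
    return wide.sort_index()


def inflate_for_dropout(result: SampleSizeResult, fraction: float) -> int:
    """Post-hoc total-N inflation for an anticipated dropout fraction.

    Divides the total by ``1 - fraction`` and ceils.  This is a crude
    enrolment multiplier, not part of the design formula.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"dropout fraction must be in [0, 1), got {fraction}")
    return math.ceil(result.n_total / (1 - fraction))


def smallest_power_adequate_n(
    delta: float, sigma: float, alpha: float = 0.05, target: float = 0.80,
    n_max: int = 10_000_000,
) -> int:
    """Smallest equal per-arm n whose analytic power meets the target.

    Linear search over the power function itself — the brute-force
    counterpart of :func:`n_per_arm_raw` used to validate the closed-form
    inversion.
    """
    n = 1
    while n <= n_max:
        if analytic_power(n, n, delta, sigma, alpha).power >= target:
            return n
        n += 1
    raise RuntimeError("no adequate n found below n_max")
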