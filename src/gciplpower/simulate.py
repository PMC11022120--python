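"""Synthetic cohorts and Monte Carlo validation of the analytic design.

Two jobs live here.  ``generate_cohort`` fabricates per-eye longitudinal
records with the structure of the real pilot data — a normal baseline, a
proportional mean loss at each follow-up, correlated within-eye noise,
and an optional treatment arm that prevents a stated fraction of the
loss.  ``simulate_trial_power`` plays out the two-arm trial many times
and counts rejections of the two-sided z-test, giving an empirical check
on the closed-form power and sample-size formulas.

The within-eye correlation is a shared eye-level random effect scaled
into each visit's residual; its default (0.7) is a synthetic-data
convenience with no empirical basis — the two-sample formulas never see
it, because they consume only marginal means and SDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import EyeRecord, FOLLOWUPS, METRICS
from .design import DEFAULT_EFFECTS, DEFAULT_POWERS, SampleSizeResult, grid, grid_frame
from .effects import METHODS
from .errors import InsufficientDataError
from .power import power as analytic_power

#: Floor applied to generated measurements; EyeRecord requires positive values.
_POSITIVE_FLOOR = 1e-6

#: Reference generator parameters per metric: baseline moments from the
#: pilot cohort, loss fractions from its observed mean losses, and
#: measurement-noise-scale residual SDs (OCT repeatability order).
_REFERENCE_PARAMS = {
    "volume": dict(
        baseline_mean=0.534, baseline_sd=0.134,
        loss_fraction_m2=0.2959, loss_fraction_m6=0.3708,
        residual_sd_m2=0.03, residual_sd_m6=0.03,
    ),
    "thickness": dict(
        baseline_mean=73.664, baseline_sd=18.497,
        loss_fraction_m2=0.2999, loss_fraction_m6=0.3716,
        residual_sd_m2=3.0, residual_sd_m6=3.0,
    ),
}


@dataclass(frozen=True)
class CohortModel:
    """Generative model for one metric of a synthetic eye cohort.

    Baseline values are N(baseline_mean, baseline_sd²).  The follow-up
    value of eye *i* at visit *t* is

        baseline_i * (1 - loss_fraction_t * (1 - treatment_effect)) + e_it

    where the residual e_it has SD residual_sd_t and shares an eye-level
    component across visits with correlation ``within_eye_correlation``.
    ``treatment_effect`` is the fraction of loss prevented (0 = control).
    """

    n_eyes: int
    metric: str = "volume"
    baseline_mean: float = 0.534
    baseline_sd: float = 0.134
    loss_fraction_m2: float = 0.2959
    loss_fraction_m6: float = 0.3708
    residual_sd_m2: float = 0.03
    residual_sd_m6: float = 0.03
    within_eye_correlation: float = 0.7
    treatment_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.baseline_sd < 0 or self.residual_sd_m2 < 0 or self.residual_sd_m6 < 0:
            raise ValueError("standard deviations must be non-negative")
        if not (0 <= self.loss_fraction_m2 < 1 and 0 <= self.loss_fraction_m6 < 1):
            raise ValueError("loss fractions must be in [0, 1)")
        if not 0 <= self.within_eye_correlation < 1:
            raise ValueError("within_eye_correlation must be in [0, 1)")
        if not 0 <= self.treatment_effect <= 1:
            raise ValueError("treatment_effect must be in [0, 1]")

    @classmethod
    def reference(
        cls, metric: str, n_eyes: int, treatment_effect: float = 0.0, seed: int = 0
    ) -> "CohortModel":
        """Model whose moments emulate the pilot cohort for *metric*."""
        if metric not in _REFERENCE_PARAMS:
            raise ValueError(f"metric must be one of {METRICS}")
        return cls(
            n_eyes=n_eyes, metric=metric, treatment_effect=treatment_effect,
            seed=seed, **_REFERENCE_PARAMS[metric],
        )

    def followup_mean(self, followup: str) -> float:
        """Implied population mean at a follow-up visit."""
        loss = {"m2": self.loss_fraction_m2, "m6": self.loss_fraction_m6}[followup]
        return self.baseline_mean * (1 - loss * (1 - self.treatment_effect))

    def followup_sd(self, followup: str) -> float:
        """Implied marginal SD at a follow-up visit.

        The shared eye-level effect correlates the baseline and follow-up
        residuals (correlation rho), so the variance carries a
        2*shrink*rho*baseline_sd*residual_sd cross term on top of the
        shrunk baseline variance and the residual variance.
        """
        loss = {"m2": self.loss_fraction_m2, "m6": self.loss_fraction_m6}[followup]
        res = {"m2": self.residual_sd_m2, "m6": self.residual_sd_m6}[followup]
        shrink = 1 - loss * (1 - self.treatment_effect)
        rho = self.within_eye_correlation
        var = (shrink * self.baseline_sd) ** 2 + res**2
        var += 2 * shrink * rho * self.baseline_sd * res
        return math.sqrt(var)


@dataclass(frozen=True)
class SimulationReport:
    """Outcome of a Monte Carlo power run against its analytic reference."""

    replicates: int
    seed: int
    rejections: int
    empirical_power: float
    mc_se: float
    analytic_power: float

    @property
    def discrepant(self) -> bool:
        """True when empirical and analytic power disagree by > 4 MC SE."""
        return abs(self.empirical_power - self.analytic_power) > 4 * self.mc_se


def _correlated_residuals(
    rng: np.random.Generator, n: int, sds: Sequence[float], rho: float
) -> np.ndarray:
    """(n, len(sds)) residual matrix with cross-visit correlation rho."""
    shared = rng.standard_normal(n)
    out = np.empty((n, len(sds)))
    for j, sd in enumerate(sds):
        own = rng.standard_normal(n)
        out[:, j] = sd * (math.sqrt(rho) * shared + math.sqrt(1 - rho) * own)
    return out


def _metric_values(rng: np.random.Generator, model: CohortModel) -> dict[str, np.ndarray]:
    resid = _correlated_residuals(
        rng,
        model.n_eyes,
        (model.baseline_sd, model.residual_sd_m2, model.residual_sd_m6),
        model.within_eye_correlation,
    )
    baseline = model.baseline_mean + resid[:, 0]
    keep = 1 - (1 - model.treatment_effect) * np.array(
        [model.loss_fraction_m2, model.loss_fraction_m6]
    )
    m2 = baseline * keep[0] + resid[:, 1]
    m6 = baseline * keep[1] + resid[:, 2]
    values = {"baseline": baseline, "m2": m2, "m6": m6}
    return {t: np.maximum(v, _POSITIVE_FLOOR) for t, v in values.items()}


def generate_cohort(
    model: CohortModel, second: CohortModel | None = None
) -> list[EyeRecord]:
    """Generate a synthetic eye cohort, reproducible from ``model.seed``.

    ``model`` parameterizes one metric; ``second`` the other.  When
    ``second`` is omitted, the reference model for the remaining metric
    (matched n, treatment effect) completes the records, since every eye
    record carries both thickness and volume.  The two metrics are
    generated independently.
    """
    if model.n_eyes < 2:
        raise InsufficientDataError(f"n_eyes must be >= 2, got {model.n_eyes}")
    if second is None:
        other = "thickness" if model.metric == "volume" else "volume"
        second = CohortModel.reference(
            other, n_eyes=model.n_eyes, treatment_effect=model.treatment_effect
        )
    if second.metric == model.metric:
        raise ValueError("the two models must cover distinct metrics")
    if second.n_eyes != model.n_eyes:
        second = replace(second, n_eyes=model.n_eyes)

    rng = np.random.default_rng(model.seed)
    by_metric = {model.metric: _metric_values(rng, model)}
    by_metric[second.metric] = _metric_values(rng, second)

    records = []
    for i in range(model.n_eyes):
        records.append(
            EyeRecord(
                case_id=f"S{i + 1}",
                laterality="OD" if i % 2 == 0 else "OS",
                thickness_um={t: float(by_metric["thickness"][t][i]) for t in by_metric["thickness"]},
                volume_mm3={t: float(by_metric["volume"][t][i]) for t in by_metric["volume"]},
            )
        )
    return records


def cohort_to_frame(records: Sequence[EyeRecord]) -> pd.DataFrame:
    """Long-format frame in the cohort CSV dialect (for ``to_csv``)."""
    from .cohort import METRIC_CSV_LABELS, TIMEPOINTS

    rows = []
    for r in records:
        for metric, label in METRIC_CSV_LABELS.items():
            for t in TIMEPOINTS:
                rows.append(
                    {
                        "case_id": r.case_id,
                        "laterality": r.laterality,
                        "metric": label,
                        "timepoint": t,
                        "value": r.value(metric, t),
                    }
                )
    return pd.DataFrame(rows)


def simulate_trial_power(
    n_test: int,
    n_gc: int,
    gc_mean: float,
    test_mean: float,
    sigma: float,
    alpha: float = 0.05,
    replicates: int = 100_000,
    seed: int = 0,
    use_welch_t: bool = False,
) -> SimulationReport:
    """Empirical power of the two-arm comparison by Monte Carlo.

    Each replicate draws the two arms from normals with common ``sigma``
    and applies the two-sided z-test (sigma known, matching the analytic
    power function).  Because the z statistic depends on the data only
    through the arm means, arm means are simulated directly.  With
    ``use_welch_t`` the full samples are drawn and an unequal-variance
    t-test is applied instead — a sensitivity check, not the default.
    """
    if replicates < 100:
        raise ValueError("need at least 100 replicates")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    from scipy.stats import norm as _norm

    if use_welch_t:
        from scipy.stats import ttest_ind

        gc = rng.normal(gc_mean, sigma, size=(replicates, n_gc))
        test = rng.normal(test_mean, sigma, size=(replicates, n_test))
        res = ttest_ind(gc, test, axis=1, equal_var=False)
        rejections = int(np.sum(res.pvalue < alpha))
    else:
        se = sigma * math.sqrt(1.0 / n_gc + 1.0 / n_test)
        mean_gc = rng.normal(gc_mean, sigma / math.sqrt(n_gc), size=replicates)
        mean_test = rng.normal(test_mean, sigma / math.sqrt(n_test), size=replicates)
        z = (mean_gc - mean_test) / se
        z_crit = _norm.ppf(1 - alpha / 2)
        rejections = int(np.sum(np.abs(z) > z_crit))

    emp = rejections / replicates
    mc_se = math.sqrt(max(emp * (1 - emp), 1e-12) / replicates)
    analytic = analytic_power(n_test, n_gc, gc_mean - test_mean, sigma, alpha).power
    return SimulationReport(
        replicates=replicates,
        seed=seed,
        rejections=rejections,
        empirical_power=emp,
        mc_se=mc_se,
        analytic_power=analytic,
    )


def _simulate_result_cell(
    result: SampleSizeResult, replicates: int, seed: int
) -> SimulationReport:
    """Monte Carlo check of one grid cell at its integer arm sizes."""
    return simulate_trial_power(
        n_test=result.n_test,
        n_gc=result.n_gc,
        gc_mean=result.delta,   # only the difference matters; place test at 0
        test_mean=0.0,
        sigma=result.sigma,
        alpha=result.design.alpha,
        replicates=replicates,
        seed=seed,
    )


def end_to_end(
    pilot: Sequence[EyeRecord] | None = None,
    volume_model: CohortModel | None = None,
    thickness_model: CohortModel | None = None,
    effects_grid: Sequence[float] = DEFAULT_EFFECTS,
    powers: Sequence[float] = DEFAULT_POWERS,
    methods: Sequence[str] = METHODS,
    metrics: Sequence[str] = METRICS,
    followups: Sequence[str] = FOLLOWUPS,
    replicates: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pilot -> sample-size grid -> per-cell Monte Carlo validation.

    Either pass an existing ``pilot`` cohort (e.g. the packaged one) or a
    generative ``volume_model`` (optionally with ``thickness_model``)
    from which a pilot is drawn.  Returns the tidy grid frame with
    ``empirical_power`` and ``mc_se`` columns appended.
    """
    if pilot is None:
        if volume_model is None:
            raise ValueError("provide either a pilot cohort or a volume_model")
        pilot = generate_cohort(volume_model, thickness_model)
    results = grid(
        pilot,
        effects_grid=effects_grid,
        powers=powers,
        methods=methods,
        metrics=metrics,
        followups=followups,
    )
    frame = grid_frame(results)
    seeds = np.random.SeedSequence(seed).spawn(len(results))
    reports = [
        _simulate_result_cell(res, replicates, int(s.generate_state(1)[0] % (2**31)))
        for res, s in zip(results, seeds)
    ]
    frame["empirical_power"] = [r.empirical_power for r in reports]
    frame["mc_se"] = [r.mc_se for r in reports]
    frame["analytic_power"] = [r.analytic_power for r in reports]
    return frame
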