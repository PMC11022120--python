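"""Per-eye longitudinal OCT cohort records and their summary statistics.

The unit of analysis is the eye.  Each eye carries macular GCIPL (ganglion
cell layer + inner plexiform layer) thickness (µm) and volume (mm³) at
three visits: baseline (acute optic neuritis onset), 2 months and 6 months.
A small glucocorticoid-treated AQP4-IgG seropositive pilot cohort (five
eyes from four patients) ships with the package and parameterizes all
downstream sample-size arithmetic.

Eyes are treated as independent even when one patient contributes both;
within-patient correlation is deliberately not modelled.  Units are fixed
per metric and never converted.  All statistics are returned unrounded;
rounding is a display concern only, because the design formulas are
sensitive to the third decimal of the dispersion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CohortParseError, CohortValidationError, InsufficientDataError

logger = logging.getLogger(__name__)

METRICS = ("thickness", "volume")
TIMEPOINTS = ("baseline", "m2", "m6")
FOLLOWUPS = ("m2", "m6")
LATERALITIES = ("OD", "OS")

#: CSV dialect: long format, one measurement per row.
CSV_COLUMNS = ("case_id", "laterality", "metric", "timepoint", "value")
#: CSV metric labels -> short metric names used throughout the API.
CSV_METRIC_LABELS = {
    "mgcipl_thickness_um": "thickness",
    "mgcipl_volume_mm3": "volume",
}
METRIC_CSV_LABELS = {v: k for k, v in CSV_METRIC_LABELS.items()}
METRIC_UNITS = {"thickness": "um", "volume": "mm3"}


@dataclass(frozen=True)
class EyeRecord:
    """One eye's mGCIPL measurements at the three visits, both metrics.

    Parameters
    ----------
    case_id
        Patient label; two eyes of one patient share it.
    laterality
        ``"OD"`` (right) or ``"OS"`` (left).
    thickness_um, volume_mm3
        Mappings ``{"baseline": v, "m2": v, "m6": v}``; all six values
        must be present and strictly positive.
    """

    case_id: str
    laterality: str
    thickness_um: dict[str, float] = field(hash=False)
    volume_mm3: dict[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            raise CohortValidationError(
                f"eye {self.case_id}: laterality must be OD or OS, got {self.laterality!r}"
            )
        for metric, values in (("thickness", self.thickness_um), ("volume", self.volume_mm3)):
            missing = [t for t in TIMEPOINTS if t not in values]
            if missing:
                raise CohortValidationError(
                    f"eye {self.case_id}/{self.laterality}: missing {metric} at {missing}"
                )
            for t in TIMEPOINTS:
                v = values[t]
                if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                    raise CohortValidationError(
                        f"eye {self.case_id}/{self.laterality}: {metric} at {t} "
                        f"must be finite and positive, got {v!r}"
                    )

    def value(self, metric: str, timepoint: str) -> float:
        """Measurement for *metric* at *timepoint*."""
        _check_metric(metric)
        _check_timepoint(timepoint)
        store = self.thickness_um if metric == "thickness" else self.volume_mm3
        return store[timepoint]

    @property
    def key(self) -> tuple[str, str]:
        return (self.case_id, self.laterality)


@dataclass(frozen=True)
class SummaryStats:
    """Location and dispersion of one metric at one visit (or of paired changes).

    ``sd`` uses the n−1 (sample) denominator.  The median of an odd-sized
    cohort is the middle order statistic; for even n it is the midpoint of
    the two central values.
    """

    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    metric: str | None = None
    timepoint: str | None = None

    def __post_init__(self) -> None:
        if not (self.min <= self.median <= self.max):
            raise ValueError("min <= median <= max violated")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "min": self.min,
            "max": self.max,
            "metric": self.metric,
            "timepoint": self.timepoint,
        }


def _check_metric(metric: str) -> None:
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")


def _check_timepoint(timepoint: str, allowed: Sequence[str] = TIMEPOINTS) -> None:
    if timepoint not in allowed:
        raise ValueError(f"timepoint must be one of {tuple(allowed)}, got {timepoint!r}")


def read_cohort(source: str | IO[str]) -> list[EyeRecord]:
    """Read a long-format cohort CSV into validated :class:`EyeRecord` objects.

    The dialect is ``case_id,laterality,metric,timepoint,value`` with
    metric labels ``mgcipl_thickness_um`` / ``mgcipl_volume_mm3`` and
    timepoints ``baseline`` / ``m2`` / ``m6``.

    Raises
    ------
    CohortParseError
        Wrong header or a non-numeric value cell (names the row).
    CohortValidationError
        An eye missing any of its six measurements, or a duplicate cell.
    """
    try:
        frame = pd.read_csv(source, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise CohortParseError("cohort CSV is empty (no header)") from exc
    if list(frame.columns) != list(CSV_COLUMNS):
        raise CohortParseError(
            f"unexpected header {list(frame.columns)}; expected {list(CSV_COLUMNS)}"
        )
    if frame.empty:
        logger.warning("cohort CSV contains a header but no records")
        return []

    values: dict[tuple[str, str], dict[str, dict[str, float]]] = {}
    for row in frame.itertuples():
        # +2: itertuples Index is 0-based and the header occupies line 1
        line_no = int(row.Index) + 2
        metric_label = row.metric
        if metric_label not in CSV_METRIC_LABELS:
            raise CohortParseError(f"row {line_no}: unknown metric {metric_label!r}")
        metric = CSV_METRIC_LABELS[metric_label]
        timepoint = row.timepoint
        if timepoint not in TIMEPOINTS:
            raise CohortParseError(f"row {line_no}: unknown timepoint {timepoint!r}")
        try:
            value = float(row.value)
        except (TypeError, ValueError) as exc:
            raise CohortParseError(
                f"row {line_no}: non-numeric value {row.value!r}"
            ) from exc
        key = (str(row.case_id), str(row.laterality))
        slot = values.setdefault(key, {m: {} for m in METRICS})
        if timepoint in slot[metric]:
            raise CohortValidationError(
                f"row {line_no}: duplicate measurement for eye "
                f"{key[0]}/{key[1]} {metric} at {timepoint}"
            )
        slot[metric][timepoint] = value

    records = []
    for (case_id, laterality), slot in values.items():
        records.append(
            EyeRecord(
                case_id=case_id,
                laterality=laterality,
                thickness_um=slot["thickness"],
                volume_mm3=slot["volume"],
            )
        )
    logger.info("read %d eye records from cohort CSV", len(records))
    return records


def load_pilot_cohort() -> list[EyeRecord]:
    """The packaged five-eye AQP4-IgG seropositive pilot cohort.

    Five affected eyes from four glucocorticoid-treated patients with a
    first episode of seropositive optic neuritis, measured at onset and at
    2 and 6 months.  This tiny cohort supplies the means and SDs that
    drive every worked example in the package.
    """
    ref = resources.files("gciplpower.data").joinpath("pilot_cohort.csv")
    with ref.open("r", encoding="utf-8") as handle:
        return read_cohort(handle)


def _values(records: Iterable[EyeRecord], metric: str, timepoint: str) -> np.ndarray:
    return np.array([r.value(metric, timepoint) for r in records], dtype=float)


def _stats(data: np.ndarray, metric: str, timepoint: str) -> SummaryStats:
    if data.size < 2:
        raise InsufficientDataError(
            f"need at least 2 records for summary statistics, got {data.size}"
        )
    return SummaryStats(
        n=int(data.size),
        mean=float(np.mean(data)),
        sd=float(np.std(data, ddof=1)),
        median=float(np.median(data)),
        min=float(np.min(data)),
        max=float(np.max(data)),
        metric=metric,
        timepoint=timepoint,
    )


def summarize(
    records: Sequence[EyeRecord], metric: str, timepoint: str
) -> SummaryStats:
    """Summary statistics of one metric at one visit across eyes.

    Values are never rounded here; callers that display results round at
    the edge.
    """
    _check_metric(metric)
    _check_timepoint(timepoint)
    return _stats(_values(records, metric, timepoint), metric, timepoint)


def summarize_change(
    records: Sequence[EyeRecord], metric: str, followup: str
) -> SummaryStats:
    """Summary statistics of per-eye loss (baseline minus follow-up).

    The mean of the paired differences equals the difference of the two
    visit means; the SD is the dispersion the change-score design formula
    consumes.
    """
    _check_metric(metric)
    _check_timepoint(followup, FOLLOWUPS)
    diffs = _values(records, metric, "baseline") - _values(records, metric, followup)
    return _stats(diffs, metric, f"baseline-{followup}")
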