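"""Cohort parsing and summary statistics."""

import io
import itertools
import logging

import pytest

from gciplpower import EyeRecord, read_cohort, summarize, summarize_change
from gciplpower.cohort import METRICS, FOLLOWUPS, TIMEPOINTS
from gciplpower.errors import (
    CohortParseError,
    CohortValidationError,
    InsufficientDataError,
)

HEADER = "case_id,laterality,metric,timepoint,value\n"

# Printed cohort statistics (mean, sd) to their published precision,
# plus the two baseline medians.  The pilot's follow-up medians printed
# alongside them do not reproduce from the raw data and are not asserted.
PRINTED_STATS = [
    ("thickness", "baseline", 73.664, 18.497),
    ("thickness", "m2", 51.576, 12.611),
    ("thickness", "m6", 46.288, 11.876),
    ("volume", "baseline", 0.534, 0.134),
    ("volume", "m2", 0.376, 0.091),
    ("volume", "m6", 0.336, 0.084),
]


def make_flat_records(n, thickness=50.0, volume=0.5):
    """n eyes all carrying the same constant measurements."""
    return [
        EyeRecord(
            case_id=f"C{i}",
            laterality="OD" if i % 2 == 0 else "OS",
            thickness_um={t: thickness for t in TIMEPOINTS},
            volume_mm3={t: volume for t in TIMEPOINTS},
        )
        for i in range(n)
    ]


def test_pilot_cohort_shape(pilot):
    assert len(pilot) == 5
    assert len({r.case_id for r in pilot}) == 4
    assert len({r.key for r in pilot}) == 5


@pytest.mark.parametrize("metric,timepoint,mean,sd", PRINTED_STATS)
def test_pilot_summary_matches_printed_values(pilot, metric, timepoint, mean, sd):
    stats = summarize(pilot, metric, timepoint)
    digits = 3
    assert round(stats.mean, digits) == mean
    assert round(stats.sd, digits) == sd
    assert stats.n == 5


def test_pilot_baseline_medians_and_ranges(pilot):
    th = summarize(pilot, "thickness", "baseline")
    assert th.median == pytest.approx(79.67)
    assert (th.min, th.max) == (41.66, 87.77)
    vol = summarize(pilot, "volume", "baseline")
    assert vol.median == pytest.approx(0.58)
    assert (vol.min, vol.max) == (0.30, 0.62)


def test_change_scores_volume_m6(pilot):
    stats = summarize_change(pilot, "volume", "m6")
    assert stats.mean == pytest.approx(0.198)
    # hand-computed per-eye losses from the fixture
    assert sorted(
        round(r.value("volume", "baseline") - r.value("volume", "m6"), 10)
        for r in pilot
    ) == [0.05, 0.14, 0.25, 0.25, 0.30]


@pytest.mark.parametrize(
    "metric,followup", list(itertools.product(METRICS, FOLLOWUPS))
)
def test_change_mean_equals_difference_of_means(pilot, metric, followup):
    change = summarize_change(pilot, metric, followup)
    base = summarize(pilot, metric, "baseline")
    after = summarize(pilot, metric, followup)
    assert change.mean == pytest.approx(base.mean - after.mean, abs=1e-12)


def test_summarize_is_permutation_invariant(pilot):
    reference = summarize(pilot, "volume", "m2")
    for perm in itertools.permutations(pilot):
        shuffled = summarize(list(perm), "volume", "m2")
        # mean/sd agree to summation-order rounding; order stats exactly
        assert shuffled.mean == pytest.approx(reference.mean, rel=1e-14)
        assert shuffled.sd == pytest.approx(reference.sd, rel=1e-14)
        assert (shuffled.median, shuffled.min, shuffled.max) == (
            reference.median, reference.min, reference.max,
        )


def test_degenerate_cohort_has_zero_dispersion():
    records = make_flat_records(5, thickness=42.0)
    stats = summarize(records, "thickness", "m2")
    assert stats.sd == 0.0
    assert stats.mean == stats.median == 42.0
    change = summarize_change(records, "thickness", "m6")
    assert change.mean == change.sd == 0.0


def test_even_cohort_median_is_midpoint():
    records = make_flat_records(4)
    for i, r in enumerate(records):
        r.volume_mm3["baseline"] = 0.1 * (i + 1)
    stats = summarize(records, "volume", "baseline")
    assert stats.median == pytest.approx(0.25)


def test_summarize_requires_two_records(pilot):
    with pytest.raises(InsufficientDataError):
        summarize(pilot[:1], "volume", "baseline")


def test_read_roundtrip_of_pilot_fixture(pilot):
    from gciplpower.simulate import cohort_to_frame

    buffer = io.StringIO()
    cohort_to_frame(pilot).to_csv(buffer, index=False)
    buffer.seek(0)
    again = read_cohort(buffer)
    assert {r.key for r in again} == {r.key for r in pilot}


def test_empty_file_with_header_warns(caplog):
    with caplog.at_level(logging.WARNING, logger="gciplpower.cohort"):
        records = read_cohort(io.StringIO(HEADER))
    assert records == []
    assert any("no records" in m for m in caplog.messages)


def test_missing_measurement_names_the_eye():
    rows = [
        HEADER,
        "1,OD,mgcipl_thickness_um,baseline,80.0\n",
        "1,OD,mgcipl_thickness_um,m2,60.0\n",
        "1,OD,mgcipl_thickness_um,m6,55.0\n",
        "1,OD,mgcipl_volume_mm3,baseline,0.6\n",
        "1,OD,mgcipl_volume_mm3,m2,0.5\n",
        # m6 volume row deliberately absent
    ]
    with pytest.raises(CohortValidationError, match="1/OD"):
        read_cohort(io.StringIO("".join(rows)))


def test_non_numeric_cell_reports_row_number():
    text = HEADER + "1,OD,mgcipl_thickness_um,baseline,eighty\n"
    with pytest.raises(CohortParseError, match="row 2"):
        read_cohort(io.StringIO(text))


def test_bad_header_rejected():
    with pytest.raises(CohortParseError, match="header"):
        read_cohort(io.StringIO("id,eye,value\n1,OD,3\n"))


def test_invalid_laterality_rejected():
    with pytest.raises(CohortValidationError, match="laterality"):
        EyeRecord(
            case_id="1",
            laterality="LEFT",
            thickness_um={t: 50.0 for t in TIMEPOINTS},
            volume_mm3={t: 0.5 for t in TIMEPOINTS},
        )


def test_nonpositive_value_rejected():
    with pytest.raises(CohortValidationError, match="positive"):
        EyeRecord(
            case_id="1",
            laterality="OD",
            thickness_um={"baseline": 50.0, "m2": 0.0, "m6": 40.0},
            volume_mm3={t: 0.5 for t in TIMEPOINTS},
        )
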