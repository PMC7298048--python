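"""Tumor-volume response metrics and mRECIST classification for PDX trials.

A PDX preclinical trial ("1x1x1" design) treats one animal per model per arm
and reads out drug response from longitudinal caliper measurements. This
module converts caliper pairs to volumes (V = length x width^2 / 2), expresses
each trajectory as percent change from baseline, and summarises it with two
statistics:

* ``best_response`` — the minimum percent change over days >= 10 (how deep the
  regression got, ignoring transient early dips);
* ``best_avg_response`` — the minimum over days t >= 14 of the mean percent
  change from day 0 through t (a duration-weighted depth of response).

The pair is mapped to an mRECIST category (CR / PR / SD / PD) by strict
threshold rules, mirroring the published convention for mouse clinical trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VolumeSeries",
    "ResponseRecord",
    "MrecistCriteria",
    "DEFAULT_CRITERIA",
    "InvalidMeasurementError",
    "InsufficientObservationError",
    "volume_from_calipers",
    "percent_change_series",
    "best_avg_response",
    "best_response",
    "classify_mrecist",
    "doubling_event",
    "response_record",
    "responses_from_measurements",
]


class InvalidMeasurementError(ValueError):
    """A caliper or volume value violates the measurement contract."""


class InsufficientObservationError(ValueError):
    """The series does not span the window a statistic requires."""


@dataclass(frozen=True)
class VolumeSeries:
    """One animal's (day, volume) trajectory.

    ``days`` are offsets (in days) from treatment start, strictly increasing
    and starting at 0; ``volumes`` are mm^3, aligned with ``days``.
    """

    model_id: str
    arm: str
    animal_id: str
    days: tuple[float, ...]
    volumes: tuple[float, ...]

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.days)
        vols = tuple(float(v) for v in self.volumes)
        if len(days) != len(vols):
            raise InvalidMeasurementError("days and volumes differ in length")
        if len(days) == 0:
            raise InvalidMeasurementError("empty series")
        if days[0] != 0:
            raise InvalidMeasurementError("first day must be 0 (baseline)")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise InvalidMeasurementError("days must be strictly increasing")
        if any(v < 0 for v in vols):
            raise InvalidMeasurementError("volumes must be non-negative")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "volumes", vols)

    @property
    def baseline_volume(self) -> float:
        return self.volumes[0]

    def truncated(self, horizon: float) -> "VolumeSeries":
        """Drop measurements after ``horizon`` days (study-window truncation)."""
        keep = [i for i, d in enumerate(self.days) if d <= horizon]
        return VolumeSeries(
            self.model_id,
            self.arm,
            self.animal_id,
            tuple(self.days[i] for i in keep),
            tuple(self.volumes[i] for i in keep),
        )


@dataclass(frozen=True)
class MrecistCriteria:
    """Ordered strict-inequality thresholds on (BestResponse, BestAvgResponse).

    Rules are applied first-match: CR, then PR, then SD; anything else is PD.
    """

    cr: tuple[float, float] = (-95.0, -40.0)
    pr: tuple[float, float] = (-50.0, -20.0)
    sd: tuple[float, float] = (35.0, 30.0)

    def ordered_rules(self) -> list[tuple[str, tuple[float, float]]]:
        return [("CR", self.cr), ("PR", self.pr), ("SD", self.sd)]


DEFAULT_CRITERIA = MrecistCriteria()

#: category order from best to worst, used for monotonicity reasoning
CATEGORY_ORDER = ("CR", "PR", "SD", "PD")


@dataclass(frozen=True)
class ResponseRecord:
    """Response summary for one model x arm."""

    model_id: str
    arm: str
    days: tuple[float, ...]
    delta_series: tuple[float, ...]
    best_response: float
    best_avg_response: float
    mrecist: str
    n_days_observed: float = field(default=0.0)


def volume_from_calipers(length_mm: float, width_mm: float) -> float:
    """Ellipsoid-approximation tumor volume, V = (length x width^2) / 2 mm^3.

    Length is the larger caliper dimension; if the pair arrives swapped it is
    corrected with a warning rather than rejected.
    """
    if length_mm < 0 or width_mm < 0:
        raise InvalidMeasurementError(
            f"negative caliper measurement ({length_mm}, {width_mm})"
        )
    if width_mm > length_mm:
        warnings.warn(
            f"width {width_mm} > length {length_mm}; swapping", stacklevel=2
        )
        length_mm, width_mm = width_mm, length_mm
    return (length_mm * width_mm**2) / 2.0


def percent_change_series(series: VolumeSeries) -> tuple[float, ...]:
    """Percent volume change from baseline at every day; exactly 0 at day 0."""
    v0 = series.baseline_volume
    if v0 <= 0:
        raise InvalidMeasurementError("baseline volume must be > 0")
    return tuple(((v - v0) / v0) * 100.0 for v in series.volumes)


def best_avg_response(
    series: VolumeSeries, window_start: float = 14.0
) -> float:
    """Minimum over eligible days t (>= window_start) of mean(delta[0..t]).

    The day-0 value (always 0) is included in every running mean.
    """
    deltas = percent_change_series(series)
    days = series.days
    means = [
        float(np.mean(deltas[: i + 1]))
        for i, d in enumerate(days)
        if d >= window_start
    ]
    if not means:
        raise InsufficientObservationError(
            f"no measurement day >= {window_start}"
        )
    return min(means)


def best_response(series: VolumeSeries, window_start: float = 10.0) -> float:
    """Minimum percent change over days >= window_start."""
    deltas = percent_change_series(series)
    eligible = [dv for d, dv in zip(series.days, deltas) if d >= window_start]
    if not eligible:
        raise InsufficientObservationError(
            f"no measurement day >= {window_start}"
        )
    return min(eligible)


def classify_mrecist(
    best_response: float,
    best_avg_response: float,
    criteria: MrecistCriteria = DEFAULT_CRITERIA,
) -> str:
    """First-match mRECIST call from the two response statistics.

    All comparisons are strict: e.g. BestResponse exactly -95 does not qualify
    for CR.
    """
    for category, (br_thr, bar_thr) in criteria.ordered_rules():
        if best_response < br_thr and best_avg_response < bar_thr:
            return category
    return "PD"


def doubling_event(series: VolumeSeries) -> tuple[float, int]:
    """Time to first volume doubling, censored at the last day if none.

    Returns ``(time_days, event)`` with ``event=1`` at the first measurement
    day where V >= 2 x baseline (inclusive), else ``event=0`` at the final day.
    """
    v0 = series.baseline_volume
    if v0 <= 0:
        raise InvalidMeasurementError("baseline volume must be > 0")
    for day, vol in zip(series.days, series.volumes):
        if day > 0 and vol >= 2.0 * v0:
            return (day, 1)
    return (series.days[-1], 0)


def response_record(
    series: VolumeSeries,
    horizon: float = 28.0,
    bar_window: float = 14.0,
    br_window: float = 10.0,
    criteria: MrecistCriteria = DEFAULT_CRITERIA,
) -> ResponseRecord:
    """Full response summary for one trajectory, truncated at ``horizon`` days."""
    series = series.truncated(horizon)
    deltas = percent_change_series(series)
    br = best_response(series, br_window)
    bar = best_avg_response(series, bar_window)
    return ResponseRecord(
        model_id=series.model_id,
        arm=series.arm,
        days=series.days,
        delta_series=deltas,
        best_response=br,
        best_avg_response=bar,
        mrecist=classify_mrecist(br, bar, criteria),
        n_days_observed=series.days[-1],
    )


def series_from_measurements(measurements: pd.DataFrame) -> list[VolumeSeries]:
    """Build per-animal volume series from a caliper measurement table.

    Expects columns ``model_id, arm, animal_id, day, length_mm, width_mm``.
    Rows with missing calipers are skipped (never interpolated).
    """
    required = {"model_id", "arm", "animal_id", "day", "length_mm", "width_mm"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns {sorted(missing)}")
    out: list[VolumeSeries] = []
    grouped = measurements.dropna(subset=["length_mm", "width_mm"]).groupby(
        ["model_id", "arm", "animal_id"], sort=True
    )
    for (model_id, arm, animal_id), grp in grouped:
        grp = grp.sort_values("day")
        vols = [
            volume_from_calipers(l, w)
            for l, w in zip(grp["length_mm"], grp["width_mm"])
        ]
        out.append(
            VolumeSeries(
                str(model_id), str(arm), str(animal_id),
                tuple(grp["day"]), tuple(vols),
            )
        )
    return out


def responses_from_measurements(
    measurements: pd.DataFrame,
    horizon: float = 28.0,
    bar_window: float = 14.0,
    br_window: float = 10.0,
    criteria: MrecistCriteria = DEFAULT_CRITERIA,
) -> pd.DataFrame:
    """Response table (one row per model x arm x animal) from caliper data.

    Animals whose observation span ends before the BestAvgResponse window
    opens are excluded with a warning — their response is undefined.
    """
    rows = []
    for series in series_from_measurements(measurements):
        try:
            rec = response_record(series, horizon, bar_window, br_window, criteria)
        except InsufficientObservationError:
            warnings.warn(
                f"{series.model_id}/{series.arm}: series ends before day "
                f"{bar_window}; excluded",
                stacklevel=2,
            )
            continue
        d_time, d_event = doubling_event(series.truncated(horizon))
        rows.append(
            {
                "model_id": rec.model_id,
                "arm": rec.arm,
                "best_response": rec.best_response,
                "best_avg_response": rec.best_avg_response,
                "mrecist": rec.mrecist,
                "n_days": rec.n_days_observed,
                "doubling_time": d_time,
                "doubling_event": d_event,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "model_id", "arm", "best_response", "best_avg_response",
            "mrecist", "n_days", "doubling_time", "doubling_event",
        ],
    )
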