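"""Caliber dynamicity at fixed locations over time.

A location (by convention 3 um from a branch point) is tracked across a
time-lapse at 5-minute intervals; its fluctuation is summarized as the
sample SD (absolute dynamicity) and %RSD = (SD / mean caliber) * 100
(relative dynamicity).  Frames where the caliber could not be scored are
missing data: they are excluded from the statistics but reported via
``n_valid``, so under-resolved thin axons are never silently averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .branching import RegressionResult, linear_fit
from .stats import PairedSample, TestResult, paired_permutation_test

__all__ = [
    "LocationTimeSeries",
    "DynamicsSummary",
    "PairedDynamics",
    "DayComparison",
    "summarize_dynamics",
    "dynamicity_regressions",
    "compare_days",
]


@dataclass
class LocationTimeSeries:
    """Caliber at one fixed location across frames; NaN marks missing entries."""

    location_id: str
    segment_id: int
    arc_pos: float
    frame_times: np.ndarray
    calibers: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.calibers = np.asarray(self.calibers, dtype=float)
        if self.frame_times.shape != self.calibers.shape:
            raise ValueError("frame_times and calibers must align")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must strictly increase")

    @property
    def valid_calibers(self) -> np.ndarray:
        return self.calibers[np.isfinite(self.calibers)]


@dataclass
class DynamicsSummary:
    location_id: str
    mean_caliber: float
    sd: float
    pct_rsd: float
    n_valid: int
    fold_range: float


@dataclass
class PairedDynamics:
    """Per-location %RSD on two imaging days, paired by location identity.

    Either day may be NaN when the location could not be re-measured;
    such locations are dropped from the comparison with a count.
    """

    location_ids: list[str]
    pct_rsd_day1: np.ndarray
    pct_rsd_day2: np.ndarray

    def __post_init__(self) -> None:
        self.pct_rsd_day1 = np.asarray(self.pct_rsd_day1, dtype=float)
        self.pct_rsd_day2 = np.asarray(self.pct_rsd_day2, dtype=float)
        if not (len(self.location_ids) == len(self.pct_rsd_day1) == len(self.pct_rsd_day2)):
            raise ValueError("location_ids and both day arrays must align")


@dataclass
class DayComparison:
    mean_day1: float
    mean_day2: float
    p_value: float
    n_pairs: int
    n_dropped: int
    test: TestResult


def summarize_dynamics(series: LocationTimeSeries) -> DynamicsSummary:
    """Mean, sample SD, %RSD and fold range of one location's time series.

    The SD uses the n-1 (sample) convention; missing frames are excluded
    from every statistic.
    """
    vals = series.valid_calibers
    if len(vals) < 2:
        raise ValueError(
            f"location {series.location_id}: need >= 2 valid calibers, got {len(vals)}"
        )
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return DynamicsSummary(
        location_id=series.location_id,
        mean_caliber=mean,
        sd=sd,
        pct_rsd=100.0 * sd / mean,
        n_valid=int(len(vals)),
        fold_range=float(vals.max() / vals.min()),
    )


def dynamicity_regressions(
    summaries: list[DynamicsSummary],
) -> tuple[RegressionResult, RegressionResult]:
    """Regressions of absolute (SD) and relative (%RSD) dynamicity on mean caliber."""
    if len(summaries) < 3:
        raise ValueError("need at least 3 location summaries")
    means = [s.mean_caliber for s in summaries]
    sd_fit = linear_fit(means, [s.sd for s in summaries])
    rsd_fit = linear_fit(means, [s.pct_rsd for s in summaries])
    return sd_fit, rsd_fit


def compare_days(
    paired: PairedDynamics,
    n_perm: int = 10000,
    seed: int | None = None,
) -> DayComparison:
    """Paired comparison of per-location %RSD across two imaging days.

    Locations missing either day are dropped (counted in ``n_dropped``);
    significance comes from the two-sided paired permutation test.
    """
    ok = np.isfinite(paired.pct_rsd_day1) & np.isfinite(paired.pct_rsd_day2)
    n_dropped = int(np.count_nonzero(~ok))
    d1 = paired.pct_rsd_day1[ok]
    d2 = paired.pct_rsd_day2[ok]
    if len(d1) < 2:
        raise ValueError("need at least 2 complete pairs")
    test = paired_permutation_test(PairedSample(d1, d2), n_perm=n_perm, seed=seed)
    return DayComparison(
        mean_day1=float(d1.mean()),
        mean_day2=float(d2.mean()),
        p_value=test.p_value,
        n_pairs=int(len(d1)),
        n_dropped=n_dropped,
        test=test,
    )
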