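"""Axon caliber and pearling around dividing basal cells.

A mitotic basal cell pulls its borders inward and rounds up; the axon
anchored at its borders is compared against the stretches on the two
flanking non-dividing neighbors.  The round and flat time points are the
consecutive frame pair across which the planar border-to-border length
increases the most; the rounded apical surface is modeled as a circular
arc of chord c and sagitta h, giving the theoretical change in axon path
length relative to the flat chord of length l.  Pearling over a span is
the sample SD of calibers at 1-um increments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .linescan import CaliberMeasurement
from .stats import PairedSample, TestResult, paired_permutation_test, rank_sum_test

__all__ = [
    "RegionLabeledMeasurements",
    "RegionComparison",
    "CellRoundingGeometry",
    "PearlingChange",
    "PairedComparison",
    "region_comparison",
    "select_round_flat_frames",
    "paired_round_flat_comparison",
    "arc_path_length",
    "pearling",
    "pearling_change",
]

REGIONS = ("dividing", "neighbor1", "neighbor2")


@dataclass
class RegionLabeledMeasurements:
    """Caliber measurements labeled by the cell region they sit over."""

    measurements: list[CaliberMeasurement]
    regions: list[str]

    def __post_init__(self) -> None:
        if len(self.measurements) != len(self.regions):
            raise ValueError("one region label per measurement required")
        bad = set(self.regions) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")

    def calibers_in(self, region: str) -> np.ndarray:
        vals = [
            m.caliber
            for m, r in zip(self.measurements, self.regions)
            if r == region and m.valid
        ]
        return np.asarray(vals, dtype=float)


@dataclass
class RegionComparison:
    means: dict[str, float]
    tests: dict[tuple[str, str], TestResult]
    skipped: list[str] = field(default_factory=list)


@dataclass
class CellRoundingGeometry:
    """Circular-segment model of the rounded cell: chord c, sagitta h."""

    flat_length: float  # l
    rounded_extent: float  # c
    rounded_height: float  # h
    arc_length: float
    path_ratio: float  # arc_length / l


@dataclass
class PearlingChange:
    pearling_round: float
    pearling_flat: float
    delta: float  # flat - round


@dataclass
class PairedComparison:
    mean_round: float
    mean_flat: float
    p_value: float
    n_pairs: int
    n_dropped: int
    test: TestResult


def region_comparison(labeled: RegionLabeledMeasurements) -> RegionComparison:
    """Per-region mean calibers and pairwise two-sided rank-sum tests.

    A region with fewer than 2 valid measurements drops out of its
    pairwise comparisons with a note; its mean is still reported when any
    measurement exists.
    """
    means: dict[str, float] = {}
    samples: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for region in REGIONS:
        vals = labeled.calibers_in(region)
        samples[region] = vals
        if len(vals):
            means[region] = float(vals.mean())
    tests: dict[tuple[str, str], TestResult] = {}
    for i, a in enumerate(REGIONS):
        for b in REGIONS[i + 1 :]:
            if len(samples[a]) < 2 or len(samples[b]) < 2:
                skipped.append(f"{a} vs {b}: fewer than 2 measurements in a region")
                continue
            tests[(a, b)] = rank_sum_test(samples[a], samples[b])
    return RegionComparison(means=means, tests=tests, skipped=skipped)


def select_round_flat_frames(border_lengths) -> tuple[int, int]:
    """Pick the consecutive frame pair with the largest length increase.

    The round frame is the first of the pair, the flat frame the second;
    ties resolve to the earliest pair.  If no pair increases, no
    flattening was captured and an error is raised.
    """
    lengths = np.asarray(border_lengths, dtype=float)
    if len(lengths) < 2:
        raise ValueError("need at least 2 frames")
    diffs = np.diff(lengths)
    if np.all(diffs <= 0):
        raise ValueError("border-to-border length never increases; no flattening captured")
    i = int(np.argmax(diffs))  # argmax returns the earliest maximal index
    return i, i + 1


def paired_round_flat_comparison(
    round_calibers: dict[str, float],
    flat_calibers: dict[str, float],
    n_perm: int = 10000,
    seed: int | None = None,
) -> PairedComparison:
    """Compare calibers at matched locations between the round and flat frames.

    Inputs map location id -> caliber; locations present in only one frame
    are dropped with a count.  Significance comes from the two-sided
    paired permutation test on the per-location differences.
    """
    common = sorted(set(round_calibers) & set(flat_calibers))
    n_dropped = len(set(round_calibers) ^ set(flat_calibers))
    if len(common) < 2:
        raise ValueError("need at least 2 matched locations")
    r = np.array([round_calibers[k] for k in common], dtype=float)
    f = np.array([flat_calibers[k] for k in common], dtype=float)
    test = paired_permutation_test(PairedSample(r, f), n_perm=n_perm, seed=seed)
    return PairedComparison(
        mean_round=float(r.mean()),
        mean_flat=float(f.mean()),
        p_value=test.p_value,
        n_pairs=len(common),
        n_dropped=n_dropped,
        test=test,
    )


def arc_path_length(flat_length: float, rounded_extent: float, rounded_height: float) -> CellRoundingGeometry:
    """Arc length of the axon path over the rounded cell.

    The apical surface is a circular segment with chord c and sagitta h:
    R = (c^2 + 4 h^2) / (8 h), arc = 2 R asin(c / 2R); h = 0 degenerates
    to the straight chord.  ``path_ratio`` compares the arc to the flat
    chord of length l.
    """
    l, c, h = float(flat_length), float(rounded_extent), float(rounded_height)
    if not (l >= c > 0):
        raise ValueError("require flat_length >= rounded_extent > 0")
    if h < 0:
        raise ValueError("rounded_height must be non-negative")
    if h == 0:
        arc = c
    else:
        R = (c**2 + 4.0 * h**2) / (8.0 * h)
        half_angle = math.asin(min(c / (2.0 * R), 1.0))
        if h > c / 2.0:  # deeper than a semicircle: the major arc applies
            half_angle = math.pi - half_angle
        arc = 2.0 * R * half_angle
    return CellRoundingGeometry(
        flat_length=l,
        rounded_extent=c,
        rounded_height=h,
        arc_length=arc,
        path_ratio=arc / l,
    )


def pearling(calibers) -> float:
    """Pearling of a lengthwise caliber profile: sample SD of the calibers."""
    vals = np.asarray(calibers, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 3:
        raise ValueError("need at least 3 locations for a pearling estimate")
    return float(vals.std(ddof=1))


def pearling_change(round_profile, flat_profile) -> PearlingChange:
    """Pearling on the round and flat frames and the flat-minus-round change."""
    p_round = pearling(round_profile)
    p_flat = pearling(flat_profile)
    return PearlingChange(pearling_round=p_round, pearling_flat=p_flat, delta=p_flat - p_round)
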