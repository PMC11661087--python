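"""Branch-point symmetry and taper statistics.

At a branch point the segment entering from the spinal-cord side is the
primary (P); the thicker and thinner daughters are S1 and S2.  Segment
caliber is the mean of measurements 3, 4 and 5 um from the branch point.
Symmetry is S2/S1, identically equal to the normalized-S2 over
normalized-S1 ratio; taper is summarized by the combined secondary
cross-sectional area over the primary area and by the radius scaling
ratios S1/P and S2/P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .linescan import CaliberMeasurement

__all__ = [
    "BranchPointRecord",
    "TaperSummary",
    "RegressionResult",
    "SegmentUnusableError",
    "segment_mean_caliber",
    "assign_branch_roles",
    "taper_ratios",
    "linear_fit",
    "branch_records",
    "pooled_scaling_ratios",
    "MEAN_POSITIONS_UM",
]

MEAN_POSITIONS_UM = (3.0, 4.0, 5.0)


class SegmentUnusableError(ValueError):
    """A segment cannot contribute a mean caliber (missing/flagged positions)."""


@dataclass
class BranchPointRecord:
    """Mean calibers (um) of the three segments meeting at one branch point."""

    P: float
    S1: float
    S2: float
    branch_point_id: str = ""

    def __post_init__(self) -> None:
        if not (self.S1 >= self.S2 > 0):
            raise ValueError("require S1 >= S2 > 0")
        if self.P <= 0:
            raise ValueError("require P > 0")

    @property
    def norm_S1(self) -> float:
        return self.S1 / self.P

    @property
    def norm_S2(self) -> float:
        return self.S2 / self.P

    @property
    def symmetry(self) -> float:
        return self.S2 / self.S1


@dataclass
class TaperSummary:
    area_P: float
    area_S1: float
    area_S2: float
    area_ratio: float
    ratio_S1: float
    ratio_S2: float
    pooled: tuple[float, float]  # {S1/P, S2/P} entries for population averaging


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


def segment_mean_caliber(measurements: list[CaliberMeasurement]) -> float:
    """Mean of the calibers at exactly 3, 4 and 5 um from the branch point.

    Any flagged or missing position makes the segment unusable (the caller
    logs it as an exclusion rather than averaging fewer points).
    """
    by_pos: dict[float, CaliberMeasurement] = {}
    for m in measurements:
        for p in MEAN_POSITIONS_UM:
            if math.isclose(m.arc_pos, p, abs_tol=1e-6):
                by_pos[p] = m
    missing = [p for p in MEAN_POSITIONS_UM if p not in by_pos]
    if missing:
        raise SegmentUnusableError(f"missing measurements at {missing} um")
    bad = [p for p, m in by_pos.items() if not m.valid]
    if bad:
        raise SegmentUnusableError(f"flagged measurements at {sorted(bad)} um")
    return float(np.mean([by_pos[p].caliber for p in MEAN_POSITIONS_UM]))


def assign_branch_roles(
    primary_mean: float,
    secondary_means: dict[int, float],
    branch_point_id: str = "",
) -> BranchPointRecord:
    """Designate the thicker secondary S1 and the thinner S2.

    Exactly two secondaries are required.  On an exact tie the segment
    with the lower id is S1 (deterministic; symmetry is 1 either way).
    """
    if len(secondary_means) != 2:
        raise ValueError(f"expected exactly 2 secondary segments, got {len(secondary_means)}")
    # sort by caliber descending, then id ascending for the tie
    (id_a, c_a), (id_b, c_b) = sorted(
        secondary_means.items(), key=lambda kv: (-kv[1], kv[0])
    )
    return BranchPointRecord(P=primary_mean, S1=c_a, S2=c_b, branch_point_id=branch_point_id)


def taper_ratios(record: BranchPointRecord) -> TaperSummary:
    """Cross-sectional-area taper ratio and radius scaling ratios.

    area = pi * (caliber/2)^2; area_ratio = (area_S1 + area_S2) / area_P,
    which equals (S1/P)^2 + (S2/P)^2 exactly.
    """
    area = lambda c: math.pi * (c / 2.0) ** 2
    a_p, a_1, a_2 = area(record.P), area(record.S1), area(record.S2)
    return TaperSummary(
        area_P=a_p,
        area_S1=a_1,
        area_S2=a_2,
        area_ratio=(a_1 + a_2) / a_p,
        ratio_S1=record.S1 / record.P,
        ratio_S2=record.S2 / record.P,
        pooled=(record.S1 / record.P, record.S2 / record.P),
    )


def pooled_scaling_ratios(records: list[BranchPointRecord]) -> float:
    """Population-average radius scaling ratio S/P.

    Each branch point contributes both S1/P and S2/P, matching the
    combined-mean construction used for comparison with optimization
    theory.
    """
    if not records:
        raise ValueError("no records")
    vals = []
    for r in records:
        vals.extend(taper_ratios(r).pooled)
    return float(np.mean(vals))


def branch_records(
    measurements: list[CaliberMeasurement],
    centerline,
) -> tuple[list[BranchPointRecord], list[str]]:
    """Assemble branch-point records from per-segment measurements.

    Measurement arc positions are taken from each segment's own origin;
    child segments start at their branch point, so their 3/4/5 um
    positions are direct, while the primary's are its length minus 3/4/5.
    Branch points whose segments cannot contribute a clean mean are
    logged, not errored.
    """
    import dataclasses as _dc

    by_seg: dict[int, list[CaliberMeasurement]] = {}
    for m in measurements:
        by_seg.setdefault(m.segment_id, []).append(m)
    records: list[BranchPointRecord] = []
    log: list[str] = []
    for k, bp in enumerate(centerline.branch_points):
        if bp.parent_id is None or len(bp.child_ids) != 2:
            log.append(f"branch point {k}: needs a primary and exactly 2 children")
            continue
        try:
            plen = centerline.segment_length(bp.parent_id)
            primary_ms = [
                _dc.replace(m, arc_pos=plen - m.arc_pos)
                for m in by_seg.get(bp.parent_id, [])
            ]
            p_mean = segment_mean_caliber(primary_ms)
            sec = {
                cid: segment_mean_caliber(by_seg.get(cid, [])) for cid in bp.child_ids
            }
            records.append(assign_branch_roles(p_mean, sec, branch_point_id=str(k)))
        except SegmentUnusableError as exc:
            log.append(f"branch point {k}: {exc}")
    return records, log


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares with r^2 = 1 - SS_res/SS_tot.

    Constant x is an error; constant y gives r^2 = 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    r2 = res.rvalue**2
    if not np.isfinite(r2):  # constant y
        r2 = 0.0
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept), r_squared=float(r2))
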