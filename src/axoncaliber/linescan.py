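"""Line-scan caliber measurement.

Caliber is scored as the distance between the two plasma-membrane
intensity peaks on a profile taken perpendicular to the axon's center
axis.  The centerline is an annotation (or generator truth), never traced
automatically.  Measurements that cannot be scored — merged peaks below
the resolution limit, a single peak, an ambiguous neighborhood — carry
flags instead of silently reporting a number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates
from scipy.signal import find_peaks

from .geometry import point_at, polyline_arclength, tangent_and_normal

__all__ = [
    "ImageFrame",
    "CenterlineAnnotation",
    "LineScanProfile",
    "CaliberMeasurement",
    "MeasurementConfig",
    "MeasurementSet",
    "ExclusionRecord",
    "ScanOutOfBoundsError",
    "FlatProfileError",
    "extract_profile",
    "measure_caliber",
    "measure_along_segment",
    "apply_exclusion_rules",
    "centerline_from_truth",
]


class ScanOutOfBoundsError(ValueError):
    pass


class FlatProfileError(ValueError):
    pass


@dataclass
class ImageFrame:
    """One 2D image with its pixel size (um/px) and acquisition time (min)."""

    pixels: np.ndarray
    pixel_size: float
    frame_time: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class BranchPointAnnotation:
    location: tuple[float, float]
    parent_id: int | None = None
    child_ids: tuple[int, ...] = ()


@dataclass
class CenterlineAnnotation:
    """User-supplied (or generator-derived) centerline geometry in um."""

    segments: dict[int, np.ndarray]
    branch_points: list[BranchPointAnnotation] = field(default_factory=list)
    parents: dict[int, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.segments = {int(k): np.asarray(v, dtype=float) for k, v in self.segments.items()}

    def segment_length(self, segment_id: int) -> float:
        return float(polyline_arclength(self.segments[segment_id])[-1])

    def branch_arc_positions(self, segment_id: int, tol: float = 0.25) -> list[float]:
        """Arc positions along ``segment_id`` of branch points lying on it."""
        pts = self.segments[segment_id]
        cum = polyline_arclength(pts)
        out = []
        for bp in self.branch_points:
            loc = np.asarray(bp.location, dtype=float)
            d2 = np.sum((pts - loc) ** 2, axis=1)
            # nearest vertex is a good enough projection at annotation density
            i = int(np.argmin(d2))
            if np.sqrt(d2[i]) <= tol:
                out.append(float(cum[i]))
        return out


def centerline_from_truth(truth) -> CenterlineAnnotation:
    """Build a measurement annotation from generator ground truth."""
    bps = [
        BranchPointAnnotation(
            location=tuple(np.asarray(bp.location, dtype=float)),
            parent_id=bp.parent_id,
            child_ids=tuple(bp.child_ids),
        )
        for bp in truth.branch_points
    ]
    parents: dict[int, int | None] = {sid: None for sid in truth.segments}
    for bp in bps:
        for cid in bp.child_ids:
            parents[cid] = bp.parent_id
    return CenterlineAnnotation(
        segments={k: v.copy() for k, v in truth.segments.items()},
        branch_points=bps,
        parents=parents,
    )


@dataclass
class LineScanProfile:
    """One perpendicular intensity profile: offsets (um, symmetric about 0)."""

    center: np.ndarray
    direction: np.ndarray
    offsets: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")
        n = np.linalg.norm(np.asarray(self.direction, dtype=float))
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("direction must be a unit vector")


@dataclass
class CaliberMeasurement:
    """Caliber at one location; ``caliber`` is present only when scorable."""

    segment_id: int
    arc_pos: float
    caliber: float | None = None
    peak_positions: tuple[float, float] | None = None
    below_resolution: bool = False
    single_peak: bool = False
    ambiguous_peaks: bool = False
    frame_time: float = 0.0

    @property
    def valid(self) -> bool:
        return self.caliber is not None and not self.below_resolution


@dataclass
class MeasurementConfig:
    """Line-scan parameters.

    ``scan_step`` and ``smoothing_sd`` default to half a pixel and one
    pixel respectively when left as None; ``smoothing_sd = 0`` disables
    smoothing.  ``resolution_limit`` is the system's lateral resolution in
    um: calibers below it are flagged, excluded from means, but counted
    for the fraction-below-resolution exclusion rule.
    """

    scan_half_length: float = 1.5
    scan_step: float | None = None
    smoothing_sd: float | None = None
    peak_prominence_fraction: float = 0.1
    resolution_limit: float = 0.14
    subpixel: bool = True
    branch_exclusion_um: float = 3.0

    def __post_init__(self) -> None:
        for name in ("scan_half_length", "peak_prominence_fraction", "resolution_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scan_step is not None and self.scan_step <= 0:
            raise ValueError("scan_step must be positive")
        if self.smoothing_sd is not None and self.smoothing_sd < 0:
            raise ValueError("smoothing_sd must be non-negative")
        if self.branch_exclusion_um < 0:
            raise ValueError("branch_exclusion_um must be non-negative")


def extract_profile(
    frame: ImageFrame,
    center,
    normal,
    config: MeasurementConfig | None = None,
) -> LineScanProfile:
    """Sample intensities along ``center + offset * normal`` by bilinear interpolation.

    Pixel centers sit at integer multiples of the pixel size, so a scan
    through pixel centers at pixel-size steps reproduces pixel values
    exactly.  Raises if any offset leaves the image.
    """
    config = config or MeasurementConfig()
    center = np.asarray(center, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    step = config.scan_step if config.scan_step is not None else frame.pixel_size / 2.0
    n_half = int(round(config.scan_half_length / step))
    offsets = np.arange(-n_half, n_half + 1) * step
    pos = center[None, :] + offsets[:, None] * normal[None, :]
    cols = pos[:, 0] / frame.pixel_size
    rows = pos[:, 1] / frame.pixel_size
    nr, nc = frame.pixels.shape
    bad = (rows < 0) | (rows > nr - 1) | (cols < 0) | (cols > nc - 1)
    if np.any(bad):
        clipped = offsets[bad]
        raise ScanOutOfBoundsError(
            f"scan exits the image at offsets {clipped.min():+.2f}..{clipped.max():+.2f} um"
        )
    vals = map_coordinates(frame.pixels, [rows, cols], order=1, mode="nearest")
    sd = config.smoothing_sd if config.smoothing_sd is not None else frame.pixel_size
    if sd > 0:
        vals = gaussian_filter1d(vals, sigma=sd / step, mode="nearest")
    return LineScanProfile(center=center, direction=normal, offsets=offsets, intensities=vals)


def _parabolic_refine(offsets: np.ndarray, vals: np.ndarray, i: int) -> float:
    if i <= 0 or i >= len(vals) - 1:
        return float(offsets[i])
    denom = vals[i - 1] - 2 * vals[i] + vals[i + 1]
    if denom >= 0:  # not a strict local max in the 3-point stencil
        return float(offsets[i])
    delta = 0.5 * (vals[i - 1] - vals[i + 1]) / denom
    step = offsets[i + 1] - offsets[i]
    return float(offsets[i] + np.clip(delta, -0.5, 0.5) * step)


def measure_caliber(
    profile: LineScanProfile,
    config: MeasurementConfig | None = None,
    segment_id: int = 0,
    arc_pos: float = 0.0,
    frame_time: float = 0.0,
) -> CaliberMeasurement:
    """Score caliber as the distance between the two membrane peaks.

    The peak pair is the nearest qualifying local maximum on each side of
    the centerline crossing (offset 0), not the two global maxima — this
    keeps neighboring structures in the scan window from hijacking the
    measurement.  Peaks are optionally refined to sub-pixel positions by a
    3-point parabola.
    """
    config = config or MeasurementConfig()
    vals = profile.intensities
    rng = float(vals.max() - vals.min())
    if rng <= 0:
        raise FlatProfileError("profile has zero intensity range")
    prominence = config.peak_prominence_fraction * rng
    idx, _ = find_peaks(vals, prominence=prominence)
    meas = CaliberMeasurement(
        segment_id=segment_id, arc_pos=arc_pos, frame_time=frame_time
    )
    left = [i for i in idx if profile.offsets[i] < 0]
    right = [i for i in idx if profile.offsets[i] > 0]
    if not left or not right:
        meas.single_peak = True
        return meas
    i_left = max(left, key=lambda i: profile.offsets[i])  # nearest below 0
    i_right = min(right, key=lambda i: profile.offsets[i])  # nearest above 0
    for chosen, cands in ((i_left, left), (i_right, right)):
        for other in cands:
            if other == chosen:
                continue
            if abs(vals[other] - vals[chosen]) < 0.10 * max(vals[chosen], 1e-300):
                meas.ambiguous_peaks = True
    if config.subpixel:
        p_left = _parabolic_refine(profile.offsets, vals, i_left)
        p_right = _parabolic_refine(profile.offsets, vals, i_right)
    else:
        p_left = float(profile.offsets[i_left])
        p_right = float(profile.offsets[i_right])
    meas.peak_positions = (p_left, p_right)
    meas.caliber = p_right - p_left
    if meas.caliber < config.resolution_limit:
        meas.below_resolution = True
    return meas


def measure_along_segment(
    frame: ImageFrame,
    centerline: CenterlineAnnotation,
    segment_id: int,
    positions,
    config: MeasurementConfig | None = None,
) -> list[CaliberMeasurement]:
    """Measure caliber at the given arc positions along one segment.

    Positions closer than ``config.branch_exclusion_um`` to a branch point
    on the segment (its endpoints included when they are branch points)
    are dropped, not errored.
    """
    config = config or MeasurementConfig()
    pts = centerline.segments[segment_id]
    length = centerline.segment_length(segment_id)
    bp_positions = centerline.branch_arc_positions(segment_id)
    out: list[CaliberMeasurement] = []
    for s in np.asarray(positions, dtype=float):
        if not (0 <= s <= length):
            raise ValueError(f"position {s} outside segment 0..{length:.2f}")
        if any(abs(s - b) < config.branch_exclusion_um for b in bp_positions):
            continue
        center = point_at(pts, s)
        _, normal = tangent_and_normal(pts, s)
        profile = extract_profile(frame, center, normal, config)
        out.append(
            measure_caliber(
                profile,
                config,
                segment_id=segment_id,
                arc_pos=float(s),
                frame_time=frame.frame_time,
            )
        )
    return out


# ---------------------------------------------------------------------------
# cohort-level exclusion rules


@dataclass
class MeasurementSet:
    """One axon's (or branch point's) measurements plus exclusion metadata.

    ``branch_spacing_um`` is the smallest spacing between branch points in
    the measured region; ``primary_below_resolution`` records whether the
    primary branch caliber fell below the resolution limit; the
    fraction-below-resolution rule is evaluated on ``day1_measurements``
    when given, else on ``measurements``.
    """

    set_id: str
    measurements: list[CaliberMeasurement]
    branch_spacing_um: float | None = None
    primary_below_resolution: bool = False
    day1_measurements: list[CaliberMeasurement] | None = None


@dataclass
class ExclusionRecord:
    set_id: str
    rule: str
    detail: str


def apply_exclusion_rules(
    sets: list[MeasurementSet],
    min_branch_spacing: float = 3.0,
    max_below_resolution_fraction: float = 0.20,
) -> tuple[list[MeasurementSet], list[ExclusionRecord]]:
    """Apply cohort exclusion rules and log every exclusion.

    Rules: branch points closer together than ``min_branch_spacing``
    (5 um for symmetry analysis, 3 um otherwise); primary branch below the
    resolution limit; more than ``max_below_resolution_fraction`` of a
    set's baseline measurements below the resolution limit.
    """
    retained: list[MeasurementSet] = []
    log: list[ExclusionRecord] = []
    for ms in sets:
        if ms.branch_spacing_um is not None and ms.branch_spacing_um < min_branch_spacing:
            log.append(
                ExclusionRecord(
                    ms.set_id,
                    "branch_spacing",
                    f"branch points {ms.branch_spacing_um:.2f} um apart "
                    f"(< {min_branch_spacing:.2f} um)",
                )
            )
            continue
        if ms.primary_below_resolution:
            log.append(
                ExclusionRecord(
                    ms.set_id, "primary_below_resolution",
                    "primary branch caliber below the resolution limit",
                )
            )
            continue
        baseline = ms.day1_measurements if ms.day1_measurements is not None else ms.measurements
        if baseline:
            n_below = sum(1 for m in baseline if m.below_resolution or m.single_peak)
            frac = n_below / len(baseline)
            if frac > max_below_resolution_fraction:
                log.append(
                    ExclusionRecord(
                        ms.set_id,
                        "fraction_below_resolution",
                        f"{n_below}/{len(baseline)} baseline measurements below the "
                        f"resolution limit ({frac:.0%} > "
                        f"{max_below_resolution_fraction:.0%})",
                    )
                )
                continue
        retained.append(ms)
    return retained, log
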