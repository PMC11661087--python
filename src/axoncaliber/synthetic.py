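"""Synthetic membrane-labeled axon scenes with exact ground truth.

The generator emulates the imaging regime the measurement pipeline is
designed for: a membrane label (bright at the two tube boundaries, dark
lumen) imaged in a single super-resolution confocal plane.  Each scene is
rendered by depositing fluorescence along the two boundary curves offset
by the local radius from the centerline, convolving with an isotropic
Gaussian PSF, and optionally adding shot (Poisson) and Gaussian read
noise.  Every scene carries its full ground truth (centerlines and radius
tables), so measurement recovery can be asserted without the images.

Defaults: 0.04 um pixels and a 0.14 um FWHM PSF — the scale of Airyscan
lateral resolution — and 5-minute frame intervals for time series.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import point_at, polyline_arclength, resample_polyline, tangent_and_normal

__all__ = [
    "AxonGroundTruth",
    "BranchPoint",
    "SceneConfig",
    "DynamicsScript",
    "RoundingScenario",
    "DynamicsSeries",
    "DivisionSeries",
    "make_pearled_radius_profile",
    "make_sinusoidal_radius_profile",
    "analytic_linescan_profile",
    "render_membrane_frame",
    "make_straight_tube_truth",
    "make_branched_truth",
    "make_dynamics_series",
    "make_division_series",
    "scripted_border_lengths",
    "FWHM_TO_SIGMA",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM * 0.4247


@dataclass
class BranchPoint:
    """A branch point: its location and the segments that meet there."""

    location: tuple[float, float]
    parent_id: int
    child_ids: tuple[int, ...]


@dataclass
class AxonGroundTruth:
    """Centerline plus radius profile per segment — the generator's truth record.

    ``segments`` maps segment id -> ordered (N, 2) points in um.
    ``radius_profiles`` maps segment id -> (s, r) dense tables in um with
    strictly increasing arc length and r > 0 everywhere.
    """

    segments: dict[int, np.ndarray]
    radius_profiles: dict[int, tuple[np.ndarray, np.ndarray]]
    branch_points: list[BranchPoint] = field(default_factory=list)
    frame_time: float = 0.0

    def __post_init__(self) -> None:
        self.segments = {int(k): np.asarray(v, dtype=float) for k, v in self.segments.items()}
        self.radius_profiles = {
            int(k): (np.asarray(s, dtype=float), np.asarray(r, dtype=float))
            for k, (s, r) in self.radius_profiles.items()
        }
        for sid, (s, r) in self.radius_profiles.items():
            if sid not in self.segments:
                raise ValueError(f"radius profile for unknown segment {sid}")
            if np.any(np.diff(s) <= 0):
                raise ValueError(f"segment {sid}: arc-length samples must strictly increase")
            if np.any(r <= 0):
                raise ValueError(f"segment {sid}: radius must be positive everywhere")
        for bp in self.branch_points:
            loc = np.asarray(bp.location, dtype=float)
            for cid in bp.child_ids:
                first = self.segments[cid][0]
                if not np.allclose(first, loc, atol=1e-6):
                    raise ValueError(
                        f"child segment {cid} does not originate at its branch point"
                    )

    def radius_at(self, segment_id: int, s) -> np.ndarray:
        tab_s, tab_r = self.radius_profiles[segment_id]
        return np.interp(np.asarray(s, dtype=float), tab_s, tab_r)

    def segment_length(self, segment_id: int) -> float:
        return float(polyline_arclength(self.segments[segment_id])[-1])


@dataclass
class SceneConfig:
    """Rendering parameters for one scene.

    ``membrane_amplitude`` is the peak membrane intensity in photons after
    blurring (the noiseless render is scaled so its maximum equals it);
    with Poisson noise on, peak SNR is therefore ~sqrt(membrane_amplitude).
    """

    pixel_size: float = 0.04
    image_shape: tuple[int, int] = (160, 360)
    psf_fwhm: float = 0.14
    membrane_amplitude: float = 100.0
    background: float = 2.0
    read_noise_sd: float = 1.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be non-negative")
        if self.membrane_amplitude <= 0:
            raise ValueError("membrane_amplitude must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")

    @property
    def psf_sigma(self) -> float:
        return self.psf_fwhm * FWHM_TO_SIGMA

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the field of view in um."""
        rows, cols = self.image_shape
        return (cols - 1) * self.pixel_size, (rows - 1) * self.pixel_size


@dataclass
class DynamicsScript:
    """One scripted caliber behavior over a time-lapse.

    behaviors: ``traveling_pearl`` (a pearl advancing ``speed`` um/frame),
    ``focal_inflation_deflation`` (a pearl whose amplitude ramps 0 -> a -> 0
    between onset and offset), ``segment_widening_narrowing`` (base radius
    modulated uniformly over ``span``), ``constriction_point`` (a
    negative-amplitude pearl toggled on between onset and offset).
    """

    behavior: str
    base_radius: float = 0.15
    amplitude: float = 0.08
    width: float = 0.8
    speed: float = 0.4
    onset: int = 1
    offset: int = 4
    n_frames: int = 6
    frame_interval: float = 5.0
    length: float = 12.0
    start_s: float = 2.0
    center_s: float = 6.0
    span: tuple[float, float] = (3.0, 9.0)

    _BEHAVIORS = (
        "traveling_pearl",
        "focal_inflation_deflation",
        "segment_widening_narrowing",
        "constriction_point",
    )

    def __post_init__(self) -> None:
        if self.behavior not in self._BEHAVIORS:
            raise ValueError(f"behavior must be one of {self._BEHAVIORS}")
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0 <= self.onset <= self.offset):
            raise ValueError("need 0 <= onset <= offset")


@dataclass
class RoundingScenario:
    """A basal-cell division: the cell contracts in plane and rounds up.

    ``flat_length`` is the flat cell's border-to-border extent (the chord
    the axon spans), ``rounded_extent`` the contracted planar extent at the
    round frame, and ``rounded_height`` the sagitta of the rounded apical
    surface.  The vertical dimension exists only in the geometry model;
    rendered frames stay planar.
    """

    flat_length: float = 12.0
    rounded_extent: float = 9.0
    rounded_height: float = 3.0
    n_frames: int = 6
    round_frame: int = 3
    base_radius: float = 0.15
    dividing_radius_factor: float = 1.0
    flat_thinning: float = 0.0
    neighbor_extent: float = 5.0
    frame_interval: float = 5.0
    pearl_amplitude_round: float = 0.0
    pearl_amplitude_flat: float = 0.0
    pearl_wavelength: float = 2.3
    second_round_frame: int | None = None  # optional later, equal contraction (tie case)

    def __post_init__(self) -> None:
        if not (0 < self.rounded_extent <= self.flat_length):
            raise ValueError("need 0 < rounded_extent <= flat_length")
        if self.rounded_height < 0:
            raise ValueError("rounded_height must be non-negative")
        if not (0 < self.round_frame + 1 < self.n_frames):
            raise ValueError("round_frame must leave at least one frame on each side")
        if not (0 <= self.flat_thinning < 1):
            raise ValueError("flat_thinning must be in [0, 1)")
        if self.second_round_frame is not None and not (
            self.round_frame + 1 < self.second_round_frame < self.n_frames - 1
        ):
            raise ValueError("second_round_frame must fall after the flat frame")

    @property
    def flat_frame(self) -> int:
        return self.round_frame + 1


@dataclass
class DynamicsSeries:
    frames: list[np.ndarray]
    truths: list[AxonGroundTruth]
    script: DynamicsScript
    config: SceneConfig

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(len(self.frames)) * self.script.frame_interval


@dataclass
class DivisionSeries:
    frames: list[np.ndarray]
    truths: list[AxonGroundTruth]
    border_positions: list[tuple[float, float]]  # arc positions of cell borders
    border_lengths: np.ndarray  # planar border-to-border length per frame
    true_path_lengths: np.ndarray  # 3D path length per frame (arc at round frame)
    regions: list[dict[str, tuple[float, float]]]  # arc spans per frame
    scenario: RoundingScenario
    config: SceneConfig

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(len(self.frames)) * self.scenario.frame_interval


# ---------------------------------------------------------------------------
# radius profiles


def make_pearled_radius_profile(
    base_radius: float,
    pearls: list[tuple[float, float, float]],
    length: float,
    step: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Radius table r(s) = base + sum of Gaussian pearls a*exp(-(s-c)^2/2w^2).

    ``pearls`` is a list of (center, amplitude, width) in um; negative
    amplitudes model constrictions.  Raises if the radius is not positive
    everywhere.
    """
    if base_radius <= 0:
        raise ValueError("base_radius must be positive")
    if length <= 0:
        raise ValueError("length must be positive")
    s = np.arange(0.0, length + step / 2, step)
    r = np.full_like(s, float(base_radius))
    for center, amp, width in pearls:
        if width <= 0:
            raise ValueError("pearl width must be positive")
        r = r + amp * np.exp(-((s - center) ** 2) / (2.0 * width**2))
    if np.any(r <= 0):
        bad = s[np.argmin(r)]
        raise ValueError(
            f"radius profile not positive: min r = {r.min():.4f} um at s = {bad:.2f} um"
        )
    return s, r


def make_sinusoidal_radius_profile(
    base_radius: float,
    amplitude: float,
    wavelength: float,
    length: float,
    step: float = 0.05,
    phase: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sinusoidal thick/thin alternation: r(s) = base + a*sin(2*pi*s/wavelength + phase).

    An alternative pearl preset for subtle periodic thick and thin stretches.
    """
    if base_radius <= 0 or wavelength <= 0 or length <= 0:
        raise ValueError("base_radius, wavelength and length must be positive")
    if abs(amplitude) >= base_radius:
        raise ValueError("amplitude must be smaller than base_radius")
    s = np.arange(0.0, length + step / 2, step)
    r = base_radius + amplitude * np.sin(2.0 * np.pi * s / wavelength + phase)
    return s, r


def analytic_linescan_profile(diameter: float, psf_sigma: float, positions) -> np.ndarray:
    """Closed-form perpendicular line-scan profile of a membrane tube.

    Two boundary line sources at +-d/2 convolved with a Gaussian PSF give

        I(x) = exp(-(x - d/2)^2 / 2 sigma^2) + exp(-(x + d/2)^2 / 2 sigma^2),

    returned peak-normalized.  This is the independent oracle for the
    measurement module: it never touches the renderer.
    """
    if diameter < 0:
        raise ValueError("diameter must be non-negative")
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    x = np.asarray(positions, dtype=float)
    half = diameter / 2.0
    prof = np.exp(-((x - half) ** 2) / (2 * psf_sigma**2)) + np.exp(
        -((x + half) ** 2) / (2 * psf_sigma**2)
    )
    return prof / prof.max()


# ---------------------------------------------------------------------------
# rendering


class GeometryOutOfBoundsError(ValueError):
    pass


def _splat_bilinear(acc: np.ndarray, xs_px: np.ndarray, ys_px: np.ndarray, w: float) -> None:
    """Deposit weight ``w`` per point into ``acc`` with bilinear interpolation."""
    x0 = np.floor(xs_px).astype(int)
    y0 = np.floor(ys_px).astype(int)
    fx = xs_px - x0
    fy = ys_px - y0
    for dy, dx, wt in (
        (0, 0, (1 - fx) * (1 - fy)),
        (0, 1, fx * (1 - fy)),
        (1, 0, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        np.add.at(acc, (y0 + dy, x0 + dx), w * wt)


def render_membrane_frame(
    truth: AxonGroundTruth,
    config: SceneConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one membrane-labeled frame from ground truth.

    Fluorescence is deposited along the two boundary curves offset by
    +-r(s) along the centerline normal, blurred by the PSF, scaled so the
    peak equals ``membrane_amplitude``, and background plus optional
    Poisson and read noise are added.  Coordinates: pixel centers sit at
    integer multiples of ``pixel_size``, origin at the center of pixel
    (0, 0).
    """
    rows, cols = config.image_shape
    px = config.pixel_size
    margin = 3.0 * config.psf_fwhm
    acc = np.zeros((rows, cols), dtype=float)
    fine = px / 5.0
    for sid, pts in truth.segments.items():
        s_vals, ctr = resample_polyline(pts, fine)
        radii = truth.radius_at(sid, s_vals)
        # vertex-interpolated normals along the resampled centerline
        normals = np.empty_like(ctr)
        tangents = np.gradient(ctr, s_vals, axis=0)
        norms = np.linalg.norm(tangents, axis=1, keepdims=True)
        tangents /= np.where(norms == 0, 1.0, norms)
        normals[:, 0] = -tangents[:, 1]
        normals[:, 1] = tangents[:, 0]
        step = s_vals[1] - s_vals[0] if len(s_vals) > 1 else fine
        for sign in (+1.0, -1.0):
            bound = ctr + sign * radii[:, None] * normals
            xs, ys = bound[:, 0], bound[:, 1]
            w, h = config.extent
            if (
                xs.min() < margin
                or ys.min() < margin
                or xs.max() > w - margin
                or ys.max() > h - margin
            ):
                raise GeometryOutOfBoundsError(
                    f"segment {sid} exits the field of view (needs a margin of "
                    f"{margin:.3f} um on a {w:.2f} x {h:.2f} um field)"
                )
            _splat_bilinear(acc, xs / px, ys / px, step)
    if config.psf_sigma > 0:
        acc = gaussian_filter(acc, sigma=config.psf_sigma / px, mode="constant")
    peak = acc.max()
    if peak > 0:
        acc *= config.membrane_amplitude / peak
    img = acc + config.background
    if config.poisson_noise or config.read_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        if config.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if config.read_noise_sd > 0:
            img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
    return img


# ---------------------------------------------------------------------------
# scene constructors


def make_straight_tube_truth(
    diameter: float,
    config: SceneConfig,
    length: float | None = None,
    radius_table: tuple[np.ndarray, np.ndarray] | None = None,
    angle_deg: float = 0.0,
    frame_time: float = 0.0,
) -> AxonGroundTruth:
    """A single straight tube centered in the field of view.

    If ``radius_table`` is given it overrides the constant ``diameter``.
    """
    w, h = config.extent
    cx, cy = w / 2.0, h / 2.0
    if radius_table is not None:
        length = float(radius_table[0][-1])
    elif length is None:
        length = min(w, h) * 0.7 if abs(angle_deg) % 180 > 30 else w * 0.8
    th = np.deg2rad(angle_deg)
    d = np.array([np.cos(th), np.sin(th)])
    n_pts = max(int(length / 0.25), 2) + 1
    t = np.linspace(-length / 2.0, length / 2.0, n_pts)
    pts = np.array([cx, cy]) + t[:, None] * d
    if radius_table is None:
        s = np.array([0.0, length])
        r = np.full(2, diameter / 2.0)
    else:
        s, r = radius_table
    return AxonGroundTruth(
        segments={0: pts},
        radius_profiles={0: (s, r)},
        branch_points=[],
        frame_time=frame_time,
    )


def make_branched_truth(
    config: SceneConfig,
    primary_diameter: float = 0.6,
    s1_diameter: float = 0.44,
    s2_diameter: float = 0.32,
    primary_length: float = 7.0,
    secondary_length: float = 7.0,
    branch_angle_deg: float = 32.0,
    frame_time: float = 0.0,
) -> AxonGroundTruth:
    """A primary segment splitting into two secondaries at one branch point.

    Segment ids: 0 = primary, 1 and 2 = secondaries (1 carries
    ``s1_diameter``).  The primary runs horizontally; the secondaries
    diverge symmetrically.
    """
    w, h = config.extent
    bx = w * 0.45
    by = h / 2.0
    n = 40
    primary = np.column_stack(
        [np.linspace(bx - primary_length, bx, n), np.full(n, by)]
    )
    th = np.deg2rad(branch_angle_deg)
    segs = {0: primary}
    radii = {0: (np.array([0.0, primary_length]), np.full(2, primary_diameter / 2.0))}
    for sid, sign, diam in ((1, +1.0, s1_diameter), (2, -1.0, s2_diameter)):
        d = np.array([np.cos(th), sign * np.sin(th)])
        t = np.linspace(0.0, secondary_length, n)
        segs[sid] = np.array([bx, by]) + t[:, None] * d
        radii[sid] = (np.array([0.0, secondary_length]), np.full(2, diam / 2.0))
    bp = BranchPoint(location=(bx, by), parent_id=0, child_ids=(1, 2))
    return AxonGroundTruth(
        segments=segs, radius_profiles=radii, branch_points=[bp], frame_time=frame_time
    )


def _dynamics_radius_table(
    script: DynamicsScript, frame: int, step: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    b = script
    if b.behavior == "traveling_pearl":
        center = b.start_s + b.speed * frame
        return make_pearled_radius_profile(
            b.base_radius, [(center, b.amplitude, b.width)], b.length, step
        )
    if b.behavior == "focal_inflation_deflation":
        if frame <= b.onset or frame >= b.offset:
            lam = 0.0
        else:
            mid = (b.onset + b.offset) / 2.0
            half = (b.offset - b.onset) / 2.0
            lam = 1.0 - abs(frame - mid) / half
        return make_pearled_radius_profile(
            b.base_radius, [(b.center_s, b.amplitude * lam, b.width)], b.length, step
        )
    if b.behavior == "segment_widening_narrowing":
        mid = (b.onset + b.offset) / 2.0
        half = max((b.offset - b.onset) / 2.0, 1e-9)
        lam = max(1.0 - abs(frame - mid) / half, 0.0) if b.onset <= frame <= b.offset else 0.0
        s = np.arange(0.0, b.length + step / 2, step)
        r = np.full_like(s, b.base_radius)
        lo, hi = b.span
        r[(s >= lo) & (s <= hi)] += b.amplitude * lam
        if np.any(r <= 0):
            raise ValueError("widening script drives radius non-positive")
        return s, r
    # constriction_point: pearl toggled on during [onset, offset]
    pearls = []
    if b.onset <= frame <= b.offset:
        pearls = [(b.center_s, b.amplitude, b.width)]
    return make_pearled_radius_profile(b.base_radius, pearls, b.length, step)


def make_dynamics_series(script: DynamicsScript, config: SceneConfig) -> DynamicsSeries:
    """Render a scripted caliber-dynamics time-lapse with per-frame truth."""
    w, h = config.extent
    x0 = (w - script.length) / 2.0
    cy = h / 2.0
    pts = np.column_stack(
        [np.linspace(x0, x0 + script.length, 60), np.full(60, cy)]
    )
    seeds = np.random.SeedSequence(config.seed).spawn(script.n_frames)
    frames, truths = [], []
    for t in range(script.n_frames):
        s, r = _dynamics_radius_table(script, t)
        truth = AxonGroundTruth(
            segments={0: pts},
            radius_profiles={0: (s, r)},
            frame_time=t * script.frame_interval,
        )
        rng = np.random.default_rng(seeds[t])
        frames.append(render_membrane_frame(truth, config, rng=rng))
        truths.append(truth)
    return DynamicsSeries(frames=frames, truths=truths, script=script, config=config)


def scripted_border_lengths(scenario: RoundingScenario) -> np.ndarray:
    """Planar border-to-border length per frame for a division scenario.

    Ramps down toward the round frame, drops to the rounded extent, and
    snaps back to the flat length at the next frame; an optional second
    contraction of equal depth creates a tie case for frame selection.
    """
    sc = scenario
    extents = np.empty(sc.n_frames)
    for t in range(sc.n_frames):
        if t < sc.round_frame:
            frac = (t + 1) / (sc.round_frame + 1)
            extents[t] = sc.flat_length - 0.35 * frac * (sc.flat_length - sc.rounded_extent)
        elif t == sc.round_frame:
            extents[t] = sc.rounded_extent
        elif sc.second_round_frame is not None and t == sc.second_round_frame:
            extents[t] = sc.rounded_extent
        else:
            extents[t] = sc.flat_length
    return extents


def make_division_series(scenario: RoundingScenario, config: SceneConfig) -> DivisionSeries:
    """Render a basal-cell-division time-lapse.

    The axon runs straight and horizontally across neighbor1, the dividing
    cell, and neighbor2.  Cell borders contract to ``rounded_extent`` at
    the round frame and relax back at the next (flat) frame; per-frame
    planar border-to-border lengths and true path lengths (the circular
    arc at the round frame) are emitted alongside the truth.
    """
    sc = scenario
    from .division import arc_path_length  # local import to avoid a cycle

    w, h = config.extent
    total = sc.neighbor_extent * 2 + sc.flat_length
    x0 = (w - total) / 2.0
    if x0 < 3.0 * config.psf_fwhm + 0.5:
        raise GeometryOutOfBoundsError(
            f"scenario span {total:.1f} um does not fit the {w:.1f} um field"
        )
    cy = h / 2.0
    cx = x0 + sc.neighbor_extent + sc.flat_length / 2.0  # dividing-cell center
    pts = np.column_stack([np.linspace(x0, x0 + total, 80), np.full(80, cy)])
    seeds = np.random.SeedSequence(config.seed).spawn(sc.n_frames)

    extents = scripted_border_lengths(sc)

    arc_round = arc_path_length(
        sc.flat_length, sc.rounded_extent, sc.rounded_height
    ).arc_length

    frames, truths, borders, regions = [], [], [], []
    true_paths = np.empty(sc.n_frames)
    step = 0.05
    s_tab = np.arange(0.0, total + step / 2, step)
    x_tab = x0 + s_tab  # horizontal axon: arc position == x offset
    for t in range(sc.n_frames):
        e = extents[t]
        b_lo, b_hi = cx - e / 2.0, cx + e / 2.0
        r = np.full_like(s_tab, sc.base_radius)
        inside = (x_tab >= b_lo) & (x_tab <= b_hi)
        r_div = sc.base_radius * sc.dividing_radius_factor
        if t == sc.flat_frame:
            r_div *= 1.0 - sc.flat_thinning
        r[inside] = r_div
        amp = 0.0
        if t == sc.round_frame:
            amp = sc.pearl_amplitude_round
        elif t == sc.flat_frame:
            amp = sc.pearl_amplitude_flat
        if amp:
            r[inside] += amp * np.sin(2.0 * np.pi * (x_tab[inside] - b_lo) / sc.pearl_wavelength)
        if np.any(r <= 0):
            raise ValueError("scenario drives radius non-positive")
        truth = AxonGroundTruth(
            segments={0: pts},
            radius_profiles={0: (s_tab, r)},
            frame_time=t * sc.frame_interval,
        )
        rng = np.random.default_rng(seeds[t])
        frames.append(render_membrane_frame(truth, config, rng=rng))
        truths.append(truth)
        borders.append((b_lo - x0, b_hi - x0))
        regions.append(
            {
                "neighbor1": (max(b_lo - x0 - sc.neighbor_extent, 0.0), b_lo - x0),
                "dividing": (b_lo - x0, b_hi - x0),
                "neighbor2": (b_hi - x0, min(b_hi - x0 + sc.neighbor_extent, total)),
            }
        )
        true_paths[t] = arc_round if t == sc.round_frame else e
    return DivisionSeries(
        frames=frames,
        truths=truths,
        border_positions=borders,
        border_lengths=extents.copy(),
        true_path_lengths=true_paths,
        regions=regions,
        scenario=sc,
        config=config,
    )


def derive_config(config: SceneConfig, **overrides) -> SceneConfig:
    return dataclasses.replace(config, **overrides)
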