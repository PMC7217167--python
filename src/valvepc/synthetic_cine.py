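"""Synthetic cine phase-contrast (PC) series with known ground truth.

Two scenes stand in for the scanner:

* a **cone phantom** — a static, water-immersed cone whose cross-sectional
  radius is a known linear function of height, imaged while the slice
  position is stepped through a programmed schedule.  Measuring the depicted
  slice radius against the analytic radius validates the slice-following
  mechanics end to end.
* a **moving-valve heart scene** — a 2-D annular inflow region whose plane
  translates along the slice normal with a configurable excursion, carrying
  a biphasic (E/A) transmitral waveform, an optional systolic regurgitant
  jet, an LVOT outflow region contaminating the *static* imaging plane in
  systole, a spatially smooth background phase offset, and complex-Gaussian
  noise propagated through the velocity encoding.

Velocity encoding follows the PC convention: pixel phase is proportional to
through-plane velocity and wraps at the VENC; the wrapped representation is
bijective on (−venc, +venc].  Noise is applied on the two underlying complex
channels, so dim pixels have proportionally noisier velocities.

All ground-truth volumes are computed by direct discrete summation over the
generated velocity fields, so a downstream quantifier working on the same
grid can recover them exactly up to noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .valve_motion import DisplacementCurve, SliceSchedule, AnnulusTrajectory, valve_velocity, build_slice_schedule

__all__ = [
    "ConeGeometry",
    "ImageGrid",
    "CinePCSeries",
    "HeartSceneParams",
    "GroundTruth",
    "PhantomValidation",
    "UndefinedRadiusError",
    "cone_radius",
    "phantom_schedule",
    "simulate_phantom_series",
    "estimate_slice_radius",
    "validate_phantom",
    "simulate_heart_scene",
    "simulate_aortic_series",
    "synthetic_short_axis_stack",
    "scene_roi_polygons",
    "validation_cohort",
    "encode_velocity_phase",
    "decode_velocity_phase",
    "write_ground_truth_csv",
]

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class UndefinedRadiusError(ValueError):
    """Raised when no disk-shaped foreground region can be measured."""


@dataclass(frozen=True)
class ConeGeometry:
    """Validation cone: radius varies linearly from base to top.

    Default dimensions are the validation phantom's: 7 cm tall, 12 cm top
    diameter, 3 cm bottom diameter, with a 5 mm planning bar at mid-height.
    """

    height_cm: float = 7.0
    top_diameter_cm: float = 12.0
    bottom_diameter_cm: float = 3.0
    bar_thickness_cm: float = 0.5
    bar_height_cm: float = 3.5

    def __post_init__(self) -> None:
        if self.height_cm <= 0:
            raise ValueError("cone height must be positive")
        if not (self.top_diameter_cm > self.bottom_diameter_cm > 0):
            raise ValueError("need top_diameter > bottom_diameter > 0")
        if not (0 <= self.bar_height_cm <= self.height_cm):
            raise ValueError("bar must sit within the cone height")


@dataclass(frozen=True)
class ImageGrid:
    """In-plane acquisition grid (isotropic pixels)."""

    matrix_rows: int
    matrix_cols: int
    pixel_spacing_mm: float
    slice_thickness_mm: float
    field_of_view_mm: float

    def __post_init__(self) -> None:
        if min(self.matrix_rows, self.matrix_cols) <= 0:
            raise ValueError("matrix size must be positive")
        if min(self.pixel_spacing_mm, self.slice_thickness_mm, self.field_of_view_mm) <= 0:
            raise ValueError("grid lengths must be positive")
        nominal = self.field_of_view_mm / self.matrix_cols
        if abs(self.pixel_spacing_mm - nominal) > 0.01 * nominal:
            raise ValueError(
                f"pixel_spacing {self.pixel_spacing_mm} inconsistent with "
                f"FOV/matrix = {nominal:.4f} mm"
            )

    @classmethod
    def from_fov(cls, matrix: int, fov_mm: float, slice_thickness_mm: float = 8.0) -> "ImageGrid":
        return cls(matrix, matrix, fov_mm / matrix, slice_thickness_mm, fov_mm)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.matrix_rows, self.matrix_cols)

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_mm**2


@dataclass
class CinePCSeries:
    """Per-phase magnitude and velocity maps of one cine PC acquisition.

    Velocity is in cm/s with positive = through-plane in the atrium-to-
    ventricle inflow direction.  ``slice_offsets`` records the programmed
    per-phase slice translation in mm along the slice normal.
    """

    magnitude: np.ndarray  # (n_phases, rows, cols), arbitrary units >= 0
    velocity: np.ndarray  # (n_phases, rows, cols), cm/s
    venc: float  # cm/s
    phase_times: np.ndarray  # ms since R-wave (phase centers)
    phase_durations: np.ndarray  # ms
    grid: ImageGrid
    slice_offsets: Optional[np.ndarray] = None  # mm per phase
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.phase_times = np.asarray(self.phase_times, dtype=float)
        self.phase_durations = np.asarray(self.phase_durations, dtype=float)
        if self.slice_offsets is not None:
            self.slice_offsets = np.asarray(self.slice_offsets, dtype=float)
        if self.magnitude.shape != self.velocity.shape or self.magnitude.ndim != 3:
            raise ValueError("magnitude and velocity must share shape (n_phases, rows, cols)")
        n = self.magnitude.shape[0]
        if self.phase_times.shape != (n,) or self.phase_durations.shape != (n,):
            raise ValueError("timing arrays must have one entry per phase")
        if self.slice_offsets is not None and self.slice_offsets.shape != (n,):
            raise ValueError("slice_offsets must have one entry per phase")
        if np.any(np.diff(self.phase_times) <= 0):
            raise ValueError("phase_times must be strictly increasing")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.magnitude.shape[1:] != self.grid.shape:
            raise ValueError("image shape must match the grid")

    @property
    def n_phases(self) -> int:
        return self.magnitude.shape[0]

    @property
    def rr_interval_ms(self) -> float:
        return float(np.sum(self.phase_durations))

    def copy(self) -> "CinePCSeries":
        return CinePCSeries(
            self.magnitude.copy(),
            self.velocity.copy(),
            self.venc,
            self.phase_times.copy(),
            self.phase_durations.copy(),
            self.grid,
            None if self.slice_offsets is None else self.slice_offsets.copy(),
            dict(self.metadata),
        )


@dataclass
class HeartSceneParams:
    """Configuration of the moving-valve heart scene.

    The transmitral waveform is normalized so the diastolic forward volume
    through the annular disk equals ``true_mitral_sv_ml`` exactly on the
    discrete grid; ``e_peak``/``a_peak`` set the E:A shape (realized peak
    velocities are recorded in the ground truth).  ``lvot_sv_ml`` is the
    systolic outflow crossing the *static* end-systolic plane; it defaults to
    the aortic stroke volume (mitral SV minus regurgitation).
    """

    rr_interval_ms: float = 1000.0
    n_phases: int = 30
    annulus_excursion_mm: float = 15.0
    annulus_radius_mm: float = 19.0
    e_peak_m_s: float = 0.6
    a_peak_m_s: float = 0.4
    true_mitral_sv_ml: float = 80.0
    regurgitant_volume_ml: float = 0.0
    lvot_sv_ml: Optional[float] = None
    background_offset: float | tuple = 1.0  # cm/s; scalar or (b0, gx/mm, gy/mm)
    noise_sd: float = 0.6  # cm/s velocity-equivalent in unit-magnitude pixels
    seed: int = 0
    end_systole_index: Optional[int] = None
    venc: float = 150.0
    plane_tilt_deg: float = 3.2
    orifice_radius_frac: float = 0.7

    def __post_init__(self) -> None:
        if self.n_phases < 8:
            raise ValueError("need at least 8 cardiac phases")
        if not (0 <= self.regurgitant_volume_ml <= self.true_mitral_sv_ml):
            raise ValueError("regurgitant volume must lie in [0, true_mitral_sv]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.annulus_excursion_mm < 0 or self.annulus_radius_mm <= 0:
            raise ValueError("annulus geometry must be non-negative / positive")
        es = self.resolved_end_systole()
        if not (1 <= es < self.n_phases - 2):
            raise ValueError("end_systole_index must leave room for diastole")

    def resolved_end_systole(self) -> int:
        if self.end_systole_index is not None:
            return int(self.end_systole_index)
        return int(round(0.38 * self.n_phases))

    def resolved_lvot_sv(self) -> float:
        if self.lvot_sv_ml is not None:
            return float(self.lvot_sv_ml)
        return self.true_mitral_sv_ml - self.regurgitant_volume_ml


@dataclass
class GroundTruth:
    """Exact volumes and motion of a simulated heart scene.

    All volume integrals are discrete sums over the generated velocity
    fields on the acquisition grid.
    """

    true_mitral_sv_ml: float
    true_aortic_sv_ml: float
    true_regurgitant_volume_ml: float
    passive_transfer_volume_ml: float
    true_planimetric_sv_ml: float
    displacement_curve_mm: np.ndarray  # per phase, re-zeroed at phase 0
    valve_velocity_cm_s: np.ndarray  # per phase (cyclic central differences)
    event_indices: dict  # end_systole, end_diastole, e_window, a_window
    e_peak_realized_m_s: float
    a_peak_realized_m_s: float


@dataclass
class PhantomValidation:
    """Per-phase theoretical vs measured slice radii and their agreement."""

    table: pd.DataFrame  # phase, offset_mm, theoretical_mm, measured_mm, error_mm
    bias_mm: float
    sd_mm: float


# ---------------------------------------------------------------------------
# velocity encoding
# ---------------------------------------------------------------------------


def encode_velocity_phase(velocity_cm_s, venc: float):
    """Map velocity to wrapped phase in (−π, π] (phase-difference convention)."""
    phi = np.pi * np.asarray(velocity_cm_s, dtype=float) / venc
    return np.pi - np.mod(np.pi - phi, 2.0 * np.pi)


def decode_velocity_phase(phase, venc: float):
    """Inverse of :func:`encode_velocity_phase`; range (−venc, +venc]."""
    return np.asarray(phase, dtype=float) * venc / np.pi


def _pc_encode(magnitude, velocity, venc, sigma_c, rng, extra_phase=None):
    """Propagate a noise-free (magnitude, velocity) pair through the encoding.

    Two complex acquisitions (flow-compensated / flow-encoded) receive
    independent complex-Gaussian noise of per-channel SD ``sigma_c`` (units
    of the water magnitude); velocity is recovered from their phase
    difference, so it wraps at the VENC and dim pixels are noisy.
    """
    phi_v = np.pi * velocity / venc
    if extra_phase is not None:
        phi_v = phi_v + extra_phase
    if sigma_c == 0.0:
        vel = decode_velocity_phase(encode_velocity_phase(velocity, venc), venc)
        if extra_phase is not None:
            vel = decode_velocity_phase(np.pi - np.mod(np.pi - phi_v, 2 * np.pi), venc)
        return magnitude.copy(), vel
    z = rng.standard_normal((2,) + magnitude.shape + (2,))
    n0 = sigma_c * (z[0, ..., 0] + 1j * z[0, ..., 1])
    n1 = sigma_c * (z[1, ..., 0] + 1j * z[1, ..., 1])
    s0 = magnitude * np.exp(-0.5j * phi_v) + n0
    s1 = magnitude * np.exp(+0.5j * phi_v) + n1
    mag = 0.5 * (np.abs(s0) + np.abs(s1))
    vel = np.angle(s1 * np.conj(s0)) * venc / np.pi
    return mag, vel


# ---------------------------------------------------------------------------
# cone phantom
# ---------------------------------------------------------------------------


def cone_radius(geometry: ConeGeometry, height_above_base_cm):
    """Analytic cone radius (cm) at a given height above the base (cm).

    Linear and exact: r(h) = r_bottom + (r_top − r_bottom) · h / H.
    """
    h = np.asarray(height_above_base_cm, dtype=float)
    if np.any(h < 0) or np.any(h > geometry.height_cm):
        raise ValueError(
            f"height {height_above_base_cm} outside [0, {geometry.height_cm}] cm"
        )
    r_bot = geometry.bottom_diameter_cm / 2.0
    r_top = geometry.top_diameter_cm / 2.0
    out = r_bot + (r_top - r_bot) * h / geometry.height_cm
    return float(out) if np.isscalar(height_above_base_cm) else out


def phantom_schedule(
    n_phases: int = 27,
    step_mm: float = 1.0,
    n_down: int = 15,
    n_hold: int = 3,
    quantum_mm: float = 1.0,
) -> SliceSchedule:
    """Programmed phantom slice schedule: down, hold, then up, 1 mm per phase.

    The slice starts at the planned location, moves inferiorly (toward the
    apex; negative offsets) for ``n_down`` phases including the start, holds
    for ``n_hold`` phases, and moves superiorly for the remaining phases.
    Both the 27- and 28-phase variants of the protocol are reachable through
    ``n_phases``; the pattern is fully configurable.
    """
    if n_phases < n_down + n_hold:
        raise ValueError("schedule needs at least n_down + n_hold phases")
    offsets = np.empty(n_phases)
    offsets[:n_down] = -step_mm * np.arange(n_down)
    floor = -step_mm * (n_down - 1)
    offsets[n_down : n_down + n_hold] = floor
    n_up = n_phases - n_down - n_hold
    offsets[n_down + n_hold :] = floor + step_mm * np.arange(1, n_up + 1)
    return SliceSchedule(offsets, quantum_mm)


_HALF_DIAG = np.sqrt(2.0) / 2.0


def _disk_coverage(shape, center_rc, radius_px, supersample: int = 16) -> np.ndarray:
    """Per-pixel area fraction covered by a disk (partial-volume rendering).

    Pixels clearly inside/outside are set exactly; boundary pixels are
    resolved by ``supersample``² sub-pixel sampling.
    """
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dist = np.hypot(rr - center_rc[0], cc - center_rc[1])
    cov = np.zeros(shape, dtype=float)
    if radius_px <= 0:
        return cov
    cov[dist <= radius_px - _HALF_DIAG] = 1.0
    boundary = (dist > radius_px - _HALF_DIAG) & (dist < radius_px + _HALF_DIAG)
    br, bc = np.nonzero(boundary)
    if br.size:
        off = (np.arange(supersample) + 0.5) / supersample - 0.5
        sub_r = br[:, None, None] + off[None, :, None]
        sub_c = bc[:, None, None] + off[None, None, :]
        d = np.hypot(sub_r - center_rc[0], sub_c - center_rc[1])
        cov[br, bc] = np.mean(d <= radius_px, axis=(1, 2))
    return cov


def simulate_phantom_series(
    geometry: ConeGeometry,
    schedule,
    grid: ImageGrid,
    start_height_cm: float = 3.5,
    noise_sd: float = 0.005,
    seed: int = 0,
    venc: float = 100.0,
    rr_interval_ms: float = 1000.0,
) -> CinePCSeries:
    """Simulate a slice-following acquisition of the static cone phantom.

    Per phase the magnitude image renders the water/cone cross-section at
    height ``start_height_cm + offset/10`` (negative offsets move inferiorly,
    toward the apex) with area-fraction partial-volume edge weighting: water
    bright (1.0), cone dark (0.0).  The phantom is static, so the velocity
    maps contain encoding noise only.  ``noise_sd`` is the complex-channel
    noise SD as a fraction of the water signal.
    """
    offsets = schedule.offsets_mm if isinstance(schedule, SliceSchedule) else np.asarray(schedule, float)
    n = offsets.size
    heights = start_height_cm + offsets / 10.0
    bad = np.nonzero((heights < 0) | (heights > geometry.height_cm))[0]
    if bad.size:
        raise ValueError(
            f"schedule drives the slice outside the cone at phase {bad[0]} "
            f"(height {heights[bad[0]]:.2f} cm)"
        )
    radii_px = cone_radius(geometry, heights) * 10.0 / grid.pixel_spacing_mm
    center = ((grid.matrix_rows - 1) / 2.0, (grid.matrix_cols - 1) / 2.0)
    rng = np.random.default_rng(seed)
    magnitude = np.empty((n,) + grid.shape)
    velocity = np.empty_like(magnitude)
    for i in range(n):
        mag_true = 1.0 - _disk_coverage(grid.shape, center, radii_px[i])
        vel_true = np.zeros(grid.shape)
        magnitude[i], velocity[i] = _pc_encode(mag_true, vel_true, venc, noise_sd, rng)
    dt = rr_interval_ms / n
    times = (np.arange(n) + 0.5) * dt
    return CinePCSeries(
        magnitude,
        velocity,
        venc,
        times,
        np.full(n, dt),
        grid,
        offsets.copy(),
        metadata={
            "scene": "phantom",
            "start_height_cm": start_height_cm,
            "tr_ms": 36.12,
            "te_ms": 4.0,
            "flip_deg": 15.0,
            "plane_mode": "following",
        },
    )


def estimate_slice_radius(magnitude, grid: ImageGrid, foreground: str = "bright") -> float:
    """Area-equivalent radius (mm) of a single disk-shaped region.

    The area is the sum of per-pixel foreground fractions times the pixel
    area and the radius is sqrt(A/π), sub-pixel accurate on partial-volume
    renderings.  Fractions are taken from the image levels themselves: fully
    foreground / background levels are measured from the eroded interior and
    the far background, and only a thin boundary band contributes
    fractionally (which keeps the estimate insensitive to the noise floor in
    the dark region).
    """
    m = np.asarray(magnitude, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a single 2-D frame")
    lo, hi = float(np.min(m)), float(np.max(m))
    if hi - lo <= 1e-12:
        raise UndefinedRadiusError("image is flat; no foreground region")
    thresh = 0.5 * (lo + hi)
    if foreground == "bright":
        mask = m > thresh
    elif foreground == "dark":
        mask = m < thresh
    else:
        raise ValueError("foreground must be 'bright' or 'dark'")
    if not mask.any():
        raise UndefinedRadiusError("no foreground pixels above threshold")
    core = ndimage.binary_erosion(mask, iterations=2)
    dilated = ndimage.binary_dilation(mask, iterations=2)
    band = dilated & ~core
    outside = ~dilated
    fg_level = float(np.median(m[core])) if core.any() else (hi if foreground == "bright" else lo)
    bg_level = float(np.median(m[outside])) if outside.any() else (lo if foreground == "bright" else hi)
    if abs(fg_level - bg_level) <= 1e-12:
        raise UndefinedRadiusError("foreground and background levels coincide")
    frac = (m[band] - bg_level) / (fg_level - bg_level)
    area_px = float(core.sum()) + float(frac.sum())
    if area_px <= 0:
        raise UndefinedRadiusError("non-positive foreground area")
    return float(np.sqrt(area_px / np.pi) * grid.pixel_spacing_mm)


def validate_phantom(
    series: CinePCSeries, geometry: ConeGeometry, start_height_cm: float = 3.5
) -> PhantomValidation:
    """Pair measured against theoretical slice radii at the programmed heights.

    Returns the per-phase radius table plus the mean signed error (bias) and
    its SD in mm.
    """
    if series.slice_offsets is None:
        raise ValueError("series carries no slice offsets; cannot validate the schedule")
    heights = start_height_cm + series.slice_offsets / 10.0
    theoretical = cone_radius(geometry, heights) * 10.0
    measured = np.array(
        [
            estimate_slice_radius(series.magnitude[i], series.grid, foreground="dark")
            for i in range(series.n_phases)
        ]
    )
    err = measured - theoretical
    table = pd.DataFrame(
        {
            "phase": np.arange(series.n_phases),
            "offset_mm": series.slice_offsets,
            "theoretical_mm": theoretical,
            "measured_mm": measured,
            "error_mm": err,
        }
    )
    sd = float(np.std(err, ddof=1)) if err.size > 1 else 0.0
    return PhantomValidation(table, float(np.mean(err)), sd)


# ---------------------------------------------------------------------------
# moving-valve heart scene
# ---------------------------------------------------------------------------

ML_PER_CMS_MM2_MS = 1e-5  # 1 cm/s across 1 mm² for 1 ms = 1e-5 ml

# diastolic timing landmarks as fractions of the RR-interval relative to
# end systole: E wave, diastasis, A wave
_E_START, _E_END = 0.02, 0.28  # offsets from end systole
_A_START, _A_END = 0.79, 0.98  # absolute fractions
_JET_START, _JET_END = 0.08, 0.92  # fractions of systole


def _lobe(frac, f0, f1):
    """Raised-cosine lobe on [f0, f1], zero elsewhere."""
    frac = np.asarray(frac, dtype=float)
    s = (frac - f0) / (f1 - f0)
    out = np.where((s > 0) & (s < 1), np.sin(np.pi * np.clip(s, 0, 1)) ** 2, 0.0)
    return out


def _background_field(offset, grid: ImageGrid) -> np.ndarray:
    """Constant or low-order (planar) background phase offset in cm/s."""
    rr, cc = np.meshgrid(np.arange(grid.matrix_rows), np.arange(grid.matrix_cols), indexing="ij")
    x = (cc - (grid.matrix_cols - 1) / 2.0) * grid.pixel_spacing_mm
    y = (rr - (grid.matrix_rows - 1) / 2.0) * grid.pixel_spacing_mm
    if np.isscalar(offset):
        return np.full(grid.shape, float(offset))
    b0, gx, gy = offset
    return b0 + gx * x + gy * y


def _scene_coords(grid: ImageGrid):
    rr, cc = np.meshgrid(np.arange(grid.matrix_rows), np.arange(grid.matrix_cols), indexing="ij")
    x = (cc - (grid.matrix_cols - 1) / 2.0) * grid.pixel_spacing_mm
    y = (rr - (grid.matrix_rows - 1) / 2.0) * grid.pixel_spacing_mm
    return x, y


def _static_block_slices(i: int):
    """Time-dependent static-tissue block (chest wall analogue)."""
    shift = (i % 3) - 1
    return slice(6, 20), slice(6 + shift, 20 + shift)


def default_heart_grid() -> ImageGrid:
    return ImageGrid.from_fov(128, 256.0, 8.0)


def _displacement_samples(params: HeartSceneParams, frac: np.ndarray, p_shape: np.ndarray) -> np.ndarray:
    """Per-phase annular displacement (mm, apical positive, not re-zeroed).

    Rises as a raised cosine to the configured excursion at end systole; the
    diastolic return is constructed so that the *cyclic central difference*
    of the samples — the derivative the analysis chain later subtracts — is
    exactly proportional to the instantaneous transmitral inflow (annular
    recoil tracks filling, and the annulus is at rest whenever inflow is
    zero).  The central difference couples alternate phases, so the return
    is built as two interleaved recurrences, each closed onto the end-
    diastolic position.
    """
    n = params.n_phases
    es = params.resolved_end_systole()
    f_es = es / n
    dd = params.annulus_excursion_mm
    d = np.empty(n + 1)
    i_sys = np.arange(es)
    d[i_sys] = dd * np.sin(np.pi * frac[i_sys] / (2 * f_es)) ** 2
    d[es] = dd
    weights = p_shape[es:n]
    if weights.sum() <= 0:  # no configured inflow; fall back to a smooth return
        s = (frac[es:n] - f_es) / (1.0 - f_es)
        d[es:n] = dd * 0.5 * (1 + np.cos(np.pi * s))
        return d[:n]
    # (d[i+1] - d[i-1]) = -c * p[i] for diastolic i; two parity chains start
    # from d[es-1] / d[es] and both land exactly on the end-diastolic value
    chain_total = {0: 0.0, 1: 0.0}
    for i in range(es, n):
        chain_total[(i + 1) % 2] += p_shape[i]
    start = {(es + 1) % 2: d[es - 1], es % 2: d[es]}
    target = d[0]
    coef = {
        q: (start[q] - target) / chain_total[q] if chain_total[q] > 0 else 0.0
        for q in (0, 1)
    }
    for i in range(es, n):
        d[i + 1] = d[i - 1] - coef[(i + 1) % 2] * p_shape[i]
    return d[:n]


def simulate_heart_scene(
    params: HeartSceneParams,
    plane_mode: str = "following",
    grid: Optional[ImageGrid] = None,
    allow_wrap: bool = False,
) -> tuple[CinePCSeries, AnnulusTrajectory, GroundTruth]:
    """Simulate one cine PC acquisition of the moving-valve heart scene.

    ``plane_mode='following'`` samples the velocity maps at the moving
    annular plane: the lab-frame velocity inside the annular disk is the
    transvalvular velocity plus the valve velocity, so subtracting the valve
    velocity recovers the true transvalvular flow.  ``plane_mode='static'``
    samples at the fixed end-systolic plane: no valve-velocity term, but an
    LVOT outflow region contaminates the annular neighbourhood in systole.

    Background offset and noise are applied after velocity encoding.  Returns
    the series, the annulus insertion-point trajectory that generated it, and
    the exact ground truth.
    """
    if plane_mode not in ("following", "static"):
        raise ValueError("plane_mode must be 'following' or 'static'")
    if grid is None:
        grid = default_heart_grid()
    n = params.n_phases
    es = params.resolved_end_systole()
    dt = params.rr_interval_ms / n
    times = (np.arange(n) + 0.5) * dt
    frac = times / params.rr_interval_ms
    f_es = es / n

    # --- temporal shapes (unit amplitude) -------------------------------
    e_lobe = _lobe(frac, f_es + _E_START, f_es + _E_END)
    a_lobe = _lobe(frac, _A_START, _A_END)
    p_shape = params.e_peak_m_s * 100.0 * e_lobe + params.a_peak_m_s * 100.0 * a_lobe
    jet_shape = _lobe(frac, _JET_START * f_es, _JET_END * f_es)

    # --- spatial profiles ----------------------------------------------
    x, y = _scene_coords(grid)
    dist = np.hypot(x, y)
    r_ann = params.annulus_radius_mm
    disk = dist <= r_ann
    ring = (dist > r_ann) & (dist <= 1.6 * r_ann)
    # flat inflow profile across the orifice: transmitral flow detaches at the
    # annulus rather than developing a no-slip tube profile, and the standard
    # clinical model (CSA x VTI) assumes a uniform velocity over the annulus
    w_inflow = disk.astype(float)
    r_o = params.orifice_radius_frac * r_ann
    w_jet = np.where(dist <= r_o, 1.0 - (dist / r_o) ** 2, 0.0)
    # static-plane systolic outflow region (LV outflow tract analogue): a
    # blunt stream toward the septal side, kept inside the annular ROI
    lvot_center = (0.0, -0.3 * r_ann)  # (y, x) mm
    d_lvot = np.hypot(x - lvot_center[1], y - lvot_center[0])
    r_l = 0.65 * r_ann
    w_lvot = np.where(d_lvot <= r_l, 1.0 - (d_lvot / r_l) ** 8, 0.0)

    a_px = grid.pixel_area_mm2
    dia = np.zeros(n, dtype=bool)
    dia[es:] = True

    # --- amplitude normalization to the configured volumes --------------
    raw_mitral = float(np.sum(p_shape[dia]) * np.sum(w_inflow) * a_px * dt) * ML_PER_CMS_MM2_MS
    scale_mitral = params.true_mitral_sv_ml / raw_mitral if raw_mitral > 0 else 0.0
    raw_jet = float(np.sum(jet_shape[:es]) * np.sum(w_jet) * a_px * dt) * ML_PER_CMS_MM2_MS
    scale_jet = params.regurgitant_volume_ml / raw_jet if raw_jet > 0 else 0.0
    # at a static basal plane, LV outflow and regurgitant convergence are one
    # indistinguishable systolic backward stream; its total volume is their sum
    static_backward = params.resolved_lvot_sv() + params.regurgitant_volume_ml
    raw_lvot = float(np.sum(jet_shape[:es]) * np.sum(w_lvot) * a_px * dt) * ML_PER_CMS_MM2_MS
    scale_lvot = static_backward / raw_lvot if raw_lvot > 0 else 0.0

    p_t = scale_mitral * p_shape  # peak-pixel inflow velocity per phase, cm/s
    jet_t = scale_jet * jet_shape
    lvot_t = scale_lvot * jet_shape

    # --- valve motion ----------------------------------------------------
    d_raw = _displacement_samples(params, frac, p_shape)
    displacement = d_raw - d_raw[0]
    curve = DisplacementCurve(displacement, times.copy())
    v_valve = valve_velocity(curve)  # the same discrete derivative the
    # quantifier subtracts later, so motion correction is self-consistent
    schedule = build_slice_schedule(curve, quantum_mm=1.0)

    # --- noise-free velocity fields -------------------------------------
    bg = _background_field(params.background_offset, grid)
    vel_true = np.empty((n,) + grid.shape)
    for i in range(n):
        if plane_mode == "static":
            v = p_t[i] * w_inflow - lvot_t[i] * w_lvot + v_valve[i] * ring
        else:
            v = p_t[i] * w_inflow - jet_t[i] * w_jet + v_valve[i] * (disk | ring)
        vel_true[i] = v + bg
    vmax = float(np.max(np.abs(vel_true)))
    if vmax >= params.venc and not allow_wrap:
        raise ValueError(
            f"peak encoded velocity {vmax:.1f} cm/s reaches the VENC "
            f"({params.venc} cm/s) with wrapping disabled"
        )

    # --- magnitude and encoding -----------------------------------------
    mag_base = np.full(grid.shape, 0.35)
    mag_base[ring] = 0.6
    mag_base[disk] = 1.0
    sigma_c = np.pi * params.noise_sd / (np.sqrt(2.0) * params.venc)
    rng = np.random.default_rng(params.seed)
    magnitude = np.empty_like(vel_true)
    velocity = np.empty_like(vel_true)
    for i in range(n):
        mag_true = mag_base.copy()
        rs, cs = _static_block_slices(i)
        mag_true[rs, cs] = 0.55
        magnitude[i], velocity[i] = _pc_encode(mag_true, vel_true[i], params.venc, sigma_c, rng)

    offsets = schedule.offsets_mm if plane_mode == "following" else np.zeros(n)
    e_idx = np.nonzero(e_lobe > 0)[0]
    a_idx = np.nonzero(a_lobe > 0)[0]
    event_indices = {
        "end_diastole": 0,
        "end_systole": es,
        "e_window": [int(e_idx[0]), int(e_idx[-1]) + 1] if e_idx.size else [es, es],
        "a_window": [int(a_idx[0]), int(a_idx[-1]) + 1] if a_idx.size else [n, n],
    }
    series = CinePCSeries(
        magnitude,
        velocity,
        params.venc,
        times,
        np.full(n, dt),
        grid,
        offsets,
        metadata={
            "scene": "heart",
            "plane_mode": plane_mode,
            "tr_ms": 5.1,
            "te_ms": 4.0,
            "flip_deg": 15.0,
            "event_indices": event_indices,
            "seed": params.seed,
        },
    )

    # --- trajectory ------------------------------------------------------
    # insertion points in the long-axis plane; +y is apical (the slice
    # normal); the annular line tilts toward end systole by the configured
    # angle without moving the midpoint.
    tilt_shape = d_raw / params.annulus_excursion_mm if params.annulus_excursion_mm > 0 else np.zeros(n)
    if params.annulus_excursion_mm > 0:
        tilt_shape = (tilt_shape - tilt_shape[0]) / max(tilt_shape[es] - tilt_shape[0], 1e-12)
    theta = np.radians(params.plane_tilt_deg) * tilt_shape
    half = np.stack([np.cos(theta), np.sin(theta)], axis=1) * r_ann  # (n, 2)
    mid = np.stack([np.zeros(n), displacement], axis=1)
    traj = AnnulusTrajectory(
        septal=mid - half,
        lateral=mid + half,
        phase_times=times.copy(),
        slice_normal=np.array([0.0, 1.0]),
    )

    # --- ground truth ----------------------------------------------------
    n_disk = int(disk.sum())
    passive = float(np.sum(-v_valve[dia]) * n_disk * a_px * dt) * ML_PER_CMS_MM2_MS
    gt = GroundTruth(
        true_mitral_sv_ml=params.true_mitral_sv_ml,
        true_aortic_sv_ml=params.true_mitral_sv_ml - params.regurgitant_volume_ml,
        true_regurgitant_volume_ml=params.regurgitant_volume_ml,
        passive_transfer_volume_ml=passive,
        true_planimetric_sv_ml=params.true_mitral_sv_ml,
        displacement_curve_mm=displacement,
        valve_velocity_cm_s=v_valve,
        event_indices=event_indices,
        e_peak_realized_m_s=float(np.max(p_t * np.max(w_inflow)) / 100.0),
        a_peak_realized_m_s=float(
            np.max(p_t[a_idx] * np.max(w_inflow)) / 100.0 if a_idx.size else 0.0
        ),
    )
    return series, traj, gt


def scene_roi_polygons(
    params: HeartSceneParams, grid: Optional[ImageGrid] = None, n_vertices: int = 48
) -> dict:
    """Default region-of-interest polygons for a simulated heart scene.

    Returns per-phase polygon lists (pixel coordinates, 0-based row/col) for
    the mitral annular border (circle with a small margin so every blood
    pixel centre falls inside) and the time-dependent static-tissue block.
    """
    if grid is None:
        grid = default_heart_grid()
    n = params.n_phases
    s = grid.pixel_spacing_mm
    center = np.array([(grid.matrix_rows - 1) / 2.0, (grid.matrix_cols - 1) / 2.0])
    # draw the ROI exactly on the annular border: the circumscribed polygon's
    # inradius matches the annulus radius, so every blood pixel centre is
    # inside while almost no moving annular tissue is pulled in (tissue in the
    # ROI biases both the forward-flow sum and the motion-correction deficit)
    r_px = (params.annulus_radius_mm / np.cos(np.pi / n_vertices) + 0.02) / s
    ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    circle = center + r_px * np.stack([np.sin(ang), np.cos(ang)], axis=1)
    mitral = [circle.copy() for _ in range(n)]
    static = []
    for i in range(n):
        rs, cs = _static_block_slices(i)
        r0, r1 = rs.start - 0.4, rs.stop - 0.6
        c0, c1 = cs.start - 0.4, cs.stop - 0.6
        static.append(np.array([[r0, c0], [r0, c1], [r1, c1], [r1, c0]]))
    return {"mitral": mitral, "static": static}


def simulate_aortic_series(
    params: HeartSceneParams,
    grid: Optional[ImageGrid] = None,
    venc: float = 180.0,
    root_radius_mm: float = 14.0,
) -> tuple[CinePCSeries, dict]:
    """Companion aortic-root acquisition for the same heartbeat.

    The systolic forward lobe and a small early-diastolic backflow are
    normalized so the whole-cycle net discrete volume equals the scene's
    aortic stroke volume (mitral SV minus regurgitation) exactly.  Positive
    velocity is forward ejection in this series' own through-plane
    convention.  Returns the series and its ROI polygons
    ({'aortic': [...], 'static': [...]}).
    """
    if grid is None:
        grid = ImageGrid.from_fov(64, 128.0, 8.0)
    n = params.n_phases
    es = params.resolved_end_systole()
    dt = params.rr_interval_ms / n
    times = (np.arange(n) + 0.5) * dt
    frac = times / params.rr_interval_ms
    f_es = es / n
    aortic_sv = params.resolved_lvot_sv() if params.lvot_sv_ml is not None else (
        params.true_mitral_sv_ml - params.regurgitant_volume_ml
    )

    fwd_shape = _lobe(frac, 0.04, f_es + 0.02)
    bwd_shape = _lobe(frac, f_es + 0.02, f_es + 0.17)
    x, y = _scene_coords(grid)
    dist = np.hypot(x, y)
    rho = dist / root_radius_mm
    w = np.where(dist <= root_radius_mm, 1.0 - rho**8, 0.0)
    ring = (dist > root_radius_mm) & (dist <= 1.5 * root_radius_mm)
    a_px = grid.pixel_area_mm2

    raw_fwd = float(np.sum(fwd_shape) * np.sum(w) * a_px * dt) * ML_PER_CMS_MM2_MS
    raw_bwd = float(np.sum(bwd_shape) * np.sum(w) * a_px * dt) * ML_PER_CMS_MM2_MS
    fwd_target, bwd_target = 1.03 * aortic_sv, 0.03 * aortic_sv
    s_fwd = fwd_target / raw_fwd if raw_fwd > 0 else 0.0
    s_bwd = bwd_target / raw_bwd if raw_bwd > 0 else 0.0

    bg = _background_field(params.background_offset, grid)
    sigma_c = np.pi * params.noise_sd / (np.sqrt(2.0) * venc)
    rng = np.random.default_rng(params.seed + 104729)
    magnitude = np.empty((n,) + grid.shape)
    velocity = np.empty_like(magnitude)
    mag_base = np.full(grid.shape, 0.35)
    mag_base[ring] = 0.6
    mag_base[dist <= root_radius_mm] = 1.0
    for i in range(n):
        vel_true = (s_fwd * fwd_shape[i] - s_bwd * bwd_shape[i]) * w + bg
        mag_true = mag_base.copy()
        rs, cs = _static_block_slices(i)
        mag_true[rs, cs] = 0.55
        magnitude[i], velocity[i] = _pc_encode(mag_true, vel_true, venc, sigma_c, rng)
    series = CinePCSeries(
        magnitude,
        velocity,
        venc,
        times,
        np.full(n, dt),
        grid,
        np.zeros(n),
        metadata={
            "scene": "aorta",
            "plane_mode": "static",
            "true_aortic_sv_ml": aortic_sv,
            "seed": params.seed,
        },
    )
    s_mm = grid.pixel_spacing_mm
    center = np.array([(grid.matrix_rows - 1) / 2.0, (grid.matrix_cols - 1) / 2.0])
    r_px = (root_radius_mm / np.cos(np.pi / 48) + 0.02) / s_mm
    ang = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    circle = center + r_px * np.stack([np.sin(ang), np.cos(ang)], axis=1)
    static = []
    for i in range(n):
        rs, cs = _static_block_slices(i)
        static.append(
            np.array(
                [
                    [rs.start - 0.4, cs.start - 0.4],
                    [rs.start - 0.4, cs.stop - 0.6],
                    [rs.stop - 0.6, cs.stop - 0.6],
                    [rs.stop - 0.6, cs.start - 0.4],
                ]
            )
        )
    rois = {"aortic": [circle.copy() for _ in range(n)], "static": static}
    return series, rois


def synthetic_short_axis_stack(
    sv_ml: float,
    ejection_fraction: float = 0.6,
    n_slices: int = 10,
    spacing_mm: float = 10.0,
):
    """Short-axis endocardial-area stack with an exact planimetric SV.

    End-diastolic and end-systolic per-slice areas follow a semi-ellipsoid
    profile from base to apex, scaled so the summed slice volumes equal
    EDV = SV / EF and ESV = EDV − SV exactly.  Returns a
    :class:`~valvepc.flow_quant.ShortAxisStack` with the ED phase at index 0
    and the ES phase at index 1.
    """
    from .flow_quant import ShortAxisStack  # local import; flow_quant imports this module

    if not (0 < ejection_fraction <= 1):
        raise ValueError("ejection fraction must lie in (0, 1]")
    edv = sv_ml / ejection_fraction
    esv = edv - sv_ml
    z = (np.arange(n_slices) + 0.5) / n_slices
    profile = 1.0 - z**2
    sp_cm = spacing_mm / 10.0
    base = profile / (profile.sum() * sp_cm)
    areas = np.stack([base * edv, base * esv], axis=1)  # cm², (n_slices, 2)
    return ShortAxisStack(areas_cm2=areas, spacing_mm=spacing_mm, ed_index=0, es_index=1)


def validation_cohort(seed: int = 0, n_scenes: int = 20) -> list[HeartSceneParams]:
    """Seeded scene cohort for the parameter-recovery validation study.

    Spans stroke volumes 40–120 ml, annular excursions 0–20 mm and
    regurgitant volumes 0–30 ml.  Three anchor scenes pin the extremes
    (excursion 0, excursion 20 mm, regurgitation 30 ml); the rest draw a
    physiologically coupled cohort: excursion tracks stroke volume (long-axis
    shortening contributes a large share of LV filling), the annulus radius
    scales with SV^(1/3) (smaller hearts, smaller annuli) and regurgitation
    is capped at 45% of the stroke volume.
    """
    rng = np.random.default_rng(seed)
    anchors = [(85.0, 0.0, 0.0), (95.0, 20.0, 0.0), (110.0, 16.0, 30.0)]
    scenes = []
    for i in range(n_scenes):
        if i < len(anchors):
            sv, exc, reg = anchors[i]
        else:
            sv = float(rng.uniform(40.0, 120.0))
            exc = float(np.clip(15.0 * sv / 97.0 + rng.normal(0.0, 2.0), 4.0, 20.0))
            reg = 0.0 if rng.random() < 0.5 else float(rng.uniform(2.0, min(30.0, 0.45 * sv)))
        radius = float(np.clip(19.0 * (sv / 80.0) ** (1.0 / 3.0), 14.0, 23.0))
        scenes.append(
            HeartSceneParams(
                true_mitral_sv_ml=sv,
                annulus_excursion_mm=exc,
                regurgitant_volume_ml=reg,
                annulus_radius_mm=radius,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return scenes


def write_ground_truth_csv(gt: GroundTruth, path) -> None:
    """One row per phase; scene-level volumes repeated as constant columns."""
    n = gt.displacement_curve_mm.size
    df = pd.DataFrame(
        {
            "phase": np.arange(n),
            "displacement_mm": gt.displacement_curve_mm,
            "valve_velocity_cm_s": gt.valve_velocity_cm_s,
            "true_mitral_sv_ml": gt.true_mitral_sv_ml,
            "true_aortic_sv_ml": gt.true_aortic_sv_ml,
            "true_regurgitant_volume_ml": gt.true_regurgitant_volume_ml,
            "passive_transfer_volume_ml": gt.passive_transfer_volume_ml,
            "true_planimetric_sv_ml": gt.true_planimetric_sv_ml,
            "end_systole_index": gt.event_indices["end_systole"],
        }
    )
    df.to_csv(path, index=False)
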