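"""Mitral annulus motion: trajectories, displacement, velocity, slice schedules.

The imaging plane of a slice-following phase-contrast acquisition is
re-positioned every cardiac phase so that it stays on the mitral annulus.
This module turns tracked annular insertion-point trajectories into

* the per-phase displacement of the annular mid-point along the slice
  normal (mm, re-zeroed at the first reconstructed phase),
* the annular through-plane velocity (cm/s, cyclic central differences),
* the angle between the end-diastolic and end-systolic annular lines,
* a quantized slice-translation schedule (offsets restricted to the 1 mm
  grid of graphically prescribed parallel slices), and
* the plain-text translation table consumed by the (simulated) sequence.

Feature tracking itself is *not* implemented here: trajectories are
ingested from the simulator or from a user CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnnulusTrajectory",
    "DisplacementCurve",
    "SliceSchedule",
    "compute_displacement",
    "valve_velocity",
    "annular_plane_angle",
    "build_slice_schedule",
    "write_translation_file",
    "read_translation_file",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

TRAJECTORY_COLUMNS = [
    "phase",
    "time_ms",
    "septal_x_mm",
    "septal_y_mm",
    "lateral_x_mm",
    "lateral_y_mm",
]


@dataclass
class AnnulusTrajectory:
    """Septal and lateral mitral insertion points tracked in the image plane.

    Coordinates are in mm in the long-axis (4-chamber) image plane.  The
    slice normal of the short-axis PC acquisition lies in this plane and is
    given as a unit vector; displacement is measured along it (positive =
    apical).
    """

    septal: np.ndarray  # (n_phases, 2) mm
    lateral: np.ndarray  # (n_phases, 2) mm
    phase_times: np.ndarray  # (n_phases,) ms, strictly increasing
    slice_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))

    def __post_init__(self) -> None:
        self.septal = np.asarray(self.septal, dtype=float)
        self.lateral = np.asarray(self.lateral, dtype=float)
        self.phase_times = np.asarray(self.phase_times, dtype=float)
        self.slice_normal = np.asarray(self.slice_normal, dtype=float)
        if self.septal.shape != self.lateral.shape or self.septal.ndim != 2:
            raise ValueError("septal and lateral trajectories must share shape (n, 2)")
        if self.septal.shape[0] != self.phase_times.size:
            raise ValueError("trajectory length must match phase_times")
        if not (np.isfinite(self.septal).all() and np.isfinite(self.lateral).all()):
            missing = np.nonzero(
                ~(np.isfinite(self.septal).all(axis=1) & np.isfinite(self.lateral).all(axis=1))
            )[0]
            raise ValueError(f"missing insertion point at phase(s) {missing.tolist()}")
        if np.any(np.diff(self.phase_times) <= 0):
            raise ValueError("phase_times must be strictly increasing")
        norm = np.hypot(*self.slice_normal)
        if norm == 0:
            raise ValueError("slice_normal must be a nonzero vector")
        self.slice_normal = self.slice_normal / norm

    @property
    def n_phases(self) -> int:
        return self.phase_times.size

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.septal + self.lateral)


@dataclass
class DisplacementCurve:
    """Valve displacement d(t) along the slice normal, zero at the first phase."""

    displacement_mm: np.ndarray
    phase_times: np.ndarray  # ms

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.phase_times = np.asarray(self.phase_times, dtype=float)
        if self.displacement_mm.shape != self.phase_times.shape:
            raise ValueError("displacement and phase_times must share shape")
        if not np.isfinite(self.displacement_mm).all():
            raise ValueError("displacement must be finite")
        if self.displacement_mm.size and self.displacement_mm[0] != 0.0:
            raise ValueError("displacement must be re-zeroed at the first phase")

    @property
    def n_phases(self) -> int:
        return self.phase_times.size


@dataclass
class SliceSchedule:
    """Per-phase slice offsets (mm), each an integer multiple of ``quantum``."""

    offsets_mm: np.ndarray
    quantum_mm: float = 1.0

    def __post_init__(self) -> None:
        self.offsets_mm = np.asarray(self.offsets_mm, dtype=float)
        if self.quantum_mm <= 0:
            raise ValueError("quantum must be positive")
        ratio = self.offsets_mm / self.quantum_mm
        if not np.allclose(ratio, np.round(ratio), atol=1e-9):
            raise ValueError("every offset must be an integer multiple of the quantum")

    @property
    def n_phases(self) -> int:
        return self.offsets_mm.size


def compute_displacement(traj: AnnulusTrajectory) -> DisplacementCurve:
    """Annular mid-point displacement projected onto the slice normal.

    The subject-specific displacement at each phase is the average of the
    septal and lateral insertion-point positions, projected onto the slice
    normal and re-zeroed at the first reconstructed phase (the slice is
    planned at a known phase; only relative translation matters).
    """
    proj = traj.midpoint @ traj.slice_normal
    return DisplacementCurve(proj - proj[0], traj.phase_times.copy())


def valve_velocity(curve: DisplacementCurve) -> np.ndarray:
    """Annular through-plane velocity (cm/s) by cyclic central differences.

    The cardiac cycle is periodic, so the stencil wraps: the neighbour of the
    last phase is the first one, one RR-interval later.  Phase spacing is
    taken from ``phase_times`` (the RR-interval is inferred from the mean
    phase duration for the wrap-around step).
    """
    d = curve.displacement_mm
    t = curve.phase_times
    if d.size < 3:
        raise ValueError("need at least 3 phases for a cyclic derivative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("phase_times must be strictly increasing")
    rr = t[-1] - t[0] + np.mean(np.diff(t))  # full cycle duration
    d_next = np.roll(d, -1)
    d_prev = np.roll(d, 1)
    t_next = np.roll(t, -1).astype(float)
    t_prev = np.roll(t, 1).astype(float)
    t_next[-1] += rr
    t_prev[0] -= rr
    # mm/ms == m/s; convert to cm/s
    return (d_next - d_prev) / (t_next - t_prev) * 100.0


def annular_plane_angle(traj: AnnulusTrajectory, ed_index: int, es_index: int) -> float:
    """Angle (degrees, in [0, 90]) between the septal-to-lateral annular line
    at end diastole and at end systole."""
    n = traj.n_phases
    for name, idx in (("ed_index", ed_index), ("es_index", es_index)):
        if not (-n <= idx < n):
            raise IndexError(f"{name} {idx} out of range for {n} phases")
    vecs = []
    for idx in (ed_index, es_index):
        v = traj.lateral[idx] - traj.septal[idx]
        norm = np.hypot(*v)
        if norm < 1e-12:
            raise ValueError(f"coincident insertion points at phase {idx}: line undefined")
        vecs.append(v / norm)
    cosang = abs(float(np.dot(vecs[0], vecs[1])))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def build_slice_schedule(curve: DisplacementCurve, quantum_mm: float = 1.0) -> SliceSchedule:
    """Quantize a displacement curve onto the slice grid.

    Each displacement is rounded to the nearest multiple of ``quantum_mm``
    (ties away from zero, symmetric for inferior/superior motion), so the
    imaged plane stays on the annulus to within half a slice spacing.
    """
    if quantum_mm <= 0:
        raise ValueError("quantum must be positive")
    offsets = _round_half_away(curve.displacement_mm / quantum_mm) * quantum_mm
    return SliceSchedule(offsets, quantum_mm)


def write_translation_file(schedule: SliceSchedule, path) -> None:
    """Write the slice-translation table: one signed mm value per line.

    Format is bit-exact: phase order, '.' decimal separator, line-feed
    terminated.  Integer-valued offsets are written without a decimal point.
    """
    if schedule.n_phases == 0:
        raise ValueError("cannot write an empty schedule")
    lines = []
    for v in schedule.offsets_mm:
        lines.append(f"{v:g}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_translation_file(path, quantum_mm: float | None = None) -> SliceSchedule:
    """Read a slice-translation table written by :func:`write_translation_file`.

    If ``quantum_mm`` is omitted it is inferred as the greatest common grid of
    the offsets (falling back to 1 mm for an all-zero table).
    """
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError as exc:
                raise ValueError(f"non-numeric translation value on line {lineno}: {text!r}") from exc
    if not values:
        raise ValueError("translation file contains no values")
    offsets = np.asarray(values, dtype=float)
    if quantum_mm is None:
        nonzero = np.abs(offsets[offsets != 0])
        if nonzero.size == 0:
            quantum_mm = 1.0
        else:
            # integer-valued mm tables are the common case
            q = float(np.min(nonzero))
            quantum_mm = q if np.allclose(offsets / q, np.round(offsets / q)) else 1.0
    return SliceSchedule(offsets, quantum_mm)


def write_trajectory_csv(traj: AnnulusTrajectory, path) -> None:
    df = pd.DataFrame(
        {
            "phase": np.arange(traj.n_phases),
            "time_ms": traj.phase_times,
            "septal_x_mm": traj.septal[:, 0],
            "septal_y_mm": traj.septal[:, 1],
            "lateral_x_mm": traj.lateral[:, 0],
            "lateral_y_mm": traj.lateral[:, 1],
        }
    )
    df.to_csv(path, index=False)


def read_trajectory_csv(path, slice_normal=(0.0, 1.0)) -> AnnulusTrajectory:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {missing}")
    df = df.sort_values("phase")
    return AnnulusTrajectory(
        septal=df[["septal_x_mm", "septal_y_mm"]].to_numpy(),
        lateral=df[["lateral_x_mm", "lateral_y_mm"]].to_numpy(),
        phase_times=df["time_ms"].to_numpy(),
        slice_normal=np.asarray(slice_normal, dtype=float),
    )
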