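"""Flow quantification from cine PC series with background and motion correction.

The chain mirrors standard valvular PC post-processing: background phase
offsets are removed using static-tissue regions, the annular through-plane
velocity is subtracted so flow is expressed relative to the moving valve,
per-phase forward/backward/net flow rates are integrated over ROIs, and the
clinical volume metrics are derived:

* mitral SV        — diastolic forward transmitral volume
* aortic SV        — whole-cycle net aortic flow volume
* planimetric SV   — EDV − ESV from short-axis endocardial areas
* regurgitant volume, three ways: planimetric − aortic SV (guidelines),
  systolic backward transmitral volume (direct), mitral − aortic SV
* E, A, E/A        — 95th-percentile peak transmitral velocities, computed
  without motion correction in analogy with echocardiography.

Conventions: ROI vertices are 0-based (row, col) pixel coordinates; pixel
inclusion is by pixel-centre-in-polygon; the forward/backward split is by
per-pixel velocity sign within the ROI; volumes are ml, rates ml/s,
velocities m/s in reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.measure import grid_points_in_poly

from .synthetic_cine import CinePCSeries

__all__ = [
    "RoiSeries",
    "FlowCurve",
    "ShortAxisStack",
    "VolumeReport",
    "roi_mask",
    "background_correct",
    "motion_correct",
    "compute_flow_curve",
    "integrate_interval",
    "summarize_volumes",
    "diastolic_peaks",
    "planimetric_volumes",
    "write_flow_curve_csv",
    "write_rois_json",
    "read_rois_json",
]

_RATE_ML_S_PER_CMS_MM2 = 0.01  # 1 cm/s across 1 mm² = 0.01 ml/s


@dataclass
class RoiSeries:
    """One closed polygon per cardiac phase, tagged with its role.

    Roles follow the analysis protocol: ``mitral``, ``aortic``,
    ``static-tissue`` (may vary per phase for slice-following images, where
    the chest-wall depiction changes with cardiac phase) or
    ``lv-endocardium``.
    """

    role: str
    polygons: list  # per phase: (k, 2) array of (row, col) vertices

    def __post_init__(self) -> None:
        self.polygons = [np.asarray(p, dtype=float) for p in self.polygons]
        for i, poly in enumerate(self.polygons):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError(f"polygon at phase {i} needs at least 3 (row, col) vertices")

    @property
    def n_phases(self) -> int:
        return len(self.polygons)


@dataclass
class FlowCurve:
    """Per-phase net, forward and backward flow rates (ml/s).

    ``net = forward + backward`` at every phase; ``forward >= 0 >= backward``.
    ``partition`` is the end-systole phase index: systole spans phases
    [0, partition), diastole [partition, n).
    """

    net: np.ndarray
    forward: np.ndarray
    backward: np.ndarray
    phase_durations: np.ndarray  # ms
    partition: int
    phase_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.net = np.asarray(self.net, dtype=float)
        self.forward = np.asarray(self.forward, dtype=float)
        self.backward = np.asarray(self.backward, dtype=float)
        self.phase_durations = np.asarray(self.phase_durations, dtype=float)
        n = self.net.size
        for name, arr in (("forward", self.forward), ("backward", self.backward), ("phase_durations", self.phase_durations)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must match the number of phases")
        if not np.allclose(self.net, self.forward + self.backward, atol=1e-9):
            raise ValueError("net must equal forward + backward at every phase")
        if np.any(self.forward < -1e-12) or np.any(self.backward > 1e-12):
            raise ValueError("need forward >= 0 >= backward")
        if not (0 <= self.partition <= n):
            raise ValueError("partition index out of range")

    @property
    def n_phases(self) -> int:
        return self.net.size


@dataclass
class ShortAxisStack:
    """Per-slice, per-phase endocardial areas (cm²) with ED/ES phase indices."""

    areas_cm2: np.ndarray  # (n_slices, n_phases)
    spacing_mm: float  # slice thickness + gap
    ed_index: int
    es_index: int

    def __post_init__(self) -> None:
        self.areas_cm2 = np.asarray(self.areas_cm2, dtype=float)
        if self.areas_cm2.ndim != 2:
            raise ValueError("areas must be (n_slices, n_phases)")
        if np.any(self.areas_cm2 < 0):
            raise ValueError("endocardial areas must be non-negative")
        if self.spacing_mm <= 0:
            raise ValueError("slice spacing must be positive")
        for name, idx in (("ed_index", self.ed_index), ("es_index", self.es_index)):
            if not (0 <= idx < self.areas_cm2.shape[1]):
                raise IndexError(f"{name} out of range")


@dataclass
class VolumeReport:
    """Volume and diastolic metrics of one quantified study (ml, m/s, %)."""

    mitral_sv_ml: float
    aortic_sv_ml: float
    planimetric_sv_ml: float = np.nan
    edv_ml: float = np.nan
    esv_ml: float = np.nan
    regurgitant_volume_guideline_ml: float = np.nan
    regurgitant_volume_direct_ml: float = np.nan
    regurgitant_volume_mitral_minus_aortic_ml: float = np.nan
    regurgitant_fraction_planimetric_pct: float = np.nan
    regurgitant_fraction_mitral_pct: float = np.nan
    e_peak_m_s: float = np.nan
    a_peak_m_s: float = np.nan
    e_over_a: float = np.nan
    flow_volumes_ml: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "mitral_sv_ml",
                "aortic_sv_ml",
                "planimetric_sv_ml",
                "edv_ml",
                "esv_ml",
                "regurgitant_volume_guideline_ml",
                "regurgitant_volume_direct_ml",
                "regurgitant_volume_mitral_minus_aortic_ml",
                "regurgitant_fraction_planimetric_pct",
                "regurgitant_fraction_mitral_pct",
                "e_peak_m_s",
                "a_peak_m_s",
                "e_over_a",
            )
        }
        out["flow_volumes_ml"] = self.flow_volumes_ml
        out["notes"] = self.notes
        return out


# ---------------------------------------------------------------------------
# pixel selection and corrections
# ---------------------------------------------------------------------------


def roi_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the polygon."""
    poly = np.asarray(polygon, dtype=float)
    if np.any(poly < -0.5) or np.any(poly[:, 0] > shape[0] - 0.5) or np.any(poly[:, 1] > shape[1] - 0.5):
        raise ValueError("ROI polygon extends outside the image bounds")
    return grid_points_in_poly(shape, poly)


def _roi_for_phase(rois: RoiSeries, phase: int) -> np.ndarray:
    if rois.n_phases == 1:
        return rois.polygons[0]
    if phase >= rois.n_phases:
        raise ValueError(f"no ROI defined for phase {phase}")
    return rois.polygons[phase]


def background_correct(series: CinePCSeries, static_rois: RoiSeries) -> CinePCSeries:
    """Remove background phase offsets using static-tissue regions.

    Per phase, the mean velocity inside that phase's static-tissue ROI is
    subtracted from the whole velocity map (static tissue should be at rest,
    so any mean there is scanner offset).
    """
    out = series.copy()
    for i in range(series.n_phases):
        mask = roi_mask(_roi_for_phase(static_rois, i), series.grid.shape)
        if not mask.any():
            raise ValueError(f"static-tissue ROI covers zero pixels at phase {i}")
        out.velocity[i] -= float(np.mean(series.velocity[i][mask]))
    out.metadata["background_corrected"] = True
    return out


def motion_correct(series: CinePCSeries, velocity_curve_cm_s) -> CinePCSeries:
    """Subtract the valve's through-plane velocity from every velocity map.

    Expresses blood velocity relative to the moving annular plane so the
    passively transferred volume is counted as flow.  Magnitude images are
    untouched.
    """
    v = np.asarray(velocity_curve_cm_s, dtype=float)
    if v.shape != (series.n_phases,):
        raise ValueError(
            f"valve-velocity curve has {v.size} entries for {series.n_phases} phases"
        )
    out = series.copy()
    out.velocity -= v[:, None, None]
    out.metadata["motion_corrected"] = True
    return out


# ---------------------------------------------------------------------------
# flow integration
# ---------------------------------------------------------------------------


def compute_flow_curve(series: CinePCSeries, rois: RoiSeries, partition: Optional[int] = None) -> FlowCurve:
    """Integrate ROI velocities into per-phase flow rates (ml/s).

    The net rate is the sum of velocity × pixel area over ROI pixels; the
    forward (backward) rate sums only pixels with positive (negative)
    velocity, so simultaneous forward and backward flow is resolved.
    """
    a_px = series.grid.pixel_area_mm2
    n = series.n_phases
    net = np.empty(n)
    fwd = np.empty(n)
    bwd = np.empty(n)
    for i in range(n):
        mask = roi_mask(_roi_for_phase(rois, i), series.grid.shape)
        vals = series.velocity[i][mask]
        net[i] = vals.sum() * a_px * _RATE_ML_S_PER_CMS_MM2
        fwd[i] = vals[vals > 0].sum() * a_px * _RATE_ML_S_PER_CMS_MM2
        bwd[i] = vals[vals < 0].sum() * a_px * _RATE_ML_S_PER_CMS_MM2
    if partition is None:
        partition = int(series.metadata.get("event_indices", {}).get("end_systole", 0))
    return FlowCurve(net, fwd, bwd, series.phase_durations.copy(), partition, series.phase_times.copy())


def _resolve_range(phase_range, n: int) -> np.ndarray:
    if isinstance(phase_range, tuple) and len(phase_range) == 2:
        start, stop = phase_range
        if start == stop:
            return np.array([], dtype=int)
        if stop > start:
            return np.arange(start, stop)
        return np.concatenate([np.arange(start, n), np.arange(0, stop)])  # wraps
    return np.asarray(phase_range, dtype=int)


def integrate_interval(curve: FlowCurve, phase_range) -> tuple[float, float, float]:
    """Rectangle-rule interval volumes (net, forward, backward) in ml.

    ``phase_range`` is a half-open (start, stop) index pair — wrapping past
    the end of the cycle is allowed — or an explicit index array.
    """
    idx = _resolve_range(phase_range, curve.n_phases)
    if idx.size == 0:
        warnings.warn("empty phase range; interval volumes are zero", stacklevel=2)
        return 0.0, 0.0, 0.0
    dt_s = curve.phase_durations[idx] / 1000.0
    return (
        float(np.sum(curve.net[idx] * dt_s)),
        float(np.sum(curve.forward[idx] * dt_s)),
        float(np.sum(curve.backward[idx] * dt_s)),
    )


def _breakdown(curve: FlowCurve) -> dict:
    n = curve.n_phases
    es = curve.partition
    sys_net, sys_fwd, sys_bwd = integrate_interval(curve, (0, es))
    dia_net, dia_fwd, dia_bwd = integrate_interval(curve, (es, n))
    return {
        "systolic": {"net": sys_net, "forward": sys_fwd, "backward": sys_bwd},
        "diastolic": {"net": dia_net, "forward": dia_fwd, "backward": dia_bwd},
    }


def summarize_volumes(
    mitral: FlowCurve,
    aortic: Optional[FlowCurve] = None,
    planimetric: Optional[tuple[float, float]] = None,
    partition: Optional[int] = None,
    *,
    plane_mode: str = "following",
    mitral_uncorrected: Optional[FlowCurve] = None,
    e_peak_m_s: float = np.nan,
    a_peak_m_s: float = np.nan,
    e_over_a: float = np.nan,
) -> VolumeReport:
    """Derive the volume metrics from mitral/aortic flow and planimetry.

    Mitral SV is the diastolic forward transmitral volume (diastolic
    backward flow is assumed to reflect ventricular or atrial flow and is
    excluded); aortic SV is the whole-cycle net aortic volume.  Regurgitant
    volume is quantified three ways; the direct (systolic backward) estimate
    is refused for static imaging planes, where systolic backward flow
    cannot be distinguished from LV outflow.  ``planimetric`` is (EDV, ESV)
    in ml; when missing, the guideline regurgitant volume and planimetric
    fraction are flagged unavailable.
    """
    if partition is not None and partition != mitral.partition:
        raise ValueError("partition disagrees with the mitral curve's end-systole index")
    es, n = mitral.partition, mitral.n_phases
    notes: list[str] = []

    _, mitral_sv, _ = integrate_interval(mitral, (es, n))
    _, sys_fwd, sys_bwd = integrate_interval(mitral, (0, es))

    if aortic is not None:
        aortic_sv = integrate_interval(aortic, (0, aortic.n_phases))[0]
    else:
        aortic_sv = np.nan
        notes.append("aortic curve missing; aortic SV and derived regurgitant volumes unavailable")

    if planimetric is not None:
        edv, esv = float(planimetric[0]), float(planimetric[1])
        plan_sv = edv - esv
        rvol_guideline = plan_sv - aortic_sv
    else:
        edv = esv = plan_sv = rvol_guideline = np.nan
        notes.append("planimetric volumes missing; guideline regurgitant volume unavailable")

    if plane_mode == "static":
        rvol_direct = np.nan
        notes.append(
            "direct regurgitant volume not reported for a static imaging plane: "
            "systolic backward flow is indistinguishable from LV outflow"
        )
    else:
        rvol_direct = -sys_bwd
    rvol_mi_ao = mitral_sv - aortic_sv

    rvol_for_fraction = rvol_direct if np.isfinite(rvol_direct) else rvol_mi_ao
    rf_plan = 100.0 * rvol_for_fraction / plan_sv if np.isfinite(plan_sv) and plan_sv > 0 else np.nan
    rf_mitral = 100.0 * rvol_for_fraction / mitral_sv if mitral_sv > 0 else np.nan

    flow_volumes = {"corrected" if mitral_uncorrected is not None else "measured": _breakdown(mitral)}
    if mitral_uncorrected is not None:
        flow_volumes["uncorrected"] = _breakdown(mitral_uncorrected)

    ratio = e_over_a
    if not np.isfinite(ratio) and np.isfinite(e_peak_m_s) and np.isfinite(a_peak_m_s) and a_peak_m_s > 0:
        ratio = e_peak_m_s / a_peak_m_s
    return VolumeReport(
        mitral_sv_ml=mitral_sv,
        aortic_sv_ml=aortic_sv,
        planimetric_sv_ml=plan_sv,
        edv_ml=edv,
        esv_ml=esv,
        regurgitant_volume_guideline_ml=rvol_guideline,
        regurgitant_volume_direct_ml=rvol_direct,
        regurgitant_volume_mitral_minus_aortic_ml=rvol_mi_ao,
        regurgitant_fraction_planimetric_pct=rf_plan,
        regurgitant_fraction_mitral_pct=rf_mitral,
        e_peak_m_s=e_peak_m_s,
        a_peak_m_s=a_peak_m_s,
        e_over_a=ratio,
        flow_volumes_ml=flow_volumes,
        notes=notes,
    )


def diastolic_peaks(
    series: CinePCSeries,
    rois: RoiSeries,
    early_window: tuple[int, int],
    late_window: tuple[int, int],
    mode: str = "pixel_percentile",
) -> tuple[float, float, float]:
    """E, A and E/A from 95th-percentile peak transmitral velocities (m/s).

    Computed on the *uncorrected* series in analogy with echocardiography.
    ``mode='pixel_percentile'`` (default) takes the 95th linear-interpolation
    percentile of per-pixel ROI velocities at each phase and the maximum over
    the window; ``mode='phase_maxima'`` takes the 95th percentile of the
    per-phase maxima across the window.  When A is non-positive the ratio is
    returned as NaN rather than raising.
    """
    e0, e1 = early_window
    l0, l1 = late_window
    if e0 < l1 and l0 < e1:  # half-open interval overlap
        raise ValueError("early and late diastolic windows must be disjoint")

    def window_stat(window):
        idx = _resolve_range(window, series.n_phases)
        if idx.size == 0:
            return np.nan
        if mode == "pixel_percentile":
            v95 = [
                np.percentile(series.velocity[i][roi_mask(_roi_for_phase(rois, i), series.grid.shape)], 95)
                for i in idx
            ]
            return float(np.max(v95)) / 100.0
        if mode == "phase_maxima":
            maxima = [
                np.max(series.velocity[i][roi_mask(_roi_for_phase(rois, i), series.grid.shape)])
                for i in idx
            ]
            return float(np.percentile(maxima, 95)) / 100.0
        raise ValueError("mode must be 'pixel_percentile' or 'phase_maxima'")

    e = window_stat(early_window)
    a = window_stat(late_window)
    ratio = e / a if np.isfinite(a) and a > 0 else np.nan
    return e, a, ratio


def planimetric_volumes(stack: ShortAxisStack) -> tuple[float, float, float]:
    """Summed slice volumes (ml): EDV, ESV and SV = EDV − ESV."""
    sp_cm = stack.spacing_mm / 10.0
    vols = stack.areas_cm2.sum(axis=0) * sp_cm  # cm³ == ml
    edv = float(vols[stack.ed_index])
    esv = float(vols[stack.es_index])
    return edv, esv, edv - esv


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------


def write_flow_curve_csv(curve: FlowCurve, path) -> None:
    df = pd.DataFrame(
        {
            "phase": np.arange(curve.n_phases),
            "time_ms": curve.phase_times if curve.phase_times is not None else np.nan,
            "duration_ms": curve.phase_durations,
            "net_ml_s": curve.net,
            "forward_ml_s": curve.forward,
            "backward_ml_s": curve.backward,
        }
    )
    df.to_csv(path, index=False)


def write_rois_json(rois: dict[str, RoiSeries] | Sequence[RoiSeries], path) -> None:
    import json

    if isinstance(rois, dict):
        items = list(rois.values())
    else:
        items = list(rois)
    payload = [
        {"role": r.role, "polygons": [p.tolist() for p in r.polygons]} for r in items
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_rois_json(path) -> dict[str, RoiSeries]:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for item in payload:
        out[item["role"]] = RoiSeries(item["role"], [np.asarray(p) for p in item["polygons"]])
    return out
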