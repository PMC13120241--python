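"""Humidity/temperature correction of MOX sensor responses.

MOX sensor resistance depends on ambient temperature and relative humidity
as well as on the target gas. The dependence is summarised by the ratio
``RS/R0`` between the resistance at the current conditions and at the
reference condition (20 degC, 65 %RH). A thin-plate-spline radial-basis
surface interpolating reference ``(temp, RH, RS/R0)`` triples yields a
correction factor ``alpha(temp, RH)``, and the divider-circuit algebra gives
the corrected output voltage

    Vout_corr = VC / ((VC/Vout - 1) / alpha + 1),      VC = 5 V,

which is the identity at alpha = 1 and exactly inverts a distortion applied
through the same divider equation. The correction applies to sensors 2-5
only; no reference surface exists for sensor 1, which passes through
unchanged.

Vendor datasheets publish RS/R0 curves but not machine-readable tables, so
the shipped per-sensor reference grids are synthetic: plausible monotone
surfaces (ratio decreasing in both temperature and humidity) normalised to
1 at the reference condition. Users can override them from CSV
(``sensor, temp_c, rh_pct, rs_over_r0``). Correctness of the module is
established by round-trip recovery against a known surface, not by
datasheet fidelity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator
from scipy.spatial import QhullError, Delaunay

from .core import N_SENSORS, FeatureVector, ResponseTrace

__all__ = [
    "VC",
    "REFERENCE_CONDITION",
    "CORRECTED_SENSORS",
    "CorrectionSurface",
    "fit_surface",
    "correct_response",
    "distort_response",
    "correct_trace",
    "augment_features",
    "default_reference_grid",
    "load_reference_grid",
    "fit_sensor_surfaces",
]

VC = 5.0  # divider circuit supply voltage, volts
REFERENCE_CONDITION = (20.0, 65.0)  # degC, %RH
CORRECTED_SENSORS = (1, 2, 3, 4)  # zero-based indices of sensors 2-5


@dataclass
class CorrectionSurface:
    """Interpolated RS/R0 correction factor over (temperature, humidity)."""

    reference_points: np.ndarray  # (n, 3): temp_c, rh_pct, rs_over_r0
    reference_condition: tuple[float, float] = REFERENCE_CONDITION
    _rbf: RBFInterpolator = field(init=False, repr=False)
    _hull: Delaunay | None = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        pts = np.asarray(self.reference_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
            raise ValueError("need >= 3 reference points of (temp, rh, ratio)")
        if np.linalg.matrix_rank(pts[:, :2] - pts[0, :2]) < 2:
            raise ValueError("reference points are collinear in (temp, rh)")
        if np.any(pts[:, 2] <= 0):
            raise ValueError("RS/R0 ratios must be positive")
        self.reference_points = pts
        # exact interpolation (no smoothing): every reference point reproduced
        self._rbf = RBFInterpolator(pts[:, :2], pts[:, 2], kernel="thin_plate_spline")
        try:
            self._hull = Delaunay(pts[:, :2])
        except QhullError:  # pragma: no cover - guarded by rank check
            self._hull = None

    def alpha(self, temp_c, rh_pct) -> np.ndarray:
        """Correction factor at the query conditions (extrapolates with warning)."""
        t = np.atleast_1d(np.asarray(temp_c, dtype=float))
        h = np.atleast_1d(np.asarray(rh_pct, dtype=float))
        q = np.column_stack(np.broadcast_arrays(t, h))
        if self._hull is not None and np.any(self._hull.find_simplex(q) < 0):
            warnings.warn(
                "query outside the reference-grid convex hull; extrapolating",
                stacklevel=2,
            )
        out = self._rbf(q)
        if np.any(out <= 0):
            warnings.warn(
                "interpolated correction factor <= 0; clipping to 1e-6",
                stacklevel=2,
            )
            out = np.clip(out, 1e-6, None)
        return out if np.ndim(temp_c) or np.ndim(rh_pct) else float(out[0])

    __call__ = alpha


def fit_surface(reference_points) -> CorrectionSurface:
    """Fit an interpolating RBF surface through (temp, RH, RS/R0) triples."""
    return CorrectionSurface(reference_points=np.asarray(reference_points, float))


def correct_response(vout, vc: float = VC, alpha=1.0):
    """Map a measured output voltage back to reference conditions.

    Closed form of the resistor-divider algebra with the sensor resistance
    rescaled by ``1/alpha``; ``alpha = 1`` is the identity.
    """
    vout = np.asarray(vout, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be > 0")
    if np.any(vout <= 0) or np.any(vout >= vc):
        raise ValueError(f"vout must lie strictly inside (0, {vc}) volts")
    out = vc / ((vc / vout - 1.0) / alpha + 1.0)
    return float(out) if out.ndim == 0 else out


def distort_response(vout, vc: float = VC, alpha=1.0):
    """Inverse of :func:`correct_response`: impose an environmental distortion.

    Rescales the sensor resistance by ``alpha`` through the same divider
    equation; correcting with the same factor recovers ``vout`` exactly.
    """
    vout = np.asarray(vout, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be > 0")
    if np.any(vout <= 0) or np.any(vout >= vc):
        raise ValueError(f"vout must lie strictly inside (0, {vc}) volts")
    out = vc / ((vc / vout - 1.0) * alpha + 1.0)
    return float(out) if out.ndim == 0 else out


def correct_trace(
    trace: ResponseTrace,
    surfaces: dict[int, CorrectionSurface],
    vc: float = VC,
) -> ResponseTrace:
    """Apply the response correction to sensors 2-5 of a trace.

    ``surfaces`` maps zero-based sensor index to that sensor's correction
    surface; sensor 1 (index 0) always passes through unchanged. Requires the
    trace's co-recorded temperature and humidity channels.
    """
    if not trace.has_env:
        raise ValueError("trace has no temperature/humidity channels to correct with")
    values = trace.values.copy()
    for s in CORRECTED_SENSORS:
        if s not in surfaces:
            continue
        a = surfaces[s].alpha(trace.temp_c, trace.rh_pct)
        values[s] = correct_response(values[s], vc=vc, alpha=a)
    return ResponseTrace(
        values=values,
        time=trace.time.copy(),
        temp_c=trace.temp_c.copy(),
        rh_pct=trace.rh_pct.copy(),
        sample_id=trace.sample_id,
        timestamp=trace.timestamp,
        day=trace.day,
        batch=trace.batch,
        label=trace.label,
        pattern_id=trace.pattern_id,
    )


def augment_features(
    x: FeatureVector, temp_c: float | None, rh_pct: float | None
) -> FeatureVector | None:
    """Append ambient temperature and humidity as two named features.

    Intended to run before scaler fitting so the environment features share
    the min-max treatment. A sample with a missing reading is excluded
    (returns None) with a warning, mirroring how malfunctioning environment
    sensors are handled in acquisition.
    """
    if temp_c is None or rh_pct is None or not np.isfinite([temp_c, rh_pct]).all():
        warnings.warn(
            f"sample {x.sample_id!r} lacks env readings; excluded from augmentation",
            stacklevel=2,
        )
        return None
    return FeatureVector(
        values=np.concatenate([x.values, [float(temp_c), float(rh_pct)]]),
        names=list(x.names) + ["env_temp_c", "env_rh_pct"],
        sample_id=x.sample_id,
    )


# ---------------------------------------------------------------------------
# Reference grids


def default_reference_grid(
    temps=(0.0, 10.0, 20.0, 30.0, 40.0),
    rhs=(25.0, 45.0, 65.0, 85.0),
    slope_scale: float = 1.0,
) -> dict[int, np.ndarray]:
    """Synthetic per-sensor RS/R0 reference grids for sensors 2-5.

    Each grid is monotone decreasing in temperature and humidity (warmer and
    wetter air lowers MOX resistance) with per-sensor slopes, and equals 1 at
    the (20 degC, 65 %RH) reference condition by construction.
    ``slope_scale`` multiplies the sensitivity slopes, for studying regimes
    with stronger environmental dependence.
    """
    slopes = {1: (0.5, 0.30), 2: (0.6, 0.40), 3: (0.4, 0.35), 4: (0.55, 0.25)}
    grids: dict[int, np.ndarray] = {}
    t0, h0 = REFERENCE_CONDITION
    for s, (kt, kh) in slopes.items():
        rows = []
        for t in temps:
            for h in rhs:
                ratio = np.exp(
                    slope_scale * (-kt * (t - t0) / 40.0 - kh * (h - h0) / 60.0)
                )
                rows.append((t, h, ratio))
        grids[s] = np.array(rows)
    return grids


def load_reference_grid(path: str | Path) -> dict[int, np.ndarray]:
    """Read per-sensor reference grids from CSV.

    Expected columns: ``sensor`` (1-based), ``temp_c``, ``rh_pct``,
    ``rs_over_r0``.
    """
    df = pd.read_csv(path)
    required = {"sensor", "temp_c", "rh_pct", "rs_over_r0"}
    if not required.issubset(df.columns):
        raise ValueError(f"reference grid CSV needs columns {sorted(required)}")
    grids: dict[int, np.ndarray] = {}
    for sensor, grp in df.groupby("sensor"):
        idx = int(sensor) - 1
        if not 0 <= idx < N_SENSORS:
            raise ValueError(f"sensor column out of range: {sensor}")
        grids[idx] = grp[["temp_c", "rh_pct", "rs_over_r0"]].to_numpy(float)
    return grids


def fit_sensor_surfaces(
    grids: dict[int, np.ndarray] | None = None,
) -> dict[int, CorrectionSurface]:
    """Fit a correction surface per sensor from reference grids."""
    if grids is None:
        grids = default_reference_grid()
    return {s: fit_surface(g) for s, g in grids.items()}
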