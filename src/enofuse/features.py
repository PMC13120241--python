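"""Feature extraction from modulation segments and continuous windows.

Two fixed feature sets are defined for modulated acquisitions:

* **large** (85 values): per-sensor maximum and range of the 7 V segment,
  plus the maximum of the EWMA-smoothed signal at alpha in
  {0.1, 0.01, 0.001} for every sensor at every modulation level
  (2*5 + 3*5*5 = 85).
* **small** (10 values): the 7 V maximum and range only.

Continuous acquisitions instead get 25 windowed time-domain statistics
(mean, population sd, max, min, RMS per sensor).

The EWMA at position m is the normalised weighted sum
``sum_i (1-a)^(m-i) x_i / sum_i (1-a)^(m-i)`` over ``i <= m``; it is computed
with the O(M) recursion that carries the weighted numerator and denominator,
which is algebraically identical to the explicit sum.

Scaling is per-feature min-max with the extrema learned on training data
only; test values falling outside the training range are deliberately not
clipped, since distribution shift between acquisition batches is exactly
what the downstream analysis studies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import FeatureVector
from .signal_processing import ModulationSegments

__all__ = [
    "EWMA_ALPHAS",
    "max_response",
    "diff_response",
    "ewma_smooth",
    "ewma_max",
    "build_feature_vector",
    "cont_features",
    "FeatureScaler",
]

EWMA_ALPHAS: tuple[float, ...] = (0.1, 0.01, 0.001)
LEVEL_7V = 7.0


def max_response(segment_7v: np.ndarray) -> np.ndarray:
    """Per-sensor maximum response over the segment."""
    seg = np.atleast_2d(np.asarray(segment_7v, dtype=float))
    if seg.shape[-1] == 0:
        raise ValueError("empty segment")
    return seg.max(axis=-1)


def diff_response(segment_7v: np.ndarray) -> np.ndarray:
    """Per-sensor response range (max minus min) over the segment."""
    seg = np.atleast_2d(np.asarray(segment_7v, dtype=float))
    if seg.shape[-1] == 0:
        raise ValueError("empty segment")
    return seg.max(axis=-1) - seg.min(axis=-1)


def ewma_smooth(segment: np.ndarray, alpha: float) -> np.ndarray:
    """Normalised exponentially weighted moving average along time.

    Recursive form: numerator ``n_m = (1-a) n_{m-1} + x_m`` and denominator
    ``d_m = (1-a) d_{m-1} + 1``, with the smoothed value ``n_m / d_m``.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    decay = 1.0 - alpha
    out = np.empty_like(seg)
    num = np.zeros(seg.shape[0])
    den = 0.0
    for m in range(seg.shape[-1]):
        num = decay * num + seg[:, m]
        den = decay * den + 1.0
        out[:, m] = num / den
    return out


def ewma_max(segment: np.ndarray, alpha: float) -> np.ndarray:
    """Per-sensor maximum of the EWMA-smoothed segment."""
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    if seg.shape[-1] == 0:
        raise ValueError("empty segment")
    return ewma_smooth(seg, alpha).max(axis=-1)


def _level_tag(v: float) -> str:
    return f"{v:g}V"


def build_feature_vector(
    segments: ModulationSegments, feature_set: str = "large"
) -> FeatureVector:
    """Assemble the ordered large (85) or small (10) feature vector.

    Order: all 7 V maxima by sensor, all 7 V ranges by sensor, then EWMA
    maxima level-major (in pattern order), sensor, alpha.
    """
    if feature_set not in ("large", "small"):
        raise ValueError(f"feature_set must be 'large' or 'small', got {feature_set!r}")
    if LEVEL_7V not in segments.segments:
        raise KeyError("missing 7 V modulation segment")
    seg7 = segments[LEVEL_7V]
    n_sensors = seg7.shape[0]

    values: list[float] = []
    names: list[str] = []
    m7 = max_response(seg7)
    d7 = diff_response(seg7)
    values.extend(m7)
    names.extend(f"m7V_s{s + 1}" for s in range(n_sensors))
    values.extend(d7)
    names.extend(f"d7V_s{s + 1}" for s in range(n_sensors))

    if feature_set == "large":
        for v in segments.levels:
            seg = segments[v]
            smoothed = {a: ewma_max(seg, a) for a in EWMA_ALPHAS}
            for s in range(n_sensors):
                for a in EWMA_ALPHAS:
                    values.append(smoothed[a][s])
                    names.append(f"ewma_{_level_tag(v)}_s{s + 1}_a{a:g}")

    return FeatureVector(
        values=np.array(values), names=names, sample_id=segments.sample_id
    )


CONT_STATS = ("mean", "sd", "max", "min", "rms")


def cont_features(window: np.ndarray, sample_id: str = "") -> FeatureVector:
    """Windowed time-domain statistics for continuous acquisition.

    Per sensor: mean, population standard deviation, maximum, minimum and
    root mean square — 25 values for a 5-sensor window.
    """
    win = np.atleast_2d(np.asarray(window, dtype=float))
    if win.shape[-1] == 0:
        raise ValueError("empty window")
    stats = {
        "mean": win.mean(axis=-1),
        "sd": win.std(axis=-1),  # population sd (ddof=0)
        "max": win.max(axis=-1),
        "min": win.min(axis=-1),
        "rms": np.sqrt(np.mean(win**2, axis=-1)),
    }
    values: list[float] = []
    names: list[str] = []
    for s in range(win.shape[0]):
        for k in CONT_STATS:
            values.append(stats[k][s])
            names.append(f"cont_{k}_s{s + 1}")
    return FeatureVector(values=np.array(values), names=names, sample_id=sample_id)


@dataclass
class FeatureScaler:
    """Per-feature min-max scaler fitted on training data only.

    Test-fold values may land outside [0, 1]; they are not clipped.
    Zero-range features map to 0 with a warning.
    """

    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None
    names: list[str] | None = None

    @property
    def fitted(self) -> bool:
        return self.mins is not None

    def fit(self, train: Sequence[FeatureVector] | np.ndarray) -> "FeatureScaler":
        X, names = _as_matrix(train)
        if X.shape[0] == 0:
            raise ValueError("cannot fit scaler on an empty training set")
        self.mins = X.min(axis=0)
        self.maxs = X.max(axis=0)
        self.names = names
        if np.any(self.maxs == self.mins):
            flat = (
                [names[i] for i in np.flatnonzero(self.maxs == self.mins)]
                if names
                else list(np.flatnonzero(self.maxs == self.mins))
            )
            warnings.warn(
                f"zero-range features map to 0 under scaling: {flat}", stacklevel=2
            )
        return self

    def transform(self, x: FeatureVector | np.ndarray):
        if not self.fitted:
            raise RuntimeError("scaler must be fitted before transform")
        single = isinstance(x, FeatureVector)
        X, _ = _as_matrix([x] if single else x)
        rng = self.maxs - self.mins
        out = np.zeros_like(X)
        np.divide(X - self.mins, rng, out=out, where=rng > 0)
        if single:
            return FeatureVector(out[0], list(x.names), sample_id=x.sample_id)
        return out

    def fit_transform(self, train):
        return self.fit(train).transform(train)

    def to_json(self, path: str | Path) -> None:
        if not self.fitted:
            raise RuntimeError("nothing to serialise: scaler not fitted")
        payload = {
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "names": self.names,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureScaler":
        payload = json.loads(Path(path).read_text())
        return cls(
            mins=np.array(payload["mins"]),
            maxs=np.array(payload["maxs"]),
            names=payload["names"],
        )


def _as_matrix(data) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(data, np.ndarray):
        return np.atleast_2d(np.asarray(data, dtype=float)), None
    vecs = list(data)
    if vecs and isinstance(vecs[0], FeatureVector):
        return np.vstack([v.values for v in vecs]), list(vecs[0].names)
    return np.atleast_2d(np.asarray(vecs, dtype=float)), None
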