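"""Segmentation and conditioning of raw modulated sensor traces.

A modulated trace is split into the five active-level segments by cumulative
stage timing (preheat and 0 V rests discarded), after which the usual
conditioning steps apply: baseline subtraction against the mean of the first
five samples, per-sensor min-max scaling, and linear-interpolation
downsampling to a fixed length for sequence models. Continuous (constant
heater) acquisitions are instead cut into fixed-duration non-overlapping
windows.

The canonical order for sequence-model input is split -> downsample ->
baseline-subtract -> min-max; the steps do not commute.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import ResponseTrace
from .patterns import ModulationPattern

logger = logging.getLogger(__name__)

__all__ = [
    "ModulationSegments",
    "SegmentationError",
    "split_modulation_levels",
    "subtract_baseline",
    "scale_segment",
    "downsample_segment",
    "window_continuous",
    "prepare_sequence_input",
]

BASELINE_SAMPLES = 5


class SegmentationError(ValueError):
    """Trace too short (or otherwise inconsistent) for the pattern timing."""


@dataclass
class ModulationSegments:
    """Per-active-level response matrices, keyed by heater voltage.

    ``segments[v]`` is the sensors x time slice of the trace recorded while
    the heater was held at ``v`` volts, in pattern order.
    """

    segments: dict[float, np.ndarray]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.segments) != 5:
            raise ValueError("expected exactly 5 modulation-level segments")
        for v, seg in self.segments.items():
            if seg.ndim != 2 or seg.shape[1] == 0:
                raise ValueError(f"segment at {v} V is empty or malformed")

    @property
    def levels(self) -> list[float]:
        return list(self.segments)

    def __getitem__(self, level: float) -> np.ndarray:
        return self.segments[level]


def split_modulation_levels(
    trace: ResponseTrace, pattern: ModulationPattern
) -> ModulationSegments:
    """Extract the five active-level segments from a modulated trace.

    Segment spans come from cumulative stage timing at the pattern's sampling
    rate, using nominal stage durations; the tail extension of the final
    stage and all 0 V rests are excluded.
    """
    spans = pattern.active_spans()
    needed = max(stop for _, stop in spans.values())
    if trace.n_points < needed:
        raise SegmentationError(
            f"trace has {trace.n_points} samples but pattern "
            f"{pattern.pattern_id} needs {needed} "
            f"({needed - trace.n_points} short)"
        )
    segs = {v: trace.values[:, start:stop] for v, (start, stop) in spans.items()}
    return ModulationSegments(segments=segs, sample_id=trace.sample_id)


def subtract_baseline(segment: np.ndarray) -> np.ndarray:
    """Subtract each sensor's baseline, the mean of its first five samples."""
    segment = np.asarray(segment, dtype=float)
    if segment.shape[-1] < BASELINE_SAMPLES:
        raise ValueError(
            f"need at least {BASELINE_SAMPLES} samples for baseline estimation"
        )
    baseline = segment[..., :BASELINE_SAMPLES].mean(axis=-1, keepdims=True)
    return segment - baseline


def scale_segment(segment: np.ndarray) -> np.ndarray:
    """Per-sensor min-max scale a segment into [0, 1].

    Zero-range (constant) sensors map to all-zeros rather than NaN so that
    degenerate channels remain usable downstream.
    """
    segment = np.asarray(segment, dtype=float)
    lo = segment.min(axis=-1, keepdims=True)
    hi = segment.max(axis=-1, keepdims=True)
    rng = hi - lo
    out = np.zeros_like(segment)
    np.divide(segment - lo, rng, out=out, where=rng > 0)
    return out


def downsample_segment(segment: np.ndarray, target_len: int) -> np.ndarray:
    """Resample each sensor onto ``target_len`` equally spaced points.

    Linear interpolation over the segment's own index axis; endpoints are
    preserved exactly. ``target_len`` greater than the segment length is
    permitted (upsampling) but logged.
    """
    segment = np.asarray(segment, dtype=float)
    m = segment.shape[-1]
    if m < 2 or target_len < 2:
        raise ValueError("need segment length >= 2 and target_len >= 2")
    if target_len > m:
        logger.warning("upsampling segment from %d to %d points", m, target_len)
    if target_len == m:
        return segment.copy()
    x_old = np.linspace(0.0, 1.0, m)
    x_new = np.linspace(0.0, 1.0, target_len)
    flat = segment.reshape(-1, m)
    out = np.vstack([np.interp(x_new, x_old, row) for row in flat])
    return out.reshape(segment.shape[:-1] + (target_len,))


def window_continuous(trace: ResponseTrace, window_s: float) -> list[np.ndarray]:
    """Cut a continuous acquisition into non-overlapping fixed-length windows.

    Window length is ``floor(window_s * rate)`` samples inferred from the
    trace's time axis; the trailing partial window is dropped. A trace
    shorter than one window yields an empty list with a warning.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    if trace.n_points > 1:
        rate = 1.0 / float(np.median(np.diff(trace.time)))
    else:
        rate = 1.0
    # epsilon guards the floor against rate round-off from the time axis
    w = int(np.floor(window_s * rate + 1e-6))
    if w < 1 or trace.n_points < w:
        warnings.warn(
            f"trace shorter than one {window_s:g} s window; no windows produced",
            stacklevel=2,
        )
        return []
    n = trace.n_points // w
    return [trace.values[:, i * w : (i + 1) * w] for i in range(n)]


def prepare_sequence_input(
    trace: ResponseTrace, pattern: ModulationPattern, target_len: int
) -> dict[float, np.ndarray]:
    """Fixed-order conditioning for sequence models.

    Applies split -> downsample -> baseline-subtract -> min-max per level.
    """
    segs = split_modulation_levels(trace, pattern)
    return {
        v: scale_segment(subtract_baseline(downsample_segment(seg, target_len)))
        for v, seg in segs.segments.items()
    }
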