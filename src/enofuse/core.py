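"""Shared domain types: response traces, feature vectors, detections, predictions.

These are the in-memory currency of the pipeline. Text serialisation follows
the shipped interchange formats: one CSV per trace
(``t_s, s1_v..s5_v, temp_c, rh_pct``), a metadata CSV, JSON-lines detections
and a shared prediction CSV schema used by both modalities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_SENSORS = 5

__all__ = [
    "N_SENSORS",
    "ResponseTrace",
    "FeatureVector",
    "Detection",
    "Prediction",
    "read_detections_jsonl",
    "write_detections_jsonl",
    "predictions_to_frame",
    "frame_to_predictions",
]


@dataclass
class ResponseTrace:
    """Raw multichannel sensor acquisition with optional environment channels.

    ``values`` is the 5 x T matrix of divider output voltages (Vout); ``time``
    is seconds from acquisition start. ``temp_c`` / ``rh_pct`` are the
    co-recorded ambient temperature and relative humidity, when available.
    """

    values: np.ndarray  # shape (5, T), volts
    time: np.ndarray  # shape (T,), seconds
    temp_c: np.ndarray | None = None
    rh_pct: np.ndarray | None = None
    sample_id: str = ""
    timestamp: float = 0.0  # hours since study start
    day: int = 0
    batch: int = 0
    label: str = ""
    pattern_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != N_SENSORS:
            raise ValueError(
                f"values must be ({N_SENSORS}, T); got {self.values.shape}"
            )
        if self.values.shape[1] != self.time.shape[0]:
            raise ValueError("time axis mismatch between values and time")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    @property
    def has_env(self) -> bool:
        return self.temp_c is not None and self.rh_pct is not None

    def to_frame(self) -> pd.DataFrame:
        cols = {"t_s": self.time}
        for s in range(N_SENSORS):
            cols[f"s{s + 1}_v"] = self.values[s]
        if self.has_env:
            cols["temp_c"] = self.temp_c
            cols["rh_pct"] = self.rh_pct
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **meta) -> "ResponseTrace":
        df = pd.read_csv(path)
        values = np.vstack([df[f"s{s + 1}_v"].to_numpy() for s in range(N_SENSORS)])
        return cls(
            values=values,
            time=df["t_s"].to_numpy(),
            temp_c=df["temp_c"].to_numpy() if "temp_c" in df else None,
            rh_pct=df["rh_pct"].to_numpy() if "rh_pct" in df else None,
            **meta,
        )


@dataclass
class FeatureVector:
    """Ordered, named feature values for one sample."""

    values: np.ndarray
    names: list[str]
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.values)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.sample_id)


def feature_table(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a samples x features table."""
    if not vectors:
        return pd.DataFrame()
    names = vectors[0].names
    for v in vectors[1:]:
        if v.names != names:
            raise ValueError("inconsistent feature names across samples")
    return pd.DataFrame(
        np.vstack([v.values for v in vectors]),
        columns=names,
        index=[v.sample_id for v in vectors],
    )


@dataclass(frozen=True)
class Detection:
    """One detector output: a pixel bounding box with class and confidence.

    Coordinates use an image origin at the top-left, with ``x1 < x2`` and
    ``y1 < y2``.
    """

    x1: float
    y1: float
    x2: float
    y2: float
    cls: str
    conf: float

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError("degenerate box: require x1 < x2 and y1 < y2")
        if not (0.0 <= self.conf <= 1.0):
            raise ValueError("conf must be in [0, 1]")

    @property
    def box(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)


@dataclass(frozen=True)
class Prediction:
    """A classifier decision for one sample from one modality.

    ``available`` is False when the modality produced no usable input for the
    sample (e.g. a night image); in that case ``label``/``confidence`` are
    placeholders and must not enter accuracy computed over available samples.
    """

    sample_id: str
    label: str
    confidence: float
    modality: str  # "odour" | "image" | "fused"
    available: bool = True

    def __post_init__(self) -> None:
        if self.available and not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must be in [0, 1] when available")


def write_detections_jsonl(
    path: str | Path, per_sample: dict[str, list[Detection] | None]
) -> None:
    """Write per-sample detections as JSON-lines.

    Samples with no image (``None``) are written with ``boxes: null`` so that
    missing-image and zero-detection cases stay distinguishable on disk.
    """
    with open(path, "w") as fh:
        for sample_id, dets in per_sample.items():
            boxes = (
                None
                if dets is None
                else [
                    {
                        "x1": d.x1,
                        "y1": d.y1,
                        "x2": d.x2,
                        "y2": d.y2,
                        "cls": d.cls,
                        "conf": d.conf,
                    }
                    for d in dets
                ]
            )
            fh.write(json.dumps({"sample_id": sample_id, "boxes": boxes}) + "\n")


def read_detections_jsonl(path: str | Path) -> dict[str, list[Detection] | None]:
    out: dict[str, list[Detection] | None] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            boxes = rec["boxes"]
            out[rec["sample_id"]] = (
                None if boxes is None else [Detection(**b) for b in boxes]
            )
    return out


def predictions_to_frame(preds: Iterable[Prediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "label_pred": p.label,
                "confidence": p.confidence,
                "modality": p.modality,
                "available": p.available,
            }
            for p in preds
        ]
    )


def frame_to_predictions(df: pd.DataFrame) -> list[Prediction]:
    return [
        Prediction(
            sample_id=str(r.sample_id),
            label=str(r.label_pred),
            confidence=float(r.confidence),
            modality=str(r.modality),
            available=bool(r.available),
        )
        for r in df.itertuples(index=False)
    ]
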