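"""Synthetic odour/image dataset generator.

Emulates an open-air fruit-ripeness monitoring campaign: temperature-
modulated MOX sensor traces whose response amplitude depends on the ripeness
class, ambient temperature/humidity daily cycles that distort the responses
through a known RS/R0 surface, slow inter-batch sensor drift, a per-day
environmental effect shared by all samples of a day (the source of temporal
label correlation), and an image side represented purely by detector
outputs: per-fruit bounding boxes whose detection probability and confidence
depend on the lighting category, with night samples having no image at all.

Response kinetics are first-order: within each heater stage the deviation
from baseline relaxes exponentially toward an amplitude target specific to
the (class, sensor, heater-voltage) triple, with separate rise and decay
time constants — the standard approximation for MOX transients under
heater modulation.

All randomness flows from ``SimConfig.seed`` (dataset layout, per-sample
streams, and day-keyed streams for effects shared within a day), so an
identical config reproduces an identical dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import Detection, ResponseTrace, write_detections_jsonl
from .env_correction import (
    VC,
    CorrectionSurface,
    default_reference_grid,
    distort_response,
    fit_sensor_surfaces,
)
from .patterns import ModulationPattern, get_pattern

__all__ = [
    "EnvModel",
    "DetectQuality",
    "SimConfig",
    "SimulatedDataset",
    "simulate_trace",
    "simulate_detections",
    "simulate_dataset",
    "simulate_prediction_frame",
]

LIGHTINGS = ("well_lit", "backlit", "artificial", "night")


class EnvModel(BaseModel):
    """Daily sinusoidal temperature / humidity cycles.

    Temperature peaks mid-afternoon; humidity moves in antiphase. Each day
    gets a phase jitter drawn from a day-keyed stream so environment is
    correlated within a day but varies between days.
    """

    temp_mean_c: float = 18.0
    temp_amp_c: float = 6.0
    rh_mean_pct: float = 65.0
    rh_amp_pct: float = 15.0
    period_h: float = 24.0
    peak_hour: float = 15.0
    phase_jitter_h: float = 1.5


class DetectQuality(BaseModel):
    """Per-lighting detector behaviour on the image side."""

    p_detect: dict[str, float]  # per true fruit class
    conf_mean: dict[str, float]
    conf_sd: float = 0.08
    p_misclass: float = 0.03


def _default_detect_quality() -> dict[str, "DetectQuality"]:
    return {
        "well_lit": DetectQuality(
            p_detect={"ripe": 0.92, "unripe": 0.88, "overripe": 0.90},
            conf_mean={"ripe": 0.78, "unripe": 0.85, "overripe": 0.80},
            conf_sd=0.07,
            p_misclass=0.03,
        ),
        "backlit": DetectQuality(
            p_detect={"ripe": 0.40, "unripe": 0.62, "overripe": 0.45},
            conf_mean={"ripe": 0.55, "unripe": 0.70, "overripe": 0.58},
            conf_sd=0.10,
            p_misclass=0.12,
        ),
        "artificial": DetectQuality(
            p_detect={"ripe": 0.85, "unripe": 0.82, "overripe": 0.84},
            conf_mean={"ripe": 0.80, "unripe": 0.82, "overripe": 0.80},
            conf_sd=0.07,
            p_misclass=0.04,
        ),
    }


class SimConfig(BaseModel):
    """Full parameterisation of one simulated acquisition campaign."""

    model_config = ConfigDict(validate_assignment=True)

    classes: tuple[str, str] = ("ripe", "unripe")
    n_samples_per_class: int = Field(default=60, ge=1)
    pattern_id: Literal["DAQ10", "DAQ48", "DAQcont"] = "DAQ10"
    sampling_rate: float = Field(default=10.0, gt=0)
    n_days: int = Field(default=25, ge=1)

    baselines_v: tuple[float, ...] = (0.8, 0.9, 1.0, 1.1, 1.2)
    class_amplitudes: dict[str, tuple[float, ...]] = {
        "ripe": (1.15, 1.0, 1.35, 1.2, 1.3),
        "unripe": (1.0, 0.85, 1.15, 1.0, 1.1),
        "overripe": (1.3, 1.15, 1.55, 1.35, 1.45),
    }
    rise_tau_s: float = Field(default=8.0, gt=0)
    decay_tau_s: float = Field(default=15.0, gt=0)
    noise_sd_v: float = Field(default=0.02, ge=0)

    drift_rate: float = 0.002  # fractional baseline shift per day
    drift_onset_day: int = 12  # batch boundary / step-drift onset
    drift_mode: Literal["linear", "step"] = "linear"
    day_effect_sd: float = Field(default=0.12, ge=0)

    # 0: labels independent of time; 1: first class entirely late-campaign.
    # Ripening is gradual, so labels track calendar time with overlap; this
    # temporal label clustering is what makes shuffled k-fold optimistic
    # relative to leave-day-out splitting.
    label_time_correlation: float = Field(default=0.6, ge=0, le=1)

    env_model: EnvModel = EnvModel()
    distort_with_surface: bool = True
    true_alpha_grids: Optional[dict[int, list[tuple[float, float, float]]]] = None

    night_fraction: float = Field(default=0.5, ge=0, le=1)
    lighting_probs: Optional[dict[str, float]] = None
    detect_quality: dict[str, DetectQuality] = Field(
        default_factory=_default_detect_quality
    )
    n_fruits_mean: float = Field(default=2.0, ge=0)
    image_size: tuple[int, int] = (640, 480)
    cont_duration_s: float = Field(default=3600.0, gt=0)

    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "SimConfig":
        for cls in self.classes:
            if cls not in self.class_amplitudes:
                raise ValueError(f"class_amplitudes missing class {cls!r}")
            if len(self.class_amplitudes[cls]) != len(self.baselines_v):
                raise ValueError("class_amplitudes must give one value per sensor")
        if self.lighting_probs is None:
            day_split = {"well_lit": 0.5, "backlit": 0.3, "artificial": 0.2}
            object.__setattr__(
                self,
                "lighting_probs",
                {
                    **{
                        k: v * (1.0 - self.night_fraction)
                        for k, v in day_split.items()
                    },
                    "night": self.night_fraction,
                },
            )
        probs = self.lighting_probs
        if set(probs) != set(LIGHTINGS):
            raise ValueError(f"lighting_probs must cover {LIGHTINGS}")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("lighting probabilities must sum to 1")
        if abs(probs["night"] - self.night_fraction) > 1e-9:
            raise ValueError("lighting_probs['night'] must equal night_fraction")
        ripe_like = self.classes[0]
        dq = self.detect_quality
        if "well_lit" in dq and "backlit" in dq and ripe_like in dq["well_lit"].p_detect:
            if not (
                dq["backlit"].p_detect[ripe_like] <= dq["well_lit"].p_detect[ripe_like]
                and dq["backlit"].conf_mean[ripe_like]
                <= dq["well_lit"].conf_mean[ripe_like]
            ):
                raise ValueError(
                    "backlit detection quality for the ripe-like class must not "
                    "exceed well-lit quality"
                )
        return self

    def pattern(self) -> ModulationPattern:
        p = get_pattern(self.pattern_id)
        if self.pattern_id == "DAQcont":
            n = int(round(self.cont_duration_s * self.sampling_rate))
            p = replace(
                p,
                stages=((5.0, self.cont_duration_s),),
                nominal_points=n,
                sampling_rate=self.sampling_rate,
            )
        elif self.sampling_rate != p.sampling_rate:
            raise ValueError(
                f"{self.pattern_id} is defined at {p.sampling_rate} Hz"
            )
        return p

    def true_surfaces(self) -> dict[int, CorrectionSurface]:
        grids = (
            {s: np.asarray(g, float) for s, g in self.true_alpha_grids.items()}
            if self.true_alpha_grids is not None
            else default_reference_grid()
        )
        return fit_sensor_surfaces(grids)


# ---------------------------------------------------------------------------
# Day-keyed streams: effects shared by every sample of a given day


def _day_rng(config_seed: int, day: int) -> np.random.Generator:
    return np.random.default_rng([config_seed & 0x7FFFFFFF, 7919, int(day)])


def _day_effect(config: SimConfig, day: int) -> float:
    """Multiplicative amplitude effect common to all samples of one day."""
    if config.day_effect_sd == 0:
        return 1.0
    z = _day_rng(config.seed, day).standard_normal()
    return float(max(0.2, 1.0 + config.day_effect_sd * z))


def _day_phase(config: SimConfig, day: int) -> float:
    if config.env_model.phase_jitter_h == 0:
        return 0.0
    # independent draw stream from the day effect
    return float(
        _day_rng(config.seed, day).normal(size=2)[1] * config.env_model.phase_jitter_h
    )


def _env_trajectory(
    config: SimConfig, day: int, hour: float, t_s: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    em = config.env_model
    phase = _day_phase(config, day)
    h = hour + t_s / 3600.0
    cyc = np.cos(2.0 * np.pi * (h - em.peak_hour - phase) / em.period_h)
    temp = em.temp_mean_c + em.temp_amp_c * cyc
    rh = em.rh_mean_pct - em.rh_amp_pct * cyc
    # keep within the reference-grid hull so correction never extrapolates
    return np.clip(temp, 1.0, 39.0), np.clip(rh, 26.0, 84.0)


def _drift_factor(config: SimConfig, day: int) -> float:
    if config.drift_mode == "linear":
        return 1.0 + config.drift_rate * day
    return 1.0 + (
        config.drift_rate * config.drift_onset_day
        if day >= config.drift_onset_day
        else 0.0
    )


def _level_gain(vh: float) -> float:
    """Relative plateau amplitude at heater voltage ``vh`` (1 at 7 V).

    Quadratic in voltage: heater power, hence operating temperature and
    response magnitude, scales roughly with VH^2.
    """
    return (vh / 7.0) ** 2 if vh > 0 else 0.0


def _kinetic_deviation(
    pattern: ModulationPattern,
    amps: np.ndarray,
    rise_tau: float,
    decay_tau: float,
    n_points: int,
) -> np.ndarray:
    """First-order response deviation from baseline over the acquisition.

    Piecewise-exponential relaxation toward each stage's plateau target,
    continuous across stage boundaries; rise and decay use separate taus.
    """
    rate = pattern.sampling_rate
    stages = [pattern.preheat, *pattern.stages]
    if pattern.tail_pad_s > 1e-9 and pattern.stages:
        stages.append((pattern.stages[-1][0], pattern.tail_pad_s))
    n_sensors = amps.shape[0]
    out = np.zeros((n_sensors, n_points))
    x0 = np.zeros(n_sensors)
    t_start = 0.0
    for vh, dur in stages:
        if dur <= 0:
            continue
        target = amps * _level_gain(vh)
        tau = np.where(target > x0, rise_tau, decay_tau)
        i0 = round(t_start * rate)
        i1 = min(round((t_start + dur) * rate), n_points)
        if i1 > i0:
            dt = np.arange(i0, i1) / rate - t_start
            out[:, i0:i1] = target[:, None] + (x0 - target)[:, None] * np.exp(
                -dt[None, :] / tau[:, None]
            )
        x0 = target + (x0 - target) * np.exp(-dur / tau)
        t_start += dur
    return out


def simulate_trace(
    config: SimConfig,
    label: str,
    day: int,
    seed: int,
    hour: float | None = None,
    sample_id: str = "",
    surfaces: dict[int, CorrectionSurface] | None = None,
) -> ResponseTrace:
    """Simulate one acquisition for a sample of the given class and day.

    The clean signal is ``baseline * drift(day) + amplitude * kinetics``; the
    environment then distorts sensors 2-5 through the true RS/R0 surface at
    the instantaneous (temperature, humidity), and Gaussian read noise is
    added last. Deterministic given (config, label, day, seed, hour).
    """
    if label not in config.class_amplitudes:
        raise KeyError(f"no amplitudes configured for label {label!r}")
    rng = np.random.default_rng(seed)
    if hour is None:
        hour = float(rng.uniform(0.0, 24.0))
    pattern = config.pattern()
    n = pattern.nominal_points
    t_s = np.arange(n) / pattern.sampling_rate

    temp, rh = _env_trajectory(config, day, hour, t_s)
    amps = np.asarray(config.class_amplitudes[label], float) * _day_effect(config, day)
    dev = _kinetic_deviation(
        pattern, amps, config.rise_tau_s, config.decay_tau_s, n
    )
    baselines = np.asarray(config.baselines_v, float)[:, None]
    values = baselines * _drift_factor(config, day) + dev

    if config.distort_with_surface:
        if surfaces is None:
            surfaces = config.true_surfaces()
        for s, surf in surfaces.items():
            alpha = surf.alpha(temp, rh)
            values[s] = distort_response(values[s], vc=VC, alpha=alpha)

    if config.noise_sd_v > 0:
        values = values + rng.normal(0.0, config.noise_sd_v, size=values.shape)

    return ResponseTrace(
        values=values,
        time=t_s,
        temp_c=temp,
        rh_pct=rh,
        sample_id=sample_id,
        timestamp=day * 24.0 + hour,
        day=int(day),
        batch=0 if day < config.drift_onset_day else 1,
        label=label,
        pattern_id=pattern.pattern_id,
    )


def _random_box(rng: np.random.Generator, size: tuple[int, int]) -> tuple:
    w_img, h_img = size
    w = float(rng.uniform(30, min(140, w_img - 2)))
    h = float(rng.uniform(30, min(140, h_img - 2)))
    x1 = float(rng.uniform(0, w_img - w))
    y1 = float(rng.uniform(0, h_img - h))
    return x1, y1, x1 + w, y1 + h


def simulate_detections(
    config: SimConfig, label: str, lighting: str, seed: int
) -> list[Detection] | None:
    """Simulate the detector output for one sample's image.

    Night returns None (no usable image). Otherwise the scene holds one fruit
    of the sample's class plus a Poisson number of fruits of the other class;
    each fruit is detected independently with the lighting- and class-
    dependent probability, receives a confidence from the lighting/class
    distribution (clipped to [0.05, 0.99]) and is occasionally reported with
    the wrong class.
    """
    if lighting == "night":
        return None
    if lighting not in config.detect_quality:
        raise KeyError(f"no detect_quality configured for lighting {lighting!r}")
    rng = np.random.default_rng(seed)
    dq = config.detect_quality[lighting]
    other = config.classes[1] if label == config.classes[0] else config.classes[0]
    fruits = [label] + [other] * int(rng.poisson(config.n_fruits_mean))
    dets: list[Detection] = []
    for cls in fruits:
        if rng.uniform() >= dq.p_detect.get(cls, 0.5):
            continue
        conf = float(np.clip(rng.normal(dq.conf_mean.get(cls, 0.6), dq.conf_sd), 0.05, 0.99))
        reported = cls
        if rng.uniform() < dq.p_misclass:
            reported = other if cls == label else label
        x1, y1, x2, y2 = _random_box(rng, config.image_size)
        dets.append(Detection(x1=x1, y1=y1, x2=x2, y2=y2, cls=reported, conf=conf))
    return dets


@dataclass
class SimulatedDataset:
    """One simulated campaign: traces, image-side detections and ground truth."""

    config: SimConfig
    traces: list[ResponseTrace]
    detections: list[list[Detection] | None]
    image_available: np.ndarray  # bool per sample
    labels: list[str]
    day_index: np.ndarray
    batch_id: np.ndarray
    lighting: list[str]

    def __post_init__(self) -> None:
        n = len(self.traces)
        if not (
            len(self.detections) == len(self.labels) == len(self.lighting) == n
            and len(self.image_available) == len(self.day_index) == n
        ):
            raise ValueError("per-sample arrays must have equal length")
        for avail, det in zip(self.image_available, self.detections):
            if not avail and det is not None:
                raise ValueError("night samples must have no detections")

    @property
    def n_samples(self) -> int:
        return len(self.traces)

    @property
    def sample_ids(self) -> list[str]:
        return [t.sample_id for t in self.traces]

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "timestamp": [t.timestamp for t in self.traces],
                "day": self.day_index,
                "batch": self.batch_id,
                "label": self.labels,
                "lighting": self.lighting,
                "image_available": self.image_available,
            }
        )

    def write(self, out_dir: str | Path) -> None:
        """Write traces, metadata and detections in the text interchange formats."""
        out = Path(out_dir)
        (out / "traces").mkdir(parents=True, exist_ok=True)
        for tr in self.traces:
            tr.to_csv(out / "traces" / f"{tr.sample_id}.csv")
        self.metadata().to_csv(out / "metadata.csv", index=False)
        write_detections_jsonl(
            out / "detections.jsonl",
            dict(zip(self.sample_ids, self.detections)),
        )


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Simulate a full campaign under ``config``.

    Samples are laid out in time: timestamps uniform over ``n_days`` days
    (sorted), balanced classes shuffled across the timeline, lighting drawn
    per sample from ``lighting_probs``, batch membership set by the drift
    onset day. All per-sample seeds derive from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_samples_per_class * len(config.classes)
    timestamps = np.sort(rng.uniform(0.0, config.n_days * 24.0, size=n_total))
    # class balance is exact; temporal clustering of the first class toward
    # the late campaign is controlled by label_time_correlation
    c = config.label_time_correlation
    score = (1.0 - c) * rng.uniform(size=n_total) + c * (
        np.arange(n_total) / max(n_total - 1, 1)
    )
    ripe_like = np.zeros(n_total, dtype=bool)
    ripe_like[np.argsort(score)[-config.n_samples_per_class:]] = True
    labels = [config.classes[0] if r else config.classes[1] for r in ripe_like]
    lightings = rng.choice(
        LIGHTINGS, size=n_total, p=[config.lighting_probs[k] for k in LIGHTINGS]
    )
    sample_seeds = rng.integers(0, 2**31 - 1, size=(n_total, 2))
    surfaces = config.true_surfaces() if config.distort_with_surface else None

    traces: list[ResponseTrace] = []
    detections: list[list[Detection] | None] = []
    width = len(str(n_total - 1))
    for i in range(n_total):
        day = int(timestamps[i] // 24.0)
        hour = float(timestamps[i] % 24.0)
        sid = f"sample_{i:0{width}d}"
        traces.append(
            simulate_trace(
                config,
                label=labels[i],
                day=day,
                seed=int(sample_seeds[i, 0]),
                hour=hour,
                sample_id=sid,
                surfaces=surfaces,
            )
        )
        detections.append(
            simulate_detections(
                config, labels[i], str(lightings[i]), seed=int(sample_seeds[i, 1])
            )
        )
    day_index = np.array([t.day for t in traces])
    return SimulatedDataset(
        config=config,
        traces=traces,
        detections=detections,
        image_available=np.array([li != "night" for li in lightings]),
        labels=labels,
        day_index=day_index,
        batch_id=np.array([t.batch for t in traces]),
        lighting=[str(li) for li in lightings],
    )


def simulate_prediction_frame(
    n: int,
    acc_odour: float,
    acc_image: float,
    availability: float,
    seed: int,
    classes: tuple[str, str] = ("ripe", "unripe"),
    conf_correct: tuple[float, float] = (0.85, 0.95),
    conf_wrong: tuple[float, float] = (0.55, 0.65),
) -> pd.DataFrame:
    """Sample-level predictions with conditionally independent error processes.

    For studying fusion behaviour in isolation from the trace pipeline: each
    modality independently predicts the true label with its stated accuracy;
    the image modality is available with the stated probability. Correct
    predictions draw higher confidences than wrong ones, so confidence is
    informative, as max-confidence fusion assumes. Columns: ``label``,
    ``odour_pred``, ``odour_conf``, ``image_pred``, ``image_conf``,
    ``image_available``.
    """
    rng = np.random.default_rng(seed)
    truth = rng.choice(classes, size=n)
    rows = {}
    for name, acc in (("odour", acc_odour), ("image", acc_image)):
        correct = rng.uniform(size=n) < acc
        other = np.where(truth == classes[0], classes[1], classes[0])
        rows[f"{name}_pred"] = np.where(correct, truth, other)
        conf = np.where(
            correct,
            rng.uniform(*conf_correct, size=n),
            rng.uniform(*conf_wrong, size=n),
        )
        rows[f"{name}_conf"] = conf
    return pd.DataFrame(
        {
            "label": truth,
            **rows,
            "image_available": rng.uniform(size=n) < availability,
        }
    )
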