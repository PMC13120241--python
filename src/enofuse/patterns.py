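"""Heater-voltage modulation patterns for temperature-modulated MOX acquisition.

A pattern is the schedule of voltages applied to the sensor heater (VH): a
pre-heating stage followed by alternating active levels and 0 V rests. The
transient response induced at each active level is what carries the
discriminative information; the five active levels (7, 5.5, 5, 6 and 6.5 V)
define the segmentation used by all downstream feature extraction.

Two modulated protocols are shipped (a 10-minute and a 48-minute acquisition)
plus a continuous 5 V protocol for which no segmentation applies. Stage tables
are plain data and can be overridden from a YAML/dict config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ModulationPattern",
    "DAQ10",
    "DAQ48",
    "DAQCONT",
    "PATTERNS",
    "get_pattern",
]

ACTIVE_LEVELS: tuple[float, ...] = (7.0, 5.5, 5.0, 6.0, 6.5)


@dataclass(frozen=True)
class ModulationPattern:
    """Schedule of heater voltages defining one acquisition.

    Parameters
    ----------
    pattern_id
        Short protocol name (``"DAQ10"``, ``"DAQ48"``, ``"DAQcont"``).
    preheat
        ``(voltage_v, duration_s)`` of the pre-heating stage.
    stages
        Ordered ``(voltage_v, duration_s)`` pairs following the preheat,
        including 0 V rests. Nominal durations; see ``tail_pad_s``.
    nominal_points
        Total saved samples per acquisition. The stage table of the modulated
        protocols sums to 30 s less than the nominal duration; the final
        active stage is held for the remainder so that exactly
        ``nominal_points`` samples are recorded.
    sampling_rate
        Samples per second of the saved signal.
    active_levels
        The analysis voltages in acquisition order. Empty for the continuous
        protocol.
    """

    pattern_id: str
    preheat: tuple[float, float]
    stages: tuple[tuple[float, float], ...]
    nominal_points: int
    sampling_rate: float = 10.0
    active_levels: tuple[float, ...] = field(default=ACTIVE_LEVELS)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.preheat[1] < 0 or any(d <= 0 for _, d in self.stages):
            raise ValueError("stage durations must be > 0")
        if self.active_levels:
            if len(self.active_levels) != 5:
                raise ValueError("a modulated pattern has exactly 5 active levels")
            stage_vs = [v for v, _ in self.stages if v > 0]
            for v in self.active_levels:
                if stage_vs.count(v) != 1:
                    raise ValueError(
                        f"active level {v} V must appear exactly once in stages"
                    )

    @property
    def is_modulated(self) -> bool:
        return bool(self.active_levels)

    @property
    def scheduled_duration_s(self) -> float:
        """Preheat + stage-table duration (before the tail extension)."""
        return self.preheat[1] + sum(d for _, d in self.stages)

    @property
    def nominal_duration_s(self) -> float:
        return self.nominal_points / self.sampling_rate

    @property
    def tail_pad_s(self) -> float:
        """Extra seconds the final stage is held to reach ``nominal_points``."""
        return self.nominal_duration_s - self.scheduled_duration_s

    def active_spans(self) -> dict[float, tuple[int, int]]:
        """Half-open sample-index span ``[start, stop)`` of each active level.

        Spans use the nominal stage durations, so the tail extension of the
        final stage is recorded in the trace but not part of any analysis
        segment.
        """
        if not self.is_modulated:
            raise ValueError(f"{self.pattern_id} has no modulation levels")
        spans: dict[float, tuple[int, int]] = {}
        t = self.preheat[1]
        for v, dur in self.stages:
            start = round(t * self.sampling_rate)
            stop = round((t + dur) * self.sampling_rate)
            if v in self.active_levels:
                spans[v] = (start, stop)
            t += dur
        return {v: spans[v] for v in self.active_levels}

    def voltage_at(self, t_s: float) -> float:
        """Heater voltage at elapsed time ``t_s`` (final stage extended)."""
        if t_s < self.preheat[1]:
            return self.preheat[0]
        t = self.preheat[1]
        for v, dur in self.stages:
            if t_s < t + dur:
                return v
            t += dur
        # tail extension: hold the last stage's voltage
        return self.stages[-1][0] if self.stages else self.preheat[0]


def _rest_interleave(durations: dict[str, float]) -> tuple[tuple[float, float], ...]:
    """Active stages interleaved with 0 V rests: v1, 0, v2, 0, ... , v5."""
    act = durations["active"]
    rest = durations["rest"]
    out: list[tuple[float, float]] = []
    for i, v in enumerate(ACTIVE_LEVELS):
        if i > 0:
            out.append((0.0, rest))
        out.append((v, act))
    return tuple(out)


DAQ10 = ModulationPattern(
    pattern_id="DAQ10",
    preheat=(5.0, 300.0),
    stages=_rest_interleave({"active": 30.0, "rest": 30.0}),
    nominal_points=6000,
)

DAQ48 = ModulationPattern(
    pattern_id="DAQ48",
    preheat=(5.0, 1200.0),
    # the long protocol rests 30 s after the preheat before the first level
    stages=((0.0, 30.0),) + _rest_interleave({"active": 300.0, "rest": 30.0}),
    nominal_points=28_800,
)

DAQCONT = ModulationPattern(
    pattern_id="DAQcont",
    preheat=(5.0, 0.0),  # none: constant 5 V heating throughout
    stages=((5.0, 3600.0),),
    nominal_points=36_000,
    active_levels=(),
)

PATTERNS: dict[str, ModulationPattern] = {
    p.pattern_id: p for p in (DAQ10, DAQ48, DAQCONT)
}


def get_pattern(pattern_id: str) -> ModulationPattern:
    try:
        return PATTERNS[pattern_id]
    except KeyError:
        raise KeyError(
            f"unknown pattern {pattern_id!r}; known: {sorted(PATTERNS)}"
        ) from None
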