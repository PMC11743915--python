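"""Discrete-time trigger/switch channel state machines.

This module re-implements, in simulation, the per-channel event-detection
logic of a microcontroller trigger box: a ``Trigger`` channel samples one
analog input at a fixed rate, fires a TTL output pulse when the signal
crosses a threshold, and shapes that pulse with three timing parameters —

* ``min_pulse_duration`` — minimum time between the initial threshold
  crossing and pulse termination;
* ``pulse_increment`` — minimum time between the *most recent* threshold
  crossing and termination (0 gives fixed-duration pulses; > 0 sustains the
  pulse through gaps in the input no longer than the increment);
* ``refractory_period`` — minimum time between one output-pulse onset and
  the next (output de-bouncing).

A ``Switch`` channel registers de-bounced closures of a push-button.

All conditions are evaluated only at sample instants, so emitted durations
are quantized to the sample period.  Times in this module are microseconds,
matching the firmware parameter menu; thresholds are raw ADC counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .signal_bank import DigitizedTrace

__all__ = [
    "TriggerConfig",
    "SwitchConfig",
    "TriggerState",
    "PulseTrain",
    "step",
    "run_trigger",
    "run_switch",
]

_MODES = ("oscillatory", "dc", "switch")


@dataclass
class TriggerConfig:
    """Per-channel trigger parameters (durations in µs, threshold in ADC counts)."""

    sampling_frequency: float            # Hz
    threshold: int = 50                  # ADC counts, 0–1023 for a 10-bit ADC
    min_pulse_duration: float = 10_000.0
    pulse_increment: float = 0.0
    refractory_period: float = 0.0
    mode: str = "oscillatory"
    polarity: str = "rising"             # dc mode may trigger on falling signals
    adc_bits: int = 10

    def __post_init__(self) -> None:
        if not self.sampling_frequency > 0:
            raise ValueError("sampling_frequency must be positive")
        if not 0 <= self.threshold < 2 ** self.adc_bits:
            raise ValueError("threshold outside ADC range")
        for name in ("min_pulse_duration", "pulse_increment", "refractory_period"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.polarity not in ("rising", "falling"):
            raise ValueError("polarity must be 'rising' or 'falling'")

    @property
    def sample_period(self) -> float:
        """Sample period in µs."""
        return 1e6 / self.sampling_frequency


@dataclass
class SwitchConfig:
    """Push-button channel parameters (µs)."""

    sampling_frequency: float
    debounce_time: float = 20_000.0      # typical mechanical bounce settles < 20 ms
    refractory_period: float = 100_000.0

    def __post_init__(self) -> None:
        if not self.sampling_frequency > 0:
            raise ValueError("sampling_frequency must be positive")
        if self.debounce_time < 0 or self.refractory_period < 0:
            raise ValueError("durations must be non-negative")

    @property
    def sample_period(self) -> float:
        return 1e6 / self.sampling_frequency


@dataclass
class TriggerState:
    """Mutable state carried between ticks of one trigger channel."""

    phase: str = "idle"                       # 'idle' | 'in_pulse'
    last_onset_time: Optional[float] = None   # µs, gates the refractory period
    last_supra_time: Optional[float] = None   # µs, gates the pulse increment
    pulse_start_time: Optional[float] = None  # µs
    _t_prev: Optional[float] = None

    def __post_init__(self) -> None:
        if self.phase == "in_pulse":
            if self.pulse_start_time is None or self.last_supra_time is None:
                raise ValueError("in_pulse state requires pulse_start_time and last_supra_time")
            if self.last_supra_time < self.pulse_start_time:
                raise ValueError("last_supra_time must not precede pulse_start_time")


def step(
    config: TriggerConfig,
    state: TriggerState,
    sample: float,
    t: float,
) -> tuple[TriggerState, Optional[str]]:
    """Advance the trigger machine by one sample; return any output edge.

    Returns ``(state, edge)`` where ``edge`` is ``"high"``, ``"low"`` or
    ``None``.  ``t`` must advance strictly between calls.  Within a tick,
    pulse termination is evaluated before new-onset logic: a still-supra
    sample at a would-be termination tick extends the pulse via the
    increment rather than re-triggering.
    """
    if state._t_prev is not None and t <= state._t_prev:
        raise ValueError(f"non-monotone sample time: {t} after {state._t_prev}")
    state._t_prev = t

    if config.polarity == "rising":
        supra = sample > config.threshold
    else:
        supra = sample < config.threshold

    edge: Optional[str] = None
    if state.phase == "in_pulse":
        if supra:
            state.last_supra_time = t
        if (
            t - state.pulse_start_time >= config.min_pulse_duration
            and t - state.last_supra_time >= config.pulse_increment
        ):
            state.phase = "idle"
            state.pulse_start_time = None
            state.last_supra_time = None
            edge = "low"
    elif supra:
        if (
            state.last_onset_time is None
            or t - state.last_onset_time >= config.refractory_period
        ):
            state.phase = "in_pulse"
            state.pulse_start_time = t
            state.last_supra_time = t
            state.last_onset_time = t
            edge = "high"
    return state, edge


@dataclass
class PulseTrain:
    """Rising/falling edge times (µs) of one output line.

    ``offsets`` pairs with ``onsets``; when ``open_end`` is true the final
    pulse never terminated within the observed record and ``offsets`` is one
    element shorter.
    """

    onsets: np.ndarray
    offsets: np.ndarray
    line_id: str = "out"
    open_end: bool = False

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        expected = len(self.onsets) - (1 if self.open_end else 0)
        if len(self.offsets) != expected:
            raise ValueError("onsets/offsets length mismatch")
        seq = np.empty(len(self.onsets) + len(self.offsets))
        seq[0::2] = self.onsets
        seq[1::2] = self.offsets
        if len(seq) > 1 and np.any(np.diff(seq) <= 0):
            raise ValueError("edges must strictly increase and alternate high/low")

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def edges(self) -> Iterator[tuple[float, str]]:
        """Edges as ordered ``(time_µs, level)`` pairs."""
        for i, on in enumerate(self.onsets):
            yield (on, "high")
            if i < len(self.offsets):
                yield (self.offsets[i], "low")

    @property
    def durations(self) -> np.ndarray:
        """Durations (µs) of the terminated pulses."""
        n = len(self.offsets)
        return self.offsets - self.onsets[:n]

    def shifted(self, delta: float) -> "PulseTrain":
        return PulseTrain(self.onsets + delta, self.offsets + delta, self.line_id, self.open_end)


def _trace_times_us(trace: DigitizedTrace) -> np.ndarray:
    return trace.times * 1e6


def run_trigger(
    config: TriggerConfig,
    trace: DigitizedTrace,
    line_id: str = "out",
) -> PulseTrain:
    """Fold :func:`step` over an ADC trace and collect the output edges.

    ``trace`` holds ADC counts sampled at the channel's configured rate
    (its ``start_time`` may carry the channel's scan offset).  The same
    train is emitted on every output line the channel drives, so a single
    train is returned.
    """
    if len(trace) and abs(trace.rate - config.sampling_frequency) > 1e-6 * config.sampling_frequency:
        raise ValueError("trace rate does not match the channel's sampling frequency")
    state = TriggerState()
    onsets: list[float] = []
    offsets: list[float] = []
    values = trace.values
    times = _trace_times_us(trace)
    for sample, t in zip(values, times):
        state, edge = step(config, state, sample, t)
        if edge == "high":
            onsets.append(t)
        elif edge == "low":
            offsets.append(t)
    return PulseTrain(
        np.array(onsets), np.array(offsets), line_id, open_end=state.phase == "in_pulse"
    )


def run_switch(
    config: SwitchConfig,
    trace: DigitizedTrace,
    line_id: str = "out",
) -> PulseTrain:
    """De-bounced closure events from a binary (closed/open) trace.

    A closure registers once its closed state has persisted for
    ``debounce_time``; the event is timestamped at the first sample of the
    stable closed run.  Subsequent events are gated by the refractory
    period (onset to onset).  The output goes low when the de-bounced
    closure ends.
    """
    values = np.asarray(trace.values, dtype=bool)
    times = _trace_times_us(trace)
    onsets: list[float] = []
    offsets: list[float] = []
    last_event: Optional[float] = None
    open_end = False
    i, n = 0, len(values)
    while i < n:
        if not values[i]:
            i += 1
            continue
        j = i
        while j < n and values[j]:
            j += 1
        t_first, t_last = times[i], times[j - 1]
        if t_last - t_first >= config.debounce_time and (
            last_event is None or t_first - last_event >= config.refractory_period
        ):
            onsets.append(t_first)
            last_event = t_first
            if j < n:
                offsets.append(times[j])
            else:
                open_end = True
        i = j
    return PulseTrain(np.array(onsets), np.array(offsets), line_id, open_end=open_end)
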