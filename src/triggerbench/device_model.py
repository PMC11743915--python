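"""Whole-device emulation: front ends, ADC, and the sequential channel scan.

The emulated firmware services up to eight input channels (tip and ring of
four TRS jacks) strictly sequentially within each sample tick, with no
sample-and-hold: each channel reads the live analog source at its own
instant, a fixed per-channel processing cost later than the previous one.
Two consequences follow, both reproduced here:

* channels fed the same source can detect an onset whole processing-offsets
  apart — or one full sample apart in the other direction if the crossing
  falls between two channels' sampling instants within one tick;
* the total per-tick processing time bounds the feasible sampling rate; the
  device is healthy only while "idle" main-loop iterations remain.

Analog front ends model the two input paths: a unipolar ADC read that
clips negative excursions (half-wave effect), and a DC-biased path that
shifts the signal up by V_CC/2 = 1.65 V so negative excursions remain
measurable.

Costs and event times are microseconds; sources are functions of seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence, Union

import numpy as np

from .signal_bank import DigitizedTrace
from .trigger_core import (
    PulseTrain,
    SwitchConfig,
    TriggerConfig,
    run_switch,
    run_trigger,
)

__all__ = [
    "ChannelFrontEnd",
    "DeviceConfig",
    "SimulationResult",
    "front_end_read",
    "simulate",
    "max_sampling_rate",
    "idle_fraction",
]

V_CC = 3.3

#: Firmware rate menu: 50 kHz divided down to round sample periods
#: (20/40/80/100/160 µs).  Divisors 3, 6 and 7 would give fractional-µs or
#: non-round periods and are inconsistent with the device's documented
#: per-channel-count rate ceilings, so they are not offered.
DEFAULT_RATE_MENU = tuple(50_000.0 / n for n in (1, 2, 4, 5, 8))


@dataclass
class ChannelFrontEnd:
    """Analog conditioning + ADC for one input channel."""

    kind: str = "half_wave"      # 'half_wave' | 'dc_biased'
    full_scale: float = V_CC     # volts
    adc_bits: int = 10
    bias: float | None = None    # volts; defaults per kind

    def __post_init__(self) -> None:
        if self.kind not in ("half_wave", "dc_biased"):
            raise ValueError("kind must be 'half_wave' or 'dc_biased'")
        if self.bias is None:
            self.bias = self.full_scale / 2 if self.kind == "dc_biased" else 0.0
        if not 0 <= self.bias <= self.full_scale:
            raise ValueError("bias must lie within [0, full_scale]")


def front_end_read(fe: ChannelFrontEnd, v) -> np.ndarray | int:
    """Convert analog volts to ADC counts through a front end.

    The ADC only captures voltages in [0, full_scale]: a ``half_wave`` front
    end therefore clips negative excursions to zero, while ``dc_biased``
    first shifts the signal up by the bias voltage.  Quantization is
    ``floor(v / full_scale · 2^bits)`` clamped to the top code.
    """
    scalar = np.isscalar(v)
    x = np.asarray(v, dtype=float) + fe.bias
    x = np.clip(x, 0.0, fe.full_scale)
    levels = 2 ** fe.adc_bits
    counts = np.minimum(np.floor(x / fe.full_scale * levels), levels - 1).astype(int)
    return int(counts) if scalar else counts


Channel = tuple[ChannelFrontEnd, Union[TriggerConfig, SwitchConfig]]


@dataclass
class DeviceConfig:
    """Ordered channel list plus the scan-timing model."""

    channels: Sequence[Channel]
    trigger_cost: float = 16.5    # µs to sample and process one trigger channel
    switch_cost: float = 0.5      # µs for a switch channel
    loop_overhead: float = 0.0    # µs per tick outside the channel scan
    rate_menu: Sequence[float] = DEFAULT_RATE_MENU

    def __post_init__(self) -> None:
        if not 1 <= len(self.channels) <= 8:
            raise ValueError("device supports 1 to 8 channels")
        if self.trigger_cost <= 0 or self.switch_cost <= 0:
            raise ValueError("per-channel costs must be positive")
        if self.loop_overhead < 0:
            raise ValueError("loop_overhead must be non-negative")

    def channel_costs(self) -> np.ndarray:
        """Per-channel processing cost (µs) in scan order."""
        return np.array(
            [
                self.switch_cost if isinstance(cfg, SwitchConfig) else self.trigger_cost
                for _, cfg in self.channels
            ]
        )

    def scan_offsets(self) -> np.ndarray:
        """Each channel's sampling instant relative to its tick (µs)."""
        costs = self.channel_costs()
        return np.concatenate([[0.0], np.cumsum(costs)[:-1]])

    def total_cost(self) -> float:
        return float(self.channel_costs().sum() + self.loop_overhead)


@dataclass
class SimulationResult:
    """Per-channel outputs of one emulated run."""

    pulse_trains: list[PulseTrain]
    adc_traces: list[DigitizedTrace]
    idle_fraction: float
    sampling_frequency: float


def idle_fraction(device: DeviceConfig, rate: float) -> float:
    """Fraction of each sample period left to idle loops, floored at zero."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return max(0.0, 1.0 - device.total_cost() * rate / 1e6)


def max_sampling_rate(device: DeviceConfig) -> float:
    """Largest menu rate at which idle loops still remain.

    A rate is feasible iff the summed per-channel costs (plus loop
    overhead) fit strictly within one sample period.
    """
    total = device.total_cost()
    feasible = [r for r in device.rate_menu if total < 1e6 / r]
    if not feasible:
        raise ValueError(
            f"no feasible rate in the menu: per-tick cost {total:.1f} µs "
            f"exceeds every sample period"
        )
    return max(feasible)


def _as_source(src) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(src, DigitizedTrace):
        return src.as_function()
    if callable(src):
        return src
    raise TypeError("source must be a DigitizedTrace or a callable of time (s)")


def simulate(
    device: DeviceConfig,
    sources: Mapping[int, object],
    sampling_frequency: float,
    duration: float,
) -> SimulationResult:
    """Run the device on continuous analog sources for ``duration`` seconds.

    ``sources`` maps channel index (0-based, scan order) to a continuous
    analog source — a callable ``f(times_s) -> volts`` or a trace read
    through interpolation; unmapped channels see 0 V.  Tick ``n`` occurs at
    ``n·T_s``; channel ``i`` samples at ``n·T_s + Σ_{j<i} cost_j`` and its
    output edges are applied when its processing completes, one channel
    cost after its sampling instant.
    """
    period = 1e6 / sampling_frequency
    total = device.total_cost()
    if total >= period:
        raise ValueError(
            f"no idle loops at {sampling_frequency:g} Hz: per-tick cost "
            f"{total:.1f} µs ≥ period {period:.1f} µs; "
            f"max feasible rate is {max_sampling_rate(device):g} Hz"
        )
    n_ticks = int(np.floor(duration * sampling_frequency))
    ticks_us = np.arange(n_ticks) * period
    offsets = device.scan_offsets()
    costs = device.channel_costs()

    trains: list[PulseTrain] = []
    traces: list[DigitizedTrace] = []
    for i, (fe, cfg) in enumerate(device.channels):
        t_us = ticks_us + offsets[i]
        src = _as_source(sources[i]) if i in sources else (lambda t: np.zeros_like(t))
        volts = np.asarray(src(t_us * 1e-6), dtype=float)
        # the device-wide rate setting overrides each channel's configured rate
        if cfg.sampling_frequency != sampling_frequency:
            cfg = replace(cfg, sampling_frequency=sampling_frequency)
        if isinstance(cfg, SwitchConfig):
            levels = volts > fe.full_scale / 2
            trace = DigitizedTrace(levels, sampling_frequency, start_time=offsets[i] * 1e-6)
            train = run_switch(cfg, trace, line_id=f"ch{i + 1}")
        else:
            counts = front_end_read(fe, volts)
            trace = DigitizedTrace(counts, sampling_frequency, start_time=offsets[i] * 1e-6)
            train = run_trigger(cfg, trace, line_id=f"ch{i + 1}")
        trains.append(train.shifted(costs[i]))
        traces.append(trace)
    return SimulationResult(trains, traces, idle_fraction(device, sampling_frequency), sampling_frequency)
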