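"""Seeded stimulus generators and a virtual digitizer.

Everything the timing bench consumes is generated here: abrupt-onset test
tones, noise bursts, randomized stimulus trains, auditory-oddball sequences,
and the high-rate "virtual digitizer" that stands in for a lab data
acquisition card.  All stochastic generators take an explicit seed (or
:class:`numpy.random.Generator`) and are bit-reproducible under it.

Times in this module are seconds and rates are Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal as _sig

__all__ = [
    "DigitizedTrace",
    "StimulusSchedule",
    "onset_tone",
    "noise_burst",
    "stimulus_train",
    "oddball_sequence",
    "digitize",
    "ttl_waveform",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("stochastic generators require an explicit seed")
    return np.random.default_rng(seed)


@dataclass
class DigitizedTrace:
    """A uniformly sampled sequence of voltages (or ADC counts).

    Parameters
    ----------
    values : ndarray
        Sample values, one per grid point.
    rate : float
        Sampling rate in Hz.
    start_time : float
        Time of the first sample, in seconds.
    """

    values: np.ndarray
    rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(len(self.values)) / self.rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.rate

    def as_function(self) -> Callable[[np.ndarray], np.ndarray]:
        """Linear-interpolation view of the trace as a continuous source.

        Outside the sampled support the trace is held at zero, matching a
        silent line before and after a recording.
        """
        t = self.times
        v = np.asarray(self.values, dtype=float)

        def f(query):
            return np.interp(np.asarray(query, dtype=float), t, v, left=0.0, right=0.0)

        return f


@dataclass
class StimulusSchedule:
    """Ground-truth event list for a rendered stimulus sequence."""

    onsets: np.ndarray          # seconds, strictly increasing
    labels: list = field(default_factory=list)
    durations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if len(self.onsets) and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("schedule onsets must be strictly increasing")
        if self.durations is not None:
            self.durations = np.asarray(self.durations, dtype=float)

    def __len__(self) -> int:
        return len(self.onsets)


def onset_tone(
    f0: float = 100.0,
    amplitude: float = 1.0,
    total: float = 0.100,
    rate: float = 44100.0,
    flat: float = 0.050,
) -> DigitizedTrace:
    """Abrupt-onset cosine-phase tone tapering to silence.

    The carrier starts at its positive peak (cosine phase) so the very first
    sample equals ``+amplitude`` — the abrupt edge a threshold trigger should
    catch.  The envelope is flat for ``flat`` seconds and then decays with a
    raised cosine, reaching exactly zero at ``total``.
    """
    if rate <= 2 * f0:
        raise ValueError("rate must exceed twice the carrier frequency")
    n = round(total * rate)
    t = np.arange(n) / rate
    carrier = np.cos(2 * np.pi * f0 * t)
    env = np.ones(n)
    tail = t >= flat
    env[tail] = 0.5 * (1 + np.cos(np.pi * (t[tail] - flat) / (total - flat)))
    return DigitizedTrace(amplitude * carrier * env, rate)


def noise_burst(
    duration: float = 0.025,
    sd: float = 1.0,
    rate: float = 44100.0,
    seed=None,
) -> DigitizedTrace:
    """Zero-mean white-noise burst with a rectangular envelope."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = _as_rng(seed)
    n = round(duration * rate)
    return DigitizedTrace(rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n), rate)


def stimulus_train(
    waveform: DigitizedTrace | Callable[[np.random.Generator], DigitizedTrace],
    n: int,
    isi_range: tuple[float, float] = (0.25, 1.0),
    rate: float | None = None,
    seed=None,
    pad: float = 0.1,
) -> tuple[DigitizedTrace, StimulusSchedule]:
    """Place ``n`` copies of a waveform with i.i.d. uniform onset-to-onset gaps.

    ``waveform`` may be a fixed trace, or a callable ``f(rng) -> trace`` that
    draws a fresh realization per event (independently generated noise
    bursts).  The first onset is itself drawn from ``isi_range`` so that the
    train starts at random phase.  The returned schedule records the onsets
    as rendered (quantized to the output grid).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = _as_rng(seed) if n > 0 else None
    draws = callable(waveform)
    proto = waveform(np.random.default_rng(0)) if draws else waveform
    if rate is None:
        rate = proto.rate
    lo, hi = isi_range
    if not 0 < lo <= hi:
        raise ValueError("invalid isi_range")
    if n == 0:
        return DigitizedTrace(np.zeros(0), rate), StimulusSchedule(np.zeros(0), [], np.zeros(0))

    onsets = np.cumsum(rng.uniform(lo, hi, size=n))
    events = [waveform(rng) if draws else waveform for _ in range(n)]
    dur = max(len(ev) for ev in events) / rate
    total_n = round((onsets[-1] + dur + pad) * rate)
    out = np.zeros(total_n)
    rendered = np.empty(n)
    durations = np.empty(n)
    for i, (onset, ev) in enumerate(zip(onsets, events)):
        if ev.rate != rate:
            ev = digitize(ev.as_function(), rate=rate, duration=ev.duration)
        i0 = round(onset * rate)
        out[i0 : i0 + len(ev)] += ev.values
        rendered[i] = i0 / rate
        durations[i] = len(ev) / rate
    sched = StimulusSchedule(rendered, ["stimulus"] * n, durations)
    return DigitizedTrace(out, rate), sched


def _square_beep(f0: float, duration: float, rate: float, amplitude: float) -> DigitizedTrace:
    t = np.arange(round(duration * rate)) / rate
    return DigitizedTrace(amplitude * _sig.square(2 * np.pi * f0 * t), rate)


def _distractor(rng: np.random.Generator, duration: float, rate: float, amplitude: float) -> DigitizedTrace:
    # one-off novel sound: band-limited noise, unique per event
    n = round(duration * rate)
    raw = rng.normal(size=n)
    sos = _sig.butter(4, [200.0, 2000.0], btype="band", fs=rate, output="sos")
    v = _sig.sosfilt(sos, raw)
    peak = np.max(np.abs(v))
    return DigitizedTrace(amplitude * v / peak if peak > 0 else v, rate)


def oddball_sequence(
    n_standard: int = 270,
    n_target: int = 80,
    n_distractor: int = 60,
    soa: float = 1.0,
    beep_duration: float = 0.340,
    f_standard: float = 400.0,
    f_target: float = 575.0,
    rate: float = 44100.0,
    amplitude: float = 1.0,
    seed=None,
) -> tuple[DigitizedTrace, StimulusSchedule]:
    """Auditory oddball sequence: frequent standards, rare targets, one-off distractors.

    Square-wave beeps at the standard/target fundamentals plus unique
    noise-like distractor sounds, presented in seeded random order with
    onsets on the SOA grid (one stimulus per second by default).
    """
    counts = (n_standard, n_target, n_distractor)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    n = sum(counts)
    if n == 0:
        return DigitizedTrace(np.zeros(0), rate), StimulusSchedule(np.zeros(0), [], np.zeros(0))
    rng = _as_rng(seed)
    labels = np.array(
        ["standard"] * n_standard + ["target"] * n_target + ["distractor"] * n_distractor
    )
    labels = labels[rng.permutation(n)]
    std = _square_beep(f_standard, beep_duration, rate, amplitude)
    tgt = _square_beep(f_target, beep_duration, rate, amplitude)
    onsets = np.arange(n) * soa
    out = np.zeros(round((onsets[-1] + beep_duration + 0.1) * rate))
    for onset, lab in zip(onsets, labels):
        if lab == "standard":
            ev = std
        elif lab == "target":
            ev = tgt
        else:
            ev = _distractor(rng, beep_duration, rate, amplitude)
        i0 = round(onset * rate)
        out[i0 : i0 + len(ev)] += ev.values
    sched = StimulusSchedule(onsets, list(labels), np.full(n, beep_duration))
    return DigitizedTrace(out, rate), sched


def digitize(
    source: DigitizedTrace | Callable[[np.ndarray], np.ndarray],
    rate: float = 100_000.0,
    duration: float | None = None,
    start_time: float = 0.0,
) -> DigitizedTrace:
    """Sample a continuous source on a uniform grid — the virtual digitizer.

    ``source`` is either a callable ``f(times_s) -> volts`` or an existing
    trace (read through linear interpolation, e.g. to resample a 44.1 kHz
    recording at 100 kHz).  Edge times observed through the returned trace
    are quantized to the digitizer grid (10 µs at the default 100 kHz).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if isinstance(source, DigitizedTrace):
        if duration is None:
            duration = source.duration
        f = source.as_function()
    else:
        if duration is None:
            raise ValueError("duration is required for a callable source")
        f = source
    t = start_time + np.arange(round(duration * rate)) / rate
    return DigitizedTrace(np.asarray(f(t), dtype=float), rate, start_time)


def ttl_waveform(train, high: float = 3.3, low: float = 0.0) -> Callable[[np.ndarray], np.ndarray]:
    """Continuous TTL voltage as a function of time (seconds) for a pulse train.

    ``train`` provides rising/falling edge times in microseconds
    (:class:`~triggerbench.trigger_core.PulseTrain`).  An unterminated final
    pulse stays high to the end of time.
    """
    rises = np.asarray(train.onsets, dtype=float) * 1e-6
    falls = np.asarray(train.offsets, dtype=float) * 1e-6
    if train.open_end:
        falls = np.append(falls, np.inf)

    def f(query):
        q = np.asarray(query, dtype=float)
        inside = np.searchsorted(rises, q, side="right") > np.searchsorted(falls, q, side="right")
        return np.where(inside, high, low)

    return f
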