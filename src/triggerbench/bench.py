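"""End-to-end characterization benches.

Each function wires the generators, the device emulator, the virtual
digitizer and the analysis pipeline into one of the standard validation
experiments for a trigger box:

* :func:`latency_bench` — input-to-output latency/jitter for abrupt tone
  onsets (the raster/latency experiment);
* :func:`pulse_duration_bench` — fixed and extended output-pulse durations
  driven by noise bursts;
* :func:`sequential_offset_experiment` — inter-channel onset offsets caused
  by the sequential, sample-and-hold-free channel scan;
* :func:`erp_demo` — ERP averages with and without stimulus-latency jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import erp_jitter, signal_bank, timing_analysis
from .device_model import ChannelFrontEnd, DeviceConfig, simulate
from .signal_bank import DigitizedTrace, digitize, ttl_waveform
from .timing_analysis import TimingReport, detect_onsets, edge_times, group_correct, latency_stats
from .trigger_core import TriggerConfig

__all__ = [
    "latency_bench",
    "pulse_duration_bench",
    "sequential_offset_experiment",
    "erp_demo",
]


def _trigger_device(
    n_channels: int,
    sampling_frequency: float,
    threshold: int,
    min_pulse_us: float,
    increment_us: float,
    refractory_us: float,
    trigger_cost: float,
    front_end_kind: str = "half_wave",
) -> DeviceConfig:
    cfg = TriggerConfig(
        sampling_frequency=sampling_frequency,
        threshold=threshold,
        min_pulse_duration=min_pulse_us,
        pulse_increment=increment_us,
        refractory_period=refractory_us,
    )
    fe = ChannelFrontEnd(front_end_kind)
    return DeviceConfig([(fe, cfg)] * n_channels, trigger_cost=trigger_cost)


def latency_bench(
    seed: int,
    n_stimuli: int = 187,
    n_channels: int = 8,
    sampling_frequency: float = 6250.0,
    amplitude: float = 1.0,
    threshold: int = 50,
    min_pulse_ms: float = 10.0,
    refractory_ms: float = 200.0,
    trigger_cost: float = 16.5,
    digitizer_rate: float = 100_000.0,
    diff_threshold: float = 0.2,
    measure_channel: int = 0,
) -> dict:
    """Simulate the tone-onset latency experiment and analyze it.

    Plays ``n_stimuli`` abrupt-onset cosine-phase 100 Hz tones with uniform
    0.25–1 s inter-stimulus intervals into every trigger channel, digitizes
    stimulus and TTL output together at ``digitizer_rate``, then runs
    onset detection, group correction and latency pairing.  Stimulus onsets
    fall at uniform-random phase relative to the device's sample grid, so
    the latency S.D. approaches T_s/√12 for sample period T_s.
    """
    tone = signal_bank.onset_tone(amplitude=amplitude)
    stim, sched = signal_bank.stimulus_train(tone, n_stimuli, seed=seed)
    device = _trigger_device(
        n_channels, sampling_frequency, threshold,
        min_pulse_ms * 1000.0, 0.0, refractory_ms * 1000.0, trigger_cost,
    )
    duration = stim.duration + 0.05
    sources = {i: stim for i in range(n_channels)}
    sim = simulate(device, sources, sampling_frequency, duration)

    stim_dig = digitize(stim, rate=digitizer_rate, duration=duration)
    train = sim.pulse_trains[measure_channel]
    ttl_dig = digitize(ttl_waveform(train), rate=digitizer_rate, duration=duration)

    raw_onsets = detect_onsets(stim_dig, diff_threshold)
    corrected = group_correct(stim_dig, raw_onsets)
    out_train = edge_times(ttl_dig)
    report = latency_stats(corrected, out_train.onsets * 1e-6)
    return {
        "report": report,
        "schedule": sched,
        "raw_onsets": raw_onsets,
        "corrected_onsets": corrected,
        "output_train": out_train,
        "simulation": sim,
        "stimulus_digitized": stim_dig,
        "ttl_digitized": ttl_dig,
    }


def pulse_duration_bench(
    seed: int,
    n_bursts: int = 200,
    min_pulse_ms: float = 10.0,
    increment_ms: float = 0.0,
    noise_sd: float = 1.0,
    n_channels: int = 8,
    sampling_frequency: float = 6250.0,
    threshold: int = 50,
    refractory_ms: float = 200.0,
    trigger_cost: float = 16.5,
    front_end_kind: str = "half_wave",
    digitizer_rate: float = 100_000.0,
    measure_channel: int = 0,
) -> dict:
    """Drive the device with independently generated 25 ms noise bursts.

    With ``increment_ms = 0`` the output pulses have fixed duration (the
    configured minimum, quantized to the sample period); with a positive
    increment the pulse is sustained through input gaps up to the increment,
    so durations track burst length plus the increment minus random
    onset/offset gaps.  Durations are reported both exactly (from the
    emulator's pulse train) and as measured through the virtual digitizer.
    """
    rng = np.random.default_rng(seed)
    burst = lambda r: signal_bank.noise_burst(0.025, sd=noise_sd, rate=44100.0, seed=r)
    stim, sched = signal_bank.stimulus_train(burst, n_bursts, seed=rng)
    device = _trigger_device(
        n_channels, sampling_frequency, threshold,
        min_pulse_ms * 1000.0, increment_ms * 1000.0, refractory_ms * 1000.0,
        trigger_cost, front_end_kind,
    )
    duration = stim.duration + 0.1
    sim = simulate(device, {i: stim for i in range(n_channels)}, sampling_frequency, duration)
    train = sim.pulse_trains[measure_channel]
    ttl_dig = digitize(ttl_waveform(train), rate=digitizer_rate, duration=duration)
    measured = edge_times(ttl_dig)
    return {
        "schedule": sched,
        "simulation": sim,
        "exact_durations_ms": train.durations / 1000.0,
        "measured_durations_ms": measured.durations / 1000.0,
        "output_train": train,
    }


def sequential_offset_experiment(
    crossing: str = "pre_tick",
    n_channels: int = 8,
    trigger_cost: float = 16.7,
    sampling_frequency: float = 6250.0,
    threshold: int = 50,
    step_volts: float = 1.0,
) -> float:
    """Onset-time difference (µs) between the last and first scanned channel.

    All channels read the same step input.  ``crossing='pre_tick'`` places
    the threshold crossing just before a tick, so every channel detects on
    the same tick and the outputs land one scan apart
    (``(n−1)·cost``).  ``crossing='intra_tick'`` places it between the
    first and last channel's sampling instants within one tick, so the last
    channel detects one whole sample before the first and the difference is
    ``(n−1)·cost − T_s``.
    """
    period = 1e6 / sampling_frequency
    device = _trigger_device(
        n_channels, sampling_frequency, threshold, 10_000.0, 0.0, 0.0, trigger_cost,
    )
    tick = 100  # an arbitrary tick well inside the run
    if crossing == "pre_tick":
        t_cross = tick * period - 1.0
    elif crossing == "intra_tick":
        t_cross = tick * period + (n_channels - 1) * trigger_cost / 2.0
    else:
        raise ValueError("crossing must be 'pre_tick' or 'intra_tick'")
    t_cross_s = t_cross * 1e-6

    def source(t):
        return np.where(np.asarray(t) >= t_cross_s, step_volts, 0.0)

    duration = (tick + 200) * period * 1e-6
    sim = simulate(device, {i: source for i in range(n_channels)}, sampling_frequency, duration)
    first, last = sim.pulse_trains[0], sim.pulse_trains[-1]
    if len(first) == 0 or len(last) == 0:
        raise RuntimeError("step input did not trigger all channels")
    return float(last.onsets[0] - first.onsets[0])


def erp_demo(
    seed: int,
    n_epochs: int = 410,
    latency_offset_ms: float = 227.0,
    latency_jitter_sd_ms: float = 30.7,
    noise_sd_uv: float = 10.0,
    template: Optional[erp_jitter.ERPTemplate] = None,
) -> dict:
    """Hardware-locked vs software-locked ERP averages under latency jitter.

    The hardware-locked average aligns each trial to the physical stimulus
    (TTL pulse), so components sit at their nominal latencies; the
    software-locked average aligns to the play command, so every trial is
    late by the audio latency and smeared by its jitter.  Returns both
    averages with peak metrics for the MMN and P3a windows.
    """
    if template is None:
        template = erp_jitter.make_template()
    rng = np.random.default_rng(seed)
    hw = erp_jitter.simulate_epochs(template, n_epochs, noise_sd_uv, 0.0, 0.0, rng)
    sw = erp_jitter.simulate_epochs(
        template, n_epochs, noise_sd_uv, latency_offset_ms, latency_jitter_sd_ms, rng
    )
    hw_mean, hw_sem = erp_jitter.average_epochs(hw)
    sw_mean, sw_sem = erp_jitter.average_epochs(sw)
    t = template.times
    mmn_win = (100.0, 250.0)
    p3a_win = (250.0, 400.0)
    off = latency_offset_ms
    metrics = {
        "mmn_hw": erp_jitter.peak_metrics(hw_mean, t, mmn_win, "negative"),
        "p3a_hw": erp_jitter.peak_metrics(hw_mean, t, p3a_win, "positive"),
        "mmn_sw": erp_jitter.peak_metrics(
            sw_mean, t, (mmn_win[0] + off, mmn_win[1] + off), "negative"
        ),
        "p3a_sw": erp_jitter.peak_metrics(
            sw_mean, t, (p3a_win[0] + off, p3a_win[1] + off), "positive"
        ),
    }
    return {
        "template": template,
        "times_ms": t,
        "hw_mean": hw_mean,
        "hw_sem": hw_sem,
        "sw_mean": sw_mean,
        "sw_sem": sw_sem,
        "metrics": metrics,
        "hw_epochs": hw,
        "sw_epochs": sw,
    }
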