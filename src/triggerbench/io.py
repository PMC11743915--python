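"""File formats, configuration and run manifests.

Traces travel as WAV (float PCM, audio or digitizer rates) or two-column
CSV (``time`` in seconds, ``voltage`` in volts); event lists as
tab-separated tables with the ``onset`` / ``duration`` / ``trial_type``
columns conventional for neuroimaging events files; device and channel
configuration as YAML; reports and manifests as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .device_model import ChannelFrontEnd, DeviceConfig
from .signal_bank import DigitizedTrace, StimulusSchedule
from .trigger_core import PulseTrain, SwitchConfig, TriggerConfig

__all__ = [
    "read_trace",
    "write_trace",
    "write_events",
    "read_events",
    "load_device_config",
    "device_from_dict",
    "write_manifest",
]

_REL_TOL = 1e-6


def read_trace(path, fmt: str | None = None) -> DigitizedTrace:
    """Read a recording as a :class:`DigitizedTrace`.

    ``fmt`` is ``'wav'`` or ``'csv'``; inferred from the suffix when omitted.
    CSV files must have ``time`` and ``voltage`` columns with uniform
    timestamps — the sampling rate is taken from the time column, and any
    row breaking uniformity is rejected by number.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "wav":
        rate, data = wavfile.read(path)
        if data.ndim > 1:
            data = data[:, 0]
        if np.issubdtype(data.dtype, np.integer):
            data = data / float(np.iinfo(data.dtype).max)
        return DigitizedTrace(np.asarray(data, dtype=np.float64), float(rate))
    if fmt == "csv":
        df = pd.read_csv(path)
        missing = {"time", "voltage"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        t = df["time"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError(f"{path}: need at least two samples to infer a rate")
        dt = np.diff(t)
        step = dt[0]
        bad = np.flatnonzero(np.abs(dt - step) > _REL_TOL * max(abs(step), 1e-12))
        if step <= 0 or len(bad):
            # bad[k] indexes an interval; the later sample breaks uniformity.
            # +1 for that sample, +1 for the header line, +1 for 1-based rows.
            row = int(bad[0]) + 3 if len(bad) else 2
            raise ValueError(
                f"{path}: non-uniform timestamps (first offending data row {row})"
            )
        return DigitizedTrace(
            df["voltage"].to_numpy(dtype=float), 1.0 / step, start_time=float(t[0])
        )
    raise ValueError(f"unsupported trace format: {fmt!r}")


def write_trace(trace: DigitizedTrace, path, fmt: str | None = None) -> Path:
    """Write a trace as WAV (float64 PCM) or CSV; round trips bit-identically."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "wav":
        wavfile.write(path, int(round(trace.rate)), np.asarray(trace.values, dtype=np.float64))
    elif fmt == "csv":
        df = pd.DataFrame({"time": trace.times, "voltage": trace.values})
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unsupported trace format: {fmt!r}")
    return path


def write_events(events: StimulusSchedule | PulseTrain, path) -> Path:
    """Write an events table (TSV: onset, duration, trial_type; seconds).

    Accepts either a stimulus schedule or a pulse train (pulses become
    ``pulse`` events with their measured durations).  Onset precision is
    well under a microsecond.
    """
    path = Path(path)
    if isinstance(events, PulseTrain):
        n_closed = len(events.offsets)
        onsets = events.onsets * 1e-6
        durations = np.full(len(events.onsets), np.nan)
        durations[:n_closed] = events.durations * 1e-6
        labels = ["pulse"] * len(onsets)
    else:
        onsets = events.onsets
        durations = (
            events.durations
            if events.durations is not None
            else np.full(len(onsets), np.nan)
        )
        labels = list(events.labels) if events.labels else ["event"] * len(onsets)
    df = pd.DataFrame({"onset": onsets, "duration": durations, "trial_type": labels})
    df.to_csv(path, sep="\t", index=False, float_format="%.9f")
    return path


def read_events(path) -> StimulusSchedule:
    """Read an events TSV back into a schedule."""
    df = pd.read_csv(path, sep="\t")
    return StimulusSchedule(
        df["onset"].to_numpy(dtype=float),
        [str(x) for x in df["trial_type"]],
        df["duration"].to_numpy(dtype=float),
    )


def _channel_from_dict(d: dict) -> tuple[ChannelFrontEnd, TriggerConfig | SwitchConfig]:
    fe = ChannelFrontEnd(kind=d.get("front_end", "half_wave"))
    kind = d.get("mode", "oscillatory")
    fs = float(d.get("sampling_frequency", 6250.0))
    if kind == "switch":
        cfg = SwitchConfig(
            sampling_frequency=fs,
            debounce_time=float(d.get("debounce_time_ms", 20.0)) * 1000.0,
            refractory_period=float(d.get("refractory_ms", 100.0)) * 1000.0,
        )
    else:
        cfg = TriggerConfig(
            sampling_frequency=fs,
            threshold=int(d.get("threshold", 50)),
            min_pulse_duration=float(d.get("min_pulse_ms", 10.0)) * 1000.0,
            pulse_increment=float(d.get("increment_ms", 0.0)) * 1000.0,
            refractory_period=float(d.get("refractory_ms", 0.0)) * 1000.0,
            mode=kind,
            polarity=d.get("polarity", "rising"),
        )
    return fe, cfg


def device_from_dict(d: dict) -> DeviceConfig:
    """Build a :class:`DeviceConfig` from the documented YAML key schema.

    Schema (all durations in ms, costs in µs)::

        trigger_cost: 16.5
        switch_cost: 0.5
        loop_overhead: 0.0
        channels:
          - {mode: oscillatory, threshold: 50, min_pulse_ms: 10,
             increment_ms: 0, refractory_ms: 200, front_end: half_wave,
             sampling_frequency: 6250}
          - {mode: switch, debounce_time_ms: 20, refractory_ms: 100}
    """
    channels = [_channel_from_dict(c) for c in d.get("channels", [{}])]
    return DeviceConfig(
        channels,
        trigger_cost=float(d.get("trigger_cost", 16.5)),
        switch_cost=float(d.get("switch_cost", 0.5)),
        loop_overhead=float(d.get("loop_overhead", 0.0)),
        rate_menu=tuple(d["rate_menu"]) if "rate_menu" in d else DeviceConfig.__dataclass_fields__["rate_menu"].default,
    )


def load_device_config(path) -> DeviceConfig:
    with open(path) as fh:
        return device_from_dict(yaml.safe_load(fh) or {})


def write_manifest(outdir, command: str, params: dict, seed=None) -> Path:
    """Record everything needed to rerun a command in ``outdir/manifest.json``."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package": "triggerbench",
        "version": __version__,
        "seed": seed,
        "params": {k: _jsonable(v) for k, v in params.items()},
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _jsonable(v):
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, Path):
        return str(v)
    return v
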