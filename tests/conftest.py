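"""Shared fixtures and independent reference implementations.

The reference trigger machine below is deliberately naive: it walks a 1 µs
time grid restricted to the tick instants and re-derives every condition
from the full event history on each tick (no incremental state), so it can
serve as an oracle for the production state machine.
"""

from __future__ import annotations

import numpy as np
import pytest


def naive_trigger(config, samples, times_us):
    """Brute-force trigger reference: history-based re-evaluation per tick.

    Walks integer-µs time, acting only at tick instants; recomputes the
    supra-sample history and onset history from scratch instead of carrying
    the emulator's compact state.  Returns (onset times, offset times) µs.
    """
    ticks = {int(round(t)): s for s, t in zip(samples, times_us)}
    if not ticks:
        return [], []
    onsets, offsets = [], []
    onset_history: list[int] = []
    supra_history: list[int] = []  # supra ticks since the current pulse began
    output_high = False
    for t in range(min(ticks), max(ticks) + 1):
        if t not in ticks:
            continue
        supra = ticks[t] > config.threshold
        if output_high:
            if supra:
                supra_history.append(t)
            pulse_start = onset_history[-1]
            last_supra = max(supra_history)
            if (
                t - pulse_start >= config.min_pulse_duration
                and t - last_supra >= config.pulse_increment
            ):
                output_high = False
                offsets.append(t)
        elif supra:
            ok = all(t - o >= config.refractory_period for o in onset_history)
            if ok:
                output_high = True
                onset_history.append(t)
                supra_history = [t]
                onsets.append(t)
    return onsets, offsets


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
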