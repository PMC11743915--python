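"""Latency/jitter measurement pipeline for digitizer recordings.

Mirrors the bench analysis used to characterize a hardware trigger box:

1. stimulus onsets are detected as the first sample at which the absolute
   sample-to-sample voltage change exceeds a threshold;
2. the raw estimates are *group-corrected* (Woody-style realignment): each
   time-locked epoch is shifted to the lag that maximizes its correlation
   with the mean epoch, iterating until the shifts settle, so that the
   estimates are not unduly driven by small peri-threshold voltage noise;
3. TTL output edges are read off the digitized pulse line with sub-sample
   linear interpolation;
4. paired input-to-output latencies are summarized as mean/S.D./min/max.

Traces and onset arguments are in seconds; reports and pulse trains are in
microseconds, the scale on which the latencies live.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .signal_bank import DigitizedTrace
from .trigger_core import PulseTrain

__all__ = [
    "EpochSet",
    "TimingReport",
    "detect_onsets",
    "group_correct",
    "edge_times",
    "latency_stats",
    "extract_epochs",
]


@dataclass
class EpochSet:
    """A stack of equal-length time-locked epochs."""

    epochs: np.ndarray                 # (n_events, n_samples)
    window: tuple[float, float]        # (pre, post) seconds relative to alignment
    align_times: np.ndarray            # seconds, strictly increasing
    rate: float
    true_shifts: np.ndarray | None = None   # ground truth, when simulated

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        self.align_times = np.asarray(self.align_times, dtype=float)
        if len(self.align_times) != self.epochs.shape[0]:
            raise ValueError("one alignment time per epoch required")
        if len(self.align_times) > 1 and np.any(np.diff(self.align_times) <= 0):
            raise ValueError("alignment times must strictly increase")

    @property
    def times(self) -> np.ndarray:
        """Epoch-relative sample times in seconds."""
        n = self.epochs.shape[1]
        return self.window[0] + np.arange(n) / self.rate


@dataclass
class TimingReport:
    """Summary statistics (µs) over n paired measurements."""

    n: int
    mean: float
    sd: float
    min: float
    max: float
    n_unpaired: int = 0

    def __post_init__(self) -> None:
        if self.n > 0 and not (self.min <= self.mean <= self.max):
            raise ValueError("inconsistent report: mean outside [min, max]")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_us": self.mean,
            "sd_us": self.sd,
            "min_us": self.min,
            "max_us": self.max,
            "n_unpaired": self.n_unpaired,
        }


def detect_onsets(
    trace: DigitizedTrace,
    diff_threshold: float,
    min_separation: float = 0.100,
) -> np.ndarray:
    """Event onsets (s) via the sample-to-sample-change criterion.

    The onset estimate for each event is the time of the first sample at
    which ``|v[k] - v[k-1]|`` exceeds ``diff_threshold``; further detections
    within ``min_separation`` seconds belong to the same event and are
    suppressed.
    """
    if diff_threshold <= 0:
        raise ValueError("diff_threshold must be positive")
    v = np.asarray(trace.values, dtype=float)
    if len(v) < 2:
        return np.zeros(0)
    hits = np.flatnonzero(np.abs(np.diff(v)) > diff_threshold) + 1
    if len(hits) == 0:
        return np.zeros(0)
    keep = [hits[0]]
    gap = min_separation * trace.rate
    for h in hits[1:]:
        if h - keep[-1] >= gap:
            keep.append(h)
    return trace.start_time + np.asarray(keep) / trace.rate


def extract_epochs(
    trace: DigitizedTrace,
    onsets: np.ndarray,
    window: tuple[float, float],
) -> EpochSet:
    """Cut equal-length epochs around the given onsets (edge-padded with zeros)."""
    pre, post = window
    v = np.asarray(trace.values, dtype=float)
    n_samp = int(round((post - pre) * trace.rate))
    out = np.zeros((len(onsets), n_samp))
    for k, onset in enumerate(np.asarray(onsets, dtype=float)):
        i0 = int(round((onset - trace.start_time + pre) * trace.rate))
        lo, hi = max(i0, 0), min(i0 + n_samp, len(v))
        if hi > lo:
            out[k, lo - i0 : hi - i0] = v[lo:hi]
    return EpochSet(out, window, np.asarray(onsets, dtype=float), trace.rate)


def _best_lag(segment: np.ndarray, template: np.ndarray, max_lag: int) -> int:
    """Lag (samples) maximizing Pearson correlation of template with segment.

    ``segment`` is the epoch extended by ``max_lag`` samples on both sides.
    Ties are broken toward the smallest |lag| (prefer the original estimate).
    """
    n = len(template)
    windows = np.lib.stride_tricks.sliding_window_view(segment, n)  # (2*max_lag+1, n)
    wz = windows - windows.mean(axis=1, keepdims=True)
    tz = template - template.mean()
    denom = np.sqrt((wz ** 2).sum(axis=1)) * np.sqrt((tz ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, wz @ tz / denom, -np.inf)
    lags = np.arange(-max_lag, max_lag + 1)
    best = np.flatnonzero(r == r.max())
    return int(lags[best[np.argmin(np.abs(lags[best]))]])


def group_correct(
    trace: DigitizedTrace,
    onsets: np.ndarray,
    window: tuple[float, float] = (-0.001, 0.005),
    max_shift: float = 0.002,
    max_iter: int = 10,
) -> np.ndarray:
    """Realign onset estimates to maximize correlation with the mean epoch.

    Iteratively: extract epochs at the current onsets, form the (full) mean
    epoch, shift each onset within ±``max_shift`` to the correlation-
    maximizing lag, and repeat until every shift is zero or ``max_iter``
    sweeps have run.  Fewer than two onsets are returned unchanged.
    """
    onsets = np.asarray(onsets, dtype=float).copy()
    if len(onsets) < 2:
        return onsets
    if max_shift <= 0:
        raise ValueError("max_shift must be positive")
    max_lag = int(round(max_shift * trace.rate))
    pre, post = window
    ext = (pre - max_lag / trace.rate, post + max_lag / trace.rate)
    for _ in range(max_iter):
        core = extract_epochs(trace, onsets, window)
        template = core.epochs.mean(axis=0)
        extended = extract_epochs(trace, onsets, ext)
        shifts = np.array(
            [_best_lag(seg, template, max_lag) for seg in extended.epochs]
        )
        if not shifts.any():
            break
        onsets = onsets + shifts / trace.rate
    return onsets


def edge_times(
    ttl: DigitizedTrace,
    logic_threshold: Optional[float] = None,
    line_id: str = "ttl",
) -> PulseTrain:
    """Rising/falling edges (µs) of a digitized TTL line.

    ``logic_threshold`` defaults to 50 % of the observed high level.  Edge
    times are interpolated linearly between the two samples bracketing each
    crossing, giving sub-sample precision.  A final pulse that never falls
    is flagged open-ended.
    """
    v = np.asarray(ttl.values, dtype=float)
    if len(v) == 0:
        return PulseTrain(np.zeros(0), np.zeros(0), line_id)
    if logic_threshold is None:
        logic_threshold = 0.5 * v.max()
        if logic_threshold <= v.min():
            return PulseTrain(np.zeros(0), np.zeros(0), line_id)
    high = v > logic_threshold
    flips = np.flatnonzero(high[1:] != high[:-1])
    t = ttl.times
    crossings = []
    for i in flips:
        frac = (logic_threshold - v[i]) / (v[i + 1] - v[i])
        crossings.append((t[i] + frac / ttl.rate, high[i + 1]))
    rises = np.array([c for c, up in crossings if up])
    falls = np.array([c for c, up in crossings if not up])
    if high[0]:  # started mid-pulse: drop the orphan leading fall
        falls = falls[1:] if len(falls) else falls
    open_end = len(rises) == len(falls) + 1
    return PulseTrain(rises * 1e6, falls * 1e6, line_id, open_end=open_end)


def latency_stats(
    input_onsets: np.ndarray,
    output_onsets: np.ndarray,
    pairing_window: float = 0.050,
) -> TimingReport:
    """Input-to-output latency statistics (µs).

    Each input onset is paired with the nearest *following* output onset no
    more than ``pairing_window`` seconds later; inputs with no such output
    are counted as unpaired and excluded.  The S.D. is the sample standard
    deviation (ddof=1) over the paired differences.
    """
    if pairing_window <= 0:
        raise ValueError("pairing_window must be positive")
    inp = np.sort(np.asarray(input_onsets, dtype=float))
    out = np.sort(np.asarray(output_onsets, dtype=float))
    lat = []
    unpaired = 0
    idx = np.searchsorted(out, inp, side="left")
    for t_in, j in zip(inp, idx):
        if j < len(out) and out[j] - t_in <= pairing_window:
            lat.append(out[j] - t_in)
        else:
            unpaired += 1
    if not lat:
        raise ValueError("no input/output pairs found within the pairing window")
    lat_us = np.asarray(lat) * 1e6
    sd = float(lat_us.std(ddof=1)) if len(lat_us) > 1 else 0.0
    return TimingReport(
        n=len(lat_us),
        mean=float(lat_us.mean()),
        sd=sd,
        min=float(lat_us.min()),
        max=float(lat_us.max()),
        n_unpaired=unpaired,
    )
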