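"""Effect of stimulus-latency jitter on event-related-potential averages.

An ERP difference wave (e.g. distractor minus standard in an auditory
oddball) is modeled as a sum of bell-shaped components — by default a
mismatch negativity (MMN, a negative peak expected 100–250 ms after
stimulus onset) and a P3a (a positive peak near 300 ms).  Single trials
are the template shifted by a per-trial stimulus latency (a constant
software/audio delay plus normally distributed jitter) plus additive
noise.  Time-locked averaging then smears the components: the expected
average is exactly the template convolved with the latency density, so a
large latency S.D. (tens of ms) visibly delays, widens and attenuates the
peaks — the contrast between software-locked and hardware-locked averages.

Component amplitudes/widths are demo defaults, not measured values.
Times are milliseconds, amplitudes microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .timing_analysis import EpochSet

__all__ = [
    "ERPComponent",
    "ERPTemplate",
    "make_template",
    "simulate_epochs",
    "average_epochs",
    "smear_oracle",
    "peak_metrics",
    "peak_latency_se",
    "DEFAULT_COMPONENTS",
]


@dataclass(frozen=True)
class ERPComponent:
    """One bell-shaped ERP component (Gaussian in time).

    ``amplitude`` is signed (negative for the MMN); ``width`` is the
    Gaussian standard deviation in ms.
    """

    amplitude: float   # µV, signed
    latency: float     # ms post-stimulus
    width: float       # ms (Gaussian sd)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("component width must be positive")


#: Demo difference-wave components: MMN −3 µV at 175 ms, P3a +5 µV at 300 ms.
DEFAULT_COMPONENTS = (
    ERPComponent(-3.0, 175.0, 40.0),
    ERPComponent(+5.0, 300.0, 60.0),
)


@dataclass
class ERPTemplate:
    """Analytic ERP waveform with a default sampling grid."""

    components: Sequence[ERPComponent] = DEFAULT_COMPONENTS
    rate: float = 300.0                       # Hz, EEG sampling rate
    span: tuple[float, float] = (-100.0, 800.0)  # ms

    @property
    def times(self) -> np.ndarray:
        """Grid times in ms."""
        step = 1000.0 / self.rate
        return np.arange(self.span[0], self.span[1] + step / 2, step)

    def waveform(self, t_ms=None) -> np.ndarray:
        """Evaluate the template at arbitrary times (ms); grid by default."""
        t = self.times if t_ms is None else np.asarray(t_ms, dtype=float)
        out = np.zeros_like(t, dtype=float)
        for c in self.components:
            out += c.amplitude * np.exp(-0.5 * ((t - c.latency) / c.width) ** 2)
        return out


def make_template(
    components: Sequence[ERPComponent] = DEFAULT_COMPONENTS,
    rate: float = 300.0,
    span: tuple[float, float] = (-100.0, 800.0),
) -> ERPTemplate:
    """Build an ERP difference-wave template from bell-shaped components."""
    return ERPTemplate(tuple(components), rate, span)


def simulate_epochs(
    template: ERPTemplate,
    n: int,
    noise_sd: float = 10.0,
    latency_offset: float = 0.0,
    latency_jitter_sd: float = 0.0,
    seed=None,
) -> EpochSet:
    """Draw ``n`` single-trial epochs with per-trial latency shifts.

    Each epoch is the template evaluated at ``t - shift`` (continuous
    evaluation, so non-integer shifts are exact) plus white noise, where
    ``shift ~ offset + Normal(0, jitter_sd)`` in ms.  The true shifts are
    retained on the returned :class:`EpochSet` for oracle tests.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = template.times
    shifts = latency_offset + (
        rng.normal(0.0, latency_jitter_sd, size=n) if latency_jitter_sd > 0 else np.zeros(n)
    )
    epochs = np.stack([template.waveform(t - s) for s in shifts])
    if noise_sd > 0:
        epochs = epochs + rng.normal(0.0, noise_sd, size=epochs.shape)
    return EpochSet(
        epochs,
        window=(template.span[0] / 1000.0, template.span[1] / 1000.0),
        align_times=np.arange(n, dtype=float),  # trial index stands in for clock time
        rate=template.rate,
        true_shifts=shifts,
    )


def average_epochs(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise time-locked average and its standard error."""
    x = epochs.epochs
    if x.shape[0] == 0:
        raise ValueError("cannot average zero epochs")
    mean = x.mean(axis=0)
    if x.shape[0] >= 2:
        sem = x.std(axis=0, ddof=1) / np.sqrt(x.shape[0])
    else:
        sem = np.full_like(mean, np.nan)
    return mean, sem


def smear_oracle(
    template: ERPTemplate,
    density: Callable[[np.ndarray], np.ndarray],
    support: tuple[float, float],
    n_points: int = 4001,
) -> np.ndarray:
    """Exact expected time-locked average: template ⊛ latency density.

    ``density`` is a pdf over the latency shift in ms and ``support`` the
    interval (ms) outside which it is negligible; the convolution
    ``∫ template(t − s)·p(s) ds`` is evaluated by the trapezoid rule on the
    template's grid.  A point mass (delta density) is the identity.
    """
    s = np.linspace(support[0], support[1], n_points)
    p = np.asarray(density(s), dtype=float)
    mass = np.trapezoid(p, s)
    if not np.isclose(mass, 1.0, atol=0.02):
        raise ValueError(f"density integrates to {mass:.4f}, expected 1")
    p = p / mass
    t = template.times
    # rows: grid times; cols: shift quadrature points
    vals = template.waveform(t[:, None] - s[None, :])
    return np.trapezoid(vals * p[None, :], s, axis=1)


def peak_metrics(
    waveform: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float],
    polarity: str = "auto",
) -> tuple[float, float]:
    """Extremum amplitude and latency within a search window.

    ``polarity`` is ``'negative'``, ``'positive'`` or ``'auto'`` (largest
    absolute excursion).  Ties — including a flat waveform — resolve to the
    earliest time in the window, so a flat segment reports amplitude 0 at
    the window start.
    """
    times = np.asarray(times, dtype=float)
    waveform = np.asarray(waveform, dtype=float)
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError("search window contains no samples")
    w, t = waveform[mask], times[mask]
    if polarity == "negative":
        score = -w
    elif polarity == "positive":
        score = w
    elif polarity == "auto":
        score = np.abs(w)
    else:
        raise ValueError("polarity must be 'negative', 'positive' or 'auto'")
    i = int(np.argmax(score))  # argmax takes the first (earliest) maximizer
    return float(w[i]), float(t[i])


def peak_latency_se(
    epochs: EpochSet,
    window: tuple[float, float],
    polarity: str,
    times: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Bootstrap standard error of the averaged waveform's peak latency.

    The latency of a broad, noisy peak is a nonlinear statistic of the
    average; resampling epochs with replacement gives its sampling
    spread directly (the argmax of a shallow extremum can wander far more
    than the mean latency would suggest).
    """
    x = epochs.epochs
    rng = np.random.default_rng(seed)
    lats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, x.shape[0], x.shape[0])
        m = x[idx].mean(axis=0)
        lats[b] = peak_metrics(m, times, window, polarity)[1]
    return float(lats.std(ddof=1))
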