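"""Synthetic epileptiform iEEG with exact seizure annotations.

Real chronic-epilepsy recordings are not redistributable, so this module
fabricates single-channel traces that carry the statistical structure a
seizure detector has to exploit:

* background — 1/f^alpha ("colored") Gaussian noise, the canonical coarse
  model of interictal EEG spectra, sprinkled with sporadic biphasic
  interictal spikes at a Poisson rate;
* seizure events — a repetitive biphasic spike train at >= 3 Hz whose mean
  absolute amplitude is raised a configurable factor above background, with
  a brief low-amplitude onset ramp and a decay back to baseline at offset
  (electrographic seizures here are bounded by baseline suppression at onset
  and amplitude restoration at offset).

Everything is driven by a single integer seed: identical configs produce
bit-identical records and annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import EEGRecord, SeizureAnnotation

__all__ = ["SynthConfig", "generate_background", "generate_seizure", "assemble_record"]

#: background RMS in microvolts; an arbitrary but fixed physiological scale
_BG_RMS_UV = 50.0


@dataclass
class SynthConfig:
    """Knobs of the generator.

    duration_range_s defaults to the span of annotated event durations in the
    chronic mouse recordings this simulator stands in for (8.34-61.25 s).
    min_event_gap_s defaults to 360 s so the +/-5-min non-seizure flanks used
    for training-segment collection never reach a neighbouring event.
    """

    total_duration_s: float = 3600.0
    fs: float = 1000.0
    n_events: int = 3
    duration_range_s: tuple[float, float] = (8.34, 61.25)
    spike_freq_hz: tuple[float, float] | float = (3.0, 8.0)
    amplitude_gain: float = 2.0
    interictal_spike_rate_hz: float = 0.05
    noise_exponent: float = 1.0
    min_event_gap_s: float = 360.0
    edge_margin_s: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_duration_s <= 0 or self.fs <= 0:
            raise ValueError("total_duration_s and fs must be positive")
        lo, hi = self.duration_range_s
        if lo < 5:
            raise ValueError("duration_range_s lower bound must be >= 5 s")
        if lo > hi:
            raise ValueError("duration_range_s must be (low, high)")
        f = self.spike_freq_hz
        fmin = f[0] if isinstance(f, (tuple, list)) else f
        if fmin < 3:
            raise ValueError("spike_freq_hz must be >= 3 Hz (repetitive epileptiform spiking)")
        if self.amplitude_gain <= 1:
            raise ValueError("amplitude_gain must exceed 1")
        if self.n_events < 0 or self.interictal_spike_rate_hz < 0:
            raise ValueError("counts and rates must be non-negative")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


def _biphasic_spike(fs: float, width_s: float = 0.08) -> np.ndarray:
    """Sharp positive lobe followed by a slower negative after-wave."""
    n = max(int(round(width_s * fs)), 3)
    t = np.linspace(0, 1, n)
    pos = np.exp(-((t - 0.25) ** 2) / (2 * 0.06**2))
    neg = -0.6 * np.exp(-((t - 0.6) ** 2) / (2 * 0.15**2))
    w = pos + neg
    return w - w.mean()


def generate_background(duration_s: float, fs: float, config: SynthConfig, stream: int = 1) -> np.ndarray:
    """Zero-mean 1/f^alpha noise plus Poisson-timed interictal spikes.

    The spectral shaping multiplies the rFFT of white noise by f^(-alpha/2)
    (DC excluded), so the power spectral density falls as f^(-alpha).
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    n = int(round(duration_s * fs))
    rng = config.rng(stream)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-config.noise_exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    x *= _BG_RMS_UV / max(x.std(), 1e-12)

    if config.interictal_spike_rate_hz > 0:
        n_spikes = rng.poisson(config.interictal_spike_rate_hz * duration_s)
        spike = _biphasic_spike(fs)
        amp = 4.0 * _BG_RMS_UV
        for t0 in rng.uniform(0, max(duration_s - 0.1, 0), size=n_spikes):
            i0 = int(t0 * fs)
            seg = spike[: n - i0]
            x[i0 : i0 + seg.size] += amp * rng.uniform(0.7, 1.3) * seg * rng.choice([-1.0, 1.0])
    return x - x.mean()


def generate_seizure(
    duration_s: float,
    fs: float,
    config: SynthConfig,
    stream: int = 2,
    background_mean_abs: float | None = None,
) -> np.ndarray:
    """One seizure stretch: ramped repetitive spiking above background amplitude.

    The trace is scaled so its mean absolute amplitude equals
    ``amplitude_gain`` times the background's mean absolute amplitude, which
    keeps the downstream 1.2x amplitude gate of the event detector satisfiable
    by construction (default gain 2.0).
    """
    if duration_s < 5:
        raise ValueError("seizure duration must be >= 5 s")
    n = int(round(duration_s * fs))
    rng = config.rng(stream)
    f = config.spike_freq_hz
    spike_freq = rng.uniform(*f) if isinstance(f, (tuple, list)) else float(f)

    # impulse train with slight cycle-to-cycle jitter, convolved with a spike
    period = 1.0 / spike_freq
    times, t = [], rng.uniform(0, period / 4)
    while t < duration_s:
        times.append(t)
        t += period * rng.uniform(0.95, 1.05)
    impulses = np.zeros(n)
    idx = np.minimum((np.asarray(times) * fs).astype(int), n - 1)
    impulses[idx] = rng.uniform(0.8, 1.2, size=idx.size)
    # spike-wave complex spanning ~one cycle: keeps the spectral fundamental
    # at the repetition rate rather than at a harmonic
    spike = _biphasic_spike(fs, width_s=0.9 * period)
    x = np.convolve(impulses, spike)[:n]

    # envelope: 0.5-s onset suppression ramp, 1-s offset decay to baseline
    tt = np.arange(n) / fs
    env = np.ones(n)
    env = np.minimum(env, np.clip(tt / 0.5, 0.05, 1.0))
    env = np.minimum(env, np.clip((duration_s - tt) / 1.0, 0.05, 1.0))
    x = x * env
    x += 0.15 * rng.standard_normal(n) * x.std()  # ictal noise floor

    if background_mean_abs is None:
        background_mean_abs = _BG_RMS_UV * np.sqrt(2 / np.pi)  # Gaussian E|x|
    target = config.amplitude_gain * background_mean_abs
    x *= target / max(np.mean(np.abs(x)), 1e-12)
    return x


def _place_events(config: SynthConfig, durations: Sequence[float], rng: np.random.Generator) -> list[float]:
    """Random event onsets with pairwise gaps >= min_event_gap_s."""
    T, m = config.total_duration_s, config.edge_margin_s
    gap = config.min_event_gap_s
    need = sum(durations) + gap * max(len(durations) - 1, 0) + 2 * m
    if need > T:
        raise ValueError(
            f"config infeasible: {len(durations)} events need {need:.0f} s "
            f"(durations + {gap:.0f}-s gaps + margins) but record is {T:.0f} s"
        )
    slack = T - need
    # split the slack uniformly over the n+1 inter-event spaces
    cuts = np.sort(rng.uniform(0, slack, size=len(durations)))
    onsets, cursor = [], m
    prev_cut = 0.0
    for d, c in zip(durations, cuts):
        cursor += c - prev_cut
        onsets.append(cursor)
        cursor += d + gap
        prev_cut = c
    return onsets


def assemble_record(config: SynthConfig) -> tuple[EEGRecord, SeizureAnnotation]:
    """Background trace with ``n_events`` annotated seizures spliced in.

    Returns the record plus annotations sorted, non-overlapping, separated by
    at least ``min_event_gap_s``, every duration inside ``duration_range_s``.
    """
    rng = config.rng(0)
    bg = generate_background(config.total_duration_s, config.fs, config, stream=1)
    bg_mean_abs = float(np.mean(np.abs(bg)))
    x = bg.copy()

    durations = rng.uniform(*config.duration_range_s, size=config.n_events)
    onsets = _place_events(config, durations, rng) if config.n_events else []

    events = []
    for k, (a, d) in enumerate(zip(onsets, durations)):
        sz = generate_seizure(d, config.fs, config, stream=10 + k, background_mean_abs=bg_mean_abs)
        i0 = int(round(a * config.fs))
        # replace (not add): ictal activity dominates the electrode, with a
        # residual 20% of background bleeding through
        x[i0 : i0 + sz.size] = sz + 0.2 * bg[i0 : i0 + sz.size]
        events.append((a, a + d))

    record = EEGRecord(samples=x, fs=config.fs, record_id=f"synth-{config.seed}")
    return record, SeizureAnnotation(events).validate_against(record)
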