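"""Synthetic GCaMP ΔF/F traces with Poisson-timed transients.

Transients use a linear rise over ``rise_s`` followed by an exponential
decay with time constant ``decay_tau_s``, so the continuous-time area of
one event is analytic: amplitude × (decay_tau_s + rise_s / 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..calcium import FluorescenceTrace


@dataclass(frozen=True)
class TraceGenSpec:
    duration_s: float = 300.0
    frame_rate_hz: float = 1.0
    transient_rate_per_min: float = 0.13
    amplitude_dff: float = 0.4
    decay_tau_s: float = 8.0
    rise_s: float = 1.0
    noise_sd_dff: float = 0.02
    drift_amplitude_dff: float = 0.0
    drift_period_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.noise_sd_dff < 0:
            raise ValueError("noise_sd_dff must be >= 0")
        if self.transient_rate_per_min < 0:
            raise ValueError("transient_rate_per_min must be >= 0")
        if not (self.decay_tau_s > 0 and self.rise_s >= 0):
            raise ValueError("decay_tau_s must be > 0 and rise_s >= 0")


@dataclass(frozen=True)
class TransientTruth:
    """One injected transient: onset (s), peak amplitude, analytic area."""

    onset_s: float
    amplitude_dff: float
    area_dff_s: float


def transient_kernel(t_since_onset: np.ndarray, spec: TraceGenSpec) -> np.ndarray:
    """Noiseless transient waveform evaluated at times since onset (s)."""
    t = np.asarray(t_since_onset, dtype=float)
    out = np.zeros_like(t)
    if spec.rise_s > 0:
        rising = (t >= 0) & (t < spec.rise_s)
        out[rising] = spec.amplitude_dff * t[rising] / spec.rise_s
    decaying = t >= spec.rise_s
    out[decaying] = spec.amplitude_dff * np.exp(-(t[decaying] - spec.rise_s) / spec.decay_tau_s)
    return out


def gen_trace(spec: TraceGenSpec) -> tuple[FluorescenceTrace, list[TransientTruth]]:
    """Simulate one ΔF/F trace; returns (trace, ground-truth transients).

    Onsets are a homogeneous Poisson process at
    ``transient_rate_per_min``; Gaussian noise and an optional sinusoidal
    drift are added on top of the summed transient kernels.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration_s * spec.frame_rate_hz))
    times = np.arange(n_frames) / spec.frame_rate_hz

    n_events = rng.poisson(spec.transient_rate_per_min * spec.duration_s / 60.0)
    onsets = np.sort(rng.uniform(0.0, spec.duration_s, size=n_events))

    dff = np.zeros(n_frames)
    truth: list[TransientTruth] = []
    area = spec.amplitude_dff * (spec.decay_tau_s + spec.rise_s / 2.0)
    for onset in onsets:
        dff += transient_kernel(times - onset, spec)
        truth.append(TransientTruth(float(onset), spec.amplitude_dff, area))

    if spec.drift_amplitude_dff:
        dff += spec.drift_amplitude_dff * np.sin(2.0 * np.pi * times / spec.drift_period_s)
    if spec.noise_sd_dff:
        dff += rng.normal(0.0, spec.noise_sd_dff, size=n_frames)

    return FluorescenceTrace(dff, spec.frame_rate_hz, is_dff=True), truth
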