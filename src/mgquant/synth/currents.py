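"""Synthetic voltage-clamp current traces with Poisson-timed PSC events.

Events use a double-exponential kernel normalised to unit peak; the event
rate switches from ``event_rate_pre_hz`` to ``event_rate_post_hz`` at
``ttx_onset_s``, and an optional agonist-induced holding-current step is
added after ``agonist_onset_s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..ephys import CurrentTrace, SynapticEventList


@dataclass(frozen=True)
class EphysGenSpec:
    duration_s: float = 60.0
    sample_rate_hz: float = 20000.0
    event_rate_pre_hz: float = 2.0
    event_rate_post_hz: float = 1.0
    ttx_onset_s: float | None = None
    amplitude_mean_pA: float = 30.0
    amplitude_sd_pA: float = 5.0
    rise_ms: float = 0.5
    decay_ms: float = 5.0
    noise_sd_pA: float = 3.0
    holding_pA: float = -100.0
    agonist_step_pA: float = 0.0
    agonist_onset_s: float | None = None
    polarity: str = "inward"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_rate_pre_hz < 0 or self.event_rate_post_hz < 0:
            raise ValueError("event rates must be >= 0")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not (self.decay_ms > self.rise_ms > 0):
            raise ValueError("require decay_ms > rise_ms > 0")


def psc_kernel(t_s: np.ndarray, rise_ms: float, decay_ms: float) -> np.ndarray:
    """Unit-peak double-exponential PSC waveform for t >= 0."""
    tau_r, tau_d = rise_ms / 1000.0, decay_ms / 1000.0
    t = np.asarray(t_s, dtype=float)
    raw = np.where(t >= 0, np.exp(-t / tau_d) - np.exp(-t / tau_r), 0.0)
    t_peak = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    peak = np.exp(-t_peak / tau_d) - np.exp(-t_peak / tau_r)
    return raw / peak


def _sample_events(spec: EphysGenSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Poisson event times with a rate switch at ttx_onset_s, plus amplitudes."""
    switch = spec.ttx_onset_s if spec.ttx_onset_s is not None else spec.duration_s
    switch = min(max(switch, 0.0), spec.duration_s)
    n_pre = rng.poisson(spec.event_rate_pre_hz * switch)
    n_post = rng.poisson(spec.event_rate_post_hz * (spec.duration_s - switch))
    times = np.sort(np.concatenate([
        rng.uniform(0.0, switch, size=n_pre),
        rng.uniform(switch, spec.duration_s, size=n_post),
    ]))
    amplitudes = np.abs(rng.normal(spec.amplitude_mean_pA, spec.amplitude_sd_pA, times.size))
    return times, amplitudes


def gen_event_train(spec: EphysGenSpec) -> SynapticEventList:
    """Ground-truth event train only, without rendering current samples.

    Useful for estimator statistics over many long traces where rendering
    20-kHz samples would dominate the cost.
    """
    rng = np.random.default_rng(spec.seed)
    times, amplitudes = _sample_events(spec, rng)
    return SynapticEventList(times, amplitudes, spec.polarity)


def gen_current(spec: EphysGenSpec) -> tuple[CurrentTrace, SynapticEventList]:
    """Simulate one trace; returns (trace, ground-truth events).

    Ground-truth times are kernel onsets; amplitudes are the injected peak
    magnitudes (pA).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    samples = np.full(n, float(spec.holding_pA))

    times, amplitudes = _sample_events(spec, rng)
    sign = -1.0 if spec.polarity == "inward" else 1.0

    window = int(round(8.0 * spec.decay_ms / 1000.0 * spec.sample_rate_hz))
    kernel_t = np.arange(window) / spec.sample_rate_hz
    kernel = psc_kernel(kernel_t, spec.rise_ms, spec.decay_ms)
    for t0, amp in zip(times, amplitudes):
        i0 = int(round(t0 * spec.sample_rate_hz))
        i1 = min(i0 + window, n)
        if i0 < n:
            samples[i0:i1] += sign * amp * kernel[: i1 - i0]

    if spec.agonist_step_pA and spec.agonist_onset_s is not None:
        onset_i = int(round(spec.agonist_onset_s * spec.sample_rate_hz))
        samples[onset_i:] += spec.agonist_step_pA
    if spec.noise_sd_pA:
        samples += rng.normal(0.0, spec.noise_sd_pA, size=n)

    trace = CurrentTrace(
        samples_pA=samples,
        sample_rate_hz=spec.sample_rate_hz,
        ttx_onset_s=spec.ttx_onset_s,
        agonist_onset_s=spec.agonist_onset_s,
        polarity=spec.polarity,
    )
    return trace, SynapticEventList(times, amplitudes, spec.polarity)
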