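"""Voltage-clamp current analysis and solution chemistry.

Covers postsynaptic-current event detection on 20-kHz traces (with the
standard offline 2-kHz zero-phase low-pass), frequency comparison across
TTX application windows (180 s baseline vs 180 s starting 100 s after
onset), holding-current estimation by fitting a Gaussian to the histogram
of a 20-s segment, agonist-induced holding-current shifts, and Nernst
reversal potentials computed from solution recipes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit

GAS_CONSTANT = 8.31446261815324      # J/(mol K)
FARADAY = 96485.33212                # C/mol

#: Chloride ions released per formula unit in solution.
CL_STOICHIOMETRY = {
    "KCl": 1, "NaCl": 1, "CaCl2": 2, "MgCl2": 2, "choline-Cl": 1, "HCl": 1,
}

DEFAULT_TEMP_C = 33.0  # midpoint of the 32-34 °C bath range


class InsufficientCoverageError(ValueError):
    """The trace does not span a required analysis window."""


@dataclass
class SolutionRecipe:
    """Named components with molarities (mM) and derived ionic totals.

    Only chloride salts (KCl, NaCl, CaCl₂, MgCl₂, ...) contribute Cl⁻;
    gluconate, HEPES, phosphates and nucleotides contribute none.
    Component names are matched case-sensitively against the
    stoichiometry table; unknown components contribute zero Cl⁻.
    """

    name: str
    components_mM: dict[str, float]

    def __post_init__(self) -> None:
        for comp, mM in self.components_mM.items():
            if mM < 0:
                raise ValueError(f"negative molarity for {comp}")

    def chloride_mM(self) -> float:
        return sum(
            mM * CL_STOICHIOMETRY.get(comp, 0)
            for comp, mM in self.components_mM.items()
        )


# Printed recipes (concentrations in mM).
EXCITATORY_INTERNAL = SolutionRecipe("excitatory_internal", {
    "K-gluconate": 132.3, "KCl": 7.7, "NaCl": 4, "CaCl2": 0.5,
    "HEPES": 10, "EGTA": 5, "MgATP": 4, "Na2GTP": 0.5,
})
INHIBITORY_INTERNAL = SolutionRecipe("inhibitory_internal", {
    "K-gluconate": 140, "NaCl": 1.4, "MgCl2": 1.5, "CaCl2": 0.5,
    "HEPES": 10, "EGTA": 0.2, "MgATP": 4, "Na2GTP": 0.5,
})
ACSF = SolutionRecipe("aCSF", {
    "NaCl": 124, "KCl": 2.5, "NaHCO3": 26, "NaH2PO4": 1,
    "glucose": 10, "CaCl2": 1, "MgCl2": 2,
})


def nernst(
    valence: int,
    conc_in_mM: float,
    conc_out_mM: float,
    temp_C: float = DEFAULT_TEMP_C,
) -> float:
    """Nernst reversal potential E = (RT/zF)·ln([out]/[in]) in mV."""
    if conc_in_mM <= 0 or conc_out_mM <= 0:
        raise ValueError("concentrations must be positive")
    if valence == 0:
        raise ValueError("valence must be non-zero")
    temp_K = temp_C + 273.15
    volts = (GAS_CONSTANT * temp_K) / (valence * FARADAY) * math.log(conc_out_mM / conc_in_mM)
    return volts * 1000.0


def chloride_reversal(
    internal: SolutionRecipe,
    external: SolutionRecipe = ACSF,
    temp_C: float = DEFAULT_TEMP_C,
) -> float:
    """E_Cl (mV) from the chloride totals of two recipes, z = −1."""
    return nernst(-1, internal.chloride_mM(), external.chloride_mM(), temp_C)


@dataclass
class CurrentTrace:
    """Whole-cell voltage-clamp current samples with epoch markers."""

    samples_pA: np.ndarray
    sample_rate_hz: float = 20000.0
    ttx_onset_s: float | None = None
    agonist_onset_s: float | None = None
    holding_potential_mV: float | None = None
    polarity: str = "inward"

    def __post_init__(self) -> None:
        self.samples_pA = np.asarray(self.samples_pA, dtype=float)
        if self.samples_pA.size == 0:
            raise ValueError("empty trace")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.polarity not in ("inward", "outward"):
            raise ValueError("polarity must be 'inward' or 'outward'")
        for marker in (self.ttx_onset_s, self.agonist_onset_s):
            if marker is not None and not (0 <= marker <= self.duration_s):
                raise ValueError("epoch marker outside trace duration")

    @property
    def duration_s(self) -> float:
        return self.samples_pA.size / self.sample_rate_hz


@dataclass
class SynapticEventList:
    """Detected synaptic events: sorted times (s) and magnitudes (pA)."""

    times_s: np.ndarray
    amplitudes_pA: np.ndarray
    polarity: str = "inward"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.amplitudes_pA = np.asarray(self.amplitudes_pA, dtype=float)
        if self.times_s.size != self.amplitudes_pA.size:
            raise ValueError("times and amplitudes must have equal length")
        if self.times_s.size and np.any(np.diff(self.times_s) < 0):
            raise ValueError("event times must be sorted")
        if np.any(self.amplitudes_pA < 0):
            raise ValueError("amplitudes use a magnitude convention (>= 0)")

    def __len__(self) -> int:
        return self.times_s.size


@dataclass
class FrequencyComparison:
    baseline_freq_hz: float
    post_freq_hz: float
    baseline_amplitude_pA: float
    post_amplitude_pA: float
    baseline_window_s: tuple[float, float]
    post_window_s: tuple[float, float]


def lowpass_filter(samples: np.ndarray, sample_rate_hz: float, cutoff_hz: float = 2000.0) -> np.ndarray:
    """Zero-phase Butterworth low-pass (offline 2-kHz analysis filter)."""
    nyq = sample_rate_hz / 2.0
    if cutoff_hz >= nyq:
        return np.asarray(samples, dtype=float)
    sos = sps.butter(4, cutoff_hz / nyq, output="sos")
    return sps.sosfiltfilt(sos, samples)


def _running_median(samples: np.ndarray, sample_rate_hz: float, window_s: float = 0.5) -> np.ndarray:
    """Block-median baseline interpolated back to every sample."""
    n = samples.size
    block = max(1, int(round(window_s * sample_rate_hz)))
    starts = np.arange(0, n, block)
    centers = np.minimum(starts + block / 2.0, n - 1)
    medians = np.array([np.median(samples[s:s + block]) for s in starts])
    if medians.size == 1:
        return np.full(n, medians[0])
    return np.interp(np.arange(n), centers, medians)


def detect_events(
    trace: CurrentTrace,
    threshold_pA: float,
    min_interval_ms: float = 5.0,
    baseline_window_s: float = 0.5,
) -> SynapticEventList:
    """Detect postsynaptic-current events on a filtered trace.

    The trace is low-pass filtered at 2 kHz (zero-phase), a running-median
    baseline is subtracted, and events are local extrema whose deviation in
    the trace's polarity direction exceeds ``threshold_pA``, separated by
    at least ``min_interval_ms``.  Amplitudes are peak-minus-baseline
    magnitudes.
    """
    if threshold_pA <= 0:
        raise ValueError("threshold_pA must be positive")
    filtered = lowpass_filter(trace.samples_pA, trace.sample_rate_hz)
    baseline = _running_median(filtered, trace.sample_rate_hz, baseline_window_s)
    sign = -1.0 if trace.polarity == "inward" else 1.0
    deviation = sign * (filtered - baseline)
    distance = max(1, int(round(min_interval_ms / 1000.0 * trace.sample_rate_hz)))
    peaks, props = sps.find_peaks(deviation, height=threshold_pA, distance=distance)
    heights = props["peak_heights"]

    # suppress re-triggers on the decay of the previous event: a smaller
    # peak only counts if the signal dipped below half threshold in between
    keep: list[int] = []
    for i, pk in enumerate(peaks):
        if keep:
            prev = keep[-1]
            dip = deviation[peaks[prev]:pk + 1].min()
            if dip > 0.5 * threshold_pA and heights[i] <= heights[prev]:
                continue
        keep.append(i)
    peaks, heights = peaks[keep], heights[keep]

    return SynapticEventList(
        times_s=peaks / trace.sample_rate_hz,
        amplitudes_pA=heights,
        polarity=trace.polarity,
    )


def ttx_comparison(
    events: SynapticEventList,
    ttx_onset_s: float,
    duration_s: float,
    baseline_span_s: float = 180.0,
    post_delay_s: float = 100.0,
    post_span_s: float = 180.0,
) -> FrequencyComparison:
    """Event frequency before vs after TTX application.

    Baseline counts events in the ``baseline_span_s`` seconds immediately
    before onset; the post window starts ``post_delay_s`` after onset and
    spans ``post_span_s``.  Raises if the trace does not cover both
    windows.
    """
    b0, b1 = ttx_onset_s - baseline_span_s, ttx_onset_s
    p0, p1 = ttx_onset_s + post_delay_s, ttx_onset_s + post_delay_s + post_span_s
    if b0 < 0:
        raise InsufficientCoverageError(
            f"trace starts after required baseline window [{b0:.0f}, {b1:.0f}) s"
        )
    if p1 > duration_s:
        raise InsufficientCoverageError(
            f"trace ends before required post window [{p0:.0f}, {p1:.0f}) s"
        )
    t, a = events.times_s, events.amplitudes_pA
    in_base = (t >= b0) & (t < b1)
    in_post = (t >= p0) & (t < p1)
    return FrequencyComparison(
        baseline_freq_hz=float(in_base.sum()) / baseline_span_s,
        post_freq_hz=float(in_post.sum()) / post_span_s,
        baseline_amplitude_pA=float(a[in_base].mean()) if in_base.any() else math.nan,
        post_amplitude_pA=float(a[in_post].mean()) if in_post.any() else math.nan,
        baseline_window_s=(b0, b1),
        post_window_s=(p0, p1),
    )


def _gaussian(x: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def holding_current(
    samples_pA: np.ndarray,
    bin_width_pA: float | None = None,
) -> float:
    """Mean holding current of a segment via a Gaussian histogram fit.

    All samples are histogrammed (default bin width: half the robust noise
    SD, estimated by the median absolute deviation) and a single Gaussian
    is least-squares fitted; the fitted centre is returned.  If the fit
    diverges the histogram mode is returned with a warning.  Robust to
    sparse synaptic events, which occupy a small tail of the histogram.
    """
    samples = np.asarray(samples_pA, dtype=float)
    if samples.size == 0:
        raise ValueError("empty segment")
    if np.ptp(samples) == 0:
        return float(samples[0])
    if bin_width_pA is None:
        mad = float(np.median(np.abs(samples - np.median(samples))))
        noise_sd = 1.4826 * mad
        bin_width_pA = noise_sd / 2.0 if noise_sd > 0 else np.ptp(samples) / 100.0
    edges = np.arange(samples.min(), samples.max() + bin_width_pA, bin_width_pA)
    counts, edges = np.histogram(samples, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mode = centers[np.argmax(counts)]
    try:
        popt, _ = curve_fit(
            _gaussian, centers, counts,
            p0=(counts.max(), mode, max(bin_width_pA, 2.0 * bin_width_pA)),
            maxfev=5000,
        )
        return float(popt[1])
    except (RuntimeError, ValueError):
        warnings.warn("Gaussian fit diverged; falling back to histogram mode")
        return float(mode)


def agonist_current(
    trace: CurrentTrace,
    onset_s: float | None = None,
    segment_s: float = 20.0,
    scan_step_s: float = 1.0,
) -> float:
    """Agonist-induced holding-current shift (pA).

    Control = Gaussian-fit holding current over the ``segment_s`` seconds
    before ``onset_s``; the response is the post-onset ``segment_s`` window
    whose fitted holding current differs most from control.  The signed
    shift (response − control) is returned.
    """
    onset_s = trace.agonist_onset_s if onset_s is None else onset_s
    if onset_s is None:
        raise ValueError("agonist onset not specified")
    fs = trace.sample_rate_hz
    seg = int(round(segment_s * fs))
    onset_i = int(round(onset_s * fs))
    n = trace.samples_pA.size
    if onset_i < seg:
        raise InsufficientCoverageError("need a full control segment before agonist onset")
    if n - onset_i < seg:
        raise InsufficientCoverageError("need a full response segment after agonist onset")
    control = holding_current(trace.samples_pA[onset_i - seg:onset_i])
    step = max(1, int(round(scan_step_s * fs)))
    best_shift = 0.0
    for start in range(onset_i, n - seg + 1, step):
        shift = holding_current(trace.samples_pA[start:start + seg]) - control
        if abs(shift) > abs(best_shift):
            best_shift = shift
    return best_shift
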