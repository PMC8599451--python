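"""QRS quantification for murine ECG traces.

Per beat, the three deflections of ventricular depolarization are
measured: Q (negative, pre-R), R (positive), S (negative, post-R). Wave
amplitudes are signed voltages relative to the isoelectric baseline; wave
durations run from onset to offset, located where the waveform re-crosses
``baseline +/- 5%`` of that wave's peak amplitude (the crossing is
snapped to the suprathreshold sample nearer the peak).

R peaks are found by a derivative-energy detector in the Pan-Tompkins
tradition: detrend, differentiate, square, integrate over a short moving
window, threshold adaptively, and enforce a refractory period. The
detector is a replaceable strategy; its parameters live in
:class:`QRSDetectionParams`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import find_peaks

__all__ = [
    "ECGTrace",
    "WaveMeasurement",
    "QRSComplex",
    "QRSSummary",
    "QRSDetectionParams",
    "estimate_baseline",
    "detect_r_peaks",
    "segment_qrs",
    "summarize_qrs",
    "match_r_peaks",
]


@dataclass
class ECGTrace:
    """Uniformly sampled voltage series in millivolts."""

    voltage: np.ndarray  # mV
    sampling_rate: float  # Hz
    start_time: float = 0.0  # s

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=np.float64)
        if self.voltage.ndim != 1:
            raise ValueError("voltage must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not np.all(np.isfinite(self.voltage)):
            raise ValueError("voltage contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.voltage.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class WaveMeasurement:
    """One wave of a QRS complex: signed baseline-relative amplitude and
    onset-to-offset duration."""

    peak_index: int
    amplitude: float  # mV, signed, relative to baseline
    onset_index: int
    offset_index: int
    duration_ms: float

    def __post_init__(self) -> None:
        if not (self.onset_index <= self.peak_index <= self.offset_index):
            raise ValueError("wave ordering violated: onset <= peak <= offset")


@dataclass(frozen=True)
class QRSComplex:
    q: WaveMeasurement
    r: WaveMeasurement
    s: WaveMeasurement
    baseline_level: float  # mV


@dataclass(frozen=True)
class QRSSummary:
    beat_count: int
    heart_rate_bpm: float | None
    mean_amplitude: dict  # wave -> mV
    sd_amplitude: dict
    mean_duration_ms: dict
    sd_duration_ms: dict


@dataclass(frozen=True)
class QRSDetectionParams:
    refractory_ms: float = 40.0
    smoothing_ms: float = 1.0  # Gaussian derivative scale (matched to murine QRS)
    integration_window_ms: float = 6.0
    detrend_window_ms: float = 200.0
    threshold_fraction: float = 0.30
    search_window_ms: float = 50.0  # Q/S search and onset/offset walk
    onset_fraction: float = 0.05


def estimate_baseline(trace: ECGTrace) -> float:
    """Isoelectric ("electromagnetic neutral") reference level.

    The median of the whole trace: QRS complexes occupy a small fraction
    of each cardiac cycle, so the median sits on the isoelectric segment
    and is exactly translation-equivariant.
    """
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    return float(np.median(trace.voltage))


def _detrended(trace: ECGTrace, params: QRSDetectionParams) -> np.ndarray:
    win = int(round(params.detrend_window_ms / 1000.0 * trace.sampling_rate))
    win = max(3, win | 1)  # odd
    baseline = ndi.median_filter(trace.voltage, size=win, mode="nearest")
    return trace.voltage - baseline


def detect_r_peaks(
    trace: ECGTrace, params: QRSDetectionParams | None = None
) -> np.ndarray:
    """Detect R peaks; returns strictly increasing sample indices."""
    params = params or QRSDetectionParams()
    if trace.sampling_rate < 250:
        raise ValueError(
            f"sampling_rate {trace.sampling_rate} Hz too low for QRS detection (need >= 250)"
        )
    fs = trace.sampling_rate
    detrended = _detrended(trace, params)
    sigma = max(0.5, params.smoothing_ms / 1000.0 * fs)
    energy = ndi.gaussian_filter1d(detrended, sigma, order=1) ** 2
    win = max(1, int(round(params.integration_window_ms / 1000.0 * fs)))
    integ = ndi.uniform_filter1d(energy, size=win, mode="nearest")
    if integ.max() <= 0:
        return np.array([], dtype=int)
    refractory = max(1, int(round(params.refractory_ms / 1000.0 * fs)))
    threshold = params.threshold_fraction * np.percentile(integ, 99.9)
    if threshold <= 0:
        return np.array([], dtype=int)
    candidates, _ = find_peaks(integ, height=threshold, distance=refractory)
    # refine each energy peak to the local voltage maximum (the R apex)
    half = max(1, int(round(0.02 * fs)))
    peaks: list[int] = []
    for c in candidates:
        lo, hi = max(0, c - half), min(trace.n_samples, c + half + 1)
        r = lo + int(np.argmax(detrended[lo:hi]))
        if peaks and r - peaks[-1] < refractory:
            # keep the taller of two refinements that collapsed together
            if detrended[r] > detrended[peaks[-1]]:
                peaks[-1] = r
            continue
        peaks.append(r)
    return np.asarray(peaks, dtype=int)


def _wave_bounds(
    voltage: np.ndarray,
    peak: int,
    baseline: float,
    fraction: float,
    max_extent: int,
) -> tuple[int, int]:
    """Onset/offset where the wave re-crosses baseline +/- ``fraction`` of
    its peak amplitude; bounds are the outermost suprathreshold samples."""
    amp = voltage[peak] - baseline
    if amp == 0:
        return peak, peak
    level = abs(fraction * amp)
    rel = (voltage - baseline) * np.sign(amp)  # positive under the wave
    onset = peak
    while onset > 0 and peak - onset < max_extent and rel[onset - 1] >= level:
        onset -= 1
    offset = peak
    n = voltage.size
    while offset < n - 1 and offset - peak < max_extent and rel[offset + 1] >= level:
        offset += 1
    return onset, offset


def segment_qrs(
    trace: ECGTrace,
    r_peaks: np.ndarray,
    params: QRSDetectionParams | None = None,
) -> list[QRSComplex]:
    """Measure Q, R and S waves around each detected R peak.

    Q is the most negative extremum in a pre-R window, S the most negative
    extremum in a post-R window (window length ``search_window_ms``).
    Beats whose windows would cross the trace boundary are skipped with a
    warning.
    """
    params = params or QRSDetectionParams()
    fs = trace.sampling_rate
    baseline = estimate_baseline(trace)
    win = max(2, int(round(params.search_window_ms / 1000.0 * fs)))
    complexes: list[QRSComplex] = []
    for r in np.asarray(r_peaks, dtype=int):
        if r - win < 0 or r + win >= trace.n_samples:
            warnings.warn(f"beat at sample {r} too close to trace boundary; skipped",
                          stacklevel=2)
            continue
        v = trace.voltage
        q_idx = (r - win) + int(np.argmin(v[r - win : r]))
        s_idx = (r + 1) + int(np.argmin(v[r + 1 : r + win + 1]))

        waves = {}
        for name, peak in (("q", q_idx), ("r", r), ("s", s_idx)):
            onset, offset = _wave_bounds(v, peak, baseline, params.onset_fraction, win)
            waves[name] = WaveMeasurement(
                peak_index=peak,
                amplitude=float(v[peak] - baseline),
                onset_index=onset,
                offset_index=offset,
                duration_ms=(offset - onset) / fs * 1000.0,
            )
        complexes.append(QRSComplex(q=waves["q"], r=waves["r"], s=waves["s"],
                                    baseline_level=baseline))
    return complexes


def summarize_qrs(complexes: list[QRSComplex], sampling_rate: float | None = None) -> QRSSummary:
    """Per-wave mean/SD of amplitude and duration; RR-derived heart rate.

    Heart rate is 60 / mean RR interval (needs ``sampling_rate`` and at
    least two beats; otherwise None).
    """
    if not complexes:
        raise ValueError("summarize_qrs requires at least one complex")
    mean_amp, sd_amp, mean_dur, sd_dur = {}, {}, {}, {}
    for wave in ("q", "r", "s"):
        amps = np.array([getattr(c, wave).amplitude for c in complexes])
        durs = np.array([getattr(c, wave).duration_ms for c in complexes])
        mean_amp[wave] = float(amps.mean())
        sd_amp[wave] = float(amps.std(ddof=1)) if len(amps) > 1 else 0.0
        mean_dur[wave] = float(durs.mean())
        sd_dur[wave] = float(durs.std(ddof=1)) if len(durs) > 1 else 0.0
    heart_rate = None
    if len(complexes) >= 2 and sampling_rate:
        rr = np.diff([c.r.peak_index for c in complexes]) / sampling_rate
        heart_rate = float(60.0 / rr.mean())
    return QRSSummary(
        beat_count=len(complexes),
        heart_rate_bpm=heart_rate,
        mean_amplitude=mean_amp,
        sd_amplitude=sd_amp,
        mean_duration_ms=mean_dur,
        sd_duration_ms=sd_dur,
    )


def match_r_peaks(
    detected: np.ndarray, truth: np.ndarray, tolerance_samples: int
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected vs true R indices.

    Returns ``(true_positives, false_positives, false_negatives)``.
    """
    detected = np.sort(np.asarray(detected, dtype=int))
    truth = np.sort(np.asarray(truth, dtype=int))
    used = np.zeros(truth.size, dtype=bool)
    tp = 0
    for d in detected:
        if truth.size == 0:
            break
        j = int(np.argmin(np.abs(truth - d) + np.where(used, 10**9, 0)))
        if not used[j] and abs(truth[j] - d) <= tolerance_samples:
            used[j] = True
            tp += 1
    fp = detected.size - tp
    fn = truth.size - tp
    return tp, fp, fn
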