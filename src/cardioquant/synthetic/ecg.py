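"""Synthetic ECG traces with exact per-beat QRS ground truth.

QRS morphology is synthesized as three Gaussian deflections per beat
(Q negative, R positive, S negative) on an isoelectric baseline of zero,
plus optional sinusoidal baseline wander and additive white Gaussian
noise. Gaussians give closed-form amplitude and width truth; wave centers
are snapped to the sample grid so the true peak value equals the
specified amplitude exactly.

Ground-truth wave onsets/offsets use the same convention as the analysis
stage: the outermost samples of each clean, isolated wave whose magnitude
still reaches 5% of the wave's peak amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..ecg import ECGTrace, QRSComplex, WaveMeasurement, _wave_bounds

__all__ = ["EcgSimSpec", "gen_ecg", "noise_sd_for_snr"]


@dataclass(frozen=True)
class EcgSimSpec:
    sampling_rate: float = 1000.0  # Hz
    duration: float = 10.0  # s
    heart_rate: float = 480.0  # bpm (murine resting rates are 400-600)
    q_amp: float = -0.2  # mV (signed)
    r_amp: float = 1.0  # mV
    s_amp: float = -0.3  # mV
    qrs_width: float = 10.0  # ms, total Q-to-S footprint
    baseline_wander_amp: float = 0.0  # mV
    noise_sd: float = 0.0  # mV
    snr_db: float | None = None  # overrides noise_sd: power SNR vs clean trace RMS
    onset_fraction: float = 0.05  # truth onset/offset criterion
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate < 250:
            raise ValueError(f"sampling_rate must be >= 250 Hz, got {self.sampling_rate}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.r_amp <= 0:
            raise ValueError(f"r_amp must be > 0, got {self.r_amp}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.qrs_width <= 0:
            raise ValueError(f"qrs_width must be > 0, got {self.qrs_width}")
        if self.heart_rate <= 0:
            raise ValueError(f"heart_rate must be > 0, got {self.heart_rate}")
        if self.baseline_wander_amp < 0:
            raise ValueError("baseline_wander_amp must be >= 0")


def noise_sd_for_snr(signal_rms: float, snr_db: float) -> float:
    """Noise SD giving the stated power signal-to-noise ratio in dB."""
    return signal_rms * 10.0 ** (-snr_db / 20.0)


def gen_ecg(spec: EcgSimSpec) -> tuple[ECGTrace, list[QRSComplex]]:
    """Generate a trace and its per-beat ground-truth QRS complexes.

    Beat count is ``round(heart_rate / 60 * duration)`` (up to one beat of
    rounding at the trace end); truth amplitudes equal the spec amplitudes
    and the truth baseline is 0 mV.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    rr = 60.0 / spec.heart_rate  # s
    n_beats = int(round(spec.heart_rate / 60.0 * spec.duration))

    w = spec.qrs_width / 1000.0  # s
    sigma = w / 12.0  # s; Q/R/S separated by w/3 = 4 sigma
    sigma_samples = sigma * fs
    offset_samples = int(round(w / 3.0 * fs))

    t = np.arange(n) / fs
    voltage = np.zeros(n)
    beat_waves: list[dict] = []
    for k in range(n_beats):
        r_idx = int(round((k + 0.5) * rr * fs))
        q_idx = r_idx - offset_samples
        s_idx = r_idx + offset_samples
        if q_idx - 4 * sigma_samples < 0 or s_idx + 4 * sigma_samples >= n:
            continue
        for name, idx, amp in (
            ("q", q_idx, spec.q_amp),
            ("r", r_idx, spec.r_amp),
            ("s", s_idx, spec.s_amp),
        ):
            voltage += amp * np.exp(-0.5 * ((t - idx / fs) / sigma) ** 2)
        beat_waves.append({"q": (q_idx, spec.q_amp), "r": (r_idx, spec.r_amp),
                           "s": (s_idx, spec.s_amp)})

    # truth onsets/offsets from the clean composite trace with the same
    # 5%-of-peak re-crossing criterion the analysis stage uses (baseline 0)
    truth: list[QRSComplex] = []
    max_extent = max(2, offset_samples)
    for waves in beat_waves:
        measured = {}
        for name, (idx, amp) in waves.items():
            onset, offset = _wave_bounds(voltage, idx, 0.0, spec.onset_fraction,
                                         max_extent)
            measured[name] = WaveMeasurement(
                peak_index=idx,
                amplitude=amp,
                onset_index=onset,
                offset_index=offset,
                duration_ms=(offset - onset) / fs * 1000.0,
            )
        truth.append(QRSComplex(q=measured["q"], r=measured["r"], s=measured["s"],
                                baseline_level=0.0))

    if spec.baseline_wander_amp > 0:
        freq = rng.uniform(0.15, 0.4)  # Hz, respiratory-range drift
        phase = rng.uniform(0, 2 * np.pi)
        voltage += spec.baseline_wander_amp * np.sin(2 * np.pi * freq * t + phase)
    noise_sd = spec.noise_sd
    if spec.snr_db is not None:
        noise_sd = noise_sd_for_snr(float(np.sqrt(np.mean(voltage**2))), spec.snr_db)
    if noise_sd > 0:
        voltage += rng.normal(0.0, noise_sd, size=n)

    return ECGTrace(voltage=voltage, sampling_rate=fs), truth
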