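"""Synthetic task-evoked EEG cohort generator.

Each subject is a 16-channel recording built from band-limited oscillations
(band-pass filtered Gaussian noise, one process per channel and band), a 1/f
pink-noise background, frontal blink transients and posterior EMG bursts.

Class effects are injected multiplicatively on the per-subject band
amplitudes. The configured ``band_effect_d`` targets the *epoch-level*
standardized mean difference of amplitude-tracking features: the class-1 mean
amplitude is shifted by ``d * s`` where ``s`` is the modeled relative
standard deviation of a band's epoch amplitude (subject-level variation +
10-s block modulation + the sampling noise of a band-limited RMS estimate).
Subject-level amplitude variation makes epochs within a subject correlated,
deliberately reproducing the subject-leakage phenomenon that segment-level
cross-validation is exposed to.

Everything is a pure function of (config, seed, subject index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from eegscreen.decomposition import BAND_HZ, BAND_ORDER
from eegscreen.io_edf import CANONICAL_CHANNELS, Recording

_DEFAULT_AMPLITUDES = {
    "delta": 20.0, "theta": 15.0, "alpha": 12.0, "beta": 8.0, "gamma": 5.0,
}
# Effect directions follow reports of increased slow-wave (theta/delta)
# activity in the target class; magnitudes are free simulation parameters.
_DEFAULT_EFFECTS = {
    "delta": 0.6, "theta": 0.8, "alpha": -0.3, "beta": 0.2, "gamma": 0.0,
}

_FRONTAL_WEIGHTS = {
    "Fp1": 1.0, "Fp2": 1.0, "F3": 0.5, "F4": 0.5, "F7": 0.4, "F8": 0.4,
}
_POSTERIOR_WEIGHTS = {
    "O1": 1.0, "O2": 1.0, "T5": 0.8, "T6": 0.8, "P3": 0.6, "P4": 0.6,
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort."""

    n_dyslexic: int = 26
    n_control: int = 25
    duration_s: float = 340.0
    fs: float = 256.0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AMPLITUDES))
    band_effect_d: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECTS))
    subject_cv: float = 0.05       # between-subject amplitude spread
    epoch_cv: float = 0.2          # per-10-s-block amplitude modulation
    channel_gain_cv: float = 0.1   # per-channel static gain spread
    pink_noise_scale: float = 5.0  # uV
    blink_rate: float = 8.0        # events/min, frontal channels
    blink_amplitude: float = 120.0
    emg_rate: float = 4.0          # events/min, posterior channels
    emg_amplitude: float = 25.0
    seed: int = 0
    modulation_block_s: float = 10.0

    def validate(self) -> None:
        if self.n_dyslexic <= 0 or self.n_control <= 0:
            raise ValueError("class counts must be positive")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration must be positive")
        if self.blink_rate < 0 or self.emg_rate < 0:
            raise ValueError("event rates must be >= 0")
        nyq = self.fs / 2
        for band, amp in self.band_amplitudes.items():
            if band not in BAND_HZ:
                raise ValueError(f"unknown band {band!r}")
            if amp < 0:
                raise ValueError("band amplitudes must be >= 0")
            if amp > 0 and BAND_HZ[band][0] >= nyq:
                raise ValueError(f"band {band} lies above Nyquist at fs={self.fs}")
        for value in self.band_effect_d.values():
            if not np.isfinite(value):
                raise ValueError("effect sizes must be finite")


def amplitude_sd_model(config: CohortConfig, band: str) -> float:
    """Modeled relative SD of a band's epoch-level amplitude estimate."""
    lo, hi = BAND_HZ[band]
    bw = min(hi, 0.45 * config.fs) - lo
    t = config.modulation_block_s
    sampling_var = 1.0 / (4.0 * max(bw, 1e-6) * t)
    return float(np.sqrt(
        config.subject_cv**2 + config.epoch_cv**2
        + config.channel_gain_cv**2 + sampling_var
    ))


def _band_noise(rng, n_channels: int, n_samples: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise per channel."""
    hi = min(hi, 0.45 * fs)
    # steep edges keep cross-band bleed (and effect dilution) small
    sos = sps.butter(6, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal((n_channels, n_samples)), axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std


def _pink_noise(rng, n_channels: int, n_samples: int) -> np.ndarray:
    """Unit-variance 1/f noise per channel (FFT-shaped)."""
    spectrum = rng.standard_normal((n_channels, n_samples // 2 + 1)) + 1j * (
        rng.standard_normal((n_channels, n_samples // 2 + 1))
    )
    freqs = np.fft.rfftfreq(n_samples)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spectrum * shape, n=n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std


def _add_transients(rng, data: np.ndarray, fs: float, rate_per_min: float,
                    amplitude: float, weights: dict[str, float],
                    kind: str) -> None:
    if rate_per_min <= 0 or amplitude <= 0:
        return
    n_samples = data.shape[1]
    duration_min = n_samples / fs / 60.0
    n_events = rng.poisson(rate_per_min * duration_min)
    w = np.array([weights.get(ch, 0.1) for ch in CANONICAL_CHANNELS])
    width = int((0.4 if kind == "blink" else 0.3) * fs)
    if kind == "emg":
        sos = sps.butter(4, [30.0, min(70.0, 0.45 * fs)], btype="bandpass",
                         fs=fs, output="sos")
    for _ in range(n_events):
        start = rng.integers(0, max(n_samples - width, 1))
        envelope = np.hanning(width)
        if kind == "blink":
            pulse = envelope * amplitude
        else:
            burst = sps.sosfiltfilt(sos, rng.standard_normal(width))
            s = burst.std()
            pulse = envelope * burst / (s if s > 0 else 1.0) * amplitude
        data[:, start : start + width] += w[:, None] * pulse[None, :]


def generate_subject(
    config: CohortConfig,
    subject_index: int,
    class_label: int,
    seed: int | None = None,
) -> Recording:
    """Deterministically generate one subject's recording."""
    config.validate()
    root = config.seed if seed is None else seed
    rng = np.random.default_rng([root, subject_index])
    n_ch = len(CANONICAL_CHANNELS)
    n_samples = int(round(config.duration_s * config.fs))
    data = np.zeros((n_ch, n_samples))

    block = max(int(round(config.modulation_block_s * config.fs)), 1)
    n_blocks = int(np.ceil(n_samples / block))

    for band in BAND_ORDER:
        amp = config.band_amplitudes.get(band, 0.0)
        # scalar draws happen for every band so the stream layout is stable
        z_subj = rng.standard_normal()
        gains = 1.0 + config.channel_gain_cv * rng.standard_normal(n_ch)
        z_blocks = rng.standard_normal(n_blocks)
        if amp <= 0:
            continue
        lo, hi = BAND_HZ[band]
        noise = _band_noise(rng, n_ch, n_samples, config.fs, lo, hi)
        d_target = config.band_effect_d.get(band, 0.0)
        shift = d_target * amplitude_sd_model(config, band) if class_label == 1 else 0.0
        subject_amp = amp * max(1.0 + shift + config.subject_cv * z_subj, 0.05)
        envelope = np.repeat(
            np.maximum(1.0 + config.epoch_cv * z_blocks, 0.05), block
        )[:n_samples]
        data += subject_amp * np.clip(gains, 0.05, None)[:, None] * noise * envelope

    if config.pink_noise_scale > 0:
        data += config.pink_noise_scale * _pink_noise(rng, n_ch, n_samples)
    _add_transients(rng, data, config.fs, config.blink_rate,
                    config.blink_amplitude, _FRONTAL_WEIGHTS, "blink")
    _add_transients(rng, data, config.fs, config.emg_rate,
                    config.emg_amplitude, _POSTERIOR_WEIGHTS, "emg")

    return Recording(
        subject_id=f"S{subject_index:03d}",
        label=int(class_label),
        fs=config.fs,
        channel_names=list(CANONICAL_CHANNELS),
        data=data,
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[Recording], pd.DataFrame]:
    """Generate the full cohort plus a subject manifest.

    Dyslexic subjects come first (indices 0..n_dyslexic-1), controls after.
    """
    config.validate()
    recordings: list[Recording] = []
    rows = []
    for idx in range(config.n_dyslexic + config.n_control):
        label = 1 if idx < config.n_dyslexic else 0
        rec = generate_subject(config, idx, label)
        recordings.append(rec)
        rows.append({"subject_id": rec.subject_id, "label": label,
                     "seed": config.seed})
    return recordings, pd.DataFrame(rows)
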