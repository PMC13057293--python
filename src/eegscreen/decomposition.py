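"""Epoching and wavelet sub-band decomposition.

Recordings are cut into non-overlapping fixed-length epochs (default 10 s),
then every epoch-channel trace is decomposed with a level-6 db4 DWT and the
coefficient sets are mapped onto the classic EEG bands.

Two band-mapping modes exist because the conventional printed level->band
table (delta<-A6, theta<-D6, alpha<-D5, beta<-D4, gamma<-D3) corresponds to a
512 Hz dyadic ladder, while these recordings are 256 Hz:

* ``table3_literal`` - the printed assignment, verbatim (default).
* ``frequency_consistent`` - each coefficient set is assigned to the band
  whose Hz range it overlaps most at the actual sampling rate (at 256 Hz:
  delta<-A6+D6, theta<-D5, alpha<-D4, beta<-D3, gamma<-D2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from eegscreen import _dwt
from eegscreen.io_edf import Recording

#: Band Hz ranges.
BAND_HZ: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 60.0),
}

BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

FOUR_BANDS: tuple[str, ...] = ("delta", "theta", "alpha", "beta")
FIVE_BANDS: tuple[str, ...] = BAND_ORDER

_LITERAL_MAP = {
    "delta": ("A6",),
    "theta": ("D6",),
    "alpha": ("D5",),
    "beta": ("D4",),
    "gamma": ("D3",),
}

MAPPING_MODES = ("table3_literal", "frequency_consistent")


class TooShortError(ValueError):
    """Recording shorter than one epoch."""


@dataclass
class EpochSet:
    """Non-overlapping fixed-length segments cut from one recording."""

    subject_id: str
    label: int
    fs: float
    channel_names: list[str]
    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    epoch_length_s: float = 10.0

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class BandCoefficients:
    """Per-epoch, per-channel wavelet coefficients keyed by band.

    ``coeffs[band]`` has shape (n_epochs, n_channels, n_band_coeffs).
    """

    subject_id: str
    label: int
    channel_names: list[str]
    band_names: tuple[str, ...]
    mapping_mode: str
    coeffs: dict[str, np.ndarray] = field(repr=False)

    @property
    def n_epochs(self) -> int:
        return next(iter(self.coeffs.values())).shape[0]


def epoch_recording(rec: Recording, epoch_length_s: float = 10.0) -> EpochSet:
    """Cut ``rec`` into consecutive disjoint epochs, discarding the remainder."""
    if epoch_length_s <= 0:
        raise ValueError("epoch length must be positive")
    samples_per = int(round(epoch_length_s * rec.fs))
    n_epochs = rec.n_samples // samples_per
    if n_epochs == 0:
        raise TooShortError(
            f"recording of {rec.duration_s:.1f}s is shorter than one "
            f"{epoch_length_s:.1f}s epoch"
        )
    used = n_epochs * samples_per
    epochs = (
        rec.data[:, :used]
        .reshape(rec.n_channels, n_epochs, samples_per)
        .transpose(1, 0, 2)
        .copy()
    )
    return EpochSet(
        subject_id=rec.subject_id,
        label=rec.label,
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        epochs=epochs,
        epoch_length_s=epoch_length_s,
    )


def dwt_decompose(
    signal: np.ndarray, wavelet: str = "db4", level: int = 6,
    mode: str = "symmetric",
) -> dict[str, np.ndarray]:
    """Level-``level`` DWT of one epoch-channel trace.

    Returns an ordered mapping ``{A6, D6, D5, ..., D1}`` (for level 6).
    Only the db4 wavelet is implemented. ``mode`` selects boundary handling
    (``symmetric`` default; ``periodization`` is exactly energy-preserving).
    """
    if wavelet != "db4":
        raise ValueError(f"unsupported wavelet {wavelet!r}; only 'db4' is built in")
    coeffs = _dwt.wavedec(np.asarray(signal, dtype=np.float64), level, mode=mode)
    names = [f"A{level}"] + [f"D{j}" for j in range(level, 0, -1)]
    return dict(zip(names, coeffs))


def _dyadic_intervals(level: int, fs: float) -> dict[str, tuple[float, float]]:
    out = {f"A{level}": (0.0, fs / 2 ** (level + 1))}
    for j in range(level, 0, -1):
        out[f"D{j}"] = (fs / 2 ** (j + 1), fs / 2**j)
    return out


def frequency_consistent_map(level: int, fs: float) -> dict[str, tuple[str, ...]]:
    """Assign each coefficient set to the band its dyadic interval overlaps most."""
    intervals = _dyadic_intervals(level, fs)
    assignment: dict[str, list[str]] = {b: [] for b in BAND_ORDER}
    for name, (lo, hi) in intervals.items():
        best, best_ov = None, 0.0
        for band, (blo, bhi) in BAND_HZ.items():
            ov = max(0.0, min(hi, bhi) - max(lo, blo))
            if ov > best_ov:
                best, best_ov = band, ov
        if best is not None:
            assignment[best].append(name)
    # keep coarse-to-fine order within a band (A6 before D6 etc.)
    order = list(intervals)
    return {b: tuple(sorted(sets, key=order.index)) for b, sets in assignment.items()}


def map_bands(
    coeffs: dict[str, np.ndarray],
    mode: str = "table3_literal",
    fs: float = 256.0,
) -> dict[str, np.ndarray]:
    """Map level-6 DWT coefficient sets onto the five EEG bands.

    Returns ``{band: concatenated coefficient vector}`` for all five bands;
    callers restrict to the configured 4- or 5-band set downstream.
    """
    if mode not in MAPPING_MODES:
        raise ValueError(f"unknown mapping mode {mode!r}; choose from {MAPPING_MODES}")
    if mode == "table3_literal":
        plan = _LITERAL_MAP
    else:
        level = max(int(n[1:]) for n in coeffs if n.startswith("D"))
        plan = frequency_consistent_map(level, fs)
    out = {}
    for band in BAND_ORDER:
        parts = [coeffs[name] for name in plan.get(band, ())]
        out[band] = (
            np.concatenate(parts) if parts else np.empty(0, dtype=np.float64)
        )
    return out


def decompose_epochs(
    epoch_set: EpochSet,
    mapping_mode: str = "table3_literal",
    bands: tuple[str, ...] = FOUR_BANDS,
    wavelet: str = "db4",
    level: int = 6,
) -> BandCoefficients:
    """DWT-decompose every epoch-channel of ``epoch_set`` into band coefficients."""
    n_ep, n_ch, _ = epoch_set.epochs.shape
    store: dict[str, np.ndarray] | None = None
    for e in range(n_ep):
        for c in range(n_ch):
            mapped = map_bands(
                dwt_decompose(epoch_set.epochs[e, c], wavelet=wavelet, level=level),
                mode=mapping_mode,
                fs=epoch_set.fs,
            )
            if store is None:
                store = {
                    b: np.empty((n_ep, n_ch, mapped[b].size)) for b in bands
                }
            for b in bands:
                store[b][e, c] = mapped[b]
    assert store is not None
    return BandCoefficients(
        subject_id=epoch_set.subject_id,
        label=epoch_set.label,
        channel_names=list(epoch_set.channel_names),
        band_names=tuple(bands),
        mapping_mode=mapping_mode,
        coeffs=store,
    )
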