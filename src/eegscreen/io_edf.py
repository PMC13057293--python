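"""Classic EDF (European Data Format) reading/writing and channel selection.

Only continuous, unannotated classic EDF is supported (no EDF+/BDF). Data
records are one second long; every signal must share a single sampling rate.
Amplitudes are stored as 16-bit integers against a per-signal physical range
and read back in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: 10-20 channels retained for analysis, in canonical order. Midline
#: electrodes (Fz, Cz, Pz) are deliberately absent.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "T3", "T4",
    "T5", "T6", "P3", "P4", "O1", "O2", "C3", "C4",
)

#: Montage dialect aliases (modern name -> legacy name), matched
#: case-insensitively.
CHANNEL_ALIASES: dict[str, str] = {
    "t7": "t3",
    "t8": "t4",
    "p7": "t5",
    "p8": "t6",
}

_DIG_MIN, _DIG_MAX = -32768, 32767


class EdfFormatError(ValueError):
    """File is not a readable classic EDF."""


class UnsupportedEdfError(ValueError):
    """Structurally valid EDF that this reader does not support."""


class MissingChannelError(KeyError):
    """A channel from the retained 16-channel set is absent."""


@dataclass
class Recording:
    """One subject's multichannel EEG.

    ``data`` is a (channels x samples) float array in microvolts.
    """

    subject_id: str
    label: int
    fs: float
    channel_names: list[str]
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with ``data`` replaced."""
        return replace(self, data=np.asarray(data, dtype=np.float64))


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw.ljust(width)


def _num(value: float, width: int) -> bytes:
    text = f"{value:.10g}"[:width]
    return _pad(text, width)


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write ``rec`` as a classic EDF file with one-second data records.

    The subject id and class label are stored in the patient/recording
    identification header fields so that :func:`read_edf` round-trips them.
    """
    if not np.isfinite(rec.data).all():
        raise ValueError("recording contains non-finite samples")
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("write_edf requires an integer sampling rate")
    fs = int(round(fs))
    if rec.n_samples % fs != 0:
        raise ValueError(
            "sample count must be a whole number of seconds "
            f"(got {rec.n_samples} samples at {fs} Hz)"
        )
    n_records = rec.n_samples // fs
    n_sig = rec.n_channels

    # Symmetric per-signal physical range; degenerate all-zero signals get a
    # unit range so the gain is finite.
    phys_max = np.max(np.abs(rec.data), axis=1)
    phys_max = np.where(phys_max > 0, phys_max, 1.0)
    phys_min = -phys_max

    header = bytearray()
    header += _pad("0", 8)
    header += _pad(rec.subject_id, 80)
    header += _pad(f"label={rec.label}", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (n_sig + 1)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)
    header += _pad(str(n_sig), 4)

    for name in rec.channel_names:
        header += _pad(name, 16)
    header += b"".join(_pad("", 80) for _ in range(n_sig))
    header += b"".join(_pad("uV", 8) for _ in range(n_sig))
    header += b"".join(_num(v, 8) for v in phys_min)
    header += b"".join(_num(v, 8) for v in phys_max)
    header += b"".join(_pad(str(_DIG_MIN), 8) for _ in range(n_sig))
    header += b"".join(_pad(str(_DIG_MAX), 8) for _ in range(n_sig))
    header += b"".join(_pad("", 80) for _ in range(n_sig))
    header += b"".join(_pad(str(fs), 8) for _ in range(n_sig))
    header += b"".join(_pad("", 32) for _ in range(n_sig))

    gain = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((rec.data - phys_min[:, None]) / gain[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    # records x signals x fs, signals interleaved per record
    interleaved = (
        digital.reshape(n_sig, n_records, fs).transpose(1, 0, 2).reshape(-1)
    )
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(interleaved.tobytes())


def _read_field(buf: bytes, offset: int, width: int) -> str:
    return buf[offset : offset + width].decode("ascii", errors="replace").strip()


def read_edf(path: str | Path) -> Recording:
    """Read a classic EDF file into a :class:`Recording` (amplitudes in uV)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise EdfFormatError(f"{path}: file shorter than an EDF header")
    version = _read_field(raw, 0, 8)
    if version != "0":
        raise EdfFormatError(f"{path}: unsupported EDF version {version!r}")
    try:
        n_records = int(_read_field(raw, 236, 8))
        record_dur = float(_read_field(raw, 244, 8))
        n_sig = int(_read_field(raw, 252, 4))
    except ValueError as exc:
        raise EdfFormatError(f"{path}: malformed header numerics") from exc
    if n_sig < 1:
        raise EdfFormatError(f"{path}: no signals")
    if record_dur <= 0:
        raise EdfFormatError(f"{path}: non-positive record duration")
    sig_hdr_len = 256 * n_sig
    if len(raw) < 256 + sig_hdr_len:
        raise EdfFormatError(f"{path}: truncated signal headers")

    sh = raw[256 : 256 + sig_hdr_len]

    def col(width: int, start: int) -> list[str]:
        return [
            sh[start + i * width : start + (i + 1) * width]
            .decode("ascii", errors="replace")
            .strip()
            for i in range(n_sig)
        ]

    off = 0
    labels = col(16, off); off += 16 * n_sig
    off += 80 * n_sig  # transducer
    off += 8 * n_sig   # physical dimension
    try:
        phys_min = np.array([float(v) for v in col(8, off)]); off += 8 * n_sig
        phys_max = np.array([float(v) for v in col(8, off)]); off += 8 * n_sig
        dig_min = np.array([float(v) for v in col(8, off)]); off += 8 * n_sig
        dig_max = np.array([float(v) for v in col(8, off)]); off += 8 * n_sig
        off += 80 * n_sig  # prefiltering
        spr = np.array([int(v) for v in col(8, off)])
    except ValueError as exc:
        raise EdfFormatError(f"{path}: malformed signal header numerics") from exc

    if np.any(dig_max <= dig_min) or np.any(phys_max <= phys_min):
        raise EdfFormatError(f"{path}: degenerate physical/digital ranges")
    if len(set(spr.tolist())) != 1:
        raise UnsupportedEdfError(
            f"{path}: per-channel sampling rates differ ({sorted(set(spr.tolist()))})"
        )
    fs = spr[0] / record_dur

    payload = raw[256 + sig_hdr_len :]
    expected = n_records * int(spr.sum()) * 2
    if len(payload) < expected:
        raise EdfFormatError(f"{path}: truncated data records")
    digital = np.frombuffer(payload[:expected], dtype="<i2")
    digital = digital.reshape(n_records, n_sig, spr[0]).transpose(1, 0, 2)
    digital = digital.reshape(n_sig, -1).astype(np.float64)

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * gain[:, None] + phys_min[:, None]

    subject_id = _read_field(raw, 8, 80) or path.stem
    rec_field = _read_field(raw, 88, 80)
    label = 0
    for token in rec_field.split():
        if token.startswith("label="):
            try:
                label = int(token.split("=", 1)[1])
            except ValueError:
                pass
    return Recording(
        subject_id=subject_id,
        label=label,
        fs=float(fs),
        channel_names=labels,
        data=data,
    )


def _normalize(name: str) -> str:
    key = name.strip().lower()
    if key.startswith("eeg "):
        key = key[4:].strip()
    key = key.split("-")[0].strip()
    return CHANNEL_ALIASES.get(key, key)


def select_channels(rec: Recording) -> Recording:
    """Restrict ``rec`` to the canonical 16-channel set in canonical order.

    Matching is case-insensitive and alias-aware (T3/T7 etc.); midline and any
    extra channels are dropped. Raises :class:`MissingChannelError` naming the
    first absent retained channel.
    """
    index = {}
    for i, name in enumerate(rec.channel_names):
        index.setdefault(_normalize(name), i)
    rows = []
    for want in CANONICAL_CHANNELS:
        key = want.lower()
        if key not in index:
            raise MissingChannelError(want)
        rows.append(index[key])
    return replace(
        rec,
        channel_names=list(CANONICAL_CHANNELS),
        data=rec.data[rows].copy(),
    )
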