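"""Ten statistical descriptors per band-channel coefficient vector and
feature-matrix assembly.

All moments use population (1/N) normalization; kurtosis is non-excess
(Gaussian -> 3); skewness and kurtosis are defined as 0 for constant input.
Entropy is base-2 Shannon entropy of an equal-width histogram of the
coefficient values (default 16 bins spanning [min, max]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from eegscreen.decomposition import BandCoefficients, FIVE_BANDS, FOUR_BANDS

STATISTIC_NAMES: tuple[str, ...] = (
    "mean", "median", "variance", "std", "skewness",
    "kurtosis", "iqr", "mad", "rms", "entropy",
)


class ConsistencyError(ValueError):
    """Epoch collections disagree on channels or band sets."""


def _entropy_rows(X: np.ndarray, bins: int) -> np.ndarray:
    """Row-wise histogram Shannon entropy (bits) of a 2-D array."""
    n_rows, n = X.shape
    lo = X.min(axis=1)
    hi = X.max(axis=1)
    out = np.zeros(n_rows)
    span = hi - lo
    ok = span > 0
    if np.any(ok):
        # vectorized equal-width binning per row
        Z = (X[ok] - lo[ok, None]) / span[ok, None]
        idx = np.minimum((Z * bins).astype(np.intp), bins - 1)
        offsets = np.arange(idx.shape[0])[:, None] * bins
        counts = np.bincount(
            (idx + offsets).ravel(), minlength=idx.shape[0] * bins
        ).reshape(idx.shape[0], bins)
        p = counts / n
        logp = np.zeros_like(p)
        np.log2(p, out=logp, where=p > 0)
        out[ok] = -(p * logp).sum(axis=1)
    return out


def statistics_matrix(X: np.ndarray, entropy_bins: int = 16) -> np.ndarray:
    """Compute the 10 descriptors for each row of ``X`` -> (rows, 10)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("expected a non-empty 2-D array of coefficient vectors")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in coefficient vectors")
    if entropy_bins < 1:
        raise ValueError("entropy_bins must be >= 1")

    mean = X.mean(axis=1)
    centered = X - mean[:, None]
    variance = np.mean(centered**2, axis=1)
    std = np.sqrt(variance)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(std > 0, np.mean(centered**3, axis=1) / std**3, 0.0)
        kurt = np.where(std > 0, np.mean(centered**4, axis=1) / std**4, 0.0)
    q1, median, q3 = np.percentile(X, [25, 50, 75], axis=1)
    mad = np.mean(np.abs(centered), axis=1)
    rms = np.sqrt(np.mean(X**2, axis=1))
    ent = _entropy_rows(X, entropy_bins)
    return np.column_stack(
        [mean, median, variance, std, skew, kurt, q3 - q1, mad, rms, ent]
    )


def compute_statistics(x: np.ndarray, entropy_bins: int = 16) -> np.ndarray:
    """Ten descriptors of one coefficient vector, in ``STATISTIC_NAMES`` order."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("expected a non-empty 1-D vector")
    return statistics_matrix(x[None, :], entropy_bins=entropy_bins)[0]


@dataclass
class FeatureMatrix:
    """Epochs x named features with per-epoch labels and subject ids."""

    values: np.ndarray = field(repr=False)
    feature_names: list[str]
    labels: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n, p = self.values.shape
        if len(self.feature_names) != p:
            raise ValueError("feature_names length mismatch")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError("labels/subject_ids must align with rows")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            labels=self.labels.copy(),
            subject_ids=list(self.subject_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        df["subject_id"] = self.subject_ids
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta = ["label", "subject_id"]
        names = [c for c in df.columns if c not in meta]
        return cls(
            values=df[names].to_numpy(dtype=np.float64),
            feature_names=names,
            labels=df["label"].to_numpy(),
            subject_ids=df["subject_id"].astype(str).tolist(),
        )


def _resolve_band_set(band_set: str) -> tuple[str, ...]:
    if band_set == "4band":
        return FOUR_BANDS
    if band_set == "5band":
        return FIVE_BANDS
    if band_set in FIVE_BANDS:
        return (band_set,)
    raise ValueError(
        f"band_set must be '4band', '5band', or a band name; got {band_set!r}"
    )


def build_feature_matrix(
    band_coeffs: Iterable[BandCoefficients],
    band_set: str = "4band",
    entropy_bins: int = 16,
) -> FeatureMatrix:
    """Assemble the epoch x feature matrix over a collection of subjects.

    Column order is bands x channels x statistics; rows follow subject then
    epoch order. Column names are ``band.channel.statistic``.
    """
    bands = _resolve_band_set(band_set)
    blocks: list[np.ndarray] = []
    labels: list[int] = []
    subjects: list[str] = []
    channels: list[str] | None = None

    for bc in band_coeffs:
        if channels is None:
            channels = list(bc.channel_names)
        elif list(bc.channel_names) != channels:
            raise ConsistencyError("channel order differs across subjects")
        missing = [b for b in bands if b not in bc.coeffs]
        if missing:
            raise ConsistencyError(f"bands {missing} absent for {bc.subject_id}")
        n_ep = bc.n_epochs
        per_band = []
        for b in bands:
            arr = bc.coeffs[b]  # (n_ep, n_ch, L)
            flat = arr.reshape(n_ep * arr.shape[1], arr.shape[2])
            stats = statistics_matrix(flat, entropy_bins=entropy_bins)
            per_band.append(stats.reshape(n_ep, arr.shape[1] * len(STATISTIC_NAMES)))
        blocks.append(np.hstack(per_band))
        labels.extend([bc.label] * n_ep)
        subjects.extend([bc.subject_id] * n_ep)

    if channels is None:
        raise ValueError("no epoch collections provided")
    names = [
        f"{b}.{ch}.{st}" for b in bands for ch in channels for st in STATISTIC_NAMES
    ]
    return FeatureMatrix(
        values=np.vstack(blocks),
        feature_names=names,
        labels=np.asarray(labels),
        subject_ids=subjects,
    )
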