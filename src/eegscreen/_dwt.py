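"""Multilevel discrete wavelet transform (db4).

Orthonormal Daubechies-4 filter bank with the standard decimated pyramid
algorithm and two boundary modes:

* ``symmetric`` (default) - half-sample symmetric extension; a level with
  input length n produces floor((n + L - 1) / 2) coefficients for an L-tap
  filter. Minimizes edge artifacts but the boundary coefficients are
  redundant, so coefficient energy slightly exceeds signal energy.
* ``periodization`` - circular extension with n/2 coefficients per level;
  the transform is exactly orthonormal (Parseval holds to float precision).

Both modes reconstruct the input exactly (up to float rounding).
"""

from __future__ import annotations

import numpy as np

# Orthonormal db4 (8-tap) analysis/synthesis filters.
DEC_LO = np.array([
    -0.010597401785069032, 0.0328830116668852, 0.030841381835560764,
    -0.18703481171909309, -0.027983769416859854, 0.6308807679298589,
    0.7148465705529157, 0.2303778133088965,
])
DEC_HI = np.array([
    -0.2303778133088965, 0.7148465705529157, -0.6308807679298589,
    -0.027983769416859854, 0.18703481171909309, 0.030841381835560764,
    -0.0328830116668852, -0.010597401785069032,
])
REC_LO = DEC_LO[::-1].copy()
REC_HI = np.array([
    -0.010597401785069032, -0.0328830116668852, 0.030841381835560764,
    0.18703481171909309, -0.027983769416859854, -0.6308807679298589,
    0.7148465705529157, -0.2303778133088965,
])

_FILTER_LEN = 8


class LevelError(ValueError):
    """Signal too short for the requested decomposition depth."""


def max_level(n: int) -> int:
    """Deepest decomposition supported for a length-``n`` signal."""
    if n < _FILTER_LEN:
        return 0
    return int(np.log2(n / (_FILTER_LEN - 1)))


MODES = ("symmetric", "periodization")


def dwt_single(x: np.ndarray, mode: str = "symmetric") -> tuple[np.ndarray, np.ndarray]:
    """One analysis step: (approximation, detail) at half rate."""
    if mode == "symmetric":
        xe = np.pad(x, _FILTER_LEN - 1, mode="symmetric")
        a = np.convolve(xe, DEC_LO, mode="valid")[1::2]
        d = np.convolve(xe, DEC_HI, mode="valid")[1::2]
        return a, d
    if len(x) % 2:
        x = np.concatenate([x, x[-1:]])
    half = len(x) // 2
    xe = np.concatenate([x[-(_FILTER_LEN - 1):], x])
    a = np.convolve(xe, DEC_LO, mode="valid")[1::2][:half]
    d = np.convolve(xe, DEC_HI, mode="valid")[1::2][:half]
    return a, d


def idwt_single(a: np.ndarray, d: np.ndarray, mode: str = "symmetric") -> np.ndarray:
    """Inverse of :func:`dwt_single`."""
    if mode == "symmetric" and len(a) == len(d) + 1:
        a = a[:-1]
    if len(a) != len(d):
        raise ValueError("coefficient length mismatch")
    up_a = np.zeros(2 * len(a))
    up_a[::2] = a
    up_d = np.zeros(2 * len(d))
    up_d[::2] = d
    r = np.convolve(up_a, REC_LO) + np.convolve(up_d, REC_HI)
    if mode == "symmetric":
        start = _FILTER_LEN - 2
        return r[start : start + 2 * len(a) - _FILTER_LEN + 2]
    n = 2 * len(a)
    out = np.zeros(n)
    np.add.at(out, (np.arange(len(r)) - (_FILTER_LEN - 2)) % n, r)
    return out


def wavedec(x: np.ndarray, level: int, mode: str = "symmetric") -> list[np.ndarray]:
    """Full decomposition: ``[A_level, D_level, D_{level-1}, ..., D_1]``."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("wavedec expects a 1-D signal")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if level < 1:
        raise LevelError("level must be >= 1")
    if level > max_level(len(x)):
        raise LevelError(
            f"signal of length {len(x)} supports at most level "
            f"{max_level(len(x))}, requested {level}"
        )
    details: list[np.ndarray] = []
    a = x
    for _ in range(level):
        a, d = dwt_single(a, mode=mode)
        details.append(d)
    return [a] + details[::-1]


def waverec(coeffs: list[np.ndarray], n: int, mode: str = "symmetric") -> np.ndarray:
    """Reconstruct a length-``n`` signal from :func:`wavedec` output."""
    a = coeffs[0]
    for d in coeffs[1:]:
        a = idwt_single(a, d, mode=mode)
    return a[:n]
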