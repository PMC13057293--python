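"""Class-wise feature statistics: Cohen's d and FDR-corrected significance.

Per feature: Welch's two-sided t-test between classes, a pooled-SD Cohen's d
(class 1 minus class 0, population normalization), and Benjamini-Hochberg
adjustment across all features.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from eegscreen.features import FeatureMatrix


def feature_group_stats(X: FeatureMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature class comparison table.

    Columns: feature, band, channel, statistic, mean_diff, cohens_d, p_raw,
    p_fdr, significant, degenerate. Features with zero variance in both
    classes get d = 0, p = 1 and are flagged ``degenerate``.
    """
    y = X.labels
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    g1 = X.values[y == 1]
    g0 = X.values[y == 0]
    n1, n0 = len(g1), len(g0)
    if min(n1, n0) < 2:
        raise ValueError("each class needs >= 2 samples")

    m1, m0 = g1.mean(axis=0), g0.mean(axis=0)
    v1 = g1.var(axis=0)  # population normalization, consistent with features
    v0 = g0.var(axis=0)
    pooled = np.sqrt((n1 * v1 + n0 * v0) / (n1 + n0))

    degenerate = pooled == 0
    d = np.zeros(X.n_features)
    np.divide(m1 - m0, pooled, out=d, where=~degenerate)

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate (near-constant) columns are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p_raw = stats.ttest_ind(g1, g0, axis=0, equal_var=False)
    p_raw = np.where(degenerate | ~np.isfinite(p_raw), 1.0, p_raw)

    significant, p_fdr, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")

    def part(name: str, i: int) -> str:
        bits = name.split(".")
        return bits[i] if len(bits) == 3 else ""

    return pd.DataFrame(
        {
            "feature": X.feature_names,
            "band": [part(n, 0) for n in X.feature_names],
            "channel": [part(n, 1) for n in X.feature_names],
            "statistic": [part(n, 2) for n in X.feature_names],
            "mean_diff": m1 - m0,
            "cohens_d": d,
            "p_raw": p_raw,
            "p_fdr": p_fdr,
            "significant": significant,
            "degenerate": degenerate,
        }
    )


def band_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Significant-feature counts per band."""
    return (
        table.groupby("band", sort=False)
        .agg(n_features=("feature", "size"), n_significant=("significant", "sum"))
        .reset_index()
    )
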