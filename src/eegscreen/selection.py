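"""Filter-based feature ranking: mutual-information mRMR and ReliefF.

Both rankers are implemented from first principles. Mutual information uses a
plug-in estimate on equal-frequency discretized features (base-2 logs). mRMR
performs greedy forward selection: the first feature maximizes relevance
I(x; C) and each subsequent feature maximizes
``I(x; C) - (1/|S|) * sum_{s in S} I(x; s)`` (difference scheme; a quotient
scheme is available). ReliefF runs the classic k-nearest hits/misses weight
update on range-scaled features with Manhattan distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from eegscreen.features import FeatureMatrix


class DegenerateLabelError(ValueError):
    """Labels are constant; mutual information with the class is undefined."""


@dataclass
class MIEstimate:
    """Plug-in mutual information estimate, in bits."""

    value: float
    n_bins: int
    n_samples: int


@dataclass
class FeatureRanking:
    """Ordered feature indices (best first) with method-specific scores."""

    method: str
    order: np.ndarray
    scores: np.ndarray
    params: dict = field(default_factory=dict)
    feature_names: list[str] | None = None

    def __len__(self) -> int:
        return len(self.order)


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning; ties may merge bins."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def _mi_from_codes(cx: np.ndarray, cy: np.ndarray) -> float:
    """Plug-in MI (bits) between two integer code vectors."""
    nx = int(cx.max()) + 1
    ny = int(cy.max()) + 1
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).reshape(nx, ny)
    joint = joint / joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def estimate_mi(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> MIEstimate:
    """Mutual information between a feature column and binary labels."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length vectors with >= 2 samples")
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateLabelError("labels are constant")
    cy = np.searchsorted(classes, y)
    value = _mi_from_codes(_discretize(x, n_bins), cy)
    return MIEstimate(value=value, n_bins=n_bins, n_samples=x.size)


def _as_xy(X) -> tuple[np.ndarray, np.ndarray, list[str] | None]:
    if isinstance(X, FeatureMatrix):
        return X.values, X.labels, X.feature_names
    values, labels = X
    return np.asarray(values, dtype=np.float64), np.asarray(labels), None


def mrmr_rank(
    X,
    k: int,
    n_bins: int = 10,
    scheme: str = "difference",
) -> FeatureRanking:
    """Greedy mRMR forward selection of ``k`` features.

    ``X`` is a :class:`FeatureMatrix` or a ``(values, labels)`` pair. Ties are
    broken deterministically toward the lower feature index. ``scores`` holds
    the greedy criterion value at the step each feature was selected.
    """
    values, labels, names = _as_xy(X)
    n, p = values.shape
    if k <= 0:
        raise ValueError("k must be positive")
    if k > p:
        raise ValueError(f"k={k} exceeds feature count {p}")
    if scheme not in ("difference", "quotient"):
        raise ValueError("scheme must be 'difference' or 'quotient'")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 samples per class")

    codes = np.column_stack([_discretize(values[:, j], n_bins) for j in range(p)])
    cy = np.searchsorted(classes, labels)
    relevance = np.array([_mi_from_codes(codes[:, j], cy) for j in range(p)])

    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(p)
    remaining = np.ones(p, dtype=bool)
    for _ in range(k):
        if selected:
            mean_red = redundancy_sum / len(selected)
            if scheme == "difference":
                criterion = relevance - mean_red
            else:
                criterion = relevance / (mean_red + 1e-12)
        else:
            criterion = relevance.copy()
        criterion = np.where(remaining, criterion, -np.inf)
        # lowest index within float tolerance of the maximum wins, so exact
        # ties are not decided by summation-order noise
        cmax = criterion.max()
        tol = 1e-9 * (abs(cmax) + 1.0)
        best = int(np.flatnonzero(criterion >= cmax - tol)[0])
        selected.append(best)
        scores.append(float(criterion[best]))
        remaining[best] = False
        if len(selected) < k:
            new = codes[:, best]
            for j in np.flatnonzero(remaining):
                redundancy_sum[j] += _mi_from_codes(codes[:, j], new)
    return FeatureRanking(
        method="mrmr",
        order=np.asarray(selected),
        scores=np.asarray(scores),
        params={"n_bins": n_bins, "scheme": scheme, "k": k},
        feature_names=names,
    )


def relieff_weights(
    X,
    k_neighbors: int = 10,
    m: int | None = None,
    seed: int = 0,
) -> FeatureRanking:
    """ReliefF feature weights via k-nearest hits and misses.

    With ``m=None`` every instance is visited once (deterministic full pass);
    otherwise ``m`` instances are sampled without replacement using ``seed``.
    Features are min-max scaled internally so weights lie in [-1, 1].
    """
    values, labels, names = _as_xy(X)
    n, p = values.shape
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts <= k_neighbors):
        raise ValueError(
            f"every class needs > {k_neighbors} samples (got {counts.tolist()})"
        )
    lo = values.min(axis=0)
    span = values.max(axis=0) - lo
    span = np.where(span > 0, span, 1.0)
    Z = (values - lo) / span

    if m is None:
        visit = np.arange(n)
    else:
        if not 0 < m <= n:
            raise ValueError("m must be in (0, n]")
        visit = np.sort(np.random.default_rng(seed).choice(n, size=m, replace=False))
    m_eff = len(visit)

    priors = counts / n
    prior_of = dict(zip(classes.tolist(), priors.tolist()))
    w = np.zeros(p)
    order_key = np.arange(n)
    for i in visit:
        diffs = np.abs(Z - Z[i])  # n x p
        dist = diffs.sum(axis=1)
        ci = labels[i]
        # hits
        mask = (labels == ci) & (order_key != i)
        idx = np.flatnonzero(mask)
        nearest = idx[np.lexsort((idx, dist[idx]))][:k_neighbors]
        w -= diffs[nearest].mean(axis=0) / m_eff
        # misses, prior-weighted over the other classes
        for c in classes:
            if c == ci:
                continue
            factor = prior_of[c] / (1.0 - prior_of[ci])
            idx = np.flatnonzero(labels == c)
            nearest = idx[np.lexsort((idx, dist[idx]))][:k_neighbors]
            w += factor * diffs[nearest].mean(axis=0) / m_eff
    order = np.lexsort((np.arange(p), -w))
    return FeatureRanking(
        method="relieff",
        order=order,
        scores=w[order],
        params={"k_neighbors": k_neighbors, "m": m, "seed": seed},
        feature_names=names,
    )


def select_top_k(ranking: FeatureRanking, k: int) -> tuple[np.ndarray, list[str] | None]:
    """First ``k`` entries of a ranking: (indices, names or None)."""
    if k <= 0 or k > len(ranking):
        raise ValueError(f"k must be in [1, {len(ranking)}]")
    idx = ranking.order[:k]
    names = (
        [ranking.feature_names[i] for i in idx]
        if ranking.feature_names is not None
        else None
    )
    return idx, names
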