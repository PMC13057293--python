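"""mRMR and ReliefF against independent brute-force oracles."""

import numpy as np
import pytest

from eegscreen.selection import (
    DegenerateLabelError,
    estimate_mi,
    mrmr_rank,
    relieff_weights,
    select_top_k,
)
from tests.conftest import gaussian_feature_matrix


# ---------------------------------------------------------------- oracles
def oracle_mi_bits(cx, cy):
    """Direct summation of the plug-in MI formula over the joint table."""
    cx, cy = np.asarray(cx), np.asarray(cy)
    n = len(cx)
    total = 0.0
    for vx in np.unique(cx):
        for vy in np.unique(cy):
            pxy = np.mean((cx == vx) & (cy == vy))
            if pxy == 0:
                continue
            px = np.mean(cx == vx)
            py = np.mean(cy == vy)
            total += pxy * np.log2(pxy / (px * py))
    return total


def oracle_discretize(x, n_bins):
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def oracle_mrmr(values, labels, k, n_bins):
    """Exhaustive re-computation of the greedy difference rule."""
    n, p = values.shape
    codes = [oracle_discretize(values[:, j], n_bins) for j in range(p)]
    classes = np.unique(labels)
    cy = np.searchsorted(classes, labels)
    relevance = [oracle_mi_bits(codes[j], cy) for j in range(p)]
    selected = []
    while len(selected) < k:
        scores = {}
        for j in range(p):
            if j in selected:
                continue
            if selected:
                red = np.mean([oracle_mi_bits(codes[j], codes[s])
                               for s in selected])
                scores[j] = relevance[j] - red
            else:
                scores[j] = relevance[j]
        best_score = max(scores.values())
        tol = 1e-9 * (abs(best_score) + 1.0)
        best_j = min(j for j, s in scores.items() if s >= best_score - tol)
        selected.append(best_j)
    return selected


def oracle_relieff(values, labels, k_neighbors):
    """Naive O(n^2 p) full-pass ReliefF with Manhattan distances."""
    n, p = values.shape
    lo, hi = values.min(axis=0), values.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    Z = (values - lo) / span
    classes, counts = np.unique(labels, return_counts=True)
    priors = dict(zip(classes.tolist(), (counts / n).tolist()))
    w = np.zeros(p)
    for i in range(n):
        d = np.array([np.sum(np.abs(Z[i] - Z[j])) for j in range(n)])
        for c in classes:
            idx = [j for j in range(n) if labels[j] == c and j != i]
            idx.sort(key=lambda j: (d[j], j))
            near = idx[:k_neighbors]
            contrib = np.mean([np.abs(Z[i] - Z[j]) for j in near], axis=0)
            if c == labels[i]:
                w -= contrib / n
            else:
                w += priors[c] / (1 - priors[labels[i]]) * contrib / n
    return w


# ------------------------------------------------------------------ tests
class TestEstimateMi:
    def test_identity_balanced_binary(self):
        y = np.tile([0, 1], 50)
        est = estimate_mi(y.astype(float), y, n_bins=2)
        assert est.value == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        x = rng.uniform(size=5000)
        y = np.tile([0, 1], 2500)
        est = estimate_mi(x, y, n_bins=10)
        assert est.value < 0.01  # small-sample bias bound

    def test_2x2_table_against_hand_formula(self):
        # joint counts [[30, 10], [10, 30]]
        x = np.concatenate([np.zeros(40), np.ones(40)])
        y = np.concatenate([np.zeros(30), np.ones(10),
                            np.zeros(10), np.ones(30)]).astype(int)
        est = estimate_mi(x, y, n_bins=2)
        p = np.array([[30, 10], [10, 30]]) / 80
        expected = sum(
            p[i, j] * np.log2(p[i, j] / (p[i].sum() * p[:, j].sum()))
            for i in range(2) for j in range(2)
        )
        assert est.value == pytest.approx(expected)
        assert expected == pytest.approx(0.1887218755, abs=1e-9)

    def test_constant_labels_rejected(self):
        with pytest.raises(DegenerateLabelError):
            estimate_mi(np.arange(10.0), np.zeros(10, dtype=int))

    def test_nonnegative_and_bounded(self, rng):
        x = rng.normal(size=400)
        y = (x + rng.normal(size=400) > 0).astype(int)
        est = estimate_mi(x, y)
        assert 0.0 <= est.value <= 1.0  # H(Y) <= 1 bit for binary y


class TestMrmr:
    def test_k1_is_max_relevance(self, rng):
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 5))
        X[:, 3] += 3 * y  # clearly most relevant
        ranking = mrmr_rank((X, y), k=1)
        assert ranking.order.tolist() == [3]

    def test_duplicate_feature_deferred(self, rng):
        # A perfectly separates the classes (continuous, so the exact
        # duplicate A' carries large measurable redundancy with it)
        y = np.repeat([0, 1], 40)
        a = y + 0.01 * rng.normal(size=80)
        a_dup = a.copy()
        b = 0.5 * y + rng.normal(size=80)  # weakly informative, independent
        X = np.column_stack([a, a_dup, b])
        ranking = mrmr_rank((X, y), k=3)
        assert ranking.order[0] == 0  # A first (ties break to lower index)
        assert ranking.order[1] == 2  # B before the exact duplicate A'

    def test_matches_bruteforce_oracle(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:4] = [0, 0, 1, 1]  # guarantee both classes
        X = rng.normal(size=(40, 6))
        X[:, 1] += y
        X[:, 4] += 0.5 * y
        ranking = mrmr_rank((X, y), k=3, n_bins=4)
        assert ranking.order.tolist() == oracle_mrmr(X, y, 3, 4)

    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_equivalence_randomized(self, seed):
        rng = np.random.default_rng(seed)
        n, p, k = 30, 8, 8
        y = np.tile([0, 1], n // 2)
        X = rng.normal(size=(n, p)) + rng.normal(size=(n, 1)) * 0.3
        X[:, : p // 2] += y[:, None] * rng.uniform(0.2, 1.5, size=p // 2)
        ranking = mrmr_rank((X, y), k=k, n_bins=5)
        assert ranking.order.tolist() == oracle_mrmr(X, y, k, 5)

    def test_bad_k_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.tile([0, 1], 10)
        with pytest.raises(ValueError):
            mrmr_rank((X, y), k=0)
        with pytest.raises(ValueError):
            mrmr_rank((X, y), k=4)


class TestRelieff:
    def test_constant_feature_zero_weight(self, rng):
        y = np.repeat([0, 1], 20)
        X = rng.normal(size=(40, 4))
        X[:, 2] = 7.0
        ranking = relieff_weights((X, y), k_neighbors=3)
        pos = ranking.order.tolist().index(2)
        assert ranking.scores[pos] == 0.0

    def test_perfect_separator_wins_8_sample_table(self, rng):
        y = np.repeat([0, 1], 4)
        X = rng.uniform(size=(8, 3)) * 0.5
        X[:, 0] = y.astype(float)  # 0.0 for class 0, 1.0 for class 1
        ranking = relieff_weights((X, y), k_neighbors=2)
        assert ranking.order[0] == 0
        assert ranking.scores[0] > 0

    def test_matches_naive_oracle(self, rng):
        y = np.tile([0, 1], 15)
        X = rng.normal(size=(30, 5))
        X[:, 0] += y * 1.5
        ranking = relieff_weights((X, y), k_neighbors=4)
        expected = oracle_relieff(X, y, 4)
        np.testing.assert_allclose(ranking.scores, np.sort(expected)[::-1],
                                   atol=1e-12)
        order_expected = np.lexsort((np.arange(5), -expected))
        np.testing.assert_array_equal(ranking.order, order_expected)

    def test_full_pass_invariant_to_sample_permutation(self, rng):
        y = np.tile([0, 1], 12)
        X = rng.normal(size=(24, 4))
        r1 = relieff_weights((X, y), k_neighbors=3)
        perm = rng.permutation(24)
        r2 = relieff_weights((X[perm], y[perm]), k_neighbors=3)
        np.testing.assert_allclose(
            np.sort(r1.scores), np.sort(r2.scores), atol=1e-12
        )

    def test_weights_bounded(self, rng):
        fm = gaussian_feature_matrix(n_per_class=25, effect=2.0, seed=4)
        ranking = relieff_weights(fm, k_neighbors=5)
        assert np.all(ranking.scores >= -1.0 - 1e-12)
        assert np.all(ranking.scores <= 1.0 + 1e-12)

    def test_noise_weight_near_zero_over_seeds(self):
        # label-independent feature -> weight ~ 0 in expectation
        weights = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            y = np.tile([0, 1], 25)
            X = np.column_stack([y + 0.3 * rng.normal(size=50),
                                 rng.normal(size=50)])
            r = relieff_weights((X, y), k_neighbors=5)
            pos = r.order.tolist().index(1)
            weights.append(r.scores[pos])
        assert abs(np.mean(weights)) < 0.05

    def test_small_class_rejected(self, rng):
        y = np.array([0] * 3 + [1] * 20)
        X = rng.normal(size=(23, 2))
        with pytest.raises(ValueError, match="class"):
            relieff_weights((X, y), k_neighbors=5)

    def test_sampled_mode_deterministic_in_seed(self, rng):
        y = np.tile([0, 1], 20)
        X = rng.normal(size=(40, 3))
        r1 = relieff_weights((X, y), k_neighbors=3, m=20, seed=9)
        r2 = relieff_weights((X, y), k_neighbors=3, m=20, seed=9)
        np.testing.assert_array_equal(r1.order, r2.order)
        np.testing.assert_allclose(r1.scores, r2.scores)


class TestSelectTopK:
    def test_full_length(self, separable_features):
        ranking = relieff_weights(separable_features, k_neighbors=5)
        idx, names = select_top_k(ranking, len(ranking))
        assert len(idx) == separable_features.n_features
        assert sorted(idx.tolist()) == list(range(separable_features.n_features))

    def test_top10_distinct_names(self, separable_features):
        ranking = mrmr_rank(separable_features, k=12)
        idx, names = select_top_k(ranking, 10)
        assert len(names) == 10
        assert len(set(names)) == 10

    def test_prefix_property(self, separable_features):
        ranking = relieff_weights(separable_features, k_neighbors=5)
        top10, _ = select_top_k(ranking, 10)
        top12, _ = select_top_k(ranking, 12)
        np.testing.assert_array_equal(top12[:10], top10)

    def test_k_too_large_rejected(self, separable_features):
        ranking = mrmr_rank(separable_features, k=5)
        with pytest.raises(ValueError):
            select_top_k(ranking, 6)
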