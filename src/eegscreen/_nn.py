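"""Minimal feed-forward classifier in numpy.

Architecture: repeated [dense -> batch-norm -> ReLU -> dropout] blocks, then a
dense layer and 2-way softmax, trained with Nadam on mini-batch cross-entropy
with optional early stopping on validation loss. Fully deterministic for a
given seed.
"""

from __future__ import annotations

import numpy as np

_BN_EPS = 1e-5


class MLPNet:
    def __init__(
        self,
        input_dim: int,
        hidden_sizes: tuple[int, ...],
        n_classes: int = 2,
        dropout: float = 0.5,
        learning_rate: float = 1e-3,
        batch_size: int = 16,
        max_epochs: int = 30,
        patience: int = 5,
        seed: int = 0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        bn_momentum: float = 0.9,
    ) -> None:
        if not 0 <= dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        self.input_dim = input_dim
        self.hidden_sizes = tuple(hidden_sizes)
        self.n_classes = n_classes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.beta1, self.beta2 = beta1, beta2
        self.bn_momentum = bn_momentum
        self._init_params()

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.seed)
        dims = [self.input_dim, *self.hidden_sizes]
        self.params: dict[str, np.ndarray] = {}
        for i in range(len(self.hidden_sizes)):
            fan_in = dims[i]
            self.params[f"W{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(dims[i], dims[i + 1])
            )
            self.params[f"b{i}"] = np.zeros(dims[i + 1])
            self.params[f"g{i}"] = np.ones(dims[i + 1])
            self.params[f"be{i}"] = np.zeros(dims[i + 1])
        L = len(self.hidden_sizes)
        self.params[f"W{L}"] = rng.normal(
            0.0, np.sqrt(2.0 / dims[-1]), size=(dims[-1], self.n_classes)
        )
        self.params[f"b{L}"] = np.zeros(self.n_classes)
        self.running_mean = [np.zeros(h) for h in self.hidden_sizes]
        self.running_var = [np.ones(h) for h in self.hidden_sizes]
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self._rng = rng

    # ------------------------------------------------------------------
    def _forward_train(self, X: np.ndarray):
        cache: list[dict] = []
        h = X
        for i in range(len(self.hidden_sizes)):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            inv = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (z - mu) * inv
            bn = self.params[f"g{i}"] * xhat + self.params[f"be{i}"]
            relu = np.maximum(bn, 0.0)
            if self.dropout > 0:
                mask = (
                    self._rng.random(relu.shape) >= self.dropout
                ) / (1.0 - self.dropout)
            else:
                mask = np.ones_like(relu)
            out = relu * mask
            mom = self.bn_momentum
            self.running_mean[i] = mom * self.running_mean[i] + (1 - mom) * mu
            self.running_var[i] = mom * self.running_var[i] + (1 - mom) * var
            cache.append(
                {"h": h, "z": z, "mu": mu, "inv": inv, "xhat": xhat,
                 "bn": bn, "mask": mask}
            )
            h = out
        L = len(self.hidden_sizes)
        logits = h @ self.params[f"W{L}"] + self.params[f"b{L}"]
        cache.append({"h": h})
        return logits, cache

    def _backward(self, cache, dlogits) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        L = len(self.hidden_sizes)
        grads[f"W{L}"] = cache[L]["h"].T @ dlogits
        grads[f"b{L}"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params[f"W{L}"].T
        for i in range(L - 1, -1, -1):
            c = cache[i]
            B = c["z"].shape[0]
            drelu = dh * c["mask"]
            dbn = drelu * (c["bn"] > 0)
            grads[f"g{i}"] = (dbn * c["xhat"]).sum(axis=0)
            grads[f"be{i}"] = dbn.sum(axis=0)
            dxhat = dbn * self.params[f"g{i}"]
            # batch-norm backward (vectorized standard form)
            dz = (
                c["inv"] / B
                * (
                    B * dxhat
                    - dxhat.sum(axis=0)
                    - c["xhat"] * (dxhat * c["xhat"]).sum(axis=0)
                )
            )
            grads[f"W{i}"] = c["h"].T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"W{i}"].T
        return grads

    def _nadam_step(self, grads: dict[str, np.ndarray]) -> None:
        self._adam_t += 1
        t, b1, b2 = self._adam_t, self.beta1, self.beta2
        lr, eps = self.learning_rate, 1e-8
        for k, g in grads.items():
            m = self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            v = self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            m_hat = m / (1 - b1**t)
            v_hat = v / (1 - b2**t)
            update = (b1 * m_hat + (1 - b1) * g / (1 - b1**t)) / (
                np.sqrt(v_hat) + eps
            )
            self.params[k] -= lr * update

    # ------------------------------------------------------------------
    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _log_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        proba = self.predict_proba(X)
        p = np.clip(proba[np.arange(len(y)), y], 1e-12, None)
        return float(-np.mean(np.log(p)))

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "MLPNet":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.intp)
        n = len(X)
        best_loss = np.inf
        best_state = None
        stale = 0
        for _ in range(self.max_epochs):
            perm = self._rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = perm[start : start + self.batch_size]
                if len(idx) < 2:
                    continue  # batch statistics need >= 2 samples
                logits, cache = self._forward_train(X[idx])
                proba = self._softmax(logits)
                dlogits = proba.copy()
                dlogits[np.arange(len(idx)), y[idx]] -= 1.0
                dlogits /= len(idx)
                self._nadam_step(self._backward(cache, dlogits))
            if X_val is not None and len(X_val):
                loss = self._log_loss(X_val, y_val)
                if loss < best_loss - 1e-6:
                    best_loss = loss
                    best_state = self._snapshot()
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        if best_state is not None:
            self._restore(best_state)
        return self

    def _snapshot(self):
        return (
            {k: v.copy() for k, v in self.params.items()},
            [v.copy() for v in self.running_mean],
            [v.copy() for v in self.running_var],
        )

    def _restore(self, state) -> None:
        params, rmean, rvar = state
        self.params = {k: v.copy() for k, v in params.items()}
        self.running_mean = [v.copy() for v in rmean]
        self.running_var = [v.copy() for v in rvar]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        h = np.asarray(X, dtype=np.float64)
        for i in range(len(self.hidden_sizes)):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            xhat = (z - self.running_mean[i]) / np.sqrt(
                self.running_var[i] + _BN_EPS
            )
            h = np.maximum(self.params[f"g{i}"] * xhat + self.params[f"be{i}"], 0.0)
        L = len(self.hidden_sizes)
        return self._softmax(h @ self.params[f"W{L}"] + self.params[f"b{L}"])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)
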