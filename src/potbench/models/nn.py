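"""Feed-forward neural network regression with a masked multi-task loss.

A ReLU multilayer perceptron maps a 1024-bit fingerprint to one output neuron
per target.  Because the compound x target label matrix is sparse, the
training loss is a *masked* mean squared error: only (compound, target)
entries flagged in a boolean mask contribute to the loss and hence to the
gradient, so missing annotations and held-out test labels never influence the
weights.  Training uses the Adam optimizer, optional inverted dropout and
batch normalization, and early termination on a held-out validation slice of
the training data (best weights restored), up to a maximum epoch budget.

The network is implemented directly on NumPy arrays with explicit
backpropagation, which keeps the gradient of the masked loss fully
inspectable (see :func:`masked_mse_grad`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["masked_mse_loss", "masked_mse_grad", "MaskedMLPRegressor"]


def masked_mse_loss(pred: np.ndarray, labels: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared error over masked-in entries only.

    ``pred`` and ``labels`` are dense (n, k) arrays; ``mask`` is boolean of
    the same shape.  Values at masked-out positions (including NaN labels)
    are ignored entirely.  Raises ``ValueError`` on an empty mask — there is
    nothing to train on.
    """
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if pred.shape != labels.shape or pred.shape != mask.shape:
        raise ValueError("pred, labels and mask must have identical shapes")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: no labels to compute the loss on")
    diff = np.where(mask, pred - labels, 0.0)
    return float(np.sum(diff * diff) / n)


def masked_mse_grad(pred: np.ndarray, labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Gradient of :func:`masked_mse_loss` with respect to ``pred``.

    Exactly zero at every masked-out position: missing or held-out labels
    contribute no gradient signal.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: no labels to compute the loss on")
    return np.where(mask, 2.0 * (np.asarray(pred, float) - np.asarray(labels, float)) / n, 0.0)


@dataclass
class _Layer:
    W: np.ndarray
    b: np.ndarray
    # batch-norm parameters (hidden layers only)
    gamma: np.ndarray | None = None
    beta: np.ndarray | None = None
    run_mean: np.ndarray | None = None
    run_var: np.ndarray | None = None


class MaskedMLPRegressor:
    """ReLU MLP trained with Adam on the masked MSE loss.

    Parameters mirror the hyper-parameter search space of the benchmark:
    hidden layer widths, learning rate, dropout rate, batch size and batch
    normalization on/off.  ``max_epochs`` defaults to 200 with early
    termination (10% validation holdout, patience 10, best weights restored).
    """

    def __init__(
        self,
        hidden_layers: tuple[int, ...] = (2000, 1000),
        n_outputs: int = 1,
        learning_rate: float = 1e-4,
        dropout: float = 0.1,
        batch_size: int = 128,
        batch_norm: bool = False,
        max_epochs: int = 200,
        patience: int = 10,
        val_fraction: float = 0.1,
        seed: int = 0,
    ):
        self.hidden_layers = tuple(int(w) for w in hidden_layers)
        self.n_outputs = int(n_outputs)
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.batch_size = int(batch_size)
        self.batch_norm = batch_norm
        self.max_epochs = int(max_epochs)
        self.patience = int(patience)
        self.val_fraction = val_fraction
        self.seed = int(seed)
        self.layers_: list[_Layer] | None = None
        self.n_epochs_: int = 0

    # -- construction -------------------------------------------------------

    def _init_layers(self, n_features: int, rng: np.random.Generator, y0: np.ndarray) -> None:
        widths = [n_features, *self.hidden_layers, self.n_outputs]
        self.layers_ = []
        for i in range(len(widths) - 1):
            fan_in, fan_out = widths[i], widths[i + 1]
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            b = np.zeros(fan_out)
            layer = _Layer(W=W, b=b)
            hidden = i < len(widths) - 2
            if hidden and self.batch_norm:
                layer.gamma = np.ones(fan_out)
                layer.beta = np.zeros(fan_out)
                layer.run_mean = np.zeros(fan_out)
                layer.run_var = np.ones(fan_out)
            self.layers_.append(layer)
        # start the output head at the masked label mean: pKi lives around 5-11
        self.layers_[-1].b[:] = y0

    def _params(self) -> list[np.ndarray]:
        ps = []
        for layer in self.layers_:
            ps += [layer.W, layer.b]
            if layer.gamma is not None:
                ps += [layer.gamma, layer.beta]
        return ps

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool, rng: np.random.Generator | None):
        cache = []
        a = X
        eps = 1e-5
        for i, layer in enumerate(self.layers_[:-1]):
            z = a @ layer.W + layer.b
            bn_cache = None
            if layer.gamma is not None:
                if training:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    layer.run_mean = 0.9 * layer.run_mean + 0.1 * mu
                    layer.run_var = 0.9 * layer.run_var + 0.1 * var
                else:
                    mu, var = layer.run_mean, layer.run_var
                zhat = (z - mu) / np.sqrt(var + eps)
                bn_cache = (zhat, var)
                z = layer.gamma * zhat + layer.beta
            h = np.maximum(z, 0.0)
            drop = None
            if training and self.dropout > 0.0:
                drop = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * drop
            cache.append((a, z, bn_cache, drop))
            a = h
        out_layer = self.layers_[-1]
        yhat = a @ out_layer.W + out_layer.b
        cache.append((a, None, None, None))
        return yhat, cache

    def _backward(self, cache, d_yhat: np.ndarray) -> list[np.ndarray]:
        grads: list[np.ndarray] = []
        eps = 1e-5
        a_last = cache[-1][0]
        out_layer = self.layers_[-1]
        gW_out = a_last.T @ d_yhat
        gb_out = d_yhat.sum(axis=0)
        da = d_yhat @ out_layer.W.T
        layer_grads = [[gW_out, gb_out]]
        for i in range(len(self.layers_) - 2, -1, -1):
            layer = self.layers_[i]
            a_prev, z_post, bn_cache, drop = cache[i]
            dh = da
            if drop is not None:
                dh = dh * drop
            dz = dh * (z_post > 0.0)
            g_extra = []
            if layer.gamma is not None:
                zhat, var = bn_cache
                m = dz.shape[0]
                dgamma = (dz * zhat).sum(axis=0)
                dbeta = dz.sum(axis=0)
                dzhat = dz * layer.gamma
                inv_std = 1.0 / np.sqrt(var + eps)
                dz = (inv_std / m) * (
                    m * dzhat - dzhat.sum(axis=0) - zhat * (dzhat * zhat).sum(axis=0)
                )
                g_extra = [dgamma, dbeta]
            gW = a_prev.T @ dz
            gb = dz.sum(axis=0)
            da = dz @ layer.W.T
            layer_grads.append([gW, gb, *g_extra])
        for lg in reversed(layer_grads):
            grads += lg
        return grads

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray, mask: np.ndarray | None = None) -> "MaskedMLPRegressor":
        """Train on fingerprints X (n, d) and labels Y (n, k) under ``mask``.

        ``mask`` defaults to all-observed (non-NaN) entries; an all-empty
        mask raises.  1-D ``Y`` is treated as a single-output task.
        """
        X = np.asarray(X, dtype=np.float64)
        Y = np.asarray(Y, dtype=np.float64)
        if Y.ndim == 1:
            Y = Y[:, None]
        if mask is None:
            mask = ~np.isnan(Y)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != Y.shape:
            raise ValueError("mask shape must match label shape")
        if not mask.any():
            raise ValueError("empty mask: nothing to train on")
        if Y.shape[1] != self.n_outputs:
            raise ValueError(f"expected {self.n_outputs} outputs, got {Y.shape[1]}")
        Yz = np.where(mask, Y, 0.0)

        rng = np.random.default_rng(self.seed)
        y0 = Yz.sum(axis=0) / np.maximum(mask.sum(axis=0), 1)
        y0 = np.where(mask.any(axis=0), y0, Yz.sum() / mask.sum())
        self._init_layers(X.shape[1], rng, y0)

        n = X.shape[0]
        # validation holdout for early termination; fall back to no holdout
        # when the data is too small to spare rows on both sides
        n_val = int(round(self.val_fraction * n))
        use_val = n_val >= 1 and n - n_val >= 2
        perm = rng.permutation(n)
        if use_val:
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            if not mask[val_idx].any() or not mask[tr_idx].any():
                use_val = False
        if not use_val:
            tr_idx = perm
            val_idx = np.array([], dtype=int)

        params = self._params()
        m_adam = [np.zeros_like(p) for p in params]
        v_adam = [np.zeros_like(p) for p in params]
        t_adam = 0
        beta1, beta2, eps_adam = 0.9, 0.999, 1e-8

        best_loss = np.inf
        best_state = [p.copy() for p in params]
        best_bn = self._bn_state()
        stale = 0
        bs = max(1, min(self.batch_size, len(tr_idx)))
        for epoch in range(self.max_epochs):
            order = tr_idx[rng.permutation(len(tr_idx))]
            for start in range(0, len(order), bs):
                idx = order[start : start + bs]
                mb = mask[idx]
                if not mb.any():
                    continue
                yhat, cache = self._forward(X[idx], training=True, rng=rng)
                d_yhat = masked_mse_grad(yhat, Yz[idx], mb)
                grads = self._backward(cache, d_yhat)
                t_adam += 1
                for p, g, mm, vv in zip(params, grads, m_adam, v_adam):
                    mm *= beta1
                    mm += (1 - beta1) * g
                    vv *= beta2
                    vv += (1 - beta2) * g * g
                    mhat = mm / (1 - beta1**t_adam)
                    vhat = vv / (1 - beta2**t_adam)
                    p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps_adam)
            self.n_epochs_ = epoch + 1
            if use_val:
                val_pred, _ = self._forward(X[val_idx], training=False, rng=None)
                val_loss = masked_mse_loss(val_pred, Yz[val_idx], mask[val_idx])
                if val_loss < best_loss - 1e-9:
                    best_loss = val_loss
                    best_state = [p.copy() for p in params]
                    best_bn = self._bn_state()
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        if use_val:
            for p, bp in zip(params, best_state):
                p[...] = bp
            self._restore_bn(best_bn)
        return self

    def _bn_state(self):
        return [
            (None if l.run_mean is None else l.run_mean.copy(),
             None if l.run_var is None else l.run_var.copy())
            for l in self.layers_
        ]

    def _restore_bn(self, state) -> None:
        for layer, (rm, rv) in zip(self.layers_, state):
            if rm is not None:
                layer.run_mean, layer.run_var = rm, rv

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Dense (n, k) predictions; callers apply availability masks."""
        if self.layers_ is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=np.float64)
        yhat, _ = self._forward(X, training=False, rng=None)
        return yhat
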