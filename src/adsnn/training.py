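"""Minimal gradient trainer for analog networks with the ASN transfer function.

Trains small fully connected classifiers whose hidden units use the adaptive
neuron transfer function f(S) as their activation (AAN units), with
categorical cross-entropy loss and plain mini-batch gradient descent.  Batch
normalization (optional, recommended for the saturating half-sigmoid) is
trained with batch statistics and frozen to full-training-set statistics at
the end, so the exported network is deterministic.  Inputs are standardized
with training-set statistics stored on the input layer, mirroring the use of
a normalizing first layer ahead of the input spike encoders.

The resulting :class:`~adsnn.network.NetworkSpec` is ready for conversion to
a spiking network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from . import transfer
from .asn_core import ASNParams
from .network import LayerSpec, NetworkSpec, forward_ann, softmax

__all__ = ["TrainConfig", "train_mlp", "fixture_network", "accuracy"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the toy trainer."""

    hidden: Tuple[int, ...] = (20, 20)
    epochs: int = 200
    lr: float = 0.2
    batch_size: int = 32
    use_batchnorm: bool = True
    bn_eps: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden):
            raise ValueError("hidden sizes must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.lr <= 0 or self.batch_size <= 0:
            raise ValueError("lr and batch_size must be > 0")


def accuracy(spec: NetworkSpec, X: np.ndarray, y: np.ndarray) -> float:
    """Classification accuracy (fraction) of the analog forward pass."""
    probs = forward_ann(spec, X)
    return float(np.mean(probs.argmax(axis=1) == y))


def train_mlp(
    data, config: TrainConfig, params: Optional[ASNParams] = None
) -> NetworkSpec:
    """Train a dense AAN classifier on a :class:`~adsnn.toydata.ToyDataset`.

    Returns a :class:`NetworkSpec` with input standardization, dense layers
    (with batch-normalization layers when ``config.use_batchnorm``) and a
    softmax readout.  Training is seeded and reproducible.
    """
    params = params if params is not None else ASNParams()
    if params.h is None:
        params = transfer.normalized_params(params)
    constants = transfer.compute_constants(params)

    X, y = np.asarray(data.X_train, dtype=float), np.asarray(data.y_train)
    n, d = X.shape
    K = int(data.n_classes)
    mu, var = X.mean(axis=0), X.var(axis=0)
    Xs = (X - mu) / np.sqrt(var)

    rng = np.random.default_rng(config.seed)
    sizes = [d, *config.hidden, K]
    weights = [
        rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_out, fan_in))
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:])
    ]
    biases = [np.zeros(s) for s in sizes[1:]]
    n_hidden = len(config.hidden)
    use_bn = config.use_batchnorm
    gammas = [np.ones(s) for s in config.hidden]
    betas = [np.zeros(s) for s in config.hidden]

    def hidden_forward(xb):
        """Forward through the hidden stack; returns activations and caches."""
        a = transfer.aan_activation(xb, constants)
        caches = []
        for l in range(n_hidden):
            z = a @ weights[l].T + biases[l]
            if use_bn:
                bmu, bvar = z.mean(axis=0), z.var(axis=0)
                invstd = 1.0 / np.sqrt(bvar + config.bn_eps)
                zhat = (z - bmu) * invstd
                u = gammas[l] * zhat + betas[l]
            else:
                zhat, invstd, u = None, None, z
            a_next = transfer.aan_activation(u, constants)
            caches.append((a, zhat, invstd, u, a_next))
            a = a_next
        return a, caches

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = Xs[idx], y[idx]
            B = len(idx)
            a, caches = hidden_forward(xb)
            logits = a @ weights[-1].T + biases[-1]
            probs = softmax(logits)
            if not np.all(np.isfinite(probs)):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite outputs"
                )
            dlogits = probs.copy()
            dlogits[np.arange(B), yb] -= 1.0
            dlogits /= B

            grads_w = [None] * len(weights)
            grads_b = [None] * len(weights)
            grads_w[-1] = dlogits.T @ a
            grads_b[-1] = dlogits.sum(axis=0)
            da = dlogits @ weights[-1]
            for l in range(n_hidden - 1, -1, -1):
                a_in, zhat, invstd, u, _ = caches[l]
                du = da * transfer.aan_derivative(u, constants)
                if use_bn:
                    dgamma = (du * zhat).sum(axis=0)
                    dbeta = du.sum(axis=0)
                    dzhat = du * gammas[l]
                    dz = (
                        invstd
                        / B
                        * (
                            B * dzhat
                            - dzhat.sum(axis=0)
                            - zhat * (dzhat * zhat).sum(axis=0)
                        )
                    )
                    gammas[l] -= config.lr * dgamma
                    betas[l] -= config.lr * dbeta
                else:
                    dz = du
                grads_w[l] = dz.T @ a_in
                grads_b[l] = dz.sum(axis=0)
                da = dz @ weights[l]
            for l in range(len(weights)):
                weights[l] -= config.lr * grads_w[l]
                biases[l] -= config.lr * grads_b[l]
        wmax = max(np.abs(w).max() for w in weights)
        if not np.isfinite(wmax) or wmax > 1e6:
            raise RuntimeError(
                f"training diverged at epoch {epoch}: max |weight| = {wmax:.3g}"
            )

    layers = [
        LayerSpec(
            kind="input",
            bn_mean=mu,
            bn_var=var,
            bn_scale=np.ones(d),
            bn_offset=np.zeros(d),
            bn_eps=0.0,
        )
    ]
    if use_bn and config.epochs > 0:
        # freeze BN statistics over the full training set (deterministic)
        a = transfer.aan_activation(Xs, constants)
        for l in range(n_hidden):
            z = a @ weights[l].T + biases[l]
            layers.append(LayerSpec(kind="dense", weights=weights[l], bias=biases[l]))
            layers.append(
                LayerSpec(
                    kind="batchnorm",
                    bn_mean=z.mean(axis=0),
                    bn_var=z.var(axis=0),
                    bn_scale=gammas[l].copy(),
                    bn_offset=betas[l].copy(),
                    bn_eps=config.bn_eps,
                )
            )
            invstd = 1.0 / np.sqrt(z.var(axis=0) + config.bn_eps)
            u = gammas[l] * (z - z.mean(axis=0)) * invstd + betas[l]
            a = transfer.aan_activation(u, constants)
    else:
        for l in range(n_hidden):
            layers.append(LayerSpec(kind="dense", weights=weights[l], bias=biases[l]))
    layers.append(LayerSpec(kind="readout", weights=weights[-1], bias=biases[-1]))

    return NetworkSpec(
        layers=layers,
        params=params,
        metadata={"dataset": getattr(data, "tag", "unknown"), "seed": config.seed},
    )


def fixture_network(params: Optional[ASNParams] = None) -> NetworkSpec:
    """Hand-set 2-2-2 network with documented weights for exact-value tests.

    Hidden layer: W1 = [[1.0, -0.5], [0.25, 1.0]], b1 = [0.0, 0.1];
    readout:      W2 = [[1.2, -0.6], [-0.4, 1.0]], b2 = [0.05, -0.05].
    """
    params = params if params is not None else ASNParams()
    if params.h is None:
        params = transfer.normalized_params(params)
    layers = [
        LayerSpec(kind="input"),
        LayerSpec(
            kind="dense",
            weights=np.array([[1.0, -0.5], [0.25, 1.0]]),
            bias=np.array([0.0, 0.1]),
        ),
        LayerSpec(
            kind="readout",
            weights=np.array([[1.2, -0.6], [-0.4, 1.0]]),
            bias=np.array([0.05, -0.05]),
        ),
    ]
    return NetworkSpec(layers=layers, params=params, metadata={"dataset": "fixture"})
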