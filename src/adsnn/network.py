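"""Analog network descriptions and their conversion to spiking networks.

An analog network trained with the adaptive-neuron transfer function f(S)
(an "AAN" network) is described as an ordered list of :class:`LayerSpec`.
Conversion to a spiking network is unit-for-unit: every analog unit becomes
an adaptive spiking neuron with shared parameters, the trained weights are
kept, and the normalized spike height h scales the per-spike postsynaptic
impact so layers communicate with binary spikes only.

Conversion rules:

* batch-normalization layers are folded into the preceding layer's weights
  and biases (exact, function preserving);
* an input encoding layer (optionally with its own normalization statistics)
  turns analog features into spike trains;
* pooling layers are merged into the next spiking layer: the merged layer
  first filters incoming spikes into per-unit activations, applies the
  pooling operator on those analog traces, and only then computes its own
  weighted activation and spikes;
* biases are added to the postsynaptic activation S, not passed through the
  synaptic filters;
* the last layer is a non-spiking smoothed readout (slow membrane filter,
  50 ms by default) followed by softmax at every timestep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from . import transfer
from .asn_core import ASNParams, ASNState, psp_scale, step_neuron

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "MergedPool",
    "SpikingNetwork",
    "fold_batchnorm",
    "fold_network",
    "merge_pooling",
    "convert",
    "forward_ann",
    "softmax",
]

LAYER_KINDS = ("input", "dense", "conv2d", "maxpool", "avgpool", "batchnorm", "readout")

#: membrane-filter time constant (ms) of the smoothed readout layer
READOUT_TAU_PHI = 50.0


@dataclass
class LayerSpec:
    """One layer of an analog network.

    ``weights``/``bias`` apply to dense (out x in), conv2d
    (out_ch x in_ch x kh x kw) and readout layers.  ``bn_*`` fields hold
    per-channel batch-normalization statistics for ``batchnorm`` layers and,
    on the ``input`` layer, an optional fixed feature standardization.
    """

    kind: str
    weights: Optional[np.ndarray] = None
    bias: Optional[np.ndarray] = None
    pool_size: Optional[int] = None
    stride: int = 1
    padding: str = "same"
    bn_mean: Optional[np.ndarray] = None
    bn_var: Optional[np.ndarray] = None
    bn_scale: Optional[np.ndarray] = None
    bn_offset: Optional[np.ndarray] = None
    bn_eps: float = 1e-3

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("dense", "readout"):
            if self.weights is None or self.weights.ndim != 2:
                raise ValueError(f"{self.kind} layer needs a 2-D weight matrix")
        if self.kind == "conv2d":
            if self.weights is None or self.weights.ndim != 4:
                raise ValueError("conv2d layer needs a 4-D kernel tensor")
        if self.kind in ("maxpool", "avgpool"):
            if self.pool_size is None or self.pool_size < 2:
                raise ValueError("pooling needs pool_size >= 2")
        if self.kind == "batchnorm":
            for name in ("bn_mean", "bn_var", "bn_scale", "bn_offset"):
                if getattr(self, name) is None:
                    raise ValueError(f"batchnorm layer needs {name}")
            if np.any(np.asarray(self.bn_var) <= 0):
                raise ValueError("batchnorm variance must be > 0")
        if self.weights is not None and self.bias is not None:
            if self.weights.shape[0] != self.bias.shape[0]:
                raise ValueError("bias length must match the number of output units")

    @property
    def has_bn(self) -> bool:
        return self.bn_mean is not None

    def out_features(self) -> Optional[int]:
        if self.weights is not None:
            return self.weights.shape[0]
        return None


@dataclass
class NetworkSpec:
    """Ordered analog network description plus the neuron parameters it was
    trained with and free-form metadata (dataset tag, seed, ...)."""

    layers: List[LayerSpec]
    params: ASNParams = field(default_factory=ASNParams)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("network needs at least one layer")
        if self.layers[0].kind != "input":
            raise ValueError("first layer must be the input encoder")
        if self.layers[-1].kind != "readout":
            raise ValueError("last layer must be the readout")
        if self.layers[-2].kind in ("maxpool", "avgpool", "batchnorm"):
            # pooling merges forward and BN folds backward; neither has a
            # carrier if it directly precedes the readout's weights... the
            # readout is a weighted layer, so only pooling-last is illegal.
            if self.layers[-2].kind != "batchnorm":
                pass
        for layer in self.layers[1:-1]:
            if layer.kind in ("input", "readout"):
                raise ValueError("input/readout layers only at the ends")


@dataclass(frozen=True)
class MergedPool:
    """Plan for a pooling layer merged into the following spiking layer."""

    pool_kind: str  # "max" or "avg"
    pool_size: int
    layer: LayerSpec


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _bn_apply(z: np.ndarray, layer: LayerSpec) -> np.ndarray:
    shape = (1, -1) + (1,) * (z.ndim - 2)
    mean = np.asarray(layer.bn_mean).reshape(shape)
    var = np.asarray(layer.bn_var).reshape(shape)
    scale = np.asarray(layer.bn_scale).reshape(shape)
    offset = np.asarray(layer.bn_offset).reshape(shape)
    return scale * (z - mean) / np.sqrt(var + layer.bn_eps) + offset


def _input_affine(x: np.ndarray, layer: LayerSpec) -> np.ndarray:
    if not layer.has_bn:
        return x
    return _bn_apply(x, layer)


def conv2d_forward(
    x: np.ndarray, weights: np.ndarray, stride: int = 1, padding: str = "same"
) -> np.ndarray:
    """Strided 2-D cross-correlation, NCHW layout, zero padding."""
    out_ch, in_ch, kh, kw = weights.shape
    if x.shape[1] != in_ch:
        raise ValueError("channel mismatch in conv2d")
    if padding == "same":
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
        x = np.pad(x, ((0, 0), (0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw)))
    elif padding != "valid":
        raise ValueError("padding must be 'same' or 'valid'")
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]
    return np.einsum("nchwij,ocij->nohw", windows, weights, optimize=True)


def pool_forward(x: np.ndarray, pool_size: int, kind: str) -> np.ndarray:
    """Non-overlapping 2-D pooling (NCHW); spatial dims must divide evenly."""
    n, c, hgt, wid = x.shape
    p = pool_size
    if hgt % p or wid % p:
        raise ValueError("pooling requires spatial dims divisible by pool_size")
    blocks = x.reshape(n, c, hgt // p, p, wid // p, p)
    if kind == "max":
        return blocks.max(axis=(3, 5))
    return blocks.mean(axis=(3, 5))


def fold_batchnorm(layer: LayerSpec, bn: LayerSpec) -> LayerSpec:
    """Fold a batch-normalization layer into the preceding weighted layer.

    Returns a layer computing exactly ``bn(layer(x))``:
    ``w' = w * scale / sqrt(var + eps)`` per output channel and
    ``b' = (b - mean) * scale / sqrt(var + eps) + offset``.
    """
    if bn.kind != "batchnorm":
        raise ValueError("second argument must be a batchnorm layer")
    if layer.kind not in ("dense", "conv2d", "readout"):
        raise ValueError(f"cannot fold batchnorm into a {layer.kind} layer")
    n_out = layer.weights.shape[0]
    mean = np.asarray(bn.bn_mean, dtype=float)
    if mean.shape[0] != n_out:
        raise ValueError("batchnorm width does not match the layer's outputs")
    factor = np.asarray(bn.bn_scale) / np.sqrt(np.asarray(bn.bn_var) + bn.bn_eps)
    w_shape = (n_out,) + (1,) * (layer.weights.ndim - 1)
    bias = layer.bias if layer.bias is not None else np.zeros(n_out)
    return replace(
        layer,
        weights=layer.weights * factor.reshape(w_shape),
        bias=(bias - mean) * factor + np.asarray(bn.bn_offset, dtype=float),
        bn_mean=None,
        bn_var=None,
        bn_scale=None,
        bn_offset=None,
    )


def fold_network(spec: NetworkSpec) -> NetworkSpec:
    """Fold every batchnorm layer into its predecessor; input-layer
    standardization is kept on the input layer (it is already an affine map)."""
    layers: List[LayerSpec] = []
    for layer in spec.layers:
        if layer.kind == "batchnorm":
            if not layers or layers[-1].kind not in ("dense", "conv2d", "readout"):
                raise ValueError("batchnorm must follow a weighted layer")
            layers[-1] = fold_batchnorm(layers[-1], layer)
        else:
            layers.append(layer)
    return replace(spec, layers=layers)


def merge_pooling(pool: LayerSpec, next_layer: LayerSpec) -> MergedPool:
    """Merge a pooling layer into the next spiking layer.

    In the spiking network the merged layer computes its incoming analog
    activations from spikes first, applies the pooling operator on those
    traces, and then produces spikes; this mirrors analog pooling of
    activations because the transfer function is monotone.
    """
    if pool.kind not in ("maxpool", "avgpool"):
        raise ValueError("first argument must be a pooling layer")
    if next_layer.kind not in ("dense", "conv2d", "readout"):
        raise ValueError("pooling must precede a weighted layer")
    return MergedPool(
        pool_kind="max" if pool.kind == "maxpool" else "avg",
        pool_size=pool.pool_size,
        layer=next_layer,
    )


def forward_ann(
    spec: NetworkSpec,
    x: np.ndarray,
    params: Optional[ASNParams] = None,
    return_hidden: bool = False,
):
    """Reference analog forward pass with the AAN transfer function.

    Returns softmax class probabilities of shape (n, K); with
    ``return_hidden`` also a list of post-activation arrays per weighted
    layer (the quantities the spiking network's decoded traces approximate).
    """
    params = params if params is not None else spec.params
    if params.h is None:
        params = transfer.normalized_params(params)
    constants = transfer.compute_constants(params)

    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if not np.all(np.isfinite(x)):
        raise ValueError("inputs must be finite")

    hidden: List[np.ndarray] = []
    a: np.ndarray = x
    layers = spec.layers
    i = 0
    while i < len(layers):
        layer = layers[i]
        if layer.kind == "input":
            a = transfer.aan_activation(_input_affine(a, layer), constants)
            hidden.append(a)
        elif layer.kind in ("dense", "conv2d", "readout"):
            if layer.kind == "conv2d":
                z = conv2d_forward(a, layer.weights, layer.stride, layer.padding)
                if layer.bias is not None:
                    z = z + layer.bias.reshape(1, -1, 1, 1)
            else:
                if a.ndim > 2:
                    a = a.reshape(a.shape[0], -1)
                z = a @ layer.weights.T
                if layer.bias is not None:
                    z = z + layer.bias
            if i + 1 < len(layers) and layers[i + 1].kind == "batchnorm":
                z = _bn_apply(z, layers[i + 1])
                i += 1
            if layer.kind == "readout":
                out = softmax(z)
                return (out, hidden) if return_hidden else out
            a = transfer.aan_activation(z, constants)
            hidden.append(a)
        elif layer.kind in ("maxpool", "avgpool"):
            a = pool_forward(a, layer.pool_size, "max" if layer.kind == "maxpool" else "avg")
        else:  # pragma: no cover - batchnorm handled with its predecessor
            raise ValueError("batchnorm must follow a weighted layer")
        i += 1
    raise ValueError("network did not end in a readout layer")


# --------------------------------------------------------------------------
# spiking execution


class _Stage:
    """One spiking layer: weighted input (optionally through a merged pooling
    front end) driving a population of ASNs."""

    def __init__(self, layer: LayerSpec, pool: Optional[MergedPool], params: ASNParams):
        self.layer = layer
        self.pool = pool
        self.params = params
        self.scale = psp_scale(params)
        self.state: Optional[ASNState] = None
        self.front: Optional[Tuple[np.ndarray, np.ndarray]] = None  # psc, s of pool front
        self.fan_out: Optional[np.ndarray] = None  # per-neuron synapse count

    def reset(self, in_shape: Tuple[int, ...], batch: int) -> Tuple[int, ...]:
        """Allocate state for a batch; returns this stage's output shape."""
        if self.layer.kind == "dense":
            if self.pool is None and len(in_shape) > 1:
                in_shape = (int(np.prod(in_shape)),)
            out_shape: Tuple[int, ...] = (self.layer.weights.shape[0],)
        else:  # conv2d: infer from a dry run
            probe = np.zeros((1,) + in_shape)
            if self.pool is not None:
                probe = pool_forward(probe, self.pool.pool_size, self.pool.pool_kind)
            out_shape = conv2d_forward(
                probe, self.layer.weights, self.layer.stride, self.layer.padding
            ).shape[1:]
        if self.pool is not None:
            z = lambda: np.zeros((batch,) + in_shape)
            self.front = (z(), z())
        self.state = ASNState.fresh(self.params, (batch,) + out_shape)
        self.in_shape = in_shape
        self.out_shape = out_shape
        return out_shape

    def _weighted(self, a: np.ndarray) -> np.ndarray:
        if self.layer.kind == "dense":
            if a.ndim > 2:
                a = a.reshape(a.shape[0], -1)
            return a @ self.layer.weights.T
        return conv2d_forward(a, self.layer.weights, self.layer.stride, self.layer.padding)

    def step(self, spikes_in: np.ndarray) -> np.ndarray:
        bias = self.layer.bias if self.layer.bias is not None else 0.0
        if self.layer.kind == "conv2d" and np.ndim(bias):
            bias = np.reshape(bias, (1, -1, 1, 1))
        if self.pool is None:
            drive = self.scale * self._weighted(spikes_in.astype(float))
            _, spikes = step_neuron(self.state, drive, self.params, bias=bias)
        else:
            # merged pooling: filter incoming spikes into per-unit analog
            # activations, pool those traces, then weight and spike.
            psc, s = self.front
            a_beta = self.params.decay(self.params.tau_beta)
            a_phi = self.params.decay(self.params.tau_phi)
            psc *= a_beta
            psc += (1.0 - a_beta) * self.scale * spikes_in
            s *= a_phi
            s += (1.0 - a_phi) * psc
            pooled = pool_forward(s, self.pool.pool_size, self.pool.pool_kind)
            activation = self._weighted(pooled)
            _, spikes = step_neuron(
                self.state, 0.0, self.params, bias=bias, activation=activation
            )
        return spikes

    def set_params(self, params: ASNParams) -> None:
        self.params = params
        self.scale = psp_scale(params)


class _Readout:
    """Non-spiking smoothed readout: slow membrane filter over weighted
    incoming spikes, bias added to the filtered activation."""

    def __init__(self, layer: LayerSpec, params: ASNParams, tau_phi: float):
        self.layer = layer
        self.params = params
        self.tau_phi = tau_phi
        self.scale = psp_scale(params)
        self.psc: Optional[np.ndarray] = None
        self.s: Optional[np.ndarray] = None

    def reset(self, in_shape: Tuple[int, ...], batch: int) -> Tuple[int, ...]:
        out = (self.layer.weights.shape[0],)
        self.psc = np.zeros((batch,) + out)
        self.s = np.zeros((batch,) + out)
        return out

    def step(self, spikes_in: np.ndarray) -> np.ndarray:
        a = spikes_in.astype(float)
        if a.ndim > 2:
            a = a.reshape(a.shape[0], -1)
        drive = self.scale * (a @ self.layer.weights.T)
        a_beta = np.exp(-self.params.dt / self.params.tau_beta)
        a_phi = np.exp(-self.params.dt / self.tau_phi)
        self.psc = a_beta * self.psc + (1.0 - a_beta) * drive
        self.s = a_phi * self.s + (1.0 - a_phi) * self.psc
        out = self.s
        if self.layer.bias is not None:
            out = out + self.layer.bias
        return out

    def set_params(self, params: ASNParams) -> None:
        self.params = params
        self.scale = psp_scale(params)


class SpikingNetwork:
    """A converted network of adaptive spiking neurons.

    Built by :func:`convert`; stepped by the simulation engine.  The analog
    weights are stored untouched; the (normalized) spike height enters only
    as a scale on per-spike postsynaptic impact, so re-converting at another
    resting threshold changes h but not the weights.
    """

    def __init__(self, spec: NetworkSpec, params: ASNParams):
        if params.h is None:
            params = transfer.normalized_params(params)
        self.spec = fold_network(spec)
        self.params = params
        layers = self.spec.layers
        self.input_layer = layers[0]
        self.input_state: Optional[ASNState] = None

        self.stages: List[_Stage] = []
        i = 1
        while i < len(layers) - 1:
            layer = layers[i]
            if layer.kind in ("maxpool", "avgpool"):
                if i + 1 >= len(layers) - 1:
                    raise ValueError("pooling cannot be the final layer")
                plan = merge_pooling(layer, layers[i + 1])
                self.stages.append(_Stage(plan.layer, plan, params))
                i += 2
            elif layer.kind in ("dense", "conv2d"):
                self.stages.append(_Stage(layer, None, params))
                i += 1
            else:
                raise ValueError(f"unsupported layer kind {layer.kind!r} after folding")
        if layers[-1].kind != "readout":
            raise ValueError("last layer must be the readout")
        self.readout = _Readout(layers[-1], params, READOUT_TAU_PHI)
        self.batch: Optional[int] = None

    # -- lifecycle ---------------------------------------------------------

    def reset(self, input_shape: Tuple[int, ...], batch: int) -> None:
        self.input_state = ASNState.fresh(self.params, (batch,) + tuple(input_shape))
        shape = tuple(input_shape)
        self._shapes = [shape]
        for stage in self.stages:
            shape = stage.reset(shape, batch)
            self._shapes.append(shape)
        self.readout.reset(shape, batch)
        self.batch = batch
        self._compute_fan_out()

    def _compute_fan_out(self) -> None:
        """Per-neuron outgoing synapse counts, used for SOP accounting."""
        self._fan_outs = []
        consumers = self.stages + [self.readout]
        for shape, consumer in zip(self._shapes, consumers):
            layer = consumer.layer
            if layer.kind in ("dense", "readout") or isinstance(consumer, _Readout):
                per_in = np.count_nonzero(layer.weights, axis=0).astype(float)
                pool = getattr(consumer, "pool", None)
                if pool is not None:
                    # every unit of a pooling window shares the pooled unit's
                    # outgoing synapses
                    per_in = np.repeat(per_in, pool.pool_size**2)[: int(np.prod(shape))]
                fan = per_in.reshape(shape) if per_in.size == np.prod(shape) else np.full(
                    shape, per_in.mean()
                )
            else:  # conv2d consumer: uniform kernel fan-out estimate
                out_ch, _, kh, kw = layer.weights.shape
                fan = np.full(shape, out_ch * kh * kw / consumer.layer.stride**2)
            self._fan_outs.append(fan.ravel())

    @property
    def n_spiking_neurons(self) -> int:
        """All spiking units (input encoders + hidden); the readout does not
        spike and is excluded."""
        return int(sum(np.prod(s) for s in self._shapes))

    # -- execution ---------------------------------------------------------

    def step(self, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Advance one dt with the input presented persistently.

        Returns (readout activations (batch, K), spikes per sample,
        synaptic operations per sample).
        """
        drive = _input_affine(np.asarray(x, dtype=float), self.input_layer)
        _, spikes = step_neuron(self.input_state, drive, self.params)
        n_spikes = spikes.reshape(len(spikes), -1).astype(float)
        sops = n_spikes @ self._fan_outs[0]
        n_spikes = n_spikes.sum(axis=1)
        for stage, fan in zip(self.stages, self._fan_outs[1:]):
            spikes = stage.step(spikes)
            flat = spikes.reshape(len(spikes), -1).astype(float)
            sops += flat @ fan
            n_spikes += flat.sum(axis=1)
        out = self.readout.step(spikes)
        return out, n_spikes, sops

    def forward_analog(self, x: np.ndarray) -> np.ndarray:
        """Analog forward pass of the (folded) converted network — the
        spikes-off reference the spiking dynamics converge to."""
        return forward_ann(self.spec, x, params=self.params)

    def snapshot(self) -> dict:
        """Deep copy of all dynamical state (for later :meth:`restore`)."""
        return {
            "input": self.input_state.copy(),
            "stages": [
                (
                    stage.state.copy(),
                    None
                    if stage.front is None
                    else (stage.front[0].copy(), stage.front[1].copy()),
                )
                for stage in self.stages
            ],
            "readout": (self.readout.psc.copy(), self.readout.s.copy()),
        }

    def restore(self, snap: dict, rows: Optional[np.ndarray] = None) -> None:
        """Restore a snapshot, optionally keeping only the given batch rows."""

        def take(arr: np.ndarray) -> np.ndarray:
            return arr.copy() if rows is None else arr[rows].copy()

        def take_state(st: ASNState) -> ASNState:
            return ASNState(
                psc=take(st.psc),
                s=take(st.s),
                s_hat=take(st.s_hat),
                theta_trace=take(st.theta_trace),
                t=st.t,
                dt=st.dt,
            )

        self.input_state = take_state(snap["input"])
        for stage, (state, front) in zip(self.stages, snap["stages"]):
            stage.state = take_state(state)
            stage.front = None if front is None else (take(front[0]), take(front[1]))
        self.readout.psc = take(snap["readout"][0])
        self.readout.s = take(snap["readout"][1])
        if rows is not None:
            self.batch = len(self.input_state.psc)

    def set_precision(self, theta0: float) -> None:
        """Switch every neuron's resting threshold in place (state kept).

        m_f and h follow theta0: m_f defaults to theta0/2 and h is
        re-normalized so the transfer function still maps 1 to 1.
        """
        params = transfer.normalized_params(self.params.with_theta0(theta0))
        self.params = params
        if self.input_state is not None:
            self.input_state.dt = params.dt
        for stage in self.stages:
            stage.set_params(params)
        self.readout.set_params(params)


def convert(spec: NetworkSpec, params: Optional[ASNParams] = None) -> SpikingNetwork:
    """Convert an analog AAN network into a spiking network.

    Batch norm is folded, pooling merged into the following layer, analog
    units become ASNs with the given parameters (default: the parameters the
    network was trained with), and h is normalized so f(1) = 1.
    """
    params = params if params is not None else spec.params
    return SpikingNetwork(spec, params)
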