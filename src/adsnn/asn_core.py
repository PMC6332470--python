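"""Discrete-time simulation of Adaptive Spiking Neurons (ASNs).

An ASN is a spike-response-model (SRM) neuron that performs an online
analog-to-digital conversion of its activation: the membrane potential is the
difference between the filtered input activation ``S(t)`` and a refractory
trace ``S_hat(t)`` built from threshold-scaled spike kernels, and a spike is
emitted whenever that difference exceeds (a fraction of) a dynamic threshold.
The threshold itself is multiplicatively incremented at every spike and decays
back to its resting value ``theta0``, implementing fast spike-frequency
adaptation: the neuron spends spikes at a rate that adapts to the dynamic
range of its input.

All kernels are exponentials, so the neuron is simulated exactly as a small
linear dynamical system with one nonlinearity (the spike trigger).  Updates
use exact decay factors ``exp(-dt/tau)`` per step, not Euler approximations.
State arrays may have any shape, so a whole population (or a batch of inputs
times a layer of neurons) is stepped with one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple, Union

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "ASNParams",
    "ASNState",
    "SpikeTrain",
    "step_neuron",
    "encode_signal",
    "decode_spikes",
    "firing_rate",
    "coding_precision",
    "steady_state_response",
    "psp_kernel",
    "psp_scale",
]

# Readings of the multiplicative adaptation coefficient that scales the
# per-spike threshold increment (and enters the analytic transfer constants).
# "mf_theta0" together with the half-threshold comparator and the "transfer"
# PSP normalization reproduces the closed-form transfer function in simulation
# to < 4% (see docs/methods.md); the other readings are kept for inspection.
_ADAPT_SCALES = ("mf_theta0", "mf", "mf_over_theta0")
_COMPARATORS = ("half", "full")
_PSP_NORMS = ("transfer", "psc", "peak")


@dataclass(frozen=True)
class ASNParams:
    """Constants of a single adaptive spiking neuron.

    Parameters
    ----------
    theta0:
        Resting threshold (dimensionless potential). Lower values give more
        spikes and higher coding precision.
    m_f:
        Adaptation speed multiplier. ``None`` resolves to ``theta0 / 2``.
    tau_gamma, tau_phi, tau_eta, tau_beta:
        Decay time constants (ms) of the adaptation kernel, the membrane
        filter, the refractory kernel and the postsynaptic current.
    h:
        Effective spike height: the postsynaptic scale of one spike. ``None``
        means "not yet normalized"; use :func:`adsnn.transfer.normalized_params`
        to set it so the transfer function maps an activation of 1 to 1.
    dt:
        Simulation step (ms).
    comparator:
        Spike trigger: ``"half"`` fires on ``V > theta/2`` (mid-tread
        quantizer, the shipped default), ``"full"`` on ``V > theta``.
    adaptation_scale:
        Rendering of the multiplicative adaptation coefficient:
        ``"mf_theta0"`` (default, per-spike threshold increment
        ``m_f*theta0*theta``), ``"mf"`` (``m_f*theta``) or
        ``"mf_over_theta0"`` (``(m_f/theta0)*theta``).
    psp_norm:
        Normalization of the PSP kernel kappa = PSC * membrane filter.
        ``"transfer"`` (default): one spike kicks the postsynaptic current by
        ``h/2``, the scale at which the decoded steady-state mean equals the
        analytic transfer function f(S).  ``"psc"``: PSC kick of ``h``.
        ``"peak"``: the convolved kernel is peak-normalized so one PSP peaks
        at exactly ``h``.
    """

    theta0: float = 0.05
    m_f: Optional[float] = None
    tau_gamma: float = 15.0
    tau_phi: float = 5.0
    tau_eta: float = 50.0
    tau_beta: float = 50.0
    h: Optional[float] = None
    dt: float = 1.0
    comparator: str = "half"
    adaptation_scale: str = "mf_theta0"
    psp_norm: str = "transfer"

    def __post_init__(self) -> None:
        for name in ("tau_gamma", "tau_phi", "tau_eta", "tau_beta", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.theta0 > 0:
            raise ValueError("theta0 must be > 0")
        if self.h is not None and not self.h > 0:
            raise ValueError("h must be > 0")
        if self.m_f is not None and self.m_f < 0:
            raise ValueError("m_f must be >= 0")
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"comparator must be one of {_COMPARATORS}")
        if self.adaptation_scale not in _ADAPT_SCALES:
            raise ValueError(f"adaptation_scale must be one of {_ADAPT_SCALES}")
        if self.psp_norm not in _PSP_NORMS:
            raise ValueError(f"psp_norm must be one of {_PSP_NORMS}")

    @property
    def mf(self) -> float:
        """Resolved adaptation speed (defaults to ``theta0 / 2``)."""
        return self.theta0 / 2.0 if self.m_f is None else self.m_f

    @property
    def adapt_coeff(self) -> float:
        """Coefficient multiplying the threshold in the per-spike increment."""
        if self.adaptation_scale == "mf_theta0":
            return self.mf * self.theta0
        if self.adaptation_scale == "mf_over_theta0":
            return self.mf / self.theta0
        return self.mf

    @property
    def spike_height(self) -> float:
        if self.h is None:
            raise ValueError(
                "spike height h is unset; normalize it first "
                "(adsnn.transfer.normalized_params)"
            )
        return self.h

    def decay(self, tau: float) -> float:
        return float(np.exp(-self.dt / tau))

    def with_theta0(self, theta0: float) -> "ASNParams":
        """Same neuron at a different resting threshold (m_f and h unset,
        to be re-resolved for the new precision level)."""
        return replace(self, theta0=theta0, m_f=None, h=None)


@dataclass
class ASNState:
    """Dynamical state of one or many ASNs (arrays broadcast elementwise).

    ``psc`` is the postsynaptic-current trace (decays with ``tau_beta``),
    ``s`` the filtered activation S(t) (membrane filter ``tau_phi``),
    ``s_hat`` the refractory sum and ``theta_trace`` the adaptive part of the
    threshold, so the instantaneous threshold is ``theta0 + theta_trace``.
    A fresh state is all-zero with threshold ``theta0``.
    """

    psc: np.ndarray
    s: np.ndarray
    s_hat: np.ndarray
    theta_trace: np.ndarray
    t: float = 0.0
    dt: float = 1.0

    @classmethod
    def fresh(cls, params: ASNParams, shape: Tuple[int, ...] = ()) -> "ASNState":
        z = lambda: np.zeros(shape, dtype=float)
        return cls(psc=z(), s=z(), s_hat=z(), theta_trace=z(), t=0.0, dt=params.dt)

    def copy(self) -> "ASNState":
        return ASNState(
            psc=self.psc.copy(),
            s=self.s.copy(),
            s_hat=self.s_hat.copy(),
            theta_trace=self.theta_trace.copy(),
            t=self.t,
            dt=self.dt,
        )


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (ms) of a single neuron within a window ``[0, duration)``."""

    spike_times: np.ndarray
    duration: float
    neuron_id: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


def _check_state(state: ASNState, params: ASNParams) -> None:
    if abs(state.dt - params.dt) > 1e-12:
        raise ValueError(f"state dt {state.dt} does not match params dt {params.dt}")


def step_neuron(
    state: ASNState,
    input_current: Union[float, np.ndarray],
    params: ASNParams,
    bias: Union[float, np.ndarray] = 0.0,
    activation: Optional[np.ndarray] = None,
) -> Tuple[ASNState, np.ndarray]:
    """Advance the neuron(s) by one time step; returns the state and a binary spike.

    Within-step ordering: decay all traces, integrate the input through the
    PSC and membrane filters, evaluate the spike condition, then apply spike
    effects (refractory increment by the current threshold, multiplicative
    threshold increment).  At most one spike per step.  The state is updated
    in place and also returned.

    ``bias`` is added to the filtered activation S (it does not pass through
    the synaptic filters).  If ``activation`` is given, it is taken as an
    externally filtered S(t) and the internal input filters are bypassed —
    used for merged-pooling layers whose activation is pooled upstream.
    """
    _check_state(state, params)
    state.s_hat = state.s_hat * params.decay(params.tau_eta)
    state.theta_trace = state.theta_trace * params.decay(params.tau_gamma)

    if activation is None:
        current = np.asarray(input_current, dtype=float)
        if not np.all(np.isfinite(current)):
            raise ValueError("input current must be finite")
        a_beta = params.decay(params.tau_beta)
        a_phi = params.decay(params.tau_phi)
        state.psc = a_beta * state.psc + (1.0 - a_beta) * current
        state.s = a_phi * state.s + (1.0 - a_phi) * state.psc
    else:
        if not np.all(np.isfinite(activation)):
            raise ValueError("activation must be finite")
        state.s = np.broadcast_to(np.asarray(activation, dtype=float), state.s.shape).copy()

    theta = params.theta0 + state.theta_trace
    v = (state.s + bias) - state.s_hat
    boundary = 0.5 * theta if params.comparator == "half" else theta
    spike = v > boundary

    state.s_hat = state.s_hat + np.where(spike, theta, 0.0)
    state.theta_trace = state.theta_trace + np.where(
        spike, params.adapt_coeff * theta, 0.0
    )
    state.t += params.dt
    return state, spike.astype(np.int8)


def psp_kernel(params: ASNParams, n_steps: Optional[int] = None) -> np.ndarray:
    """Discrete unit-impulse response of the PSC -> membrane-filter cascade.

    Both single-pole filters are DC-gain normalized, so the kernel sums to 1;
    scaling of actual PSPs is applied on top via :func:`psp_scale`.
    """
    if n_steps is None:
        n_steps = int(np.ceil(12.0 * max(params.tau_beta, params.tau_phi) / params.dt))
    impulse = np.zeros(n_steps)
    impulse[0] = 1.0
    return _cascade_filter(impulse, params)


def _cascade_filter(
    x: np.ndarray, params: ASNParams, tau_phi: Optional[float] = None
) -> np.ndarray:
    """Apply the DC-normalized PSC (tau_beta) then membrane (tau_phi) filter
    along axis 0."""
    a_beta = params.decay(params.tau_beta)
    a_phi = float(np.exp(-params.dt / (tau_phi if tau_phi is not None else params.tau_phi)))
    y = lfilter([1.0 - a_beta], [1.0, -a_beta], x, axis=0)
    return lfilter([1.0 - a_phi], [1.0, -a_phi], y, axis=0)


def psp_scale(params: ASNParams) -> float:
    """Impulse magnitude injected into the DC-normalized cascade per spike.

    With the shipped ``psp_norm="transfer"`` one spike kicks the postsynaptic
    current by ``h/2``; this is the (empirically calibrated) scale at which
    the steady-state mean of the decoded output equals the analytic transfer
    function f(S).  ``"psc"`` kicks the PSC by ``h``; ``"peak"`` normalizes
    the convolved PSP kernel so one PSP peaks at exactly ``h``.
    """
    h = params.spike_height
    if params.psp_norm == "transfer":
        return 0.5 * h / (1.0 - params.decay(params.tau_beta))
    if params.psp_norm == "psc":
        return h / (1.0 - params.decay(params.tau_beta))
    return h / float(psp_kernel(params).max())


def decode_spikes(
    train: SpikeTrain, params: ASNParams, n_steps: Optional[int] = None
) -> np.ndarray:
    """Reconstruct the normalized postsynaptic contribution y(t) of a train.

    y(t) is the sum of PSP kernels (height scale ``h``) placed at the spike
    times; it is linear in the spike set, so decoding the union of disjoint
    trains equals the sum of their decodings.
    """
    if n_steps is None:
        n_steps = int(round(train.duration / params.dt))
    impulses = np.zeros(n_steps)
    idx = np.round(train.spike_times / params.dt).astype(int)
    if np.any(idx >= n_steps):
        raise ValueError("spike times exceed the decoding window")
    np.add.at(impulses, idx, psp_scale(params))
    return _cascade_filter(impulses, params)


def encode_signal(
    signal: np.ndarray, params: ASNParams
) -> Tuple[SpikeTrain, np.ndarray]:
    """Encode an analog activation time series into spikes and decode it back.

    The signal (sampled at ``params.dt``) is injected as a current; because
    both input filters are DC-gain normalized, a constant signal value equals
    the steady-state activation S seen by the spike trigger.  Returns the
    spike train and the reconstruction y(t) from :func:`decode_spikes`.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    params.spike_height  # fail early if h is unset

    state = ASNState.fresh(params)
    spikes = np.empty(signal.size, dtype=np.int8)
    for i, value in enumerate(signal):
        _, spikes[i] = step_neuron(state, value, params)
    times = np.nonzero(spikes)[0] * params.dt
    train = SpikeTrain(spike_times=times, duration=signal.size * params.dt)
    return train, decode_spikes(train, params, n_steps=signal.size)


def firing_rate(train: SpikeTrain) -> float:
    """Average firing rate of the train in Hz (duration is in ms)."""
    return train.n_spikes / train.duration * 1000.0


def coding_precision(
    reconstruction: np.ndarray,
    window: Tuple[float, float],
    dt: float = 1.0,
) -> float:
    """Deviation of y(t) from its mean over a steady-state window.

    ``window`` is ``(t_start, t_stop)`` in ms; choose ``t_start`` after the
    encoding transient (10 * tau_eta is a safe default).  Returns the standard
    deviation of the samples in the window; smaller means higher precision.
    """
    i0, i1 = (int(round(t / dt)) for t in window)
    if not 0 <= i0 < i1 <= len(reconstruction):
        raise ValueError("window must lie within the series")
    if i1 - i0 < 2:
        raise ValueError("window must contain at least 2 samples")
    return float(np.std(reconstruction[i0:i1]))


def steady_state_response(
    S_values: Union[float, np.ndarray],
    params: ASNParams,
    T: float = 2000.0,
    transient: float = 500.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Batched constant-input simulation of a single ASN.

    For each activation value, the neuron is driven for ``T`` ms and the mean
    decoded output y and the firing rate (Hz) are measured after discarding
    the first ``transient`` ms.  This is the empirical counterpart of the
    analytic transfer function.
    """
    S = np.atleast_1d(np.asarray(S_values, dtype=float))
    n_steps = int(round(T / params.dt))
    if not n_steps * params.dt > transient:
        raise ValueError("T must exceed the transient")
    state = ASNState.fresh(params, shape=S.shape)
    spikes = np.empty((n_steps,) + S.shape, dtype=np.int8)
    for i in range(n_steps):
        _, spikes[i] = step_neuron(state, S, params)
    y = _cascade_filter(spikes * psp_scale(params), params)
    keep = (np.arange(n_steps) + 1) * params.dt > transient
    window_s = keep.sum() * params.dt / 1000.0
    y_mean = y[keep].mean(axis=0)
    rate = spikes[keep].sum(axis=0) / window_s
    if np.isscalar(S_values):
        return y_mean[0], rate[0]
    return y_mean, rate
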