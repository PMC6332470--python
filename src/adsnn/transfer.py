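"""Closed-form transfer function of the adaptive spiking neuron.

For a constant activation S, the adaptive spike-based code settles into
periodic firing, and the average postsynaptic contribution y of the emitted
spikes is a deterministic, saturating ("half-sigmoid") function of S:

    f(S) = max(0, h / (exp((c1*S + c2) / (c3*S + c4)) - 1) - c0 + h/2)

with constants computed from the neuron parameters,

    c1 = 2 * a * tau_gamma**2
    c2 = 2 * theta0 * tau_eta * tau_gamma
    c3 = tau_gamma * (a * tau_gamma + (2*a + 1) * tau_eta)
    c4 = theta0 * tau_eta * (tau_gamma + tau_eta)
    c0 = h / (exp((c1*theta0 + c2) / (c3*theta0 + c4)) - 1)

where ``a`` is the multiplicative adaptation coefficient (``params.adapt_coeff``)
and ``h`` the effective spike height.  By construction f(theta0) = h/2.

Normalizing f(1) = 1 turns ``h`` into a global scaling factor for a trained
network's weights: analog units trained with f as their activation
(adaptive artificial neurons, AANs) can then be swapped for spiking neurons
that communicate binary spikes.  Because c0 is linear in h, the
normalization has a closed form.

f (and its analytic derivative, zero on the clipped branch) is also the
activation used for gradient training of the analog networks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np

from .asn_core import ASNParams

__all__ = [
    "TransferConstants",
    "compute_constants",
    "f_S",
    "normalize_h",
    "normalized_params",
    "aan_activation",
    "aan_derivative",
]

#: Validity range of activations checked at construction time.
S_MAX = 10.0


@dataclass(frozen=True)
class TransferConstants:
    c0: float
    c1: float
    c2: float
    c3: float
    c4: float
    h: float

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ValueError("h must be > 0")
        if self.c4 <= 0 or self.c3 * S_MAX + self.c4 <= 0:
            raise ValueError(f"denominator c3*S + c4 must stay positive on [0, {S_MAX}]")


def _raw_constants(params: ASNParams) -> tuple[float, float, float, float]:
    """c1..c4 (independent of the spike height h)."""
    a = params.adapt_coeff
    tg, te, th0 = params.tau_gamma, params.tau_eta, params.theta0
    c1 = 2.0 * a * tg**2
    c2 = 2.0 * th0 * te * tg
    c3 = tg * (a * tg + (2.0 * a + 1.0) * te)
    c4 = th0 * te * (tg + te)
    return c1, c2, c3, c4


def _inv_expm1(x: float, c1: float, c2: float, c3: float, c4: float) -> float:
    return 1.0 / np.expm1((c1 * x + c2) / (c3 * x + c4))


def compute_constants(params: ASNParams, h: float | None = None) -> TransferConstants:
    """Transfer constants for a parameter set; ``h`` defaults to ``params.h``."""
    h = params.spike_height if h is None else h
    c1, c2, c3, c4 = _raw_constants(params)
    c0 = h * _inv_expm1(params.theta0, c1, c2, c3, c4)
    return TransferConstants(c0=c0, c1=c1, c2=c2, c3=c3, c4=c4, h=h)


def f_S(
    S: Union[float, np.ndarray], constants: TransferConstants
) -> Union[float, np.ndarray]:
    """Mean postsynaptic contribution of an ASN driven at constant activation S."""
    S_arr = np.asarray(S, dtype=float)
    if not np.all(np.isfinite(S_arr)):
        raise ValueError("S must be finite")
    denom = constants.c3 * S_arr + constants.c4
    # Left of the pole of the exponent the rectifier is identically zero
    # (c0 >= h/2 in any valid regime), so only evaluate where denom > 0.
    safe = denom > 0
    g = (constants.c1 * S_arr + constants.c2) / np.where(safe, denom, 1.0)
    with np.errstate(over="ignore"):
        inner = constants.h / np.expm1(g) - constants.c0 + constants.h / 2.0
    out = np.where(safe, np.maximum(0.0, inner), 0.0)
    return float(out) if np.isscalar(S) else out


def normalize_h(params: ASNParams) -> float:
    """Spike height for which f(1) = 1.

    c0 is linear in h, so the condition is closed form:
    ``h = 1 / (inv(1) - inv(theta0) + 1/2)`` with
    ``inv(x) = 1/(exp((c1*x + c2)/(c3*x + c4)) - 1)``.
    """
    c1, c2, c3, c4 = _raw_constants(params)
    denom = (
        _inv_expm1(1.0, c1, c2, c3, c4)
        - _inv_expm1(params.theta0, c1, c2, c3, c4)
        + 0.5
    )
    if denom <= 0:
        raise ValueError("invalid parameter regime: normalization denominator <= 0")
    return 1.0 / denom


def normalized_params(params: ASNParams) -> ASNParams:
    """Copy of ``params`` with the spike height set so that f(1) = 1."""
    return replace(params, h=normalize_h(params))


def aan_activation(
    S: Union[float, np.ndarray], constants: TransferConstants
) -> Union[float, np.ndarray]:
    """Activation of the adaptive artificial neuron (identical to f_S)."""
    return f_S(S, constants)


def aan_derivative(
    S: Union[float, np.ndarray], constants: TransferConstants
) -> Union[float, np.ndarray]:
    """Analytic derivative df/dS, defined as 0 on the clipped branch."""
    S_arr = np.asarray(S, dtype=float)
    denom = constants.c3 * S_arr + constants.c4
    safe = denom > 0
    denom = np.where(safe, denom, 1.0)
    g = (constants.c1 * S_arr + constants.c2) / denom
    dg = (constants.c1 * constants.c4 - constants.c2 * constants.c3) / denom**2
    with np.errstate(over="ignore", invalid="ignore"):
        slope = -constants.h * np.exp(g) * dg / np.expm1(g) ** 2
        inner = constants.h / np.expm1(g) - constants.c0 + constants.h / 2.0
    out = np.where(safe & (inner > 0), slope, 0.0)
    return float(out) if np.isscalar(S) else out
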