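"""Time-stepped execution of spiking networks and the evaluation metrics.

Inputs are presented persistently for a window ``T`` (1 ms steps by
default) and the smoothed readout is classified by argmax at every step.
The metrics mirror how spiking classifiers are benchmarked:

Matching Time (MT)
    the earliest time at which the classification error over the evaluation
    set reaches 101% of its minimum over the window — the latency until the
    spiking network performs at (practically) its best level.
Firing Rate (FR)
    average spikes per spiking neuron per input per second over the full
    presentation window.
NoS / SOPs
    total number of spikes and synaptic operations (each spike counted once
    per outgoing synapse of the emitting neuron), accumulated up to MT and
    averaged per input — the work actually needed to classify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import transfer
from .network import NetworkSpec, SpikingNetwork, convert, forward_ann
from .asn_core import ASNParams

__all__ = [
    "SimConfig",
    "SimResult",
    "EvalMetrics",
    "run",
    "matching_time",
    "evaluate",
    "precision_sweep",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation window: ``T`` ms of persistent input at step ``dt``."""

    dt: float = 1.0
    T: float = 500.0

    def __post_init__(self) -> None:
        if self.T <= 0 or self.dt <= 0:
            raise ValueError("T and dt must be > 0")
        steps = self.T / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("T must be a multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))


@dataclass
class SimResult:
    """Per-timestep traces of one simulation.

    ``outputs``: readout activations (n_steps, n_inputs, K);
    ``decisions``: argmax class per step (n_steps, n_inputs);
    ``spikes_t`` / ``sops_t``: spikes and synaptic operations emitted in each
    step, summed over neurons, per input.
    """

    outputs: np.ndarray
    decisions: np.ndarray
    spikes_t: np.ndarray
    sops_t: np.ndarray
    n_neurons: int
    config: SimConfig

    @property
    def total_spikes(self) -> float:
        return float(self.spikes_t.sum())


@dataclass(frozen=True)
class EvalMetrics:
    """Dataset-level metrics of a spiking classifier."""

    accuracy_pct: float
    firing_rate_hz: float
    matching_time_ms: float
    accuracy_std_after_mt: float
    nos: float
    sops: float
    n_neurons: int
    fr_window_ms: Tuple[float, float]
    count_window_ms: Tuple[float, float]


def run(net: SpikingNetwork, inputs: np.ndarray, config: SimConfig) -> SimResult:
    """Present ``inputs`` (n, features) persistently for T ms.

    Deterministic: the same network, inputs and config give identical
    results.  All neuron updates go through the single-step ASN update."""
    X = np.asarray(inputs, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs must be finite")
    net.reset(X.shape[1:], batch=len(X))

    steps = config.n_steps
    outputs = None
    decisions = np.empty((steps, len(X)), dtype=int)
    spikes_t = np.empty((steps, len(X)))
    sops_t = np.empty((steps, len(X)))
    for i in range(steps):
        out, n_spikes, sops = net.step(X)
        if outputs is None:
            outputs = np.empty((steps,) + out.shape)
        outputs[i] = out
        decisions[i] = out.argmax(axis=1)
        spikes_t[i] = n_spikes
        sops_t[i] = sops
    return SimResult(
        outputs=outputs,
        decisions=decisions,
        spikes_t=spikes_t,
        sops_t=sops_t,
        n_neurons=net.n_spiking_neurons,
        config=config,
    )


def matching_time(error_trace: np.ndarray, dt: float = 1.0) -> float:
    """First time (ms) at which the error reaches 101% of its window minimum.

    The trace's i-th sample is taken at time (i+1)*dt.  The first crossing
    counts even if the error rises again later; ties resolve to the earliest
    step."""
    err = np.asarray(error_trace, dtype=float)
    if err.size == 0:
        raise ValueError("error trace must be non-empty")
    idx = int(np.argmax(err <= 1.01 * err.min()))
    return (idx + 1) * dt


def evaluate(
    net: SpikingNetwork,
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[SimConfig] = None,
) -> EvalMetrics:
    """Run the labeled set through the network and compute all metrics.

    MT is defined on the aggregate error trace of the whole set; NoS/SOPs are
    counted up to MT and averaged per input; FR uses the full window."""
    config = config if config is not None else SimConfig()
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("dataset must be non-empty")
    result = run(net, X, config)
    acc_t = (result.decisions == y[None, :]).mean(axis=1)
    mt = matching_time(1.0 - acc_t, config.dt)
    mt_steps = int(round(mt / config.dt))

    n_inputs = len(y)
    window_s = config.T / 1000.0
    fr = result.total_spikes / (result.n_neurons * n_inputs * window_s)
    return EvalMetrics(
        accuracy_pct=float(acc_t[mt_steps - 1 :].mean() * 100.0),
        firing_rate_hz=float(fr),
        matching_time_ms=float(mt),
        accuracy_std_after_mt=float(acc_t[mt_steps - 1 :].std()),
        nos=float(result.spikes_t[:mt_steps].sum(axis=0).mean()),
        sops=float(result.sops_t[:mt_steps].sum(axis=0).mean()),
        n_neurons=result.n_neurons,
        fr_window_ms=(0.0, config.T),
        count_window_ms=(0.0, mt),
    )


def precision_sweep(
    spec: NetworkSpec,
    X: np.ndarray,
    y: np.ndarray,
    theta0_list: Sequence[float],
    config: Optional[SimConfig] = None,
    base_params: Optional[ASNParams] = None,
    match_tol_pct: float = 1.0,
) -> Tuple[pd.DataFrame, Optional[float]]:
    """Evaluate the converted network across resting thresholds.

    For each theta0 the spike height is re-normalized and the network
    re-converted (weights untouched).  Returns the metric table and the
    theta0 with the lowest firing rate among those matching the analog test
    accuracy within ``match_tol_pct`` percentage points (None if no match).
    """
    if len(theta0_list) == 0:
        raise ValueError("theta0 list must be non-empty")
    base = base_params if base_params is not None else spec.params
    analog_acc = float(np.mean(forward_ann(spec, X).argmax(axis=1) == y) * 100.0)

    rows = []
    for theta0 in theta0_list:
        params = transfer.normalized_params(base.with_theta0(theta0))
        metrics = evaluate(convert(spec, params), X, y, config)
        rows.append(
            {
                "theta0": theta0,
                "fr_hz": metrics.firing_rate_hz,
                "accuracy": metrics.accuracy_pct,
                "mt_ms": metrics.matching_time_ms,
                "acc_std": metrics.accuracy_std_after_mt,
                "nos": metrics.nos,
                "sops": metrics.sops,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["analog_accuracy"] = analog_acc
    matching = table[np.abs(table["accuracy"] - analog_acc) <= match_tol_pct]
    matched_theta0 = (
        None if matching.empty else float(matching.loc[matching["fr_hz"].idxmin(), "theta0"])
    )
    return table, matched_theta0
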