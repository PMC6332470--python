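"""Uncertainty-gated arousal: per-input switching of neural coding precision.

The network runs at a low default precision (high resting threshold, few
spikes).  For each input, the separation between the winning and the
runner-up readout is accumulated over a short window starting at ``t_sa``;
inputs whose accumulated margin fails to exceed a threshold theta_A are
"highlighted" and the whole network is switched in place to a high-precision
setting (lower theta0; m_f and the spike height h follow), then simulated
for an extended window.  Easy inputs are thus classified cheaply, and spikes
are spent only on ambiguous ones.

theta_A grows linearly with the accumulation interval,
``theta_A = p1 * (t - t_sa) + p2``; the coefficients are calibrated on the
training set from the margins of inputs misclassified at low precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from . import transfer
from .asn_core import ASNParams
from .network import NetworkSpec, SpikingNetwork, convert

__all__ = [
    "ArousalConfig",
    "ArousalOutcome",
    "CalibrationResult",
    "accumulate_margin",
    "theta_A_at",
    "select",
    "selectivity",
    "calibrate_theta_A",
    "run_with_arousal",
    "evaluate_with_arousal",
    "low_precision_margins",
]


@dataclass(frozen=True)
class ArousalConfig:
    """Precision levels and selection schedule.

    ``theta0_lp``/``theta0_hp``: resting thresholds of the low/high precision
    regimes; ``t_sa``: accumulation start (ms); ``window``: accumulation
    length (ms); ``p1``, ``p2``: linear theta_A schedule; ``T``: standard
    presentation window (ms); ``T_ext``: extended window for selected inputs.
    """

    theta0_lp: float = 0.3
    theta0_hp: float = 0.06
    t_sa: float = 150.0
    window: float = 50.0
    p1: float = 0.0
    p2: float = 0.0
    T: float = 500.0
    T_ext: float = 1000.0
    rerank_each_step: bool = True

    def __post_init__(self) -> None:
        if not self.theta0_hp < self.theta0_lp:
            raise ValueError("theta0_hp must be below theta0_lp")
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.t_sa + self.window > self.T or self.T > self.T_ext:
            raise ValueError("need t_sa + window <= T <= T_ext")


@dataclass(frozen=True)
class ArousalOutcome:
    """Result of one input under the arousal policy."""

    selected: bool
    decision: int
    spikes_used: float
    decision_time: float
    margin: float


@dataclass(frozen=True)
class CalibrationResult:
    """theta_A schedule fitted on low-precision training margins."""

    p1: float
    p2: float
    theta_A: float
    selectivity_pct: float
    disabled: bool = False


def accumulate_margin(
    output_trace: np.ndarray,
    t_sa: float,
    window: float,
    dt: float = 1.0,
    rerank_each_step: bool = True,
) -> Union[float, np.ndarray]:
    """Accumulated winner-minus-runner-up margin over the selection window.

    ``output_trace`` has shape (n_steps, K) or (n_steps, n_inputs, K), with
    sample i taken at time (i+1)*dt.  The margin sums, over the window
    ``(t_sa, t_sa + window]``, the difference between the highest and the
    second-highest output; with ``rerank_each_step`` the winner is
    re-determined at every step, otherwise it is fixed at the window start.
    """
    trace = np.asarray(output_trace, dtype=float)
    squeeze = trace.ndim == 2
    if squeeze:
        trace = trace[:, None, :]
    i0 = int(round(t_sa / dt))
    i1 = int(round((t_sa + window) / dt))
    if i1 > trace.shape[0] or i0 < 0:
        raise ValueError("output trace does not cover the accumulation window")
    win = trace[i0:i1]
    if rerank_each_step:
        top2 = np.sort(win, axis=-1)[..., -2:]
        margins = (top2[..., 1] - top2[..., 0]).sum(axis=0)
    else:
        ranking = win[0].argsort(axis=-1)
        first, second = ranking[..., -1], ranking[..., -2]
        cols = np.arange(win.shape[1])
        margins = (win[:, cols, first] - win[:, cols, second]).sum(axis=0)
    return float(margins[0]) if squeeze else margins


def theta_A_at(t: float, config: ArousalConfig) -> float:
    """Selection threshold at time t (ms): ``p1 * (t - t_sa) + p2``."""
    if t < config.t_sa:
        raise ValueError("theta_A is defined from t_sa onward")
    return config.p1 * (t - config.t_sa) + config.p2


def select(margin: Union[float, np.ndarray], theta_A: float) -> Union[bool, np.ndarray]:
    """An input is highlighted unless its margin strictly exceeds theta_A."""
    out = np.asarray(margin) <= theta_A
    return bool(out) if np.isscalar(margin) else out


def selectivity(outcomes: Union[Sequence[ArousalOutcome], np.ndarray]) -> float:
    """Percentage of inputs highlighted by the arousal criterion."""
    flags = np.asarray(
        [o.selected for o in outcomes]
        if len(outcomes) and isinstance(outcomes[0], ArousalOutcome)
        else outcomes,
        dtype=bool,
    )
    if flags.size == 0:
        raise ValueError("no outcomes")
    return float(flags.mean() * 100.0)


def calibrate_theta_A(
    margins: np.ndarray,
    correct: np.ndarray,
    target_fraction: float = 0.95,
    p1: float = 0.0,
) -> CalibrationResult:
    """Choose the selection threshold from low-precision training margins.

    theta_A is set to the smallest value selecting at least
    ``target_fraction`` of the inputs that were misclassified at low
    precision.  With a constant-threshold schedule (``p1 = 0``), ``p2`` is
    theta_A itself.  If every training input was correct at low precision,
    arousal is disabled (no input is ever selected).
    """
    margins = np.asarray(margins, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if margins.shape != correct.shape:
        raise ValueError("margins and correctness must align")
    wrong = margins[~correct]
    if wrong.size == 0:
        return CalibrationResult(
            p1=0.0, p2=-np.inf, theta_A=-np.inf, selectivity_pct=0.0, disabled=True
        )
    k = int(np.ceil(target_fraction * wrong.size))
    theta_A = float(np.sort(wrong)[max(k - 1, 0)])
    sel = float(np.mean(margins <= theta_A) * 100.0)
    return CalibrationResult(p1=p1, p2=theta_A, theta_A=theta_A, selectivity_pct=sel)


def _lp_params(config: ArousalConfig, base: Optional[ASNParams]) -> ASNParams:
    base = base if base is not None else ASNParams()
    return transfer.normalized_params(base.with_theta0(config.theta0_lp))


def _simulate_arousal(
    spec: NetworkSpec,
    X: np.ndarray,
    config: ArousalConfig,
    base_params: Optional[ASNParams],
):
    """Batched arousal policy; returns (outcomes, outputs at decision trace)."""
    dt = (base_params or spec.params).dt
    net = convert(spec, _lp_params(config, base_params))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n = len(X)
    net.reset(X.shape[1:], batch=n)

    steps_T = int(round(config.T / dt))
    decide_step = int(round((config.t_sa + config.window) / dt))
    outputs = np.empty((steps_T, n, spec.layers[-1].weights.shape[0]))
    spikes = np.zeros(n)
    snap = None
    spikes_at_decision = None
    for i in range(steps_T):
        out, n_spikes, _ = net.step(X)
        outputs[i] = out
        spikes += n_spikes
        if i + 1 == decide_step:
            snap = net.snapshot()
            spikes_at_decision = spikes.copy()

    margins = accumulate_margin(
        outputs, config.t_sa, config.window, dt, config.rerank_each_step
    )
    thr = theta_A_at(config.t_sa + config.window, config)
    selected = np.asarray(select(margins, thr), dtype=bool)
    decisions = outputs[-1].argmax(axis=1)
    decision_time = np.full(n, config.T)
    final_spikes = spikes.copy()

    if selected.any():
        rows = np.nonzero(selected)[0]
        net.restore(snap, rows=rows)
        net.set_precision(config.theta0_hp)
        hp_spikes = spikes_at_decision[rows].copy()
        steps_ext = int(round(config.T_ext / dt)) - decide_step
        x_sel = X[rows]
        out = None
        for _ in range(steps_ext):
            out, n_spikes, _ = net.step(x_sel)
            hp_spikes += n_spikes
        decisions[rows] = out.argmax(axis=1)
        final_spikes[rows] = hp_spikes
        decision_time[rows] = config.T_ext

    outcomes = [
        ArousalOutcome(
            selected=bool(selected[i]),
            decision=int(decisions[i]),
            spikes_used=float(final_spikes[i]),
            decision_time=float(decision_time[i]),
            margin=float(margins[i]),
        )
        for i in range(n)
    ]
    return outcomes


def run_with_arousal(
    spec: NetworkSpec,
    x: np.ndarray,
    config: ArousalConfig,
    base_params: Optional[ASNParams] = None,
) -> ArousalOutcome:
    """Classify one input under the arousal policy.

    The input runs at low precision; if selected at ``t_sa + window``, every
    neuron switches to the high-precision parameters in place (state
    preserved) and the simulation continues to ``T_ext``.
    """
    return _simulate_arousal(spec, np.atleast_2d(x), config, base_params)[0]


def evaluate_with_arousal(
    spec: NetworkSpec,
    X: np.ndarray,
    y: np.ndarray,
    config: ArousalConfig,
    base_params: Optional[ASNParams] = None,
) -> Tuple[List[ArousalOutcome], dict]:
    """Arousal policy over a labeled set, with summary statistics."""
    outcomes = _simulate_arousal(spec, X, config, base_params)
    decisions = np.array([o.decision for o in outcomes])
    spikes = np.array([o.spikes_used for o in outcomes])
    summary = {
        "accuracy_pct": float(np.mean(decisions == np.asarray(y)) * 100.0),
        "mean_spikes_per_input": float(spikes.mean()),
        "selectivity_pct": selectivity(outcomes),
    }
    return outcomes, summary


def low_precision_margins(
    spec: NetworkSpec,
    X: np.ndarray,
    y: np.ndarray,
    config: ArousalConfig,
    base_params: Optional[ASNParams] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Margins and correctness of a plain low-precision run (for calibration)."""
    from .sim_engine import SimConfig, run as sim_run

    dt = (base_params or spec.params).dt
    net = convert(spec, _lp_params(config, base_params))
    result = sim_run(net, X, SimConfig(dt=dt, T=config.T))
    margins = accumulate_margin(
        result.outputs, config.t_sa, config.window, dt, config.rerank_each_step
    )
    correct = result.decisions[-1] == np.asarray(y)
    return np.asarray(margins), correct
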