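"""Single-neuron dynamics: spiking condition, adaptation, encode/decode."""

import numpy as np
import pytest
from dataclasses import replace

from adsnn import (
    ASNParams,
    ASNState,
    SpikeTrain,
    coding_precision,
    decode_spikes,
    encode_signal,
    f_S,
    firing_rate,
    compute_constants,
    normalized_params,
    steady_state_response,
    step_neuron,
)
from adsnn.asn_core import psp_kernel, psp_scale


def simulate_constant(value, params, n_steps):
    state = ASNState.fresh(params)
    spikes = []
    for _ in range(n_steps):
        _, sp = step_neuron(state, value, params)
        spikes.append(int(sp))
    return state, np.array(spikes)


class TestStepNeuron:
    def test_zero_input_is_silent(self, default_params):
        state, spikes = simulate_constant(0.0, default_params, 200)
        assert spikes.sum() == 0
        assert state.s == 0 and state.s_hat == 0 and state.theta_trace == 0

    def test_subthreshold_input_never_spikes(self, default_params):
        # theta0/2 = 0.025 is the firing boundary for constant input
        _, spikes = simulate_constant(0.01, default_params, 2000)
        assert spikes.sum() == 0

    @pytest.mark.parametrize("value", [0.0, -0.5, -2.0])
    def test_rectification_nonpositive_input(self, default_params, value):
        _, spikes = simulate_constant(value, default_params, 1000)
        assert spikes.sum() == 0

    def test_constant_unit_activation_decodes_to_one(self, default_params):
        y_mean, _ = steady_state_response(1.0, default_params)
        assert y_mean == pytest.approx(1.0, rel=0.05)

    def test_without_adaptation_threshold_is_fixed(self):
        # m_f = 0 reduces the model to a fixed-threshold SRM0 neuron
        params = normalized_params(ASNParams(m_f=0.0))
        state, spikes = simulate_constant(1.0, params, 500)
        assert spikes.sum() > 0
        assert state.theta_trace == 0.0

    def test_adaptation_raises_threshold(self, default_params):
        state, spikes = simulate_constant(1.0, default_params, 500)
        assert spikes.sum() > 0
        assert state.theta_trace > 0

    def test_traces_decay_to_zero_after_input_removal(self, default_params):
        state, _ = simulate_constant(1.0, default_params, 500)
        silence = int(10 * max(default_params.tau_eta, default_params.tau_beta))
        for _ in range(silence):
            step_neuron(state, 0.0, default_params)
        for trace in (state.psc, state.s, state.s_hat, state.theta_trace):
            assert abs(trace) < 1e-3

    def test_nonfinite_input_rejected(self, default_params):
        state = ASNState.fresh(default_params)
        with pytest.raises(ValueError):
            step_neuron(state, np.nan, default_params)

    def test_dt_mismatch_rejected(self, default_params):
        state = ASNState.fresh(replace(default_params, dt=0.5))
        with pytest.raises(ValueError):
            step_neuron(state, 0.0, default_params)

    def test_batched_state_matches_scalar(self, default_params):
        values = np.array([0.3, 1.0])
        state = ASNState.fresh(default_params, shape=(2,))
        totals = np.zeros(2)
        for _ in range(300):
            _, sp = step_neuron(state, values, default_params)
            totals += sp
        for i, v in enumerate(values):
            _, spikes = simulate_constant(v, default_params, 300)
            assert totals[i] == spikes.sum()


class TestRateMonotonicity:
    def test_rate_nondecreasing_in_activation(self, default_params):
        grid = np.array([0.1, 0.3, 0.6, 1.0, 1.5, 2.0])
        _, rates = steady_state_response(grid, default_params)
        assert np.all(np.diff(rates) >= 0)

    def test_rate_nonincreasing_in_theta0(self):
        rates = []
        for theta0 in (0.05, 0.1, 0.25):
            params = normalized_params(ASNParams(theta0=theta0))
            _, rate = steady_state_response(1.0, params)
            rates.append(rate)
        assert rates[0] > rates[1] > rates[2]


class TestEncodeDecode:
    def test_all_zero_signal(self, default_params):
        train, y = encode_signal(np.zeros(300), default_params)
        assert train.n_spikes == 0
        assert np.all(y == 0)

    def test_empty_signal_rejected(self, default_params):
        with pytest.raises(ValueError):
            encode_signal(np.array([]), default_params)

    def test_constant_signal_reconstruction_matches_transfer(self, default_params):
        S = 0.8
        _, y = encode_signal(np.full(2000, S), default_params)
        target = f_S(S, compute_constants(default_params))
        assert y[500:].mean() == pytest.approx(target, rel=0.05)

    def test_step_lower_threshold_more_spikes_higher_precision(self):
        signal = np.concatenate([np.zeros(100), np.ones(1900)])
        results = {}
        for theta0 in (0.05, 0.25):
            params = normalized_params(ASNParams(theta0=theta0))
            train, y = encode_signal(signal, params)
            window = (100 + int(10 * params.tau_eta), len(signal))
            results[theta0] = (train.n_spikes, coding_precision(y, window))
        assert results[0.05][0] > results[0.25][0]
        assert results[0.05][1] < results[0.25][1]

    def test_decode_empty_train_is_zero(self, default_params):
        train = SpikeTrain(spike_times=np.array([]), duration=100.0)
        assert np.all(decode_spikes(train, default_params) == 0)

    def test_single_spike_peak_normalized_kernel(self, default_params):
        # under the "peak" convention one PSP literally peaks at h
        params = replace(default_params, psp_norm="peak")
        train = SpikeTrain(spike_times=np.array([0.0]), duration=600.0)
        y = decode_spikes(train, params)
        assert y.max() == pytest.approx(params.h, rel=1e-12)

    def test_default_kernel_is_half_psc_kick(self, default_params):
        # shipped convention: one spike kicks the PSC by h/2, so the decoded
        # kernel sums to (h/2) * tau_beta / dt within truncation error
        train = SpikeTrain(spike_times=np.array([0.0]), duration=600.0)
        y = decode_spikes(train, default_params)
        expected = default_params.h / 2 / (1 - np.exp(-1 / default_params.tau_beta))
        assert y.sum() == pytest.approx(expected, rel=1e-3)

    def test_decode_linearity(self, default_params):
        t1 = SpikeTrain(spike_times=np.array([5.0, 40.0]), duration=200.0)
        t2 = SpikeTrain(spike_times=np.array([10.0, 90.0]), duration=200.0)
        merged = SpikeTrain(
            spike_times=np.array([5.0, 10.0, 40.0, 90.0]), duration=200.0
        )
        np.testing.assert_allclose(
            decode_spikes(t1, default_params) + decode_spikes(t2, default_params),
            decode_spikes(merged, default_params),
            atol=1e-12,
        )


class TestSpikeTrainAndMetrics:
    def test_firing_rate_arithmetic(self):
        train = SpikeTrain(spike_times=np.linspace(0, 499, 10), duration=500.0)
        assert firing_rate(train) == pytest.approx(20.0)

    def test_firing_rate_empty(self):
        train = SpikeTrain(spike_times=np.array([]), duration=1000.0)
        assert firing_rate(train) == 0.0

    def test_invalid_trains_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrain(spike_times=np.array([5.0, 5.0]), duration=100.0)
        with pytest.raises(ValueError):
            SpikeTrain(spike_times=np.array([150.0]), duration=100.0)

    def test_coding_precision_constant_series(self):
        assert coding_precision(np.ones(100), (10, 90)) == 0.0

    def test_coding_precision_matches_brute_force(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=400)
        assert coding_precision(y, (100, 300)) == pytest.approx(np.std(y[100:300]))

    def test_coding_precision_window_validation(self):
        with pytest.raises(ValueError):
            coding_precision(np.ones(100), (50, 51))
        with pytest.raises(ValueError):
            coding_precision(np.ones(100), (50, 200))


class TestParams:
    def test_mf_defaults_to_half_theta0(self):
        assert ASNParams(theta0=0.2).mf == pytest.approx(0.1)

    def test_invalid_params_rejected(self):
        for kwargs in (
            {"theta0": 0.0},
            {"tau_eta": -1.0},
            {"dt": 0.0},
            {"comparator": "maybe"},
            {"psp_norm": "other"},
        ):
            with pytest.raises(ValueError):
                ASNParams(**kwargs)

    def test_kernel_sums_to_one(self, default_params):
        assert psp_kernel(default_params).sum() == pytest.approx(1.0, abs=1e-4)
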