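"""Greedy spike rule, decoding, and trial protocol."""

import numpy as np
import pytest

from predcoding.filters import NeuronSpec, bank_from_specs, build_filter_bank
from predcoding.simulator import (
    SpikeRaster,
    cost_delta_oracle,
    decode_estimate,
    run_trials,
    simulate_network,
)
from predcoding.stimuli import Stimulus, make_noise_bank, make_stimulus

DT = 0.1


def total_input(stimulus, noise, m):
    if noise is None:
        return stimulus.values
    return stimulus.values + noise.matrix()[m]


class TestBasics:
    def test_zero_stimulus_zero_spikes(self, pair_bank):
        stim = make_stimulus("constant", 200, DT, amplitude=0.0)
        res = simulate_network(pair_bank, stim)
        assert res.raster.total_spikes == 0
        assert np.all(res.estimate == 0.0)

    def test_real_minus_ideal_is_delta(self, pair_bank):
        stim = make_stimulus("constant", 300, DT, amplitude=5.0)
        res = simulate_network(pair_bank, stim)
        for ideal, real in zip(res.raster.ideal_times, res.raster.real_times):
            assert np.allclose(real - ideal, pair_bank.delta)

    def test_one_spike_per_neuron_per_bin(self, pair_bank):
        stim = make_stimulus("filtered_noise", 500, DT, amplitude=10.0, tau=5.0, seed=2)
        res = simulate_network(pair_bank, stim)
        for t in res.raster.ideal_times:
            assert np.all(np.diff(t) >= DT - 1e-12)

    def test_estimate_is_decode_of_raster(self, mixed_bank_small):
        stim = make_stimulus("filtered_noise", 400, DT, amplitude=5.0, tau=15.0, seed=3)
        res = simulate_network(mixed_bank_small, stim)
        assert np.allclose(
            res.estimate, decode_estimate(res.raster, mixed_bank_small, len(stim))
        )

    def test_grid_mismatch_rejected(self, pair_bank):
        stim = Stimulus(dt=0.2, values=np.ones(100))
        with pytest.raises(ValueError):
            simulate_network(pair_bank, stim)

    def test_noise_shape_validated(self, pair_bank):
        stim = make_stimulus("constant", 100, DT, amplitude=1.0)
        with pytest.raises(ValueError):
            simulate_network(pair_bank, stim, noise=np.zeros((3, len(stim))))


class TestDecode:
    def test_empty_raster_decodes_to_zero(self, pair_bank):
        raster = SpikeRaster([np.array([]), np.array([])], pair_bank.delta)
        assert np.all(decode_estimate(raster, pair_bank, 1000) == 0.0)

    def test_single_spike_places_shifted_filter(self, pair_bank):
        raster = SpikeRaster([np.array([10.0]), np.array([])], pair_bank.delta)
        out = decode_estimate(raster, pair_bank, 2000)
        L = pair_bank.g.shape[1]
        assert np.allclose(out[100 : 100 + L], pair_bank.g[0][: 2000 - 100])
        assert np.all(out[:100] == 0.0)

    def test_superposition(self, pair_bank):
        r1 = SpikeRaster([np.array([5.0, 30.0]), np.array([])], pair_bank.delta)
        r2 = SpikeRaster([np.array([12.0]), np.array([8.0])], pair_bank.delta)
        merged = SpikeRaster(
            [np.array([5.0, 12.0, 30.0]), np.array([8.0])], pair_bank.delta
        )
        a = decode_estimate(r1, pair_bank, 800) + decode_estimate(r2, pair_bank, 800)
        assert np.allclose(a, decode_estimate(merged, pair_bank, 800))

    def test_off_grid_spike_rejected(self, pair_bank):
        raster = SpikeRaster([np.array([0.123]), np.array([])], pair_bank.delta)
        with pytest.raises(ValueError, match="off-grid"):
            decode_estimate(raster, pair_bank, 100)


class TestGreedyRule:
    def test_first_crossing_matches_exhaustive_oracle(self, type1_bank):
        # drive a single neuron so that the window projection marginally
        # exceeds the threshold; the spike must appear at the first step where
        # the exhaustively evaluated error difference is positive
        bank = type1_bank  # nu = mu = 0
        level = 1.02 * bank.theta_base[0] / (bank.g_in[0].sum() * DT)
        stim = make_stimulus("constant", 40, DT, amplitude=level)
        res = simulate_network(bank, stim)
        assert res.raster.total_spikes >= 1
        first = res.raster.ideal_times[0][0]
        # oracle: evaluate the error difference for every candidate time
        empty = SpikeRaster([np.array([])], bank.delta)
        deltas = np.array(
            [
                cost_delta_oracle(empty, bank, stim.values, (0, t))
                for t in np.arange(0.0, 30.0, DT)
            ]
        )
        expected_first = np.nonzero(deltas > 0)[0][0] * DT
        assert first == pytest.approx(expected_first, abs=1e-9)

    def test_duplicate_spike_has_negative_delta_with_cost(self):
        bank = bank_from_specs([NeuronSpec("type1")], nu=1.5, mu=0.0)
        stim = make_stimulus("constant", 100, DT, amplitude=2.0)
        res = simulate_network(bank, stim)
        assert res.raster.total_spikes > 0
        t0 = res.raster.ideal_times[0][0]
        delta = cost_delta_oracle(res.raster, bank, stim.values, (0, t0))
        assert delta < 2 * bank.nu  # re-firing an already-placed spike never pays

    def test_zero_filter_zero_delta(self, pair_bank):
        bank = pair_bank
        x = np.zeros(2000)
        empty = SpikeRaster([np.array([]), np.array([])], bank.delta)
        import copy

        b2 = copy.copy(bank)
        b2.g = bank.g.copy()
        b2.g[0] = 0.0
        assert cost_delta_oracle(empty, b2, x, (0, 50.0)) == 0.0

    def test_decisions_agree_with_error_difference(self, rng):
        # small randomized network: every first-candidate decision must agree
        # in sign with the brute-force error difference, and satisfy the exact
        # relation delta_E = 2*margin + 2*nu + 2*adapt
        specs = [
            NeuronSpec("heterogeneous", psi=float(p), phase_basis=b, sign=s)
            for p, b, s in zip(
                rng.uniform(0, 1.5, 4), ["sin", "cos", "sin", "cos"], [1, -1, -1, 1]
            )
        ]
        bank = bank_from_specs(specs, nu=1.0, mu=1.0)
        stim = make_stimulus("filtered_noise", 150, DT, amplitude=6.0, tau=10.0, seed=9)
        res = simulate_network(bank, stim, record_decisions=True)
        dec = res.decisions
        spikes = [
            (m, int(round(t / DT)))
            for m, ts in enumerate(res.raster.ideal_times)
            for t in ts
        ]
        D = bank.delta_bins
        checked = 0
        for i in rng.choice(len(dec.bin), size=60, replace=False):
            k, m = int(dec.bin[i]), int(dec.neuron[i])
            hist = [[b * DT for (j, b) in spikes if j == n and b + D < k] for n in range(bank.N)]
            raster = SpikeRaster([np.array(h) for h in hist], bank.delta)
            delta_e = cost_delta_oracle(raster, bank, stim.values, (m, (k - D) * DT))
            expected = 2 * dec.margin[i] + 2 * bank.nu + 2 * dec.adapt[i]
            assert delta_e == pytest.approx(expected, rel=1e-9, abs=1e-9)
            assert (delta_e > 2 * (bank.nu + dec.adapt[i])) == bool(dec.fired[i])
            checked += 1
        assert checked == 60


class TestDynamics:
    def test_delay_consistency_time_invariance(self, mixed_bank_small):
        # shifting the stimulus by k bins shifts all spikes by exactly k bins;
        # a silent lead-in longer than the decision window keeps the two runs'
        # boundary transients identical (both quiescent)
        sig = make_stimulus("filtered_noise", 300, DT, amplitude=6.0, tau=15.0, seed=5)
        lead = 500  # 50 ms of silence
        shift_bins = 40
        base = Stimulus(dt=DT, values=np.concatenate([np.zeros(lead), sig.values]))
        shifted = Stimulus(
            dt=DT, values=np.concatenate([np.zeros(lead + shift_bins), sig.values])
        )
        r0 = simulate_network(mixed_bank_small, base)
        r1 = simulate_network(mixed_bank_small, shifted)
        assert r0.raster.total_spikes > 20
        for a, b in zip(r0.raster.ideal_times, r1.raster.ideal_times):
            a = a[a < base.duration - shift_bins * DT]
            assert a.size == b.size
            assert np.allclose(a + shift_bins * DT, b, atol=1e-9)

    def test_adaptation_damps_ping_pong(self):
        # rapid alternation between a neuron and its sign-flipped twin
        # (over/under-shooting the estimate) is strongly damped by the
        # adaptive spike cost mu, on the same stimulus and noise
        stim = make_stimulus("filtered_noise", 2000, DT, amplitude=6.0, tau=15.0, seed=21)
        noise = make_noise_bank(2, 2, 6.0, 15.0, 2000, DT, seed=22)

        def alternations(res, win=2.0):
            events = sorted(
                [(t, 0) for t in res.raster.ideal_times[0]]
                + [(t, 1) for t in res.raster.ideal_times[1]]
            )
            return sum(
                1
                for (t0, n0), (t1, n1) in zip(events, events[1:])
                if n0 != n1 and t1 - t0 < win
            )

        rates = {}
        for mu in (0.0, 1.5):
            bank = build_filter_bank("homogeneous", 2, nu=0.5, mu=mu)
            rates[mu] = alternations(simulate_network(bank, stim, noise=noise))
        assert rates[1.5] < 0.1 * rates[0.0]

    def test_threshold_traces_bounded_below_by_base(self, pair_bank):
        stim = make_stimulus("constant", 200, DT, amplitude=8.0)
        res = simulate_network(pair_bank, stim, record_thresholds=True)
        assert np.all(
            res.threshold_traces >= pair_bank.theta_base[:, None] - 1e-12
        )
        assert res.raster.total_spikes > 0
        assert res.threshold_traces.max() > pair_bank.theta_base.max()

    def test_parallel_resolution_mode_runs(self, pair_bank):
        stim = make_stimulus("constant", 200, DT, amplitude=8.0)
        res = simulate_network(pair_bank, stim, resolution="parallel")
        assert res.raster.total_spikes > 0
        with pytest.raises(ValueError):
            simulate_network(pair_bank, stim, resolution="simultaneous")


class TestRunTrials:
    def test_identical_seeds_identical_rasters(self, mixed_bank_small):
        stim = make_stimulus("filtered_noise", 300, DT, amplitude=5.0, tau=15.0, seed=1)
        a = run_trials(mixed_bank_small, stim, 2, start_stimulus_duration=100.0, seeds=7)
        b = run_trials(mixed_bank_small, stim, 2, start_stimulus_duration=100.0, seeds=7)
        for ra, rb in zip(a, b):
            for ta, tb in zip(ra.raster.ideal_times, rb.raster.ideal_times):
                assert np.array_equal(ta, tb)

    def test_zero_start_duration_trials_identical(self, mixed_bank_small):
        stim = make_stimulus("filtered_noise", 300, DT, amplitude=5.0, tau=15.0, seed=1)
        res = run_trials(mixed_bank_small, stim, 3, start_stimulus_duration=0.0)
        ref = res[0].raster.ideal_times
        for r in res[1:]:
            for ta, tb in zip(ref, r.raster.ideal_times):
                assert np.array_equal(ta, tb)

    def test_different_starts_vary_spikes_but_both_reconstruct(self, pair_bank):
        from predcoding.metrics import normalized_mse

        stim = make_stimulus("sine", 600, DT, amplitude=8.0, frequency=5.0)
        res = run_trials(pair_bank, stim, 2, start_stimulus_duration=300.0, seeds=3)
        for r in res:
            assert r.stimulus.duration == 600
            assert all(t.min() >= 0 for t in r.raster.ideal_times if t.size)
            assert normalized_mse(stim.values, r.estimate) < 1.0
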