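# predcoding

Greedy predictive-coding spiking networks: a simulator and analysis toolkit
for recurrent populations that track a continuously varying 1-D input with
spikes, for computational neuroscientists studying efficient coding, neural
heterogeneity and trial-to-trial variability.

## The model

Each neuron *j* owns a *representing filter* g_j(t): the waveform its spike
contributes to a linear reconstruction of the stimulus,

    ŝ(t) = Σ_j Σ_i g_j(t − t_ji),

with t_ji the (ideal) spike times. A spike is fired only if it reduces the
mean-squared error ∫(s − ŝ)² of the reconstruction, net of spike costs — a
spiking form of matching pursuit. Because the decision about a contribution
placed at time T can only be taken after observing the input up to T + Δ,
every neuron carries two spike trains: the ideal train (where contributions
are placed) and the real train, delayed by exactly Δ. The rule reduces to a
filter network: neuron m maintains a membrane value

    V_m(T + Δ) = ∫ g_m(t − T) [x_m(t) − ŝ(t)] dt,     x_m = s + η_m,

and fires when V_m exceeds a threshold Θ_m = ½∫₀^Δ g_m² + ν + adaptation.
Everything else is derived from g: the input filter g_in(t) = g(Δ − t) on
[0, Δ], the lateral filters g_lat[m][j] = −(g_in[m] ∗ g_j) that subtract
already-represented signal from other membranes, the linear spike cost ν and
an adaptive cost (increment μ, decay 60 ms) that suppresses ping-pong firing
between sign-opposite neurons.

Filters are built from Gamma bases t³e^(−t): unimodal filters yield
*type-1* (integrator) neurons, bimodal filters *type-2* (resonator) neurons,
and three canonical populations are provided — homogeneous (on/off type-1),
mixed (type-1 & type-2) and fully heterogeneous. Metrics include the
spike-train coincidence factor Γ, trial reliability Γ̄, normalized MSE,
network activity A (Hz) and efficiency E = 1/(MSE̅·A), plus the standard
characterization protocols (f-I curves, PRC, STA, signal/noise
cross-correlograms, spike-triggered network activity).

## Worked example

```python
import predcoding as pc

stim = pc.make_stimulus("filtered_noise", 1500.0, 0.1, amplitude=5.0, tau=15.0, seed=8)
for kind in ("homogeneous", "heterogeneous"):
    bank = pc.build_filter_bank(kind, 100, nu=1.5, mu=1.5, seed=2)
    trials = pc.run_trials(bank, stim, n_trials=4, start_stimulus_duration=500.0, seeds=9)
    rep = pc.evaluate_trials(trials)
    print(f"{kind:14s} Gammā = {rep.gamma_mean:5.2f}   MSE̅ = {rep.mse_norm:5.3f}   "
          f"A = {rep.activity:5.1f} Hz   E = {rep.efficiency:5.2f} s")
```

prints

```
homogeneous    Gammā =  0.44   MSE̅ = 0.521   A =  11.2 Hz   E =  0.17 s
heterogeneous  Gammā =  0.47   MSE̅ = 0.020   A =  18.2 Hz   E =  2.69 s
```

Four presentations of the same 1.5 s filtered-noise stimulus (std 5,
autocorrelation 15 ms), each behind a different random 500 ms start-stimulus
and with no other noise anywhere. Γ̄ ≈ 0.45 means the spike trains differ
substantially across trials even though the code is deterministic — the code
is *degenerate* (many spike patterns reconstruct equally well). The
heterogeneous network reaches a 25× smaller reconstruction error for less
than twice the spikes, hence its ~16× higher efficiency on this stimulus.

More narrative walk-throughs live in `examples/` (network demo, neuron
types, trial variability, noise robustness, correlations/coherence); each
prints the numbers it computes and says what they mean. A thin CLI mirrors
the config-driven experiments: `predcoding sweep-efficiency --help`.

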