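# Methods

## Model

The simulator implements a recurrent spiking network derived from two
assumptions: spikes are decoded linearly, and a spike is emitted only when it
reduces the mean-squared error of the reconstruction, net of spike costs.
With representing filters g_j, the reconstruction is
ŝ(t) = Σ_j (g_j ∗ ρ_j^ideal)(t). A candidate spike of neuron m at ideal time
T is evaluated at T + Δ by the error difference

ΔE = E_no-spike(T+Δ) − E_spike(T+Δ) = 2∫ g_m(t−T)[x_m(t) − ŝ(t)] dt − ∫₀^Δ g_m²,

and the spike is fired iff ΔE > 2(ν + adaptation), which is identical to the
membrane form V_m > Θ_m with V_m the windowed residual projection and
Θ_m = ½∫₀^Δ g_m² + ν + adaptation. The equivalence is exact in the discrete
arithmetic and is exercised directly by the test suite
(ΔE = 2·(V − Θ_base − adapt) + 2ν + 2·adapt to 1e−9 on every first-candidate
decision of randomized small networks).

Causality fixes the bookkeeping: a spike decided at T + Δ enters the
reconstruction at its ideal position T, and it can influence other decisions
only from T + Δ onward. Consequently the only part of the lateral kernel
−(g_in[m] ∗ g_j) that ever acts on a membrane is its lag ≥ Δ portion; at the
moment of emission the kick on a sign-inverted twin is exactly +2(Θ − ν) and
on the neuron itself −2(Θ − ν) (instant reset). Within one time step,
suprathreshold neurons are resolved greedily: fire the largest margin, update
all membranes, re-evaluate (ties to the lowest index, at most N per step, one
spike per neuron per bin); a `resolution="parallel"` mode fires all initially
suprathreshold neurons at once. This sequential resolution is what
desynchronizes identical neurons in a noiseless homogeneous population and
produces irregular, in-vivo-like rasters from a deterministic rule.

Spike costs: ν is a constant added to the threshold (sparsity); μ is an
adaptive cost — each of a neuron's own spikes raises its threshold by μ,
decaying exponentially with τ_adapt = 60 ms — which both distributes activity
across the population and damps the ping-pong effect (measured on a twin pair
with private noise: 17 219 near-coincident opposite-sign spike pairs at μ = 0
vs 185 at μ = 1.5, same input).

Noise enters the encoders only: neuron m sees x_m = s + η_m, but the
reconstruction error is always measured against the clean s, and the decoder
target never contains noise.

## Filters and populations

All filters derive from Gamma bases Γ_n(t) = tⁿe^(−t) (t in ms): type 1 is
Γ₃; type 2 is Γ₃(t)(0.2 − 0.8 sin 0.6t); off-cells are sign-inverted copies;
heterogeneous filters are Γ₃(t)(0.2 ± 0.8 {sin|cos}(ψt)) with ψ ~ U(0, 1.5)
per neuron. Populations: homogeneous (half type-1 on, half off), mixed
(quarters of type-1/type-2 on/off), heterogeneous (half sin- and half
cos-modulated, each split between + and − modulation).

Filters are truncated where |g| falls below 1e−6 of the peak (at 50 ms at the
latest) and rescaled to a common squared norm on [0, Δ], which makes all base
thresholds identical. The default norm target is that of the raw Γ₃ on
[0, Δ] (≈ 5.58 for Δ = 7.5 ms), leaving the canonical type-1 filter unchanged
and putting peak amplitudes in roughly [1, 2]; a unit-norm mode
(`norm_mode="unit"`, base threshold exactly ½ at ν = 0) is also provided.

The type-2 filter as constructed has a net-negative integral over [0, Δ], so
a positive constant or step drive silences it; single-neuron protocols
therefore probe its sign-inverted twin. This is purely an orientation
convention — "type 2" refers to the bimodal filter shape, not its sign.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| dt | simulation step | 0.1 ms | Δ and kernel supports must be multiples |
| Δ | decision delay / input-filter support | 7.5 ms | 75 bins; also the prediction horizon |
| ν | linear spike cost | 1.5 | demo configuration uses 0.5 |
| μ | adaptive spike cost increment | 1.5 | per own spike |
| τ_adapt | adaptation decay | 60 ms | exponential kernel, amplitude 1 |
| norm target | ∫₀^Δ g² after normalization | ≈ 5.58 | raw-Γ₃ target; `unit` mode = 1 |
| p | coincidence binwidth | 2 ms | reported with every metrics table |

## Stimuli and noise

The stochastic stimulus is white noise (variance 1/dt per sample, so
statistics are grid-invariant) filtered with a normalized causal exponential
forward and then backward (zero-phase, symmetric autocorrelation with time
constant τ), mean-centred and rescaled so the sample standard deviation
equals the requested amplitude exactly. "Amplitude" of a stochastic signal
always means its standard deviation. Deterministic stimuli: constant,
step-and-hold, sine (peak-amplitude convention), rectangular pulse probes
(sub-bin widths delivered as one-sample impulses of equal area). The STA
probe uses a causal (forward-only) exponential with τ = 1 ms — a separate
mode from the zero-phase stimulus filter.

Correlated corruption is modelled as a NoiseBank: n_copies independent
filtered-noise realizations distributed over N neurons in contiguous index
blocks of ⌈N/n_copies⌉ (a seeded random assignment is available). One copy =
fully shared noise, N copies = fully independent. Mixed compositions (e.g.
an independent component plus a component shared per 10 neurons) are sums of
banks. All seeding flows through `numpy.random.SeedSequence` spawning, so
every copy has an independent substream and runs are bit-reproducible.

What the generator emulates: amplitude- and timescale-controlled stationary
1-D drive with controllable across-neuron noise correlations. What it does
not: non-stationarities, naturalistic spectra, multidimensional stimuli, or
input nonlinearities — so passing tests demonstrate properties of the coding
scheme under idealized drive, not performance on natural signals. External
1-D recordings can be ingested from single-column CSV with a stated dt.

## Numerical conventions

- All [0, Δ] integrals are rectangle sums with the inclusive (D+1)-sample
  convention dt·Σ_{i=0..D}. This is exactly the value the discrete lateral
  convolution attains at lag Δ, so the identity −g_out(Δ) = 2(Θ − ν) holds to
  machine precision rather than to quadrature tolerance.
- The input drive is computed by direct convolution (not FFT): FFT round-off
  is not translation-exact and can flip near-threshold decisions, breaking
  the time-invariance property (a stimulus shifted by k bins must shift every
  spike by exactly k bins).
- Membrane bookkeeping uses the algebraically equivalent filter form
  (precomputed input drive plus per-spike lateral-kernel additions) rather
  than recomputing residual windows; the equivalence is asserted against the
  brute-force error-difference oracle.
- Degenerate inputs: an identically zero filter on [0, Δ] is rejected at
  normalization (its input filter would vanish); a zero stimulus yields an
  exactly silent network; empty rasters decode to zero.

## Coincidence factor

Γ = (N_coinc − 2N₁N₂/K) / (½(N₁+N₂)) / (1 − 2N₂/K) with K = T/p. The chance
terms are those of a ±p coincidence window (the probability of a Poisson
spike within ±p of a given spike is ≈ 2ν₂p = 2N₂/K). Two counting modes are
provided. `window` (default): N_coinc counts train-1 spikes with a train-2
spike within ±p; identical trains give exactly 1 and independent Poisson
trains average to 0 at any rate. `binned`: trains are binned, multiply
occupied bins count once, and N_coinc is the number of co-occupied bins;
identical trains still give exactly 1, but pairing the shared-bin count
(chance N₁N₂/K) with the ±p chance terms leaves a negative bias of order
rate·p for independent trains (≈ −0.02 at 10 Hz, p = 2 ms). The binned mode
is retained because it is the natural discretization on the simulation grid;
the windowed mode is the default because it keeps both calibration points
exact. Γ is asymmetric (train 2 sets the chance rate); trial reliability Γ̄
averages Γ over neurons and consecutive trial pairs (an all-pairs option
exists), excluding NaN sentinels from silent reference neurons.

## Protocol choices

- PRC: the unperturbed period is measured from steady-state inter-spike
  intervals under constant drive; a 0.1 ms pulse is delivered at each phase
  and the normalized shift of the next spike reported (positive = advanced).
  Doublet-firing neurons are detected from the bimodal ISI distribution and
  probed separately within (short interval) and between (long interval)
  doublets. The next-spike estimator was chosen over asymptotic-shift
  estimators for robustness at the grid resolution.
- Modality ("unimodal"/"multimodal") is operationalized as the number of sign
  changes of the curve after ignoring samples below 10% of its peak, with an
  optional Gaussian smoothing whose width is given in the curve's own x-units
  (ms for an STA, phase for a PRC).
- Correlograms are computed on mean-subtracted PSTHs (chance level removed,
  so anti-correlated trains give negative values) and normalized to the total
  average spike count of the pair; signal = correlogram of trial averages,
  noise = trial-averaged per-trial correlogram minus the signal term. Default
  lags ±50 ms at 1 ms bins.
- Population rate: spikes convolved with a normalized Gaussian (σ = 6 ms),
  summed over neurons, in Hz. Spike-triggered network activity averages this
  rate around a subset's spikes; an `exclude_self` option removes each
  trigger neuron's own smoothed train, discarding the trivial
  autocorrelation peak (used when comparing type-1 vs type-2 coupling).

## Operating range and known limitations

The delayed greedy rule is exact about the past but cannot anticipate
spikes that will be decided within the next Δ. Only the lag ≥ Δ part of each
coupling kernel ever acts on membranes, which for Γ₃-based kernels carries
≈ 54% of the kernel's mass. At drive levels far above threshold this
produces a systematic over-representation: for a constant input s the
population equilibrates near ŝ ≈ 2s − 2Θᶜ/‖g‖₁ rather than ŝ ≈ s. In
practice the model therefore has a preferred operating range — stimulus
amplitudes up to a few filter peak amplitudes — where tracking is accurate
(e.g. the mixed network at amplitude 2.7, τ = 15 ms: MSE̅ ≈ 0.05, A ≈ 8 Hz
noiseless), while at amplitude 10 the homogeneous network's noiseless MSE̅
rises to ≈ 0.6. A `lateral_gain` option scales the applied coupling kernels
for sensitivity analyses of this mass deficit (gain ≈ 1.9, the full-to-tail
mass ratio, restores tracking at high amplitude for the homogeneous network
but inflates ping-pong churn and breaks the exact greedy/error-difference
identity); the default gain is 1, i.e. the faithful rule, and all shipped
tests and scripts use it.

Private (independent) per-neuron noise is compensated in the reconstruction
— the error stays far below the silent-network baseline — but at the cost of
churn: pairs of sign-opposite spikes that cancel in ŝ inflate the firing
rate well beyond the noiseless operating point (the mixed network's ~8 Hz
noiseless rate roughly doubles under the half-independent/half-shared noise
composition). Under fully shared noise the network cannot distinguish signal
from corruption, and the error grows with the shared amplitude — the
heterogeneous population degrades most gracefully there.

Problem sizes in the shipped tests and the acceptance script are desk-scale
choices: 2.5 s sweeps (500 ms start-stimuli), 20 s runs for rate operating
points, 15–20 trials of 3–4 s for correlograms (the correlation experiment
exposes a flag-free `n_trials` for full-scale runs), and 3×3 sweep grids for
network comparisons. Event-driven simulation, transmission delays other than
Δ, plasticity, and multidimensional stimuli are out of scope.
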