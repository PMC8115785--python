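"""Single-neuron protocols and network correlation analyses.

Single neurons are probed the way an electrophysiologist would probe a patched
cell: f-I curves from step-and-hold currents, phase-response curves (PRC) from
brief pulses on top of a constant drive, and spike-triggered averages (STA)
from rapidly fluctuating filtered white noise. In this framework a neuron with
a unimodal representing filter behaves like a 'type 1' integrator (continuous
f-I curve, single-signed PRC and STA) while a bimodal filter produces 'type 2'
resonator behaviour (doublet firing, sign-changing PRC and STA).

Network analyses: signal and noise cross-correlograms across repeated trials,
the Gaussian-smoothed population rate, and the spike-triggered network
activity that separates 'chorists' (neurons coupled to the population) from
'soloists'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate, correlation_lags

from .filters import FilterBank
from .simulator import SimulationResult, SpikeRaster, simulate_network
from .stimuli import Stimulus, exp_filter_causal, make_pulse_probe, make_stimulus

__all__ = [
    "ProtocolResult",
    "Correlogram",
    "fi_curves",
    "prc",
    "sta",
    "signal_correlogram",
    "noise_correlogram",
    "population_rate",
    "spike_triggered_population_activity",
    "rate_neuron_correlogram",
    "count_sign_changes",
    "classify_modality",
]


@dataclass
class ProtocolResult:
    kind: str
    x: np.ndarray
    y: np.ndarray
    params: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("protocol axes and values must have equal length")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"x": self.x, "y": self.y})


@dataclass
class Correlogram:
    lags_ms: np.ndarray
    values: np.ndarray
    normalization: str = ""
    labels: tuple = ()

    def __post_init__(self):
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    def central(self, half_width: float = 5.0) -> float:
        """Mean value within |lag| <= half_width ms."""
        m = np.abs(self.lags_ms) <= half_width
        return float(self.values[m].mean())


class ProtocolError(RuntimeError):
    """A characterization protocol could not be run (e.g. no spikes)."""


def _single_neuron(bank: FilterBank) -> None:
    if bank.N != 1:
        raise ValueError("protocol expects a single-neuron bank (N = 1)")


def _spike_times(res: SimulationResult) -> np.ndarray:
    return res.raster.real_times[0]


# ---------------------------------------------------------------------------
# f-I curves


def fi_curves(
    bank: FilterBank,
    amplitudes,
    duration: float = 1000.0,
    onset: float = 0.0,
) -> tuple[ProtocolResult, ProtocolResult]:
    """Instantaneous and mean f-I curves from step-and-hold stimuli.

    Instantaneous frequency is 1/(t2 - t1) of the first two spikes (NaN where
    fewer than two spikes occur); mean frequency is the spike count divided by
    the post-onset duration. Frequencies in Hz.
    """
    _single_neuron(bank)
    amplitudes = np.asarray(amplitudes, dtype=float)
    inst = np.full(amplitudes.size, np.nan)
    mean = np.zeros(amplitudes.size)
    isis_all = []
    for i, a in enumerate(amplitudes):
        stim = make_stimulus("step_and_hold", duration, bank.dt, amplitude=a, onset=onset)
        t = _spike_times(simulate_network(bank, stim))
        t = t[t >= onset]
        mean[i] = t.size / ((duration - onset) * 1e-3)
        if t.size >= 2:
            inst[i] = 1000.0 / (t[1] - t[0])
        isis_all.append(np.diff(t))
    params = {"duration_ms": duration, "onset_ms": onset}
    return (
        ProtocolResult("fI_instant", amplitudes, inst, params, {"isis": isis_all}),
        ProtocolResult("fI_mean", amplitudes, mean, params, {"isis": isis_all}),
    )


# ---------------------------------------------------------------------------
# phase-response curve


def _steady_spikes(bank: FilterBank, base_amplitude: float, duration: float) -> np.ndarray:
    stim = make_stimulus("constant", duration, bank.dt, amplitude=base_amplitude)
    t = _spike_times(simulate_network(bank, stim))
    t = t[t > duration / 3]  # discard onset transient
    if t.size < 6:
        raise ProtocolError(
            f"no stable periodic firing at base amplitude {base_amplitude}"
        )
    return t


def _is_doublet_firing(isis: np.ndarray) -> bool:
    if isis.size < 4:
        return False
    short, long = np.sort(isis)[: isis.size // 2], np.sort(isis)[isis.size // 2 :]
    return long.mean() > 2.0 * short.mean()


def prc(
    bank: FilterBank,
    base_amplitude: float,
    pulse_amplitude: float,
    pulse_width: float = 0.1,
    n_phases: int = 24,
    settle_duration: float = 2500.0,
) -> ProtocolResult:
    """Phase-response curve from brief pulses on a constant drive.

    The unperturbed period is measured first; a pulse is then delivered at each
    phase of one steady-state cycle and the normalized shift of the next spike
    is reported (positive = spike advanced). For doublet-firing neurons the
    within-doublet PRC (pulse inside a doublet, shift of the doublet's second
    spike) is returned as the main curve and the between-doublet PRC in
    ``extras['between']``.
    """
    _single_neuron(bank)
    spikes = _steady_spikes(bank, base_amplitude, settle_duration)
    isis = np.diff(spikes)
    phases = (np.arange(n_phases) + 0.5) / n_phases
    doublets = _is_doublet_firing(isis)

    def measure(t_ref: float, period: float) -> np.ndarray:
        expected = t_ref + period
        shifts = np.empty(n_phases)
        for i, ph in enumerate(phases):
            t_pulse = t_ref + ph * period
            stim = make_pulse_probe(
                base_amplitude, pulse_amplitude, pulse_width, t_pulse,
                expected + 3 * period, bank.dt,
            )
            t = _spike_times(simulate_network(bank, stim))
            after = t[t > t_ref + 1e-9]
            if after.size == 0:
                shifts[i] = np.nan
                continue
            shifts[i] = (expected - after[0]) / period
        return shifts

    params = {
        "base_amplitude": base_amplitude,
        "pulse_amplitude": pulse_amplitude,
        "pulse_width_ms": pulse_width,
        "doublet_firing": bool(doublets),
    }
    if not doublets:
        period = float(np.median(isis))
        k = spikes.size // 2
        y = measure(float(spikes[k]), period)
        return ProtocolResult("PRC", phases, y, params)
    # doublet firing: alternating short/long intervals
    med = float(np.median(isis))
    short_idx = np.nonzero(isis < med)[0]
    long_idx = np.nonzero(isis >= med)[0]
    k_s = short_idx[short_idx.size // 2]
    k_l = long_idx[long_idx.size // 2]
    within = measure(float(spikes[k_s]), float(isis[k_s]))
    between = measure(float(spikes[k_l]), float(isis[k_l]))
    return ProtocolResult(
        "PRC", phases, within, params,
        {"between": ProtocolResult("PRC_between", phases, between, params)},
    )


# ---------------------------------------------------------------------------
# spike-triggered average


def sta(
    bank: FilterBank,
    noise_amplitude: float,
    tau: float = 1.0,
    duration: float = 60_000.0,
    window: float = 15.0,
    seed=None,
) -> ProtocolResult:
    """Spike-triggered average of a causally filtered white-noise stimulus.

    The probe stimulus is white noise passed through a causal exponential
    filter (tau = 1 ms by default — distinct from the zero-phase stimulus
    filter), mean-centred and rescaled to ``noise_amplitude`` (std). The STA
    is the stimulus average over a pre-spike window, on lags [-window, 0] ms.
    """
    _single_neuron(bank)
    dt = bank.dt
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, 1.0 / np.sqrt(dt), size=n)
    v = exp_filter_causal(w, tau, dt)
    v -= v.mean()
    v *= noise_amplitude / v.std()
    stim = Stimulus(dt=dt, values=v, meta={"kind": "sta_probe", "tau": tau, "amplitude": noise_amplitude})
    t = _spike_times(simulate_network(bank, stim))
    wb = int(round(window / dt))
    bins = np.rint(t / dt).astype(int)
    bins = bins[(bins >= wb) & (bins < n)]
    if bins.size == 0:
        raise ProtocolError("no spikes: cannot form a spike-triggered average")
    acc = np.zeros(wb + 1)
    for b in bins:
        acc += v[b - wb : b + 1]
    lags = dt * np.arange(-wb, 1)
    return ProtocolResult(
        "STA", lags, acc / bins.size,
        {"n_spikes": int(bins.size), "tau_ms": tau, "amplitude": noise_amplitude},
    )


# ---------------------------------------------------------------------------
# modality classification


def _gaussian_smooth(y: np.ndarray, sigma_bins: float) -> np.ndarray:
    if sigma_bins <= 0:
        return y
    half = int(np.ceil(4 * sigma_bins))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma_bins) ** 2)
    k /= k.sum()
    return np.convolve(y, k, mode="same")


def count_sign_changes(values: np.ndarray, rel_threshold: float = 0.1) -> int:
    """Sign changes of a curve, ignoring samples below a fraction of its peak."""
    v = np.asarray(values, dtype=float)
    v = np.where(np.isnan(v), 0.0, v)
    peak = np.max(np.abs(v))
    if peak == 0:
        return 0
    signs = np.sign(np.where(np.abs(v) < rel_threshold * peak, 0.0, v))
    signs = signs[signs != 0]
    return int(np.count_nonzero(np.diff(signs) != 0))


def classify_modality(
    result: ProtocolResult, smooth_sigma: float = 0.0, rel_threshold: float = 0.1
) -> str:
    """'unimodal' (single-signed) or 'multimodal' (sign changes).

    ``smooth_sigma`` is a Gaussian width in the units of the protocol's x axis
    (ms for an STA, phase for a PRC); leave 0 for curves that are already
    smooth. Samples below ``rel_threshold`` times the peak are ignored.
    """
    dx = float(np.median(np.diff(result.x))) if result.x.size > 1 else 1.0
    y = np.nan_to_num(result.y)
    if smooth_sigma > 0:
        y = _gaussian_smooth(y, smooth_sigma / dx)
    return "unimodal" if count_sign_changes(y, rel_threshold) == 0 else "multimodal"


# ---------------------------------------------------------------------------
# trial correlograms


def _bin_counts(times: np.ndarray, binwidth: float, T: float) -> np.ndarray:
    K = int(round(T / binwidth))
    idx = np.minimum((np.asarray(times, float) / binwidth).astype(int), K - 1)
    out = np.zeros(K)
    np.add.at(out, idx, 1.0)
    return out


def _xcorr(a: np.ndarray, b: np.ndarray, max_lag_bins: int, demean: bool = True) -> np.ndarray:
    """c(l) = sum_t a[t] b[t + l] for l in [-max_lag, +max_lag].

    With ``demean`` the series are mean-subtracted first, so the chance level
    set by the mean rates is removed and anti-correlated trains give negative
    values.
    """
    if demean:
        a = a - a.mean()
        b = b - b.mean()
    full = correlate(b, a, mode="full")
    lags = correlation_lags(b.size, a.size, mode="full")
    keep = np.abs(lags) <= max_lag_bins
    return full[keep]


def signal_correlogram(
    trials_a: list[np.ndarray],
    trials_b: list[np.ndarray],
    T: float,
    binwidth: float = 1.0,
    max_lag: float = 50.0,
    labels: tuple = (),
) -> Correlogram:
    """Cross-correlogram of trial-averaged spike trains.

    The two neurons' trains are averaged over trials (PSTH at ``binwidth``
    ms), cross-correlated, and normalized to the total average number of
    spikes of the pair. Positive lag means neuron b fires after neuron a.
    """
    if len(trials_a) < 2 or len(trials_a) != len(trials_b):
        raise ValueError("need >= 2 trials for both neurons")
    L = int(round(max_lag / binwidth))
    avg_a = np.mean([_bin_counts(t, binwidth, T) for t in trials_a], axis=0)
    avg_b = np.mean([_bin_counts(t, binwidth, T) for t in trials_b], axis=0)
    total = avg_a.sum() + avg_b.sum()
    if total == 0:
        return Correlogram(binwidth * np.arange(-L, L + 1), np.full(2 * L + 1, np.nan),
                           "total average spikes", labels)
    c = _xcorr(avg_a, avg_b, L) / total
    return Correlogram(binwidth * np.arange(-L, L + 1), c, "total average spikes", labels)


def noise_correlogram(
    trials_a: list[np.ndarray],
    trials_b: list[np.ndarray],
    T: float,
    binwidth: float = 1.0,
    max_lag: float = 50.0,
    labels: tuple = (),
) -> Correlogram:
    """Trial-by-trial cross-correlogram minus the signal correlogram.

    The per-trial cross-correlograms are averaged over trials and the
    correlogram of the trial-averaged trains is subtracted, leaving the
    covariance of the across-trial fluctuations, with the same normalization
    as :func:`signal_correlogram`.
    """
    if len(trials_a) < 2 or len(trials_a) != len(trials_b):
        raise ValueError("need >= 2 trials for both neurons")
    L = int(round(max_lag / binwidth))
    counts_a = [_bin_counts(t, binwidth, T) for t in trials_a]
    counts_b = [_bin_counts(t, binwidth, T) for t in trials_b]
    avg_a = np.mean(counts_a, axis=0)
    avg_b = np.mean(counts_b, axis=0)
    total = avg_a.sum() + avg_b.sum()
    lags = binwidth * np.arange(-L, L + 1)
    if total == 0:
        return Correlogram(lags, np.full(2 * L + 1, np.nan), "total average spikes", labels)
    per_trial = np.mean(
        [_xcorr(a, b, L) for a, b in zip(counts_a, counts_b)], axis=0
    )
    c = (per_trial - _xcorr(avg_a, avg_b, L)) / total
    return Correlogram(lags, c, "total average spikes", labels)


# ---------------------------------------------------------------------------
# population rate and spike-triggered network activity


def population_rate(
    raster: SpikeRaster,
    T: float,
    sigma: float = 6.0,
    dt_rate: float = 1.0,
    neurons=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-smoothed summed firing rate (Hz) of a neuron subset.

    Each spike is convolved with a normalized Gaussian kernel (sigma = 6 ms by
    default); the result is the summed rate of the subset (all neurons if
    ``neurons`` is None), sampled every ``dt_rate`` ms. Returns (times, rate).
    """
    if neurons is None:
        neurons = range(raster.N)
    K = int(round(T / dt_rate))
    counts = np.zeros(K)
    for m in neurons:
        t = raster.real_times[m]
        t = t[t < T]
        if t.size:
            idx = np.minimum((t / dt_rate).astype(int), K - 1)
            np.add.at(counts, idx, 1.0)
    rate = counts / (dt_rate * 1e-3)  # Hz
    return dt_rate * np.arange(K), _gaussian_smooth(rate, sigma / dt_rate)


def spike_triggered_population_activity(
    raster: SpikeRaster,
    subset,
    T: float,
    sigma: float = 6.0,
    window: float = 50.0,
    dt_rate: float = 1.0,
    rate_neurons=None,
    exclude_self: bool = False,
) -> ProtocolResult:
    """Average population rate around the spikes of a neuron subset.

    Measures how strongly the subset couples to the overall network activity
    ('chorists' show a tall central peak, 'soloists' a flat one). The rate is
    computed over ``rate_neurons`` (all neurons by default); with
    ``exclude_self`` each trigger neuron's own smoothed train is removed from
    the rate it is averaged against, discarding the trivial autocorrelation
    peak.
    """
    subset = list(subset)
    if not subset:
        raise ProtocolError("empty trigger subset")
    times, rate = population_rate(raster, T, sigma=sigma, dt_rate=dt_rate, neurons=rate_neurons)
    wb = int(round(window / dt_rate))
    acc = np.zeros(2 * wb + 1)
    n_ref = 0
    for m in subset:
        ref = rate
        if exclude_self:
            _, own = population_rate(raster, T, sigma=sigma, dt_rate=dt_rate, neurons=[m])
            ref = rate - own
        for t in raster.real_times[m]:
            b = int(round(t / dt_rate))
            if wb <= b < times.size - wb:
                acc += ref[b - wb : b + wb + 1]
                n_ref += 1
    if n_ref == 0:
        raise ProtocolError("no usable trigger spikes in subset")
    return ProtocolResult(
        "STNA",
        dt_rate * np.arange(-wb, wb + 1),
        acc / n_ref,
        {"sigma_ms": sigma, "n_trigger_spikes": n_ref, "n_trigger_neurons": len(subset)},
    )


def rate_neuron_correlogram(
    raster: SpikeRaster,
    subset,
    T: float,
    sigma: float = 6.0,
    max_lag: float = 50.0,
    dt_rate: float = 1.0,
) -> Correlogram:
    """Average cross-correlogram between the population rate and each neuron
    of ``subset`` (its smoothed single-neuron rate), normalized per neuron."""
    subset = list(subset)
    if not subset:
        raise ProtocolError("empty subset")
    _, pop = population_rate(raster, T, sigma=sigma, dt_rate=dt_rate)
    L = int(round(max_lag / dt_rate))
    acc = np.zeros(2 * L + 1)
    for m in subset:
        _, own = population_rate(raster, T, sigma=sigma, dt_rate=dt_rate, neurons=[m])
        acc += _xcorr(own, pop, L)
    return Correlogram(
        dt_rate * np.arange(-L, L + 1),
        acc / len(subset),
        "per neuron",
        ("population",) + tuple(subset),
    )
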