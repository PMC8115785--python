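"""Performance measures: coincidence factor, reliability, MSE, activity, efficiency.

The coincidence factor Gamma is the chance-corrected, normalized count of
co-occupied time bins between two spike trains (Kistler's coincidence measure):
1 for identical trains, ~0 for independent Poisson trains, negative for
anti-correlated trains. It is asymmetric — the second train sets the chance
rate — and undefined when the second train is empty or occupies half the bins;
undefined values are returned as NaN sentinels and excluded from averages.

Network-level measures: the normalized mean-squared error MSE (reconstruction
error divided by the error of a silent network, so 1 = no better than silence),
the network activity A in spikes per neuron per second, and the efficiency
E = 1 / (MSE * A) in seconds, plus the amplitude-weighted variants
E_a = E * amplitude and E_a2 = E * amplitude^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulator import SpikeRaster

__all__ = [
    "coincidence_factor",
    "mean_reliability",
    "normalized_mse",
    "network_activity",
    "efficiency",
    "efficiency_amp",
    "efficiency_power",
    "MetricsReport",
    "evaluate_trials",
]

#: default coincidence binwidth (ms)
DEFAULT_BINWIDTH = 2.0


def bin_occupancy(times: np.ndarray, p: float, T: float) -> np.ndarray:
    """Boolean occupancy of K = T/p bins; multiply-occupied bins count once."""
    if p <= 0 or T <= 0:
        raise ValueError("binwidth and duration must be positive")
    K = int(round(T / p))
    occ = np.zeros(K, dtype=bool)
    t = np.asarray(times, dtype=float)
    if t.size:
        if t.min() < 0 or t.max() > T:
            raise ValueError("spike times must lie within [0, T]")
        idx = np.minimum((t / p).astype(int), K - 1)
        occ[idx] = True
    return occ


def coincidence_factor(
    train1,
    train2,
    p: float = DEFAULT_BINWIDTH,
    T: float | None = None,
    mode: str = "window",
) -> float:
    """Coincidence factor Gamma_12 of two spike trains.

    Gamma = (N_coinc - <N_coinc>) / (1/2 (N1 + N2)) / Norm with the chance
    level <N_coinc> = 2 N1 N2 / K and Norm = 1 - 2 N2 / K, where K = T/p.
    The chance terms are those of the +-p coincidence window (the probability
    of a Poisson spike within +-p of a given spike is ~ 2 nu2 p = 2 N2/K).
    Returns NaN when undefined (N2 = 0 or Norm <= 0). Not symmetric in (1, 2):
    train 2 sets the chance rate.

    mode
        'window' (default): N_coinc counts train-1 spikes with a train-2 spike
        within +-p; N1, N2 are raw spike counts. Identical trains give exactly
        1 and independent Poisson trains average to 0 at any rate.
        'binned': the discretized variant — trains are binned into K bins
        (multiply-occupied bins count once) and N_coinc is the number of bins
        occupied in both; N1, N2 are occupied-bin counts. Identical trains
        still give exactly 1, but the +-p chance terms over-correct the
        shared-bin chance (N1 N2 / K), leaving a small negative bias of order
        rate x p for independent trains.
    """
    t1 = np.asarray(train1, dtype=float)
    t2 = np.asarray(train2, dtype=float)
    if T is None:
        T = float(max(t1.max(initial=0.0), t2.max(initial=0.0))) + p
    if p <= 0 or T <= 0:
        raise ValueError("binwidth and duration must be positive")
    K = int(round(T / p))
    if mode == "binned":
        b1 = bin_occupancy(t1, p, T)
        b2 = bin_occupancy(t2, p, T)
        n1 = int(b1.sum())
        n2 = int(b2.sum())
        n_coinc = int(np.count_nonzero(b1 & b2))
    elif mode == "window":
        n1 = t1.size
        n2 = t2.size
        if n2:
            s2 = np.sort(t2)
            idx = np.searchsorted(s2, t1)
            left = np.where(idx > 0, t1 - s2[np.maximum(idx - 1, 0)], np.inf)
            right = np.where(idx < n2, s2[np.minimum(idx, n2 - 1)] - t1, np.inf)
            n_coinc = int(np.count_nonzero(np.minimum(left, right) <= p))
        else:
            n_coinc = 0
    else:
        raise ValueError("mode must be 'window' or 'binned'")
    norm = 1.0 - 2.0 * n2 / K
    if n2 == 0 or norm <= 0 or (n1 + n2) == 0:
        return float("nan")
    expected = 2.0 * n1 * n2 / K
    return (n_coinc - expected) / (0.5 * (n1 + n2)) / norm


def mean_reliability(
    trial_rasters: list[SpikeRaster],
    p: float = DEFAULT_BINWIDTH,
    T: float | None = None,
    pairing: str = "consecutive",
) -> float:
    """Trial-to-trial reliability Gamma-bar.

    Gamma is computed per neuron between trial pairs (the later trial is the
    chance reference) and averaged over neurons and pairs; NaN sentinels
    (silent reference neurons) are excluded. ``pairing`` is 'consecutive'
    ((1,2), (2,3), ...) or 'all' (every ordered pair i<j). Ideal spike times
    are used; the uniform delta shift drops out.
    """
    if len(trial_rasters) < 2:
        raise ValueError("need at least two trials")
    N = trial_rasters[0].N
    if any(r.N != N for r in trial_rasters):
        raise ValueError("trials disagree on neuron count")
    if T is None:
        T = max(
            (float(t.max()) for r in trial_rasters for t in r.ideal_times if t.size),
            default=p,
        ) + p
    if pairing == "consecutive":
        pairs = [(i, i + 1) for i in range(len(trial_rasters) - 1)]
    elif pairing == "all":
        pairs = [(i, j) for i in range(len(trial_rasters)) for j in range(i + 1, len(trial_rasters))]
    else:
        raise ValueError("pairing must be 'consecutive' or 'all'")
    vals = [
        coincidence_factor(trial_rasters[a].ideal_times[m], trial_rasters[b].ideal_times[m], p, T)
        for a, b in pairs
        for m in range(N)
    ]
    vals = np.asarray(vals)
    ok = ~np.isnan(vals)
    if not ok.any():
        return float("nan")
    return float(vals[ok].mean())


def normalized_mse(s: np.ndarray, s_hat: np.ndarray) -> float:
    """MSE normalized by the silent-network error: sum(s - s_hat)^2 / sum(s)^2."""
    s = np.asarray(s, dtype=float)
    s_hat = np.asarray(s_hat, dtype=float)
    if s.shape != s_hat.shape:
        raise ValueError("signal and estimate must have equal length")
    denom = float(np.dot(s, s))
    if denom == 0.0:
        return float("nan")
    err = s - s_hat
    return float(np.dot(err, err) / denom)


def network_activity(raster: SpikeRaster, N: int | None = None, T: float | None = None) -> float:
    """Mean firing rate A = total spikes / (N * T) in Hz (T given in ms)."""
    if N is None:
        N = raster.N
    if T is None or T <= 0:
        raise ValueError("duration T (ms) must be positive")
    return raster.total_spikes / (N * T * 1e-3)


def efficiency(mse_norm: float, activity: float) -> float:
    """E = 1 / (MSE * A), in seconds; NaN if either factor is not positive."""
    if not (mse_norm > 0 and activity > 0):
        return float("nan")
    return 1.0 / (mse_norm * activity)


def efficiency_amp(mse_norm: float, activity: float, amplitude: float) -> float:
    """E_a = E * stimulus amplitude."""
    return efficiency(mse_norm, activity) * amplitude


def efficiency_power(mse_norm: float, activity: float, amplitude: float) -> float:
    """E_a2 = E * stimulus amplitude^2."""
    return efficiency(mse_norm, activity) * amplitude**2


@dataclass
class MetricsReport:
    gamma_mean: float
    mse_norm: float
    activity: float
    efficiency: float
    efficiency_amp: float
    efficiency_power: float
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "gamma_mean": self.gamma_mean,
            "mse_norm": self.mse_norm,
            "activity": self.activity,
            "efficiency": self.efficiency,
            "efficiency_amp": self.efficiency_amp,
            "efficiency_power": self.efficiency_power,
            **self.params,
        }


def evaluate_trials(results, p: float = DEFAULT_BINWIDTH, burn_in: float = 0.0) -> MetricsReport:
    """Summarize a list of SimulationResults of the same stimulus.

    MSE and A are averaged over trials (after an optional burn-in discard,
    ms); Gamma-bar compares trials pairwise and needs >= 2 trials (NaN
    otherwise). The stimulus amplitude for the E_a / E_a2 variants is taken
    from the stimulus metadata (falling back to the sample std).
    """
    if not results:
        raise ValueError("no results to evaluate")
    stim = results[0].stimulus
    dt = stim.dt
    i0 = int(round(burn_in / dt))
    T = stim.duration - burn_in
    mses = [normalized_mse(r.stimulus.values[i0:], r.estimate[i0:]) for r in results]
    acts = [network_activity(r.raster, T=r.duration) for r in results]
    gamma = (
        mean_reliability([r.raster for r in results], p=p, T=stim.duration)
        if len(results) > 1
        else float("nan")
    )
    mse = float(np.mean(mses))
    act = float(np.mean(acts))
    amp = stim.meta.get("amplitude") or float(stim.values.std()) or 1.0
    return MetricsReport(
        gamma_mean=gamma,
        mse_norm=mse,
        activity=act,
        efficiency=efficiency(mse, act),
        efficiency_amp=efficiency_amp(mse, act, amp),
        efficiency_power=efficiency_power(mse, act, amp),
        params={
            "binwidth_ms": p,
            "burn_in_ms": burn_in,
            "n_trials": len(results),
            "amplitude": amp,
        },
    )
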