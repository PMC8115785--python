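"""Stimulus and noise generation.

All signals live on the simulation grid (uniform ``dt`` in ms). The stochastic
stimulus of record is zero-phase exponentially filtered white noise: white
noise passed through a normalized causal exponential filter forward and then
backward in time (so its autocorrelation is symmetric with time constant
``tau``), mean-centred and rescaled so its sample standard deviation equals the
requested amplitude exactly. "Amplitude" of a stochastic signal therefore
always means its standard deviation.

Noise correlations across a population are modelled with a :class:`NoiseBank`:
``n_copies`` independent realizations distributed among N neurons (1 copy =
fully shared noise, N copies = fully independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "Stimulus",
    "NoiseBank",
    "make_stimulus",
    "exp_filter_causal",
    "exp_filter_zero_phase",
    "make_noise_bank",
    "make_pulse_probe",
    "combine_noise",
]

STIMULUS_KINDS = ("constant", "step_and_hold", "sine", "filtered_noise")


@dataclass
class Stimulus:
    """A 1-D time series on the simulation grid, with provenance metadata."""

    dt: float
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("stimulus must be a non-empty 1-D series")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Duration in ms."""
        return self.dt * self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.values.size)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_ms": self.times, "value": self.values})

    @classmethod
    def from_csv(cls, path, dt: float, column: str | int = 0) -> "Stimulus":
        """Ingest an external 1-D signal (e.g. a recorded LFP trace) from a
        single-column CSV sampled at a stated dt."""
        import pandas as pd

        df = pd.read_csv(path)
        col = df.columns[column] if isinstance(column, int) else column
        return cls(dt=dt, values=df[col].to_numpy(float), meta={"kind": "external", "source": str(path)})


def _n_samples(duration: float, dt: float) -> int:
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / dt))
    if n < 1:
        raise ValueError("duration shorter than one time step")
    return n


def exp_filter_causal(x: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Normalized causal exponential filter (DC gain 1), forward in time."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    a = np.exp(-dt / tau)
    return lfilter([1.0 - a], [1.0, -a], np.asarray(x, float))

def exp_filter_zero_phase(x: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Zero-phase exponential smoothing: the causal filter applied forward,
    then again backward. Output length equals input length; DC gain is 1 and
    the impulse response is a symmetric two-sided exponential."""
    y = exp_filter_causal(x, tau, dt)
    return exp_filter_causal(y[::-1], tau, dt)[::-1]


def _filtered_noise(n: int, tau: float, dt: float, amplitude: float, rng) -> np.ndarray:
    # white noise of variance 1/dt so pre-rescale statistics are grid-invariant
    w = rng.normal(0.0, 1.0 / np.sqrt(dt), size=n)
    y = exp_filter_zero_phase(w, tau, dt)
    y -= y.mean()
    sd = y.std()
    if amplitude == 0.0 or sd == 0.0:
        return np.zeros(n)
    return y * (amplitude / sd)


def make_stimulus(
    kind: str,
    duration: float,
    dt: float,
    *,
    amplitude: float = 1.0,
    tau: float | None = None,
    frequency: float | None = None,
    onset: float = 0.0,
    seed=None,
) -> Stimulus:
    """Build one of the standard stimuli.

    Parameters
    ----------
    kind
        'constant' (level = amplitude), 'step_and_hold' (0 before `onset` ms,
        amplitude after), 'sine' (peak amplitude, `frequency` in Hz), or
        'filtered_noise' (zero-phase exponentially filtered white noise with
        autocorrelation time `tau` ms and sample std = amplitude).
    duration, dt
        Signal length and grid step, ms.
    """
    if kind not in STIMULUS_KINDS:
        raise ValueError(f"unknown stimulus kind {kind!r}")
    n = _n_samples(duration, dt)
    t = dt * np.arange(n)
    meta = {"kind": kind, "amplitude": amplitude, "duration": duration, "dt": dt}
    if kind == "constant":
        v = np.full(n, float(amplitude))
    elif kind == "step_and_hold":
        v = np.where(t >= onset, float(amplitude), 0.0)
        meta["onset"] = onset
    elif kind == "sine":
        if frequency is None:
            raise ValueError("sine stimulus needs a frequency (Hz)")
        v = amplitude * np.sin(2e-3 * np.pi * frequency * t)  # t in ms
        meta["frequency"] = frequency
    else:
        if tau is None or tau <= 0:
            raise ValueError("filtered_noise needs tau > 0")
        if amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        rng = np.random.default_rng(seed)
        v = _filtered_noise(n, tau, dt, amplitude, rng)
        meta.update(tau=tau, seed=seed)
    return Stimulus(dt=dt, values=v, meta=meta)


def make_pulse_probe(
    base_level: float,
    pulse_amplitude: float,
    pulse_width: float,
    pulse_time: float,
    duration: float,
    dt: float,
) -> Stimulus:
    """Constant base with an additive rectangular pulse (for PRC probing).

    A width equal to dt gives a single elevated sample; sub-dt widths are
    delivered as a one-sample impulse of equivalent area.
    """
    n = _n_samples(duration, dt)
    if not (0.0 <= pulse_time < duration):
        raise ValueError("pulse must lie inside [0, duration)")
    v = np.full(n, float(base_level))
    i0 = int(round(pulse_time / dt))
    w_bins = max(1, int(round(pulse_width / dt)))
    if pulse_width < dt:
        v[i0] += pulse_amplitude * pulse_width / dt
    else:
        v[i0 : min(n, i0 + w_bins)] += pulse_amplitude
    return Stimulus(
        dt=dt,
        values=v,
        meta={
            "kind": "pulse_probe",
            "base_level": base_level,
            "pulse_amplitude": pulse_amplitude,
            "pulse_width": pulse_width,
            "pulse_time": pulse_time,
        },
    )


@dataclass
class NoiseBank:
    """Per-neuron noise built from a limited number of independent copies.

    ``assignment[i]`` is the copy index neuron i receives; with one copy all
    neurons share identical noise, with N copies all are independent.
    """

    copies: list[Stimulus]
    assignment: np.ndarray
    relative_amplitude: float | None = None

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        n_copies = len(self.copies)
        if n_copies < 1:
            raise ValueError("need at least one noise copy")
        if self.assignment.min() < 0 or self.assignment.max() >= n_copies:
            raise ValueError("assignment refers to a missing copy")
        if len({len(c) for c in self.copies}) != 1 or len({c.dt for c in self.copies}) != 1:
            raise ValueError("all copies must share dt and length")

    @property
    def n_copies(self) -> int:
        return len(self.copies)

    @property
    def N(self) -> int:
        return self.assignment.size

    @property
    def dt(self) -> float:
        return self.copies[0].dt

    def matrix(self) -> np.ndarray:
        """Per-neuron noise as an (N, n_samples) array."""
        stack = np.stack([c.values for c in self.copies])
        return stack[self.assignment]


def make_noise_bank(
    N: int,
    n_copies: int,
    amplitude: float,
    tau: float,
    duration: float,
    dt: float,
    seed=None,
    assignment: str = "blocks",
    relative_amplitude: float | None = None,
) -> NoiseBank:
    """Independent filtered-noise copies distributed among N neurons.

    By default neurons are assigned to copies in contiguous index blocks of
    size ceil(N / n_copies) (reproducible shared-vs-not-shared pairing);
    ``assignment='random'`` shuffles the assignment with the same seed stream.
    """
    if not (1 <= n_copies <= N):
        raise ValueError(f"n_copies={n_copies} must lie in [1, N={N}]")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_copies + 1)
    copies = [
        make_stimulus(
            "filtered_noise", duration, dt, amplitude=amplitude, tau=tau, seed=child_seeds[i]
        )
        for i in range(n_copies)
    ]
    block = -(-N // n_copies)  # ceil
    assign = np.arange(N) // block
    if assignment == "random":
        np.random.default_rng(child_seeds[-1]).shuffle(assign)
    elif assignment != "blocks":
        raise ValueError("assignment must be 'blocks' or 'random'")
    return NoiseBank(copies=copies, assignment=assign, relative_amplitude=relative_amplitude)


def combine_noise(*banks: NoiseBank) -> np.ndarray:
    """Sum the per-neuron matrices of several noise banks (e.g. an independent
    component plus a component shared within groups of neurons)."""
    mats = [b.matrix() for b in banks]
    if len({m.shape for m in mats}) != 1:
        raise ValueError("noise banks must match in N and length")
    return np.sum(mats, axis=0)
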