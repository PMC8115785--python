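"""Representing filters and the kernels derived from them.

Each neuron in the network is defined by a *representing filter* ``g``: the
waveform its spike contributes to the linear reconstruction of the stimulus.
Everything else follows from ``g`` and the decision delay ``delta``:

* the input filter ``g_in(t) = g(delta - t)`` on ``[0, delta]`` (the
  time-flipped, shifted restriction with which the neuron convolves its input),
* the lateral filters ``g_lat[m][j] = -(g_in[m] * g[j])`` mediating recurrent
  suppression of already-represented signal (``g_out[m] = g_lat[m][m]``),
* the base threshold ``theta = 1/2 * integral_0^delta g(x)^2 dx + nu``.

Filters are built from Gamma-function bases ``t^n exp(-t)``; populations are
normalized so that every neuron has the same threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Kernel",
    "NeuronSpec",
    "FilterBank",
    "gamma_basis",
    "make_representing_filter",
    "build_population",
    "normalize_population",
    "derive_input_filter",
    "derive_coupling_filters",
    "base_threshold",
    "norm_sq",
    "build_filter_bank",
]

#: representing filters are truncated at this lag (ms) at the latest
T_MAX_MS = 50.0
#: ... or where |g| stays below this fraction of its own peak
TRUNC_REL_TOL = 1e-6

FILTER_KINDS = ("type1", "type2", "off_type1", "off_type2", "heterogeneous")
POPULATION_KINDS = ("homogeneous", "type1_type2", "heterogeneous")


@dataclass(frozen=True)
class Kernel:
    """A finitely supported function of time on a uniform grid.

    ``values[i]`` is the sample at time ``origin_time + i * dt`` (ms). A causal
    kernel has ``origin_time == 0`` and no samples at negative time.
    """

    dt: float
    values: np.ndarray
    origin_time: float = 0.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("kernel values must be a non-empty 1-D array")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.origin_time + self.dt * np.arange(self.values.size)

    @property
    def support(self) -> float:
        """Length of the sampled interval in ms."""
        return self.dt * self.values.size

    def truncated(self, rel_tol: float = TRUNC_REL_TOL, t_max: float = T_MAX_MS) -> "Kernel":
        """Drop trailing samples below ``rel_tol`` times the peak, cap at ``t_max``."""
        v = self.values
        n_cap = min(v.size, int(round(t_max / self.dt)) + 1)
        v = v[:n_cap]
        peak = np.max(np.abs(v)) if v.size else 0.0
        if peak > 0:
            keep = np.nonzero(np.abs(v) >= rel_tol * peak)[0]
            v = v[: keep[-1] + 1]
        return replace(self, values=v)

    def scaled(self, factor: float) -> "Kernel":
        return replace(self, values=self.values * factor)


@dataclass(frozen=True)
class NeuronSpec:
    """Recipe for one neuron's representing filter.

    ``psi`` (modulation frequency, rad/ms), ``phase_basis`` ('sin'|'cos') and
    ``sign`` (sign of the 0.8 modulation term) apply to heterogeneous neurons
    only; ``psi`` is drawn uniformly from [0, 1.5].
    """

    filter_kind: str
    psi: float | None = None
    phase_basis: str | None = None
    sign: int = 1

    def __post_init__(self):
        if self.filter_kind not in FILTER_KINDS:
            raise ValueError(f"unknown filter kind {self.filter_kind!r}")
        if self.filter_kind == "heterogeneous":
            if self.psi is None or not (0.0 <= self.psi <= 1.5):
                raise ValueError("heterogeneous neurons need psi in [0, 1.5]")
            if self.phase_basis not in ("sin", "cos"):
                raise ValueError("phase_basis must be 'sin' or 'cos'")
            if self.sign not in (-1, 1):
                raise ValueError("sign must be +1 or -1")


def _uniform_grid_check(t_grid: np.ndarray) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be 1-D with at least two samples")
    if abs(t[0]) > 1e-12:
        raise ValueError("time grid must start at 0")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
        raise ValueError("time grid must be uniform")
    return t


def gamma_basis(n: int, t_grid: np.ndarray) -> Kernel:
    """Gamma-function basis ``t^n exp(-t)`` sampled on ``t_grid`` (ms)."""
    if int(n) != n or n < 0:
        raise ValueError(f"basis order n must be a non-negative integer, got {n}")
    t = _uniform_grid_check(t_grid)
    return Kernel(dt=float(t[1] - t[0]), values=t ** int(n) * np.exp(-t))


def make_representing_filter(spec: NeuronSpec, t_grid: np.ndarray) -> Kernel:
    """Build the (unnormalized) representing filter for one neuron.

    type 1 is the Gamma basis with n=3; type 2 multiplies it by the bimodal
    modulation ``0.2 - 0.8 sin(0.6 t)``; off-cells are sign-inverted copies;
    heterogeneous filters use ``0.2 +/- 0.8 {sin|cos}(psi t)``.
    """
    t = _uniform_grid_check(t_grid)
    base = gamma_basis(3, t)
    kind = spec.filter_kind
    if kind in ("type1", "off_type1"):
        values = base.values.copy()
    elif kind in ("type2", "off_type2"):
        values = base.values * (0.2 - 0.8 * np.sin(0.6 * t))
    else:  # heterogeneous
        osc = np.sin(spec.psi * t) if spec.phase_basis == "sin" else np.cos(spec.psi * t)
        values = base.values * (0.2 + spec.sign * 0.8 * osc)
    if kind.startswith("off_"):
        values = -values
    return Kernel(dt=base.dt, values=values)


def build_population(kind: str, N: int, rng_seed=None) -> list[NeuronSpec]:
    """Neuron specs for one of the three network compositions.

    homogeneous: half type-1 on-cells, half off-cells. type1_type2: quarters of
    type1 / off_type1 / type2 / off_type2. heterogeneous: half sin-modulated and
    half cos-modulated, each half split between + and - modulation sign, with
    ``psi ~ U(0, 1.5)`` drawn per neuron.
    """
    if kind not in POPULATION_KINDS:
        raise ValueError(f"unknown population kind {kind!r}")
    groups = 2 if kind == "homogeneous" else 4
    if N <= 0 or N % groups:
        raise ValueError(f"N={N} must be a positive multiple of {groups} for {kind!r}")
    if kind == "homogeneous":
        return [NeuronSpec("type1")] * (N // 2) + [NeuronSpec("off_type1")] * (N // 2)
    if kind == "type1_type2":
        q = N // 4
        return (
            [NeuronSpec("type1")] * q
            + [NeuronSpec("off_type1")] * q
            + [NeuronSpec("type2")] * q
            + [NeuronSpec("off_type2")] * q
        )
    rng = np.random.default_rng(rng_seed)
    psis = rng.uniform(0.0, 1.5, size=N)
    specs = []
    q = N // 4
    for i in range(N):
        basis = "sin" if i < N // 2 else "cos"
        sign = 1 if (i % (N // 2)) < q else -1
        specs.append(NeuronSpec("heterogeneous", psi=float(psis[i]), phase_basis=basis, sign=sign))
    return specs


def norm_sq(g: Kernel, delta: float) -> float:
    """Rectangle-sum squared norm ``integral_0^delta g(x)^2 dx``.

    Uses the inclusive (D+1)-sample sum ``dt * sum_{i=0..D} g_i^2`` with
    ``D = delta/dt``; this is the quantity the discrete lateral convolution
    reproduces exactly at lag delta, keeping the threshold/coupling identity
    exact in the simulation arithmetic.
    """
    D = _delta_bins(delta, g.dt)
    v = g.values[: D + 1]
    return float(g.dt * np.dot(v, v))


def _delta_bins(delta: float, dt: float) -> int:
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    D = delta / dt
    if abs(D - round(D)) > 1e-6:
        raise ValueError(f"delta={delta} must be an integer multiple of dt={dt}")
    return int(round(D))


def base_threshold(g: Kernel, delta: float, nu: float) -> float:
    """Base firing threshold ``1/2 integral_0^delta g^2 + nu``."""
    return 0.5 * norm_sq(g, delta) + nu


def normalize_population(
    filters: list[Kernel], delta: float, target_norm_sq: float | None = None
) -> tuple[list[Kernel], np.ndarray]:
    """Rescale filters to a common squared norm on ``[0, delta]``.

    With a common norm the base thresholds are identical across the population.
    The default target is the squared norm of the raw type-1 filter (so the
    canonical type-1 neuron is left unchanged and peak amplitudes fall roughly
    in [1, 2]); pass ``target_norm_sq=1.0`` for unit-norm filters, whose nu=0
    threshold is exactly 0.5.
    """
    if not filters:
        raise ValueError("empty filter list")
    dt = filters[0].dt
    if any(abs(k.dt - dt) > 1e-12 for k in filters):
        raise ValueError("all kernels must share one dt")
    if target_norm_sq is None:
        D = _delta_bins(delta, dt)
        ref = gamma_basis(3, dt * np.arange(D + 1))
        target_norm_sq = norm_sq(ref, delta)
    scales = np.empty(len(filters))
    out = []
    for i, g in enumerate(filters):
        ns = norm_sq(g, delta)
        if ns <= 1e-30:
            raise ValueError(
                f"filter {i} is degenerate (identically zero on [0, {delta}] ms); "
                "its input filter would vanish"
            )
        scales[i] = np.sqrt(target_norm_sq / ns)
        out.append(g.scaled(scales[i]))
    return out, scales


def derive_input_filter(g: Kernel, delta: float) -> Kernel:
    """Input filter ``g_in(t) = g(delta - t)`` restricted to ``[0, delta]``.

    The acausal part (t outside [0, delta]) is discarded: the neuron cannot
    see the future of its input.
    """
    D = _delta_bins(delta, g.dt)
    v = g.values
    if v.size < D + 1:
        v = np.pad(v, (0, D + 1 - v.size))
    return Kernel(dt=g.dt, values=v[D::-1].copy())


def lateral_filter(g_in_m: Kernel, g_j: Kernel) -> Kernel:
    """Lateral filter ``g_lat[m][j](t) = -(g_in[m] * g_j)(t)`` (discrete conv x dt)."""
    if abs(g_in_m.dt - g_j.dt) > 1e-12:
        raise ValueError("dt mismatch between kernels")
    return Kernel(dt=g_j.dt, values=-g_j.dt * np.convolve(g_in_m.values, g_j.values))


@dataclass
class FilterBank:
    """All kernels and thresholds defining one network.

    ``g`` holds the (normalized) representing filters as an (N, L) array whose
    row i samples neuron i's filter at lags 0, dt, 2*dt, ...; ``g_in`` is
    (N, D+1); ``g_lat`` is the (N, N, D+L) array of lateral filters with
    ``g_lat[m, j]`` the effect of a spike of neuron j on neuron m, and
    ``g_out[m] = g_lat[m, m]``. ``theta_base`` already includes the linear
    spike cost ``nu``.
    """

    specs: list[NeuronSpec]
    dt: float
    delta: float
    nu: float
    mu: float
    g: np.ndarray
    g_in: np.ndarray
    g_lat: np.ndarray
    theta_base: np.ndarray
    scales: np.ndarray
    tau_adapt: float = 60.0
    norm_mode: str = "type1"
    seed: int | None = None

    @property
    def N(self) -> int:
        return len(self.specs)

    @property
    def delta_bins(self) -> int:
        return _delta_bins(self.delta, self.dt)

    @property
    def lat_tail(self) -> np.ndarray:
        """Lateral filters at lags >= delta, the only part the spike rule uses
        (a spike fired at decision time T+delta first influences decisions at
        that same moment, i.e. lag delta since its ideal time)."""
        return self.g_lat[:, :, self.delta_bins :]

    def kernel(self, m: int) -> Kernel:
        return Kernel(dt=self.dt, values=self.g[m])

    def lateral_kernel(self, m: int, j: int) -> Kernel:
        return Kernel(dt=self.dt, values=self.g_lat[m, j])

    def adaptation_decay(self) -> float:
        """Per-bin decay factor of the mu-scaled threshold increments."""
        return float(np.exp(-self.dt / self.tau_adapt))

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        """JSON descriptor (specs and parameters; kernels are re-derivable)."""
        return json.dumps(
            {
                "N": self.N,
                "dt": self.dt,
                "delta": self.delta,
                "nu": self.nu,
                "mu": self.mu,
                "tau_adapt": self.tau_adapt,
                "norm_mode": self.norm_mode,
                "seed": self.seed,
                "specs": [
                    {
                        "filter_kind": s.filter_kind,
                        "psi": s.psi,
                        "phase_basis": s.phase_basis,
                        "sign": s.sign,
                    }
                    for s in self.specs
                ],
            },
            indent=1,
        )

    def kernels_frame(self):
        """Sampled representing filters as a tidy DataFrame
        (neuron_id, time_ms, value)."""
        import pandas as pd

        n, L = self.g.shape
        return pd.DataFrame(
            {
                "neuron_id": np.repeat(np.arange(n), L),
                "time_ms": np.tile(self.dt * np.arange(L), n),
                "value": self.g.ravel(),
            }
        )


def bank_from_json(text: str) -> FilterBank:
    d = json.loads(text)
    specs = [
        NeuronSpec(
            s["filter_kind"],
            psi=s["psi"],
            phase_basis=s["phase_basis"],
            sign=s["sign"],
        )
        for s in d["specs"]
    ]
    return bank_from_specs(
        specs,
        delta=d["delta"],
        nu=d["nu"],
        mu=d["mu"],
        dt=d["dt"],
        tau_adapt=d["tau_adapt"],
        norm_mode=d["norm_mode"],
        seed=d["seed"],
    )


def derive_coupling_filters(
    g: np.ndarray, g_in: np.ndarray, dt: float
) -> np.ndarray:
    """All-pairs lateral filters ``-(g_in[m] * g[j]) * dt`` via FFT convolution.

    Returns an (N, N, D+L) array; row m, column j is the kernel a spike of
    neuron j injects into neuron m's membrane (as a function of lag since the
    spike's ideal time).
    """
    from scipy.signal import fftconvolve

    full = fftconvolve(g_in[:, None, :], g[None, :, :], axes=2)
    return -dt * full


def bank_from_specs(
    specs: list[NeuronSpec],
    *,
    delta: float = 7.5,
    nu: float = 1.5,
    mu: float = 1.5,
    dt: float = 0.1,
    tau_adapt: float = 60.0,
    norm_mode: str = "type1",
    t_max: float = T_MAX_MS,
    seed: int | None = None,
) -> FilterBank:
    """Assemble a FilterBank from neuron specs: build, truncate and normalize
    the representing filters, then derive input/lateral filters and thresholds."""
    D = _delta_bins(delta, dt)
    t_grid = dt * np.arange(int(round(t_max / dt)) + 1)
    raw = [make_representing_filter(s, t_grid).truncated(t_max=t_max) for s in specs]
    target = 1.0 if norm_mode == "unit" else None
    normed, scales = normalize_population(raw, delta, target_norm_sq=target)
    L = max(max(len(k) for k in normed), D + 1)
    g = np.zeros((len(specs), L))
    for i, k in enumerate(normed):
        g[i, : len(k)] = k.values
    g_in = g[:, D::-1].copy()
    g_lat = derive_coupling_filters(g, g_in, dt)
    theta = np.array([base_threshold(Kernel(dt, row), delta, nu) for row in g])
    return FilterBank(
        specs=specs,
        dt=dt,
        delta=delta,
        nu=nu,
        mu=mu,
        g=g,
        g_in=g_in,
        g_lat=g_lat,
        theta_base=theta,
        scales=scales,
        tau_adapt=tau_adapt,
        norm_mode=norm_mode,
        seed=seed,
    )


def build_filter_bank(
    kind: str,
    N: int,
    *,
    delta: float = 7.5,
    nu: float = 1.5,
    mu: float = 1.5,
    dt: float = 0.1,
    tau_adapt: float = 60.0,
    norm_mode: str = "type1",
    seed: int | None = None,
) -> FilterBank:
    """One-stop constructor: population specs -> normalized FilterBank."""
    specs = build_population(kind, N, rng_seed=seed)
    return bank_from_specs(
        specs,
        delta=delta,
        nu=nu,
        mu=mu,
        dt=dt,
        tau_adapt=tau_adapt,
        norm_mode=norm_mode,
        seed=seed,
    )
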