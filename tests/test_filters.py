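"""Filter construction, normalization and derived-kernel identities."""

import numpy as np
import pytest
from scipy.integrate import quad

from predcoding.filters import (
    FilterBank,
    Kernel,
    NeuronSpec,
    bank_from_json,
    bank_from_specs,
    base_threshold,
    build_filter_bank,
    build_population,
    derive_input_filter,
    gamma_basis,
    lateral_filter,
    make_representing_filter,
    norm_sq,
    normalize_population,
)

GRID = np.arange(0, 50.0, 0.1)
DELTA = 7.5


class TestGammaBasis:
    def test_vanishes_at_origin(self):
        k = gamma_basis(3, GRID)
        assert k.values[0] == 0.0

    def test_peak_at_t_equals_n(self):
        # d/dt t^n e^-t = 0 at t = n
        for n in (1, 2, 3, 5):
            k = gamma_basis(n, GRID)
            assert np.argmax(k.values) == pytest.approx(n / 0.1)

    def test_value_at_peak(self):
        k = gamma_basis(3, GRID)
        assert k.values[30] == pytest.approx(27.0 * np.exp(-3.0), rel=1e-12)

    def test_rejects_negative_order(self):
        with pytest.raises(ValueError):
            gamma_basis(-1, GRID)

    def test_rejects_nonuniform_grid(self):
        with pytest.raises(ValueError):
            gamma_basis(2, np.array([0.0, 0.1, 0.3]))


class TestRepresentingFilters:
    def test_type1_is_gamma3(self):
        k = make_representing_filter(NeuronSpec("type1"), GRID)
        assert np.allclose(k.values, GRID**3 * np.exp(-GRID))

    def test_off_cell_is_sign_inverted(self):
        for kind in ("type1", "type2"):
            on = make_representing_filter(NeuronSpec(kind), GRID)
            off = make_representing_filter(NeuronSpec(f"off_{kind}"), GRID)
            assert np.allclose(on.values + off.values, 0.0)

    def test_type2_modulation(self):
        k = make_representing_filter(NeuronSpec("type2"), GRID)
        expected = GRID**3 * np.exp(-GRID) * (0.2 - 0.8 * np.sin(0.6 * GRID))
        assert np.allclose(k.values, expected)

    def test_heterogeneous_modulation(self):
        spec = NeuronSpec("heterogeneous", psi=0.9, phase_basis="cos", sign=-1)
        k = make_representing_filter(spec, GRID)
        expected = GRID**3 * np.exp(-GRID) * (0.2 - 0.8 * np.cos(0.9 * GRID))
        assert np.allclose(k.values, expected)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            NeuronSpec("heterogeneous", psi=2.0, phase_basis="sin")
        with pytest.raises(ValueError):
            NeuronSpec("heterogeneous", psi=0.5, phase_basis="tan")
        with pytest.raises(ValueError):
            NeuronSpec("gabor")


class TestPopulations:
    def test_homogeneous_composition(self):
        specs = build_population("homogeneous", 100)
        kinds = [s.filter_kind for s in specs]
        assert kinds.count("type1") == 50 and kinds.count("off_type1") == 50

    def test_mixed_composition(self):
        specs = build_population("type1_type2", 100)
        kinds = [s.filter_kind for s in specs]
        for k in ("type1", "off_type1", "type2", "off_type2"):
            assert kinds.count(k) == 25

    def test_heterogeneous_composition_and_seeding(self):
        a = build_population("heterogeneous", 4, rng_seed=7)
        b = build_population("heterogeneous", 4, rng_seed=7)
        assert [(s.phase_basis, s.sign) for s in a] == [
            ("sin", 1), ("sin", -1), ("cos", 1), ("cos", -1)
        ]
        assert [s.psi for s in a] == [s.psi for s in b]
        assert all(0.0 <= s.psi <= 1.5 for s in a)
        c = build_population("heterogeneous", 4, rng_seed=8)
        assert [s.psi for s in a] != [s.psi for s in c]

    def test_indivisible_n_rejected(self):
        with pytest.raises(ValueError):
            build_population("homogeneous", 3)
        with pytest.raises(ValueError):
            build_population("type1_type2", 6)


class TestNormalization:
    def test_raw_gamma3_norm_matches_quadrature_oracle(self):
        # independent oracle: adaptive quadrature of t^6 e^(-2t) on [0, 7.5]
        oracle, _ = quad(lambda t: t**6 * np.exp(-2 * t), 0, DELTA)
        k = gamma_basis(3, GRID)
        assert norm_sq(k, DELTA) == pytest.approx(oracle, rel=2e-3)
        assert oracle == pytest.approx(5.5821, abs=1e-3)

    def test_type1_unchanged_under_default_target(self):
        k = gamma_basis(3, GRID)
        normed, scales = normalize_population([k], DELTA)
        assert scales[0] == pytest.approx(1.0, rel=1e-12)

    def test_unit_mode_gives_half_threshold(self):
        k = gamma_basis(3, GRID)
        normed, _ = normalize_population([k], DELTA, target_norm_sq=1.0)
        assert norm_sq(normed[0], DELTA) == pytest.approx(1.0, rel=1e-12)
        assert base_threshold(normed[0], DELTA, nu=0.0) == pytest.approx(0.5, rel=1e-12)
        assert base_threshold(normed[0], DELTA, nu=1.5) == pytest.approx(2.0, rel=1e-12)

    def test_degenerate_filter_rejected(self):
        zero = Kernel(dt=0.1, values=np.zeros(100))
        with pytest.raises(ValueError, match="degenerate"):
            normalize_population([zero], DELTA)

    def test_thresholds_equal_across_mixed_population(self):
        bank = build_filter_bank("type1_type2", 8, nu=1.5, mu=1.5)
        spread = bank.theta_base.max() - bank.theta_base.min()
        assert spread < 1e-10 * bank.theta_base.mean()

    def test_heterogeneous_peak_amplitudes_order_one(self):
        bank = build_filter_bank("heterogeneous", 16, seed=3)
        peaks = np.abs(bank.g).max(axis=1)
        assert peaks.min() > 0.5 and peaks.max() < 3.0


class TestInputFilter:
    def test_flip_endpoints(self, type1_bank):
        g = gamma_basis(3, GRID)
        gin = derive_input_filter(g, DELTA)
        assert gin.values[-1] == g.values[0] == 0.0
        assert gin.values[0] == pytest.approx(g.values[75])

    def test_interior_value(self):
        g = gamma_basis(3, GRID)
        gin = derive_input_filter(g, DELTA)
        # g_in(4.5) = g(7.5 - 4.5) = Gamma3(3)
        assert gin.values[45] == pytest.approx(27 * np.exp(-3), rel=1e-12)

    def test_support_is_delta(self):
        gin = derive_input_filter(gamma_basis(3, GRID), DELTA)
        assert len(gin) == 76

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            derive_input_filter(gamma_basis(3, GRID), 0.0)


class TestCouplingFilters:
    def test_brute_force_convolution_oracle(self, rng):
        # double-sum oracle on short kernels
        dt = 0.25
        a = Kernel(dt=dt, values=rng.normal(size=40))
        b = Kernel(dt=dt, values=rng.normal(size=50))
        lat = lateral_filter(a, b)
        oracle = np.zeros(40 + 50 - 1)
        for i in range(40):
            for j in range(50):
                oracle[i + j] -= dt * a.values[i] * b.values[j]
        assert np.allclose(lat.values, oracle, rtol=1e-9, atol=1e-12)

    def test_energy_identity(self, pair_bank):
        # -g_out(delta) = 2 (theta - nu) = integral of g^2 over the window
        D = pair_bank.delta_bins
        for m in range(pair_bank.N):
            assert -pair_bank.g_lat[m, m, D] == pytest.approx(
                2 * (pair_bank.theta_base[m] - pair_bank.nu), rel=1e-10
            )

    def test_sign_flipped_twin_identity(self, pair_bank):
        # lateral filter toward the off-cell at lag delta = +2 (theta - nu)
        D = pair_bank.delta_bins
        assert pair_bank.g_lat[0, 1, D] == pytest.approx(
            2 * (pair_bank.theta_base[0] - pair_bank.nu), rel=1e-10
        )

    def test_sign_antisymmetry(self, mixed_bank_small):
        # g_j = -g_k implies g_lat[m][j] = -g_lat[m][k] sample-wise
        bank = mixed_bank_small  # [type1, off_type1, type2, off_type2]
        assert np.allclose(bank.g_lat[0, 2], -bank.g_lat[0, 3], atol=1e-12)
        assert np.allclose(bank.g_lat[2, 0], -bank.g_lat[2, 1], atol=1e-12)

    def test_causality(self, mixed_bank_small):
        k = mixed_bank_small.lateral_kernel(0, 1)
        assert k.origin_time == 0.0  # no samples at negative lag

    def test_dt_mismatch_rejected(self):
        a = Kernel(dt=0.1, values=np.ones(5))
        b = Kernel(dt=0.2, values=np.ones(5))
        with pytest.raises(ValueError, match="dt"):
            lateral_filter(a, b)


class TestSerialization:
    def test_json_roundtrip(self):
        bank = build_filter_bank("heterogeneous", 4, nu=1.0, mu=0.5, seed=5)
        clone = bank_from_json(bank.to_json())
        assert np.allclose(clone.g, bank.g)
        assert np.allclose(clone.theta_base, bank.theta_base)
        assert clone.specs == bank.specs

    def test_kernels_frame_layout(self, pair_bank):
        df = pair_bank.kernels_frame()
        assert list(df.columns) == ["neuron_id", "time_ms", "value"]
        assert df.neuron_id.nunique() == pair_bank.N
        sub = df[df.neuron_id == 0]
        assert np.allclose(sub.value.to_numpy(), pair_bank.g[0])
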