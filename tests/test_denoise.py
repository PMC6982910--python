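import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bruxsense.denoise import (
    ShiftFamily,
    WaveletConfig,
    cycle_spin_denoise,
    denoise_once,
    estimate_sigma,
    max_decomposition_level,
    universal_threshold,
    wavedec_periodic,
    wavelet_filters,
    waverec_periodic,
)

from oracles import oracle_denoise_once, oracle_sigma, oracle_wavedec


def step_signal(n=256):
    return np.concatenate([np.zeros(n // 2), np.ones(n - n // 2)])


class TestFilters:
    @pytest.mark.parametrize("family", ["haar", "db2", "db3", "db4"])
    def test_orthonormality(self, family):
        h, g = wavelet_filters(family)
        assert np.isclose(h.sum(), np.sqrt(2.0))
        assert np.isclose((h ** 2).sum(), 1.0)
        assert np.isclose((h * g).sum(), 0.0, atol=1e-12)

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="unknown wavelet"):
            wavelet_filters("meyer")


class TestTransform:
    @pytest.mark.parametrize("family", ["haar", "db2", "db4"])
    @pytest.mark.parametrize("n", [16, 64, 256])
    def test_perfect_reconstruction(self, family, n, rng):
        x = rng.normal(size=n)
        level = max_decomposition_level(n, family)
        xr = waverec_periodic(wavedec_periodic(x, family, level), family)
        assert np.abs(x - xr).max() < 1e-10

    def test_energy_preserved(self, rng):
        x = rng.normal(size=128)
        coeffs = wavedec_periodic(x, "db4", 3)
        assert np.isclose(sum((c ** 2).sum() for c in coeffs), (x ** 2).sum())

    def test_matches_matrix_oracle(self, rng):
        h, g = wavelet_filters("db4")
        x = rng.normal(size=64)
        got = wavedec_periodic(x, "db4", 3)
        want = oracle_wavedec(x, h, g, 3)
        for a, b in zip(got, want):
            assert np.abs(a - b).max() < 1e-12

    def test_level_too_deep_names_max(self):
        with pytest.raises(ValueError, match="max level"):
            wavedec_periodic(np.zeros(16), "db4", 5)


class TestEstimateSigma:
    def test_constant_signal_zero(self):
        assert estimate_sigma(np.full(64, 3.0)) == pytest.approx(0.0, abs=1e-12)

    def test_too_short(self):
        with pytest.raises(ValueError):
            estimate_sigma(np.zeros(3))

    def test_gaussian_noise_recovery(self):
        # 50 seeds of pure N(0, 0.1^2), n = 2^14
        for seed in range(50):
            x = np.random.default_rng(seed).normal(0, 0.1, size=2 ** 14)
            assert 0.09 < estimate_sigma(x) < 0.11

    def test_robust_to_signal(self, rng):
        clean = 5.0 * np.sin(np.linspace(0, 6 * np.pi, 4096))
        noisy = clean + rng.normal(0, 0.1, size=4096)
        est = estimate_sigma(noisy)
        assert abs(est - 0.1) < abs(noisy.std() - 0.1)

    def test_matches_loop_oracle(self, rng):
        _, g = wavelet_filters("db4")
        x = rng.normal(size=100)
        assert np.isclose(estimate_sigma(x), oracle_sigma(x, g))

    def test_shift_invariant(self, rng):
        x = rng.normal(size=101)
        for s in (1, 7, 50):
            assert np.isclose(estimate_sigma(np.roll(x, s)),
                              estimate_sigma(x))


class TestDenoiseOnce:
    def test_smooth_signal_nearly_unchanged(self):
        x = np.sin(np.linspace(0, 2 * np.pi, 256))
        cfg = WaveletConfig(sigma_estimate="provided", sigma=0.0)
        assert np.abs(denoise_once(x, cfg) - x).max() < 1e-8

    def test_zero_threshold_is_identity(self, rng):
        x = rng.normal(size=128)
        cfg = WaveletConfig(sigma_estimate="provided", sigma=0.0)
        assert np.abs(denoise_once(x, cfg) - x).max() < 1e-8

    def test_reduces_rmse_on_step(self):
        clean = step_signal()
        wins = 0
        for seed in range(50):
            noisy = clean + np.random.default_rng(seed).normal(0, 0.1, 256)
            den = denoise_once(noisy)
            if np.sqrt(((den - clean) ** 2).mean()) < \
                    np.sqrt(((noisy - clean) ** 2).mean()):
                wins += 1
        assert wins >= 45

    @pytest.mark.parametrize("mode", ["soft", "hard"])
    def test_matches_bruteforce_oracle_short_signals(self, mode, rng):
        h, g = wavelet_filters("db4")
        for n in [8, 16, 24, 33, 48, 64]:
            for _ in range(5):
                x = rng.normal(size=n)
                level = 2 if n >= 16 else 1
                cfg = WaveletConfig(decomposition_level=level,
                                    threshold_mode=mode)
                got = denoise_once(x, cfg)
                want = oracle_denoise_once(x, h, g, level, mode=mode)
                assert np.abs(got - want).max() < 1e-10

    def test_level_too_deep_error(self):
        with pytest.raises(ValueError, match="max level"):
            denoise_once(np.zeros(16), WaveletConfig(decomposition_level=10))

    def test_output_length_preserved_odd_length(self, rng):
        x = rng.normal(size=100)
        assert denoise_once(x, WaveletConfig(decomposition_level=3)).shape \
            == (100,)

    def test_energy_non_expansion_soft(self, rng):
        for _ in range(10):
            x = rng.normal(size=256)
            y = denoise_once(x)
            assert np.linalg.norm(y) <= np.linalg.norm(x) + 1e-8


class TestCycleSpin:
    def test_single_shift_equals_denoise_once(self, rng):
        x = rng.normal(size=128)
        cfg = WaveletConfig()
        got = cycle_spin_denoise(x, cfg, ShiftFamily(shifts=(0,), n=128))
        assert np.allclose(got, denoise_once(x, cfg))

    def test_constant_signal_fixed_point(self):
        x = np.full(64, 2.5)
        out = cycle_spin_denoise(x, shifts=ShiftFamily.full(64))
        assert np.allclose(out, x, atol=1e-10)

    def test_too_many_shifts(self):
        with pytest.raises(ValueError):
            cycle_spin_denoise(np.zeros(16), WaveletConfig(n_shifts=40))

    def test_translation_invariance_full_shifts(self, rng):
        x = step_signal() + rng.normal(0, 0.1, 256)
        base = cycle_spin_denoise(x, shifts=ShiftFamily.full(256))
        for s in (1, 17, 100):
            lhs = cycle_spin_denoise(np.roll(x, -s),
                                     shifts=ShiftFamily.full(256))
            assert np.abs(lhs - np.roll(base, -s)).max() < 1e-8

    def test_beats_single_pass_on_step(self):
        clean = step_signal()
        r_once, r_spin, r_noisy = [], [], []
        for seed in range(50):
            noisy = clean + np.random.default_rng(seed).normal(0, 0.1, 256)
            rmse = lambda v: float(np.sqrt(((v - clean) ** 2).mean()))
            r_noisy.append(rmse(noisy))
            r_once.append(rmse(denoise_once(noisy)))
            r_spin.append(rmse(cycle_spin_denoise(noisy)))
        wins = sum(s < n for s, n in zip(r_spin, r_noisy))
        assert wins >= 45
        assert np.mean(r_spin) < np.mean(r_once)

    def test_energy_non_expansion(self, rng):
        x = rng.normal(size=256)
        y = cycle_spin_denoise(x)
        assert np.linalg.norm(y) <= np.linalg.norm(x) + 1e-8


class TestShiftFamily:
    def test_full(self):
        fam = ShiftFamily.full(8)
        assert fam.shifts == tuple(range(8))

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            ShiftFamily(shifts=(0, 0), n=8)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ShiftFamily(shifts=(8,), n=8)

    @given(st.integers(2, 64), st.integers(1, 64))
    @settings(max_examples=50, deadline=None)
    def test_evenly_spaced_valid(self, n, k):
        if k > n:
            with pytest.raises(ValueError):
                ShiftFamily.evenly_spaced(n, k)
        else:
            fam = ShiftFamily.evenly_spaced(n, k)
            assert len(fam.shifts) == len(set(fam.shifts)) == k
            assert all(0 <= h < n for h in fam.shifts)


class TestUniversalThreshold:
    def test_formula(self):
        assert universal_threshold(2.0, 100) == \
            pytest.approx(2.0 * np.sqrt(2 * np.log(100)))

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            universal_threshold(1.0, 1)
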