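"""MRF significance prior: estimators, energies, MAP support."""

import itertools

import numpy as np
import pytest

from mrftv import (LaplacianParams, MRFParams, SupportField, estimate_scale,
                   estimate_threshold, estimate_mrf_params, init_support,
                   map_support, mrf_energy, posterior_energy,
                   wavelet_analysis)
from mrftv.mrf import threshold_labels


def _coeffs_with_hh1(hh1):
    """Wavelet container whose finest diagonal subband is ``hh1``."""
    theta = wavelet_analysis(np.zeros(hh1.shape), "db4", 2)
    theta.details[0]["HH"] = hh1
    return theta


class TestThreshold:
    def test_zero_subband_gives_zero(self):
        assert estimate_threshold(_coeffs_with_hh1(np.zeros((16, 16)))) == 0.0

    def test_mad_estimator_recovers_gaussian_sigma(self, rng):
        hh1 = rng.standard_normal((256, 256))
        B = estimate_threshold(_coeffs_with_hh1(hh1), k_sigma=3.0)
        assert B == pytest.approx(3.0, rel=0.05)

    def test_homogeneity(self, rng):
        hh1 = rng.standard_normal((32, 32))
        B1 = estimate_threshold(_coeffs_with_hh1(hh1))
        B2 = estimate_threshold(_coeffs_with_hh1(2.5 * hh1))
        assert B2 == pytest.approx(2.5 * B1, rel=1e-12)


class TestScale:
    def test_mean_excess_of_two_points(self):
        B = 1.5
        assert estimate_scale(np.array([B + 1, B + 3]), B) == pytest.approx(2.0)

    def test_fallback_when_all_below_threshold(self):
        vals = np.array([0.5, 1.0, 1.5])
        assert estimate_scale(vals, 10.0) == pytest.approx(vals.mean())

    def test_consistency_on_laplacian_excesses(self, rng):
        B = 2.0
        excess = rng.exponential(scale=2.0, size=100_000)
        b = estimate_scale(B + excess, B)
        assert b == pytest.approx(2.0, rel=0.05)

    def test_positive_floor(self):
        assert estimate_scale(np.zeros(10), 0.0) > 0


class TestInitSupport:
    def test_all_zero_coefficients_are_insignificant(self):
        theta = wavelet_analysis(np.zeros((16, 16)), "db4", 2)
        supp = init_support(theta, threshold_B=0.5)
        assert all(np.all(s.labels == -1) for s in supp.values())

    def test_boundary_is_significant(self):
        assert threshold_labels(np.array([2.0]), 2.0)[0] == 1

    def test_counts_match_direct_thresholding(self, rng):
        x = rng.standard_normal((32, 32))
        theta = wavelet_analysis(x, "db4", 2)
        B = 0.3
        supp = init_support(theta, B)
        for s, o, band in theta.detail_subbands():
            assert (supp[(s, o)].labels == 1).sum() == (np.abs(band) >= B).sum()


class TestEnergy:
    def test_bias_only_energy(self):
        s = SupportField(-np.ones((4, 5), dtype=int))
        p = MRFParams(alpha=1.0, beta_h=0, beta_v=0, beta_d1=0, beta_d2=0)
        assert mrf_energy(s, p) == -20.0

    def test_2x2_ferromagnetic_clique_count(self):
        s = SupportField(np.ones((2, 2), dtype=int))
        p = MRFParams(alpha=0.0, beta_h=1, beta_v=1, beta_d1=1, beta_d2=1)
        # 2 horizontal + 2 vertical + 1 of each diagonal pair, each -1
        assert mrf_energy(s, p) == -6.0

    def test_single_flip_changes_bias_term_by_2alpha(self):
        labels = -np.ones((3, 3), dtype=int)
        p = MRFParams(alpha=0.7, beta_h=0, beta_v=0, beta_d1=0, beta_d2=0)
        e0 = mrf_energy(SupportField(labels), p)
        labels[1, 1] = 1
        assert mrf_energy(SupportField(labels), p) - e0 == pytest.approx(1.4)


def _enumerate_min_energy(theta, lap, params, gamma):
    """Independent exhaustive MAP oracle over all label configurations."""
    n = theta.size
    best = np.inf
    a = np.abs(theta).ravel()
    agree_cost = a / lap.scale_b
    for bits in itertools.product([-1, 1], repeat=n):
        s = np.array(bits).reshape(theta.shape)
        consistent = (s.ravel() == np.where(a >= lap.threshold_B, 1, -1))
        d = np.where(consistent, agree_cost, gamma).sum()
        e = d + mrf_energy(SupportField(s), params)
        best = min(best, e)
    return best


class TestMapSupport:
    def test_no_interaction_large_gamma_returns_thresholding(self, rng):
        theta = rng.standard_normal((6, 6)) * 3
        lap = LaplacianParams(threshold_B=2.0, scale_b=1.0)
        p = MRFParams(alpha=0.0, beta_h=0, beta_v=0, beta_d1=0, beta_d2=0)
        s, _ = map_support(theta, lap, p, n_sweeps=5, seed=0, gamma=1e6)
        assert np.array_equal(s.labels, threshold_labels(theta, 2.0))

    def test_strong_negative_bias_forces_insignificant(self, rng):
        theta = rng.standard_normal((5, 5))
        lap = LaplacianParams(threshold_B=0.5, scale_b=1.0)
        p = MRFParams(alpha=8.0, beta_h=0.1, beta_v=0.1, beta_d1=0.1,
                      beta_d2=0.1)
        s, _ = map_support(theta, lap, p, n_sweeps=30, seed=0, gamma=0.01)
        assert np.all(s.labels == -1)

    def test_energy_not_above_init_and_matches_enumeration(self, rng):
        for trial in range(5):
            theta = rng.standard_normal((3, 3)) * 2
            lap = LaplacianParams(threshold_B=1.0, scale_b=1.5)
            p = MRFParams(rng.uniform(0, 0.5),
                          *rng.uniform(0, 1, size=4).tolist())
            gamma = rng.uniform(0.5, 3.0)
            s0 = SupportField(threshold_labels(theta, 1.0))
            e_init = posterior_energy(s0, theta, lap, p, gamma)
            s, e = map_support(theta, lap, p, s0, n_sweeps=300,
                               seed=trial, gamma=gamma)
            assert e <= e_init + 1e-9
            assert e == pytest.approx(
                posterior_energy(s, theta, lap, p, gamma), abs=1e-9)
            assert e == pytest.approx(
                _enumerate_min_energy(theta, lap, p, gamma), abs=1e-9)

    def test_seed_reproducibility(self, rng):
        theta = rng.standard_normal((8, 8))
        lap = LaplacianParams(threshold_B=0.8, scale_b=1.0)
        p = MRFParams(alpha=0.2, beta_h=0.5, beta_v=0.5, beta_d1=0.3,
                      beta_d2=0.3)
        a, ea = map_support(theta, lap, p, n_sweeps=10, seed=5, gamma=2.0)
        b, eb = map_support(theta, lap, p, n_sweeps=10, seed=5, gamma=2.0)
        assert np.array_equal(a.labels, b.labels) and ea == eb

    def test_invalid_sweeps(self):
        lap = LaplacianParams(threshold_B=1.0, scale_b=1.0)
        with pytest.raises(ValueError):
            map_support(np.ones((3, 3)), lap, MRFParams(), n_sweeps=0)


class TestParamEstimation:
    def test_constant_field_betas_and_alpha(self):
        theta = np.full((64, 64), 3.0)
        s = SupportField(np.ones((64, 64), dtype=int))
        p = estimate_mrf_params(theta, s)
        assert p.alpha == 1.0
        for b in p.betas:
            assert b == pytest.approx(0.5, abs=0.01)
        assert np.linalg.norm(p.betas) == pytest.approx(1.0, rel=1e-12)

    def test_row_structured_field_maximizes_beta_h(self):
        theta = np.zeros((16, 16))
        theta[8, :] = 5.0
        s = SupportField(threshold_labels(theta, 1.0))
        p = estimate_mrf_params(theta, s)
        assert p.beta_h > max(p.beta_v, p.beta_d1, p.beta_d2)

    def test_single_significant_coefficient_degenerates(self):
        theta = np.zeros((8, 8))
        theta[3, 3] = 2.0
        s = SupportField(threshold_labels(theta, 1.0))
        p = estimate_mrf_params(theta, s)
        assert p.betas == (0.5, 0.5, 0.5, 0.5)
        assert p.alpha == pytest.approx(1 / 64)

    def test_all_insignificant_defaults(self):
        p = estimate_mrf_params(np.ones((8, 8)),
                                SupportField(-np.ones((8, 8), dtype=int)))
        assert p.alpha == 0.0 and p.betas == (0.5, 0.5, 0.5, 0.5)

    def test_unit_norm_and_alpha_bounds_on_random_fields(self, rng):
        for _ in range(20):
            theta = rng.standard_normal((12, 12)) * rng.uniform(0.5, 10)
            s = SupportField(threshold_labels(theta, rng.uniform(0, 2)))
            p = estimate_mrf_params(theta, s)
            if np.any(s.labels == 1):
                assert np.linalg.norm(p.betas) == pytest.approx(1.0, rel=1e-9)
                N = theta.size
                assert 1 / N - 1e-12 <= p.alpha <= 1 + 1e-12

    def test_directional_consistency_on_anisotropic_ising_samples(self):
        # Gibbs-sample supports from a ferromagnetic Ising prior with
        # beta_h > beta_v, then check the estimator ranks them the same way.
        bh, bv, bd = 0.9, 0.1, 0.05
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 24
            s = rng.choice([-1, 1], size=(n, n))
            for _ in range(40):
                for i in range(n):
                    for j in range(n):
                        h = 0.0
                        if j > 0:
                            h += bh * s[i, j - 1]
                        if j < n - 1:
                            h += bh * s[i, j + 1]
                        if i > 0:
                            h += bv * s[i - 1, j]
                        if i < n - 1:
                            h += bv * s[i + 1, j]
                        for di, dj in ((-1, -1), (-1, 1), (1, -1), (1, 1)):
                            if 0 <= i + di < n and 0 <= j + dj < n:
                                h += bd * s[i + di, j + dj]
                        prob_up = 1.0 / (1.0 + np.exp(-2.0 * h))
                        s[i, j] = 1 if rng.random() < prob_up else -1
            theta = np.where(s == 1, 3.0, 0.0) + 0.1 * rng.standard_normal((n, n))
            p = estimate_mrf_params(theta, SupportField(s))
            hits += p.beta_h > p.beta_v
        assert hits >= 9
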