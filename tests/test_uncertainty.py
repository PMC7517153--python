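"""MLPB resampling, BootCI bands, Fisher-z intervals, pointwise tests."""

import numpy as np
import pytest

from dyncorr import BivariateSeries, CorrelationPath, fisher_z_ci, mlpb_resample
from dyncorr.simulate import replicate_rngs
from dyncorr.uncertainty import (
    BootCIConfig,
    CorrelationBand,
    MLPBConfig,
    MLPBSampler,
    _block_bounds,
    boot_ci,
    boot_paths,
    disjoint,
    gamma_jp,
    pointwise_significance,
    sample_autocov,
)


def ar1_pair(T, rng, phi=0.5, cross=0.6):
    e = rng.standard_normal((2, T + 50))
    x = np.copy(e)
    for t in range(1, T + 50):
        x[:, t] = phi * x[:, t - 1] + e[:, t]
    y2 = cross * x[0] + np.sqrt(1 - cross**2) * x[1]
    return BivariateSeries(x[0, 50:] + 1.5, y2[50:] - 0.7)


class TestSampleAutocov:
    def test_lag_zero_diagonal_is_variance(self, rng):
        s = BivariateSeries(*rng.standard_normal((2, 500)))
        C0 = sample_autocov(s, 0)
        assert C0[0, 0] == pytest.approx(np.var(s.y1))
        assert C0[1, 1] == pytest.approx(np.var(s.y2))

    def test_white_noise_lag_one_near_zero(self, rng):
        s = BivariateSeries(*rng.standard_normal((2, 4000)))
        assert np.all(np.abs(sample_autocov(s, 1)) < 3 / np.sqrt(4000))

    def test_negative_lag_is_transpose(self, rng):
        s = ar1_pair(200, rng)
        for h in (1, 3, 7):
            assert np.allclose(sample_autocov(s, -h), sample_autocov(s, h).T)

    def test_lag_bound(self, rng):
        s = BivariateSeries(*rng.standard_normal((2, 10)))
        with pytest.raises(ValueError):
            sample_autocov(s, 10)


class TestGammaJP:
    def test_trapezoid_zeroes_far_blocks(self, rng):
        s = BivariateSeries(*rng.standard_normal((2, 60)))
        G = gamma_jp(s)
        T = 60
        # series layout: entry (0, j) within series-1 block is lag-j cov
        assert np.all(G[0, 2:T] == 0)
        assert G[0, 1] != 0

    def test_symmetric(self, rng):
        s = ar1_pair(80, rng)
        G = gamma_jp(s)
        assert np.allclose(G, G.T)

    def test_iid_pair_near_block_diagonal(self, rng):
        s = BivariateSeries(*rng.standard_normal((2, 2000)))
        G = gamma_jp(s)
        T = 2000
        # off lag-0 blocks are O(1/sqrt(T)); diagonal is O(1)
        assert abs(G[0, 1]) < 0.1 and abs(G[0, 0] - 1) < 0.1

    def test_interleaved_layout_permutes_to_series_layout(self, rng):
        s = BivariateSeries(*rng.standard_normal((2, 50)))
        g_i = gamma_jp(s, layout="interleaved")
        g_s = gamma_jp(s, layout="series")
        perm = np.concatenate([2 * np.arange(50), 2 * np.arange(50) + 1])
        assert np.array_equal(g_i[np.ix_(perm, perm)], g_s)

    def test_positive_definite_after_repair(self, rng):
        # strongly autocorrelated short series force the repair path
        s = ar1_pair(40, rng, phi=0.9)
        G = gamma_jp(s)
        assert np.all(np.linalg.eigvalsh(G) > 0)

    def test_taper_must_keep_diagonal(self):
        with pytest.raises(ValueError, match="kappa"):
            MLPBConfig(taper=lambda h: 0.5).taper_fn()


class TestMLPB:
    def test_fixed_seed_reproducible(self, rng):
        s = ar1_pair(100, rng)
        b1 = mlpb_resample(s, seed=7)
        b2 = mlpb_resample(s, seed=7)
        assert np.array_equal(b1.y1, b2.y1)

    def test_means_restored_on_average(self, rng):
        s = ar1_pair(120, rng)
        sampler = MLPBSampler(s)
        m1 = np.mean([sampler.resample(rng).y1.mean() for _ in range(400)])
        m2 = np.mean([sampler.resample(rng).y2.mean() for _ in range(400)])
        assert m1 == pytest.approx(s.y1.mean(), abs=0.15)
        assert m2 == pytest.approx(s.y2.mean(), abs=0.15)

    def test_covariance_preserved_within_taper_band(self, rng):
        s = ar1_pair(150, rng)
        sampler = MLPBSampler(s)
        c0s, c1s = [], []
        for _ in range(400):
            b = sampler.resample(rng)
            c0s.append(sample_autocov(b, 0))
            c1s.append(sample_autocov(b, 1))
        assert np.allclose(np.mean(c0s, axis=0), sample_autocov(s, 0), atol=0.12)
        assert np.allclose(np.mean(c1s, axis=0), sample_autocov(s, 1), atol=0.12)

    def test_flat_taper_keeps_every_lag(self, rng):
        """kappa = 1 on all lags reduces to re-coloring with the full
        (untruncated) sample covariance: every lag block is C(h)."""
        s = BivariateSeries(*rng.standard_normal((2, 40)))
        G = gamma_jp(s, MLPBConfig(taper="flat"))
        T = 40
        for h in (2, 5, 17):
            assert G[0, h] == pytest.approx(sample_autocov(s, h)[0, 0])


class TestBootCI:
    def test_block_bounds_absorb_remainder(self):
        assert _block_bounds(10, 3) == [(0, 3), (3, 6), (6, 10)]
        assert _block_bounds(10, 1) == [(0, 10)]

    def test_lower_below_upper_everywhere(self, rng):
        s = ar1_pair(120, rng)
        band = boot_ci(s, ws=15, boot=BootCIConfig(B=50), seed=1)
        assert np.all(band.lower <= band.upper)
        assert band.start == 15

    def test_band_width_grows_with_level(self, rng):
        """A 99% band is wider than a 90% band on the same bootstrap draws."""
        s = ar1_pair(200, rng)
        wide = boot_ci(s, ws=15, boot=BootCIConfig(B=60, level=0.99), seed=2)
        narrow = boot_ci(s, ws=15, boot=BootCIConfig(B=60, level=0.90), seed=2)
        assert np.median(wide.upper - wide.lower) > np.median(
            narrow.upper - narrow.lower
        )
        assert np.all(wide.lower <= narrow.lower + 1e-12)
        assert np.all(wide.upper >= narrow.upper - 1e-12)

    def test_needs_two_replicates(self, rng):
        s = ar1_pair(100, rng)
        with pytest.raises(ValueError, match="B = 2"):
            boot_paths(s, boot=BootCIConfig(B=1))


class TestFisherZ:
    def test_closed_form_at_zero(self):
        path = CorrelationPath(1, np.zeros(5))
        band = fisher_z_ci(path, T=403)
        expect = np.tanh(1.959963984540054 / 20.0)
        assert band.upper[0] == pytest.approx(expect, abs=1e-6)
        assert band.lower[0] == pytest.approx(-expect, abs=1e-6)
        assert band.upper[0] == pytest.approx(0.0977, abs=5e-4)

    def test_limit_at_one_stays_proper(self):
        path = CorrelationPath(1, np.array([1.0]))
        band = fisher_z_ci(path, T=100)
        assert band.lower[0] < 1.0 and band.upper[0] <= 1.0
        assert band.upper[0] > 0.999

    def test_asymmetric_in_rho_space(self):
        band = fisher_z_ci(CorrelationPath(1, np.array([0.6])), T=100)
        assert (band.upper[0] - 0.6) < (0.6 - band.lower[0])

    def test_monotone_in_rho(self):
        band = fisher_z_ci(CorrelationPath(1, np.array([0.1, 0.5])), T=50)
        assert band.lower[1] > band.lower[0] and band.upper[1] > band.upper[0]

    def test_interval_contains_estimate(self, rng):
        rho = rng.uniform(-0.95, 0.95, 20)
        band = fisher_z_ci(CorrelationPath(1, rho), T=200)
        assert np.all((band.lower <= rho) & (rho <= band.upper))


class TestPointwiseSignificance:
    def test_disjointness_convention(self):
        a = CorrelationBand(1, np.array([0.1]), np.array([0.3]))
        b = CorrelationBand(1, np.array([0.31]), np.array([0.5]))
        c = CorrelationBand(1, np.array([0.3]), np.array([0.5]))
        assert disjoint(a, b)[0]
        assert not disjoint(a, c)[0]  # touching counts as overlap

    def test_null_rarely_flagged_strong_signal_mostly_flagged(self):
        null_fracs, alt_fracs = [], []
        for rep_rng in replicate_rngs(66, 3):
            z = rep_rng.standard_normal((2, 200))
            flags = pointwise_significance(
                BivariateSeries(z[0], z[1]), boot=BootCIConfig(B=50), seed=rep_rng
            )
            null_fracs.append(flags.mean())
            z = rep_rng.standard_normal((2, 200))
            s = BivariateSeries(z[0], 0.9 * z[0] + np.sqrt(0.19) * z[1])
            flags = pointwise_significance(s, boot=BootCIConfig(B=50), seed=rep_rng)
            alt_fracs.append(flags.mean())
        assert np.mean(null_fracs) <= 0.05
        assert np.mean(alt_fracs) > 0.5
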