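import numpy as np
import pytest

from slowwave import coherence as coh
from slowwave.coherence import (
    adaptive_estimate,
    cmd,
    coherence_matrices,
    cross_spectral_matrix,
    default_bands,
    filterbank,
    fisher_z,
    fit_exponential,
    functional_connectivity,
    inverse_fisher_z,
    msc_from_csm,
    parcel_signals,
    resonator_coefficients,
    CoherenceLandscape,
)
from slowwave.fixtures import synthetic_coherence_field

FS = 200.0


class TestParcelSignals:
    @pytest.fixture(scope="class")
    def mesh(self):
        from slowwave.mesh import assign_hierarchy, assign_parcels, build_icosphere

        m = build_icosphere(1, medial_wall_fraction=0.0)
        m = assign_parcels(m, 6, seed=0)
        return assign_hierarchy(m)

    def test_snr_controls_noise_variance(self, mesh, rng):
        x = rng.standard_normal((20000, 6)) + np.sin(np.arange(20000) * 0.05)[:, None]
        out = parcel_signals(x, FS, mesh, snr=5.0, seed=0)
        noise = out.signals - x.T
        ratio = x.T.var(axis=1) / noise.var(axis=1)
        assert np.allclose(ratio, 5.0, rtol=0.05)

    def test_infinite_snr_is_noiseless(self, mesh, rng):
        x = rng.standard_normal((1000, 6))
        out = parcel_signals(x, FS, mesh, snr=None)
        assert np.array_equal(out.signals, x.T)

    def test_same_seed_same_noise(self, mesh, rng):
        x = rng.standard_normal((1000, 6))
        a = parcel_signals(x, FS, mesh, snr=5.0, seed=3).signals
        b = parcel_signals(x, FS, mesh, snr=5.0, seed=3).signals
        assert np.array_equal(a, b)


class TestFilterbank:
    def test_unity_gain_at_peak(self):
        from scipy.signal import freqz

        b, a = resonator_coefficients(2.0, 0.5, FS)
        w, h = freqz(b, a, worN=[2.0], fs=FS)
        assert 10 * np.log10(np.abs(h[0]) ** 2) > -3.0

    def test_attenuation_off_band(self):
        from scipy.signal import freqz

        b, a = resonator_coefficients(2.0, 0.5, FS)
        w, h = freqz(b, a, worN=[3.0], fs=FS)  # two bandwidths away
        assert 20 * np.log10(np.abs(h[0])) < -3.0

    def test_zero_in_zero_out(self):
        out = filterbank(np.zeros((3, 500)), FS, default_bands(1.0, 3.0, 1.0))
        assert np.all(out == 0)

    def test_invalid_bands_rejected(self):
        with pytest.raises(ValueError):
            resonator_coefficients(2.0, 0.0, FS)
        with pytest.raises(ValueError):
            resonator_coefficients(150.0, 1.0, FS)


class TestMsc:
    def test_identical_channels_fully_coherent(self, rng):
        x = rng.standard_normal(5000)
        csm = cross_spectral_matrix(np.vstack([x, x]))
        msc = msc_from_csm(csm)
        assert msc[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_near_zero(self, rng):
        x = rng.standard_normal((2, 100000))
        msc = msc_from_csm(cross_spectral_matrix(x))
        assert msc[0, 1] < 0.05

    def test_phase_shift_invisible_to_coherence(self, rng):
        t = np.arange(20000) / FS
        a = np.sin(2 * np.pi * 3 * t) + 0.01 * rng.standard_normal(len(t))
        b = np.sin(2 * np.pi * 3 * t + np.pi / 2) + 0.01 * rng.standard_normal(len(t))
        msc = msc_from_csm(cross_spectral_matrix(np.vstack([a, b])))
        assert msc[0, 1] > 0.99

    def test_matrix_symmetric_unit_diagonal_bounded(self, rng):
        x = rng.standard_normal((5, 4000))
        msc = msc_from_csm(cross_spectral_matrix(x))
        assert np.allclose(msc, msc.T)
        assert np.allclose(np.diag(msc), 1.0)
        assert np.nanmin(msc) >= 0.0 and np.nanmax(msc) <= 1.0

    def test_zero_variance_channel_flagged(self):
        x = np.vstack([np.zeros(1000), np.random.default_rng(0).standard_normal(1000)])
        msc = msc_from_csm(cross_spectral_matrix(x))
        assert np.isnan(msc[0, 1])


class TestFisherZ:
    def test_round_trip(self, rng):
        c = rng.uniform(0, 0.999, 100)
        assert np.allclose(inverse_fisher_z(fisher_z(c)), c, atol=1e-12)


class TestExponentialFit:
    def _landscape(self, lam, alpha, n=40, seed=0, noise=0.02):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 90, (n, 2))
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        c = np.clip(alpha * np.exp(-d / lam) * np.exp(rng.normal(0, noise, d.shape)), 1e-6, 1)
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        return CoherenceLandscape(freqs_hz=np.array([0.5]), coherence=c[None],
                                  distance_mm=d)

    def test_planted_parameter_recovery(self):
        land = fit_exponential(self._landscape(25.0, 0.8))
        assert 22.0 <= land.lambda_mm[0] <= 28.0
        assert 0.75 <= land.alpha[0] <= 0.85

    def test_distance_scaling_property(self):
        land = self._landscape(20.0, 0.6, noise=0.0)
        fit1 = fit_exponential(land).lambda_mm[0]
        land2 = CoherenceLandscape(freqs_hz=land.freqs_hz, coherence=land.coherence,
                                   distance_mm=land.distance_mm * 2)
        fit2 = fit_exponential(land2, domain_mm=(0, 200)).lambda_mm[0]
        assert fit2 == pytest.approx(2 * fit1, rel=1e-6)

    def test_flat_landscape_gives_infinite_length_constant(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 90, (30, 30))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        c = np.full((30, 30), 0.5)
        np.fill_diagonal(c, 1.0)
        land = CoherenceLandscape(freqs_hz=np.array([0.5]), coherence=c[None],
                                  distance_mm=d)
        land = fit_exponential(land)
        assert np.isinf(land.lambda_mm[0])

    def test_too_few_pairs_rejected(self):
        land = self._landscape(25.0, 0.8, n=4)
        with pytest.raises(ValueError):
            fit_exponential(land)

    def test_end_to_end_recovery_through_signal_pipeline(self):
        """Planted coherence field -> filterbank -> MSC -> fit, within 10%."""
        signals, d, fs = synthetic_coherence_field(lambda_mm=25.0, alpha=0.8,
                                                   seed=2, duration_s=400.0)
        sig = coh.ParcelSignalSet(signals=signals, fs_hz=fs, distance_mm=d, snr=None)
        bands = default_bands(1.0, 2.0, 1.0)
        land = coherence_matrices(sig, bands)
        land = fit_exponential(land)
        assert land.lambda_mm[0] == pytest.approx(25.0, rel=0.10)
        assert land.alpha[0] == pytest.approx(0.8, rel=0.10)


class TestFunctionalConnectivity:
    def _uniform_landscape(self, value, n=12):
        c = np.full((n, n), value, dtype=float)
        np.fill_diagonal(c, 1.0)
        d = np.ones((n, n))
        np.fill_diagonal(d, 0)
        return CoherenceLandscape(freqs_hz=np.array([0.5, 1.0]),
                                  coherence=np.stack([c, c]), distance_mm=d)

    def test_all_ones_fully_connected_one_community(self):
        land = self._uniform_landscape(0.999)
        pct, ncomm = functional_connectivity(land, threshold=0.5)
        assert pct == pytest.approx(100.0)
        assert ncomm == 1

    def test_two_blocks_two_communities(self):
        n = 12
        c = np.full((n, n), 0.01)
        c[:6, :6] = 0.9
        c[6:, 6:] = 0.9
        np.fill_diagonal(c, 1.0)
        land = CoherenceLandscape(freqs_hz=np.array([0.5]), coherence=c[None],
                                  distance_mm=np.ones((n, n)))
        pct, ncomm = functional_connectivity(land, threshold=0.5)
        assert ncomm == 2

    def test_percent_connected_monotone_in_threshold(self, rng):
        n = 15
        c = rng.uniform(0, 1, (n, n))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        land = CoherenceLandscape(freqs_hz=np.array([0.5]), coherence=c[None],
                                  distance_mm=np.ones((n, n)))
        pcts = [functional_connectivity(land, threshold=t)[0] for t in (0.2, 0.5, 0.8)]
        assert pcts == sorted(pcts, reverse=True)

    def test_empty_graph_counts_every_parcel_as_community(self):
        land = self._uniform_landscape(0.0)
        pct, ncomm = functional_connectivity(land, threshold=0.5)
        assert pct == 0.0
        assert ncomm == 12


class TestCmd:
    def test_self_distance_zero(self, rng):
        a = rng.standard_normal((6, 6))
        a = a @ a.T
        assert cmd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_identity_vs_all_ones_closed_form(self):
        n = 9
        assert cmd(np.eye(n), np.ones((n, n))) == pytest.approx(1 - 1 / np.sqrt(n))

    def test_symmetric_in_arguments(self, rng):
        a = rng.standard_normal((5, 5)); a = a @ a.T
        b = rng.standard_normal((5, 5)); b = b @ b.T
        assert cmd(a, b) == pytest.approx(cmd(b, a), abs=1e-12)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            cmd(np.zeros((3, 3)), np.eye(3))


class TestAdaptiveEstimate:
    BANDS = default_bands(1.0, 2.0, 1.0)

    def _stationary_source(self, seed=0, n_ch=6):
        rng_master = np.random.default_rng(seed)
        chol = np.linalg.cholesky(0.5 * np.eye(n_ch) + 0.5)

        def source(rng):
            n = int(60 * FS + 2 * 1.5 * FS)
            return chol @ rng.standard_normal((n_ch, n))

        return source

    def test_converges_to_long_run_oracle(self):
        source = self._stationary_source()
        res = adaptive_estimate(source, FS, self.BANDS, seed=1, n_repeats=2,
                                cmd_tol=3e-5, max_minutes=60)
        # oracle: one very long stationary record (half an hour)
        rng = np.random.default_rng(99)
        src = self._stationary_source()
        big = np.hstack([src(rng) for _ in range(30)])
        narrow = filterbank(big, FS, self.BANDS)
        from scipy.signal import hilbert

        z = hilbert(narrow, axis=-1)
        z = z - z.mean(axis=-1, keepdims=True)
        oracle = np.stack([msc_from_csm((z[i] @ z[i].conj().T) / z.shape[-1])
                           for i in range(len(self.BANDS))])
        iu = np.triu_indices(6, 1)
        # both estimate the same population landscape (pairwise MSC 0.25);
        # residual scatter reflects the finite effective bandwidth per minute
        assert np.allclose(res.coherence[:, iu[0], iu[1]],
                           oracle[:, iu[0], iu[1]], atol=0.05)
        assert abs(np.mean(res.coherence[:, iu[0], iu[1]]) - 0.25) < 0.03

    def test_outlier_minute_rejected(self):
        calls = {"n": 0}
        base = self._stationary_source()

        def source(rng):
            calls["n"] += 1
            if calls["n"] == 5:
                # gross outlier: uncorrelated massive noise
                n = int(60 * FS + 3 * FS)
                return 100.0 * rng.standard_normal((6, n))
            return base(rng)

        res = adaptive_estimate(source, FS, self.BANDS, seed=2, n_repeats=1,
                                cmd_tol=1e-6, max_minutes=12)
        # the population MSC of the stationary source is 0.25 (rho = 0.5).
        # If the 100x-power uncorrelated outlier entered the cumulative
        # estimate it would drag the coherence towards zero; rejection keeps
        # it near the stationary value.
        iu = np.triu_indices(6, 1)
        assert abs(np.nanmean(res.coherence[:, iu[0], iu[1]]) - 0.25) < 0.08

    def test_deterministic_under_seed(self):
        a = adaptive_estimate(self._stationary_source(), FS, self.BANDS, seed=5,
                              n_repeats=1, cmd_tol=1e-4, max_minutes=10)
        b = adaptive_estimate(self._stationary_source(), FS, self.BANDS, seed=5,
                              n_repeats=1, cmd_tol=1e-4, max_minutes=10)
        assert np.array_equal(a.csm, b.csm)
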