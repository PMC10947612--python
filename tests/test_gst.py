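"""Generalized S-transform and slant f-k estimator against independent oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

import swdisp as sw
from swdisp.errors import DomainError, NoSignalError
from swdisp.gst_dispersion import _window_matrix


def stransform_double_loop(signal, dt, freqs, beta):
    """Literal discretization of the transform: a per-sample double sum."""
    n = signal.size
    t = dt * np.arange(n)
    S = np.zeros((n, len(freqs)), complex)
    for j in range(n):
        for i, f in enumerate(freqs):
            acc = 0.0
            for l in range(n):
                w = f / np.sqrt(2 * np.pi * beta) * np.exp(-(f**2) * (t[j] - t[l]) ** 2 / (2 * beta))
                acc += signal[l] * w * np.exp(-2j * np.pi * f * t[l]) * dt
            S[j, i] = acc
    return S


class TestGeneralizedStransform:
    def test_zero_signal_gives_zero_map(self):
        tm = sw.generalized_stransform(np.zeros(32), 1e-3, np.array([100.0]))
        assert np.allclose(tm.S, 0.0)

    def test_linearity_in_the_signal(self, rng):
        sig = rng.normal(size=48)
        f = np.array([150.0, 300.0])
        a = 2.75
        S1 = sw.generalized_stransform(a * sig, 1e-3, f).S
        S2 = a * sw.generalized_stransform(sig, 1e-3, f).S
        np.testing.assert_allclose(S1, S2, rtol=1e-12)

    @pytest.mark.parametrize("beta", [1.0, 3.0])
    def test_matches_double_loop_oracle(self, rng, beta):
        sig = rng.normal(size=64)
        dt = 1 / 4000
        freqs = np.array([200.0, 500.0, 1100.0])
        fast = sw.generalized_stransform(sig, dt, freqs, beta=beta).S
        slow = stransform_double_loop(sig, dt, freqs, beta)
        assert np.max(np.abs(fast - slow)) / np.max(np.abs(slow)) <= 1e-8

    def test_tone_matches_continuous_quadrature(self):
        # unit tone at 300 Hz, long record: |S| at the midpoint equals the
        # numerically integrated continuous transform
        f0, dt, n = 300.0, 1 / 4000, 512
        t = dt * np.arange(n)
        sig = np.cos(2 * np.pi * f0 * t)
        tm = sw.generalized_stransform(sig, dt, np.array([f0]), beta=1.0)
        tau = t[n // 2]

        def windowed(s):
            return np.cos(2 * np.pi * f0 * s) * f0 / np.sqrt(2 * np.pi) * np.exp(
                -(f0**2) * (tau - s) ** 2 / 2
            )

        re = quad(lambda s: windowed(s) * np.cos(2 * np.pi * f0 * s), 0, n * dt, limit=400)[0]
        im = quad(lambda s: windowed(s) * -np.sin(2 * np.pi * f0 * s), 0, n * dt, limit=400)[0]
        oracle = abs(re + 1j * im)
        assert abs(abs(tm.S[n // 2, 0]) - oracle) / oracle <= 1e-3

    def test_window_has_unit_area(self):
        # discrete window sums (x dt) to 1 when the record spans >= 8 sigma
        dt, n, beta = 1 / 4000, 256, 1.0
        t = dt * np.arange(n)
        for f in (300.0, 700.0, 1500.0):
            assert n * dt >= 8 * np.sqrt(beta) / f
            G = _window_matrix(t, f, beta)
            mid = G[n // 2] * dt
            assert abs(mid.sum() - 1.0) <= 1e-3

    def test_zero_frequency_rejected(self):
        with pytest.raises(DomainError):
            sw.generalized_stransform(np.ones(32), 1e-3, np.array([0.0]))

    def test_above_nyquist_rejected(self):
        with pytest.raises(DomainError):
            sw.generalized_stransform(np.ones(32), 1e-3, np.array([600.0]))


class TestTimeDistanceMap:
    def _cfg(self, field):
        return sw.GSTConfig(freqs=np.array([250.0, 500.0]),
                            wavenumbers=np.linspace(10, 500, 30))

    def test_single_nonzero_row_stays_on_that_row(self):
        v = np.zeros((8, 32))
        v[3] = np.sin(2 * np.pi * 250.0 * np.arange(32) / 4000)
        fld = sw.WaveField(v=v, dx=1e-3, dt=1 / 4000)
        V = sw.build_time_distance_map(fld, 250.0, self._cfg(fld))
        nz = np.abs(V).sum(axis=1)
        assert nz[3] > 0 and np.allclose(np.delete(nz, 3), 0.0)

    def test_equals_per_row_transform(self, rng):
        v = rng.normal(size=(8, 32))
        fld = sw.WaveField(v=v, dx=1e-3, dt=1 / 4000)
        cfg = self._cfg(fld)
        V = sw.build_time_distance_map(fld, 500.0, cfg)
        for row in range(8):
            tm = sw.generalized_stransform(v[row], fld.dt, np.array([500.0]))
            np.testing.assert_allclose(V[row], tm.S[:, 0], rtol=1e-12, atol=1e-15)

    def test_off_grid_frequency_rejected(self, rng):
        fld = sw.WaveField(v=rng.normal(size=(8, 32)), dx=1e-3, dt=1 / 4000)
        with pytest.raises(DomainError):
            sw.build_time_distance_map(fld, 333.0, self._cfg(fld))


class TestSlantPhase:
    def test_tau_independent_map_gives_constant(self, rng):
        nx, nt = 16, 64
        const = rng.normal(size=nx) + 1j * rng.normal(size=nx)
        V = np.repeat(const[:, None], nt, axis=1)
        tau = np.arange(nt) / 4000
        x = 1e-3 * np.arange(nx)
        for u in (0.8, 2.0, 9.0):
            P = sw.slant_phase(V, tau, x, u)
            inside = x / u <= tau[-1]
            np.testing.assert_allclose(P[inside], const[inside], rtol=1e-12)

    def test_spatial_phase_ramp_preserved(self):
        nx, nt, xi0 = 16, 64, 150.0
        x = 1e-3 * np.arange(nx)
        V = np.repeat(np.exp(-2j * np.pi * xi0 * x)[:, None], nt, axis=1)
        tau = np.arange(nt) / 4000
        P = sw.slant_phase(V, tau, x, 2.0)
        inside = x / 2.0 <= tau[-1]
        np.testing.assert_allclose(P[inside], np.exp(-2j * np.pi * xi0 * x)[inside], rtol=1e-12)

    def test_grid_aligned_trajectory_is_exact_indexing(self, rng):
        # u chosen so tau = x/u lands exactly on grid nodes: x_j = j*dx,
        # tau = j*dtau  =>  u = dx/dtau
        nx, nt = 12, 64
        dx, dtau = 1e-3, 1 / 4000
        V = rng.normal(size=(nx, nt)) + 1j * rng.normal(size=(nx, nt))
        tau = dtau * np.arange(nt)
        x = dx * np.arange(nx)
        P = sw.slant_phase(V, tau, x, dx / dtau)
        expected = V[np.arange(nx), np.arange(nx)]
        np.testing.assert_allclose(P, expected, rtol=1e-12)


class TestSlantAmplitude:
    def test_peak_at_the_ramp_wavenumber(self):
        xi0 = 200.0
        x = 0.154e-3 * np.arange(195)
        P = np.exp(-2j * np.pi * xi0 * x)
        k = np.linspace(10, 600, 500)
        amp = sw.slant_amplitude(P, x, k)
        assert abs(k[np.argmax(amp)] - xi0) <= k[1] - k[0]

    def test_scales_linearly(self, rng):
        x = 1e-3 * np.arange(16)
        P = rng.normal(size=16) + 1j * rng.normal(size=16)
        k = np.linspace(5, 300, 40)
        np.testing.assert_allclose(
            sw.slant_amplitude(3.0 * P, x, k), 3.0 * sw.slant_amplitude(P, x, k), rtol=1e-12
        )

    def test_matches_independent_summation_oracle(self, rng):
        x = 1e-3 * np.arange(16)
        P = rng.normal(size=16) + 1j * rng.normal(size=16)
        k = np.linspace(5, 300, 40)
        amp = sw.slant_amplitude(P, x, k)
        # independent route: per-k explicit accumulation
        oracle = np.array(
            [abs(sum(P[j] * np.exp(2j * np.pi * kk * x[j]) for j in range(16)) * 1e-3) for kk in k]
        )
        assert np.max(np.abs(amp - oracle)) / oracle.max() <= 1e-10


class TestSlantFKSpectrum:
    def test_matches_brute_force_triple_loop(self, rng):
        v = rng.normal(size=(16, 64))
        fld = sw.WaveField(v=v, dx=1e-3, dt=1 / 4000)
        cfg = sw.GSTConfig(freqs=np.array([200.0, 400.0, 800.0]),
                           wavenumbers=np.linspace(20, 400, 20),
                           n_velocities=5, u_min=1.0, u_max=5.0)
        spec = sw.slant_fk_spectrum(fld, cfg)
        t, x = fld.t, fld.x - fld.x0
        K = np.zeros_like(spec.K)
        for i, f in enumerate(cfg.freqs):
            G = _window_matrix(t, f, cfg.beta)
            V = (v * np.exp(-2j * np.pi * f * t)[None, :]) @ G.T * fld.dt
            for u in cfg.steering_velocities():
                P = np.zeros(16, complex)
                for j in range(16):
                    pos = x[j] / u / fld.dt
                    if 0 <= pos <= 63:
                        i0 = min(int(np.floor(pos)), 62)
                        fr = pos - i0
                        P[j] = V[j, i0] * (1 - fr) + V[j, i0 + 1] * fr
                for kk, kval in enumerate(cfg.wavenumbers):
                    lam = abs(np.sum(P * np.exp(2j * np.pi * kval * x)) * fld.dx)
                    K[i, kk] = max(K[i, kk], lam)
        assert np.max(np.abs(spec.K - K)) / K.max() <= 1e-9

    def test_single_velocity_equals_that_slant(self, rng):
        v = rng.normal(size=(16, 64))
        fld = sw.WaveField(v=v, dx=1e-3, dt=1 / 4000)
        cfg = sw.GSTConfig(freqs=np.array([300.0]), wavenumbers=np.linspace(20, 400, 25),
                           n_velocities=1, u_min=1.9, u_max=2.1)
        u = cfg.steering_velocities()[0]
        spec = sw.slant_fk_spectrum(fld, cfg)
        V = sw.build_time_distance_map(fld, 300.0, cfg)
        P = sw.slant_phase(V, fld.t, fld.x - fld.x0, u)
        amp = sw.slant_amplitude(P, fld.x - fld.x0, cfg.wavenumbers, dx=fld.dx)
        np.testing.assert_allclose(spec.K[0], amp, rtol=1e-12)

    def test_plane_wave_peak_location(self, plane_wave_field):
        fld, f0, xi = plane_wave_field(nx=96, nt=128, m_f=30, m_k=20)
        cfg = sw.GSTConfig(freqs=np.array([f0]), wavenumbers=np.linspace(100, 1200, 400),
                           u_min=0.5, u_max=6.0)
        spec = sw.slant_fk_spectrum(fld, cfg)
        kpk = spec.k_grid[np.argmax(spec.K[0])]
        assert abs(kpk - xi) <= spec.k_grid[1] - spec.k_grid[0]

    def test_pipeline_is_linear_in_the_field(self, rng):
        v = rng.normal(size=(16, 64))
        fld = sw.WaveField(v=v, dx=1e-3, dt=1 / 4000)
        fld2 = sw.WaveField(v=4.0 * v, dx=1e-3, dt=1 / 4000)
        cfg = sw.GSTConfig(freqs=np.array([250.0, 600.0]),
                           wavenumbers=np.linspace(20, 400, 25), n_velocities=4)
        K1 = sw.slant_fk_spectrum(fld, cfg).K
        K2 = sw.slant_fk_spectrum(fld2, cfg).K
        np.testing.assert_allclose(K2, 4.0 * K1, rtol=1e-10)

    def test_time_shift_covariance(self, nondispersive_field):
        # delaying the field by m samples shifts the time-distance map by m
        # samples in tau (up to a constant phase), and leaves the extracted
        # dispersion velocities essentially unchanged
        fld = nondispersive_field
        m = 4  # ~3% of the record
        shifted = np.zeros_like(fld.v)
        shifted[:, m:] = fld.v[:, :-m]
        fld2 = sw.WaveField(v=shifted, dx=fld.dx, dt=fld.dt)
        cfg = sw.GSTConfig(freqs=np.array([400.0, 800.0]),
                           wavenumbers=np.linspace(50, 700, 200))
        V1 = sw.build_time_distance_map(fld, 400.0, cfg)
        V2 = sw.build_time_distance_map(fld2, 400.0, cfg)
        # interior tau samples only: the Gaussian window tails (sigma = 1/f
        # ~ 10 samples at 400 Hz) cross the record edges and differ there
        g = 40
        diff = np.abs(V2[:, m + g : -g]) - np.abs(V1[:, g : -g - m])
        assert np.max(np.abs(diff)) <= 1e-3 * np.abs(V1).max()
        c1 = sw.extract_curve_gst(sw.slant_fk_spectrum(fld, cfg), 0.0).c
        c2 = sw.extract_curve_gst(sw.slant_fk_spectrum(fld2, cfg), 0.0).c
        assert np.max(np.abs(c2 - c1) / c1) < 0.01


class TestExtractCurve:
    def test_plane_wave_velocity(self, plane_wave_field):
        fld, f0, xi = plane_wave_field(nx=96, nt=128, m_f=30, m_k=20)
        cfg = sw.GSTConfig(freqs=np.array([f0]), wavenumbers=np.linspace(100, 1200, 400))
        curve = sw.extract_curve_gst(sw.slant_fk_spectrum(fld, cfg), min_quality=0.0)
        dk = cfg.wavenumbers[1] - cfg.wavenumbers[0]
        c_tol = f0 / (xi - dk) - f0 / xi
        assert abs(curve.c[0] - f0 / xi) <= c_tol

    def test_nondispersive_recovery(self, nondispersive_field):
        cfg = sw.GSTConfig.for_field(nondispersive_field)
        curve = sw.extract_curve_gst(sw.slant_fk_spectrum(nondispersive_field, cfg),
                                     min_quality=0.0)
        band = (curve.freqs >= 150) & (curve.freqs <= 1500)
        assert np.all(np.isfinite(curve.c[band]))
        assert np.max(np.abs(curve.c[band] - 2.5) / 2.5) < 0.02

    def test_all_zero_spectrum_raises(self):
        spec = sw.SlantSpectrum(K=np.zeros((3, 10)), freq_grid=np.array([1.0, 2.0, 3.0]),
                                k_grid=np.linspace(1, 10, 10))
        with pytest.raises(NoSignalError):
            sw.extract_curve_gst(spec)

    def test_quality_floor_marks_weak_rows_missing(self, rng):
        K = np.zeros((2, 50))
        K[0, 20] = 1.0
        K[1, 30] = 0.01
        spec = sw.SlantSpectrum(K=K, freq_grid=np.array([100.0, 200.0]),
                                k_grid=np.linspace(10, 500, 50))
        curve = sw.extract_curve_gst(spec, min_quality=0.1)
        assert np.isfinite(curve.c[0]) and np.isnan(curve.c[1])
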