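"""Solver unit and property tests: spectral derivatives, stability, source
waveform, running DFT, PML, conservation laws."""

import numpy as np
import pytest
from scipy.signal import hilbert

from octsim.grid import GridSpec, MaterialMap
from octsim.pstd import (
    DivergedSimulationError,
    PSTDSolver,
    SourceSpec,
    SpectralProbe,
    gaussian_envelope_width,
    measure_pml_reflection,
    spectral_derivative,
    stability_limit,
)

from conftest import C, LAMBDA0, make_1d_grid


class TestSpectralDerivative:
    def test_constant_line_gives_zero(self):
        out = spectral_derivative(np.full(64, 3.7), 0.1)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_exact_fourier_mode(self):
        n, dx, m = 128, 0.05, 5
        length = n * dx
        z = np.arange(n) * dx
        f = np.sin(2 * np.pi * m * z / length)
        expected = (2 * np.pi * m / length) * np.cos(2 * np.pi * m * z / length)
        assert np.allclose(spectral_derivative(f, dx), expected, atol=1e-10)

    def test_band_limited_random_matches_high_order_fd(self, rng):
        # oracle: 8th-order central differences on an 8x oversampled copy
        n, dx = 128, 0.1
        spec = np.zeros(n, dtype=complex)
        modes = np.arange(1, n // 8)
        spec[modes] = rng.standard_normal(len(modes)) + 1j * rng.standard_normal(len(modes))
        spec[-modes] = np.conj(spec[modes])
        f = np.fft.ifft(spec).real

        over = 8
        spec_o = np.zeros(n * over, dtype=complex)
        spec_o[modes] = spec[modes] * over
        spec_o[-modes] = spec[-modes] * over
        f_o = np.fft.ifft(spec_o).real
        dxo = dx / over
        w = np.array([-1 / 280, 4 / 105, -1 / 5, 4 / 5, 0, -4 / 5, 1 / 5, -4 / 105, 1 / 280])[::-1]
        d_o = sum(w[j + 4] * np.roll(f_o, -j) for j in range(-4, 5)) / dxo
        oracle = d_o[::over]

        ours = spectral_derivative(f, dx)
        rel = np.sqrt(np.mean((ours - oracle) ** 2) / np.mean(oracle**2))
        assert rel < 1e-6

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            spectral_derivative(np.array([]), 0.1)
        with pytest.raises(ValueError):
            spectral_derivative(np.ones(3), 0.1)
        with pytest.raises(ValueError):
            spectral_derivative(np.ones(16), -1.0)


class TestStabilityLimit:
    def test_closed_form_3d(self):
        g = GridSpec(LAMBDA0 / 6, (8, 8, 8), pml_thickness=0)
        limit = stability_limit(g, 1.0)
        assert limit == pytest.approx(2 * (LAMBDA0 / 6) / (C * np.pi * np.sqrt(3)), rel=1e-12)
        assert limit == pytest.approx(0.2657, abs=5e-4)

    def test_published_time_step_is_stable(self):
        # the reference configuration: dt = 0.252 fs on a lambda0/6 grid
        g = GridSpec(LAMBDA0 / 6, (8, 8, 8), pml_thickness=0)
        assert 0.252 <= stability_limit(g, 1.0)

    def test_dimension_ratio(self):
        g3 = GridSpec(0.2, (8, 8, 8), pml_thickness=0)
        g1 = GridSpec(0.2, (1, 1, 8), pml_thickness=0)
        assert stability_limit(g1, 1.0) == pytest.approx(
            np.sqrt(3) * stability_limit(g3, 1.0), rel=1e-12)


class TestSourceWaveform:
    def test_negligible_at_t0_zero(self):
        src = SourceSpec(4, np.ones((2, 1, 1), dtype=complex), k0=2 * np.pi / LAMBDA0, W=10.0)
        assert src.envelope(0.0) <= 1e-6

    def test_envelope_peak_is_unity(self):
        src = SourceSpec(4, np.ones((2, 1, 1), dtype=complex), k0=2 * np.pi / LAMBDA0, W=10.0)
        assert src.envelope(src.t0) == pytest.approx(1.0)

    def test_band_edges_at_least_ten_percent(self):
        w = gaussian_envelope_width((1180.0, 1420.0), 1300.0)
        src = SourceSpec(4, np.ones((2, 1, 1), dtype=complex), k0=2 * np.pi / LAMBDA0, W=w)
        dt = 0.05
        t = np.arange(0, src.t0 + 6 * w, dt)
        sig = np.cos(src.omega0 * (t - src.t0)) * np.exp(-np.pi * ((t - src.t0) / w) ** 2)
        freq = np.fft.rfftfreq(t.size, d=dt)
        amp = np.abs(np.fft.rfft(sig))
        for lam_nm in (1180.0, 1420.0):
            omega_edge = 2 * np.pi * C / (lam_nm * 1e-3)  # rad/fs
            idx = np.argmin(np.abs(2 * np.pi * freq - omega_edge))
            assert amp[idx] >= 0.1 * amp.max()


def _pulse_peak_um(solver, cell_size):
    env = np.abs(hilbert(solver.E[0, 0, 0, :]))
    i = int(np.argmax(env))
    d = (env[i - 1] - env[i + 1]) / (2 * (env[i - 1] - 2 * env[i] + env[i + 1]))
    return (i + d) * cell_size


def _measure_speed(n_background, dt=0.138, nz=520):
    g, m = make_1d_grid(nz=nz, n=n_background)
    src = SourceSpec(12, np.array([[[1.0]], [[0.0]]], dtype=complex),
                     k0=2 * np.pi / LAMBDA0, W=10.0)
    s = PSTDSolver(g, m, source=src, dt=dt)
    for _ in range(int((src.t0 + 30) / s.dt)):
        s.step()
    t1, p1 = s.t_index * s.dt, _pulse_peak_um(s, g.cell_size)
    for _ in range(int(60 * n_background / s.dt)):
        s.step()
    t2, p2 = s.t_index * s.dt, _pulse_peak_um(s, g.cell_size)
    return (p2 - p1) / (t2 - t1)


class TestPropagation:
    def test_zero_fields_stay_zero(self):
        g, m = make_1d_grid(nz=64)
        s = PSTDSolver(g, m)
        for _ in range(50):
            s.step()
        assert np.all(s.E == 0) and np.all(s.H == 0)

    def test_vacuum_pulse_speed(self):
        v = _measure_speed(1.0)
        assert abs(v - C) / C < 0.01

    def test_silicone_pulse_speed(self):
        v = _measure_speed(1.42)
        assert abs(v - C / 1.42) / (C / 1.42) < 0.01

    def test_unstable_dt_rejected(self):
        g, m = make_1d_grid(nz=64)
        with pytest.raises(ValueError):
            PSTDSolver(g, m, dt=10.0)

    def test_divergence_detected_for_forced_blowup(self):
        g, m = make_1d_grid(nz=64)
        src = SourceSpec(12, np.array([[[1.0]], [[0.0]]], dtype=complex),
                         k0=2 * np.pi / LAMBDA0, W=10.0)
        s = PSTDSolver(g, m, source=src)
        s.dt *= 1.25  # past the limit, bypassing the constructor guard
        with pytest.raises(DivergedSimulationError):
            s.run(4000, check_every=100)


class TestSpectralProbe:
    def test_zero_field_zero_spectrum(self):
        g, m = make_1d_grid(nz=64)
        s = PSTDSolver(g, m)
        probe = SpectralProbe(np.array([4.5, 5.0]), "plane_E", plane_index=20)
        for _ in range(30):
            s.step()
            probe.accumulate(s)
        assert np.all(probe._acc["E"] == 0)

    def test_monochromatic_orthogonality(self):
        # a pure oscillation at omega1 accumulated over full periods gives
        # zero at a different frequency on the period lattice
        k1, n_per = 5.0, 8
        omega1 = C * k1
        period = 2 * np.pi / omega1
        n_steps = 512
        dt = n_per * period / n_steps
        t = (np.arange(n_steps) + 1) * dt
        sig = np.cos(omega1 * t)
        k2 = k1 * 2.0  # on the period lattice: integer cycles too
        acc1 = np.sum(sig * np.exp(1j * omega1 * t)) * dt
        acc2 = np.sum(sig * np.exp(1j * C * k2 * t)) * dt
        assert abs(acc2) < 1e-10 * abs(acc1)

    def test_running_dft_equals_posthoc_fft(self):
        # probe spectrum equals the DFT of the stored time series
        g, m = make_1d_grid(nz=200)
        src = SourceSpec(12, np.array([[[1.0]], [[0.0]]], dtype=complex),
                         k0=2 * np.pi / LAMBDA0, W=8.0)
        s = PSTDSolver(g, m, source=src)
        ks = np.linspace(4.6, 5.1, 5)
        probe = SpectralProbe(ks, "plane_E", plane_index=60)
        n_steps = 400
        series = np.empty(n_steps)
        for i in range(n_steps):
            s.step()
            probe.accumulate(s)
            series[i] = s.E[0, 0, 0, 60]
        t = (np.arange(n_steps) + 1) * s.dt
        posthoc = (series[None, :] * np.exp(1j * C * ks[:, None] * t[None, :])).sum(1) * s.dt
        rel = np.abs(probe._acc["E"][:, 0, 0, 0] - posthoc) / np.abs(posthoc).max()
        assert rel.max() < 1e-10


class TestPML:
    def test_default_pml_reflection_below_bound(self):
        g = GridSpec(LAMBDA0 / 6, (1, 1, 400), pml_thickness=10)
        assert measure_pml_reflection(g) <= 1e-2  # -40 dB power

    def test_no_absorber_wraps_around(self):
        g = GridSpec(LAMBDA0 / 6, (1, 1, 400), pml_thickness=0)
        assert measure_pml_reflection(g) > 0.5

    def test_doubling_thickness_does_not_increase_reflection(self):
        r10 = measure_pml_reflection(GridSpec(LAMBDA0 / 6, (1, 1, 400), pml_thickness=10))
        r20 = measure_pml_reflection(GridSpec(LAMBDA0 / 6, (1, 1, 400), pml_thickness=20))
        assert r20 <= r10 * 1.05


class TestConservationAndSymmetry:
    def _smooth_init(self, solver, seed=0, n=16):
        rng = np.random.default_rng(seed)
        kk = np.fft.fftfreq(n)
        k2 = kk[:, None, None] ** 2 + kk[None, :, None] ** 2 + kk[None, None, :] ** 2
        for c in range(3):
            for a in range(3):
                sub = solver._sub["E"][c][a]
                if sub is not None:
                    f = np.fft.fftn(rng.standard_normal((n, n, n))) * np.exp(-k2 / (2 * 0.15**2))
                    sub[:] = np.real(np.fft.ifftn(f))

    def test_energy_conserved_in_periodic_vacuum(self):
        g = GridSpec(LAMBDA0 / 6, (16, 16, 16), pml_thickness=0)
        s = PSTDSolver(g, MaterialMap.homogeneous(g), track_energy=True)
        self._smooth_init(s)
        s.step()
        e0 = s.discrete_energy()
        drift = 0.0
        for _ in range(1000):
            s.step()
            drift = max(drift, abs(s.discrete_energy() - e0))
        assert drift / e0 < 1e-6

    def test_linearity_of_scattered_fields(self):
        # superposed sources give the superposed field
        def run(amplitude_x, amplitude_y):
            g, m = make_1d_grid(nz=128)
            e = np.array([[[amplitude_x]], [[amplitude_y]]], dtype=complex)
            src = SourceSpec(12, e, k0=2 * np.pi / LAMBDA0, W=8.0)
            s = PSTDSolver(g, m, source=src)
            for _ in range(200):
                s.step()
            return s.E.copy()

        ea = run(1.0, 0.0)
        eb = run(0.0, 0.7)
        eab = run(1.0, 0.7)
        assert np.abs(eab - (ea + eb)).max() < 1e-10 * np.abs(eab).max()

    def test_direction_reversal_mirrors_pulse(self):
        nz = 257
        centre = nz // 2
        g = GridSpec(LAMBDA0 / 6, (1, 1, nz), pml_thickness=10)
        m = MaterialMap.homogeneous(g)

        def run(direction):
            src = SourceSpec(centre, np.array([[[1.0]], [[0.0]]], dtype=complex),
                             k0=2 * np.pi / LAMBDA0, W=8.0, direction=direction)
            s = PSTDSolver(g, m, source=src)
            for _ in range(250):
                s.step()
            return s.E[0, 0, 0, :]

        fwd = run(+1)
        bwd = run(-1)
        mirrored = bwd[::-1]
        assert np.abs(np.abs(fwd) - np.abs(mirrored)).max() < 1e-9 * np.abs(fwd).max()
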