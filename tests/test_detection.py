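"""Detection-chain tests: coupling overlap, interference, shot noise, eta
calibration, A-scan reconstruction and the 1D end-to-end mirror check."""

import numpy as np
import pytest

from octsim.detection import (
    CouplingSpectrum,
    DetectorModel,
    apply_shot_noise,
    calibrate_eta,
    hann_window,
    interference_power,
    overlap_coupling,
    reconstruct_ascan,
    _roi_snr_db,
)
from octsim.pipeline import OCT1DSetup, simulate_coupling_1d

K = np.linspace(2 * np.pi / 1.420, 2 * np.pi / 1.180, 256)


class TestOverlapCoupling:
    def test_no_sample_identity(self, rng):
        e_ill = rng.standard_normal((len(K), 2, 4, 4)) + 1j * rng.standard_normal((len(K), 2, 4, 4))
        alpha = overlap_coupling(e_ill, e_ill)
        cs = CouplingSpectrum(K, alpha.copy(), alpha.copy(), alpha.copy())
        assert np.allclose(interference_power(cs), 0.0, atol=1e-20)

    def test_linearity(self, rng):
        e_ill = rng.standard_normal((2, 8, 8)) + 1j * rng.standard_normal((2, 8, 8))
        f = rng.standard_normal((2, 8, 8)) + 1j * rng.standard_normal((2, 8, 8))
        g = rng.standard_normal((2, 8, 8)) + 1j * rng.standard_normal((2, 8, 8))
        a, b = 1.7 - 0.3j, -0.4 + 2.2j
        lhs = overlap_coupling(e_ill, a * f + b * g)
        rhs = a * overlap_coupling(e_ill, f) + b * overlap_coupling(e_ill, g)
        assert abs(lhs - rhs) < 1e-12 * abs(rhs)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            overlap_coupling(np.ones((2, 4, 4)), np.ones((2, 4, 5)))

    def test_mirror_round_trip_phase(self):
        # 1D mirror below the focus: unwrapped phase slope of the echo
        # coupling is twice the detector-to-mirror optical distance
        setup = OCT1DSetup(dt=0.08,
                           wavenumbers=np.linspace(2 * np.pi / 1.420, 2 * np.pi / 1.180, 128))
        mirror = 100
        cs = simulate_coupling_1d(setup, sample_mirror_index=mirror)
        echo = cs.alpha_tot - cs.alpha_ill
        slope = np.polyfit(setup.wavenumbers, np.unwrap(np.angle(echo)), 1)[0]
        # the source-normalized spectra reference phase to the source plane
        expected = 2 * (mirror - setup.source_index) * setup.cell_size
        assert slope == pytest.approx(expected, rel=0.01)


class TestIncrementalCoupling:
    def test_equivalence_with_posthoc_overlap(self, rng):
        # an incremental coupling probe must agree with the post-hoc overlap
        # of the accumulated spectral fields on a 1D toy run
        from octsim.grid import GridSpec, MaterialMap
        from octsim.pstd import PSTDSolver, SourceSpec, SpectralProbe

        g = GridSpec(1.3 / 6, (1, 1, 120), pml_thickness=10)
        m = MaterialMap.homogeneous(g)
        k = np.linspace(4.5, 5.2, 8)
        e_ill = rng.standard_normal((8, 2, 1, 1)) + 1j * rng.standard_normal((8, 2, 1, 1))
        src = SourceSpec(12, np.array([[[1.0]], [[0.0]]], dtype=complex), k0=4.85, W=8.0)
        s = PSTDSolver(g, m, source=src, dt=0.2)
        p_plane = SpectralProbe(k, "plane_E", plane_index=30)
        p_coup = SpectralProbe(k, "coupling", plane_index=30, e_ill_spectral=e_ill)
        s.run(1500, probes=[p_plane, p_coup])
        posthoc = overlap_coupling(e_ill, p_plane.E, g.cell_size)
        rel = np.abs(p_coup.alpha - posthoc) / np.abs(posthoc)
        assert rel.max() < 1e-10

    def test_source_amplitude_scaling(self):
        # doubling the source amplitude doubles the fields, hence the
        # per-wavenumber coupling (linearity of the update)
        from octsim.grid import GridSpec as GS
        from octsim.grid import MaterialMap
        from octsim.pstd import PSTDSolver, SourceSpec

        def field(amp):
            g = GS(1.3 / 6, (1, 1, 120), pml_thickness=10)
            src = SourceSpec(12, np.array([[[amp]], [[0.0]]], dtype=complex),
                             k0=4.85, W=8.0)
            s = PSTDSolver(g, MaterialMap.homogeneous(g), source=src, dt=0.2)
            for _ in range(400):
                s.step()
            return s.E

        assert np.allclose(field(2.0), 2 * field(1.0), atol=1e-12)

    def test_zero_fields_zero_coupling(self):
        from octsim.grid import GridSpec, MaterialMap
        from octsim.pstd import PSTDSolver, SpectralProbe

        g = GridSpec(1.3 / 6, (1, 1, 64), pml_thickness=10)
        s = PSTDSolver(g, MaterialMap.homogeneous(g))
        p = SpectralProbe(np.array([4.8]), "coupling", plane_index=20,
                          e_ill_spectral=np.ones((1, 2, 1, 1), dtype=complex))
        for _ in range(50):
            s.step()
            p.accumulate(s)
        assert np.all(p._acc["alpha"] == 0)


class TestInterferencePower:
    def _cs(self, a_tot, a_ref, a_ill):
        n = len(K)
        return CouplingSpectrum(K, np.full(n, a_tot, dtype=complex),
                                np.full(n, a_ref, dtype=complex),
                                np.full(n, a_ill, dtype=complex))

    def test_sample_free_leaves_reference_spectrum(self):
        cs = self._cs(0.3 + 0.1j, 0.8 - 0.2j, 0.3 + 0.1j)
        expected = np.abs((0.8 - 0.2j) - (0.3 + 0.1j)) ** 2
        assert np.allclose(interference_power(cs), expected)

    def test_symmetry_under_arm_exchange(self):
        cs1 = self._cs(0.5 + 0.4j, 0.9 - 0.1j, 0.2j)
        cs2 = self._cs(0.9 - 0.1j, 0.5 + 0.4j, 0.2j)
        assert np.allclose(interference_power(cs1), interference_power(cs2))

    def test_all_equal_gives_zero(self):
        cs = self._cs(0.7, 0.7, 0.7)
        assert np.allclose(interference_power(cs), 0.0)


class TestShotNoise:
    def test_zero_eta_gives_zero_counts(self, rng):
        out = apply_shot_noise(np.ones(100), DetectorModel(eta=0.0), rng)
        assert np.all(out == 0)

    def test_sample_mean_matches_poisson_mean(self):
        det = DetectorModel(eta=2.5, seed=7)
        i_k = np.full(10_000, 400.0)
        draws = apply_shot_noise(i_k, det)
        mean = det.eta * 400.0
        se = np.sqrt(mean / i_k.size)
        assert abs(draws.mean() - mean) < 3 * se

    def test_variance_over_mean_near_unity(self):
        det = DetectorModel(eta=1.0, seed=11)
        draws = apply_shot_noise(np.full(10_000, 1000.0), det)
        assert 0.95 <= draws.var() / draws.mean() <= 1.05

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            apply_shot_noise(np.array([-1.0]), DetectorModel())


def _mirror_image_spectra(n_ascan=4, n_k=256, depth=20.0, amp=3e-3):
    """Noise-free detected powers of a simple mirror-like image."""
    k = np.linspace(2 * np.pi / 1.420, 2 * np.pi / 1.180, n_k)
    i_k = np.abs(amp * np.exp(2j * k * depth) + amp) ** 2
    return np.tile(i_k, (n_ascan, 1)), k


class TestEtaCalibration:
    def setup_method(self):
        self.spectra, self.k = _mirror_image_spectra()
        self.z = np.arange(2.0, 40.0, 0.5)
        self.roi = (np.abs(self.z - 20.0) < 2.0)[None, :] & np.ones((4, 1), dtype=bool)
        self.noise = (self.z > 30.0)[None, :] & np.ones((4, 1), dtype=bool)
        self.spectrum = hann_window(len(self.k))

    def _snr(self, eta, seed=5):
        det = DetectorModel(eta=eta, spectrum=self.spectrum)
        return _roi_snr_db(self.spectra, det, self.k, self.z, self.roi,
                           self.noise, 6, np.random.default_rng(seed))

    def test_snr_monotone_in_eta(self):
        s = [self._snr(eta) for eta in (3e4, 3e5, 3e6)]
        assert s[0] < s[1] < s[2]

    def test_doubling_eta_adds_three_db(self):
        # shot-noise-limited: amplitude SNR scales as sqrt(eta), +3 dB per
        # doubling; averaged over several draws of the Poisson noise
        diffs = [self._snr(2e6, seed=100 + s) - self._snr(1e6, seed=s)
                 for s in range(6)]
        assert np.mean(diffs) == pytest.approx(10 * np.log10(2), abs=0.5)

    def test_high_eta_approaches_noise_free_image(self):
        det_free = DetectorModel(eta=1.0, spectrum=self.spectrum)
        ref = np.abs(reconstruct_ascan(self.spectra[0] * 1.0, self.k, self.z,
                                       self.spectrum).amplitude)
        ref /= ref.max()

        def rms(eta):
            det = DetectorModel(eta=eta, spectrum=self.spectrum)
            noisy = apply_shot_noise(self.spectra[0], det,
                                     np.random.default_rng(0))
            img = np.abs(reconstruct_ascan(noisy, self.k, self.z, self.spectrum).amplitude)
            img /= img.max()
            return np.sqrt(np.mean((img - ref) ** 2))

        assert rms(1e9) < rms(1e5)

    def test_calibration_hits_target(self):
        eta = calibrate_eta(self.spectra, self.k, self.z, self.roi, self.noise,
                            target_snr_db=25.0, spectrum=self.spectrum, seed=9,
                            n_draws=8)
        # on the calibration's own noise stream the target is met to 0.25 dB
        det = DetectorModel(eta=eta, spectrum=self.spectrum)
        achieved = _roi_snr_db(self.spectra, det, self.k, self.z, self.roi,
                               self.noise, 8, np.random.default_rng(9))
        assert abs(achieved - 25.0) <= 0.25
        # independent noise draws agree to within estimator variance
        assert abs(self._snr(eta, seed=42) - 25.0) < 2.5


class TestReconstruction:
    def test_unit_counts_give_axial_psf(self):
        # n(k) = 1: |A| is the transform of the window, peaked at z = 0
        s = hann_window(len(K))
        z = np.arange(-15.0, 15.0, 0.1)
        a = np.abs(reconstruct_ascan(np.ones(len(K)), K, z, s).amplitude)
        assert z[np.argmax(a)] == pytest.approx(0.0, abs=0.1)
        # amplitude FWHM matches the Hann transform's -6 dB width of
        # 2 bins: 2 * 2pi / (2 dk) on the round-trip depth axis
        dk = K[-1] - K[0]
        fwhm = z[a >= a.max() / 2][-1] - z[a >= a.max() / 2][0]
        assert fwhm == pytest.approx(2.0 * 2 * np.pi / (2 * dk), rel=0.05)

    def test_cosine_counts_place_sidepeak_at_depth(self):
        d = 12.5
        n_k_counts = 1.0 + np.cos(2 * K * d)
        z = np.arange(0.0, 30.0, 0.2)
        a = np.abs(reconstruct_ascan(n_k_counts, K, z, hann_window(len(K))).amplitude)
        sel = z > 5.0
        assert z[sel][np.argmax(a[sel])] == pytest.approx(d, abs=0.2)

    def test_hann_first_sidelobe_level(self):
        s = hann_window(2048)
        k = np.linspace(2 * np.pi / 1.420, 2 * np.pi / 1.180, 2048)
        z = np.arange(0.0, 40.0, 0.02)
        a = np.abs(reconstruct_ascan(np.ones(2048), k, z, s).amplitude)
        main = a.max()
        # first sidelobe: after the first null
        da = np.diff(a)
        minima = np.nonzero((da[:-1] < 0) & (da[1:] >= 0))[0]
        first_min = minima[0]
        maxima_after = np.nonzero((da[first_min:-1] > 0) & (da[first_min + 1:] <= 0))[0]
        side = a[first_min + maxima_after[0] + 1]
        assert 20 * np.log10(side / main) <= -31.0

    def test_parseval_without_window(self):
        rng = np.random.default_rng(2)
        n_tilde = rng.random(len(K))
        dk = K[1] - K[0]
        # conjugate axis u = 2z with du*dk_total = 2pi/n
        du = 2 * np.pi / (len(K) * dk)
        z = 0.5 * du * np.arange(len(K))
        a = reconstruct_ascan(n_tilde, K, z).amplitude
        lhs = np.sum(np.abs(a) ** 2) * du
        rhs = np.sum(np.abs(n_tilde) ** 2) * dk / (2 * np.pi)
        assert lhs == pytest.approx(rhs, rel=1e-8)

    def test_nonuniform_wavenumbers_rejected(self):
        k_bad = np.sort(np.random.default_rng(0).random(64)) * 0.9 + 4.4
        with pytest.raises(ValueError):
            reconstruct_ascan(np.ones(64), k_bad, np.arange(0, 5, 0.1))


class TestEndToEndMirror:
    def test_mirror_peak_at_optical_depth_with_clean_background(self):
        setup = OCT1DSetup()
        mirror = 120
        cs = simulate_coupling_1d(setup, sample_mirror_index=mirror)
        i_k = interference_power(cs)
        dz = 0.35
        z = np.arange(0.0, 80.0, dz)
        a = np.abs(reconstruct_ascan(i_k, setup.wavenumbers, z,
                                     hann_window(len(setup.wavenumbers))).amplitude)
        depth = setup.optical_depth_of(mirror)
        sel = z > 8.0  # exclude the DC autocorrelation lobe
        peak_z = z[sel][np.argmax(a[sel])]
        assert abs(peak_z - depth) <= dz
        # far background (beyond the Hann sidelobe skirt) is 60 dB down
        far = z > depth + 25.0
        assert 20 * np.log10(a[far].max() / a.max()) <= -60.0


class TestRayleighSpeckle:
    def test_dense_scatterer_amplitudes_are_rayleigh(self):
        from octsim.analysis import amplitude_histogram
        from octsim.speckle import SpeckleModel

        img = SpeckleModel().image(seed=4)
        _, _, scale, ks, pval = amplitude_histogram(img[::16, ::16])  # decorrelated samples
        assert pval > 0.01
        assert scale > 0
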