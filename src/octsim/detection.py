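"""Fiber coupling, interferometric spectrum, shot noise and A-scan
reconstruction.

The scattered light reaching the detection fiber is summarized per vacuum
wavenumber by the scalar overlap ``alpha(k) = integral (T e_ill)^T (T e_tot)
d^2r`` over the detection plane (transverse components only, unconjugated
product).  The detected power is ``i(k) ∝ |alpha_tot - alpha_ill + alpha_ref
- alpha_ill|^2`` (the source plane emits both ways, so the illumination
contribution is subtracted from both sample and reference terms); photon
counts are Poisson with mean ``eta * i(k)``; the complex A-scan follows by
the inverse transform ``A(z) = (1/2pi) sum S(k) n(k) exp(i 2 k z) dk`` with
the round-trip factor 2 and the Hann system spectrum ``S(k)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CouplingSpectrum",
    "DetectorModel",
    "AScan",
    "overlap_coupling",
    "interference_power",
    "apply_shot_noise",
    "calibrate_eta",
    "reconstruct_ascan",
    "hann_window",
]


@dataclass
class CouplingSpectrum:
    """Raw coupling amplitudes versus vacuum wavenumber.

    ``alpha_tot`` from the sample run, ``alpha_ref`` from the reference
    (mirror) run, ``alpha_ill`` from the homogeneous illumination-only run.
    """

    wavenumbers: np.ndarray
    alpha_tot: np.ndarray
    alpha_ref: np.ndarray
    alpha_ill: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.wavenumbers)
        for a in (self.alpha_tot, self.alpha_ref, self.alpha_ill):
            if len(a) != n:
                raise ValueError("coupling arrays must share the wavenumber length")


@dataclass
class DetectorModel:
    """Shot-noise-limited spectrometer model.

    ``eta`` converts relative optical power to mean photon counts per
    spectral bin; ``spectrum`` is the effective system spectrum S(k) applied
    during reconstruction (Hann window by default); ``seed`` drives the
    Poisson draws.
    """

    eta: float = 1.0
    spectrum: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.spectrum is not None and np.any(np.asarray(self.spectrum) < 0):
            raise ValueError("spectrum weights must be non-negative")


def hann_window(n_k: int) -> np.ndarray:
    """Hann spectral window vanishing at the band edges."""
    return np.hanning(n_k + 2)[1:-1]


def overlap_coupling(e_ill_plane: np.ndarray, e_tot_plane: np.ndarray,
                     cell_size: float = 1.0) -> complex | np.ndarray:
    """Scalar fiber-coupling overlap on the detection plane.

    ``alpha = sum (T e_ill)^T (T e_tot) dA`` with ``T`` the transverse
    projector: the unconjugated product of the transverse components,
    integrated over the plane.  Accepts single planes ``(2, nx, ny)`` or
    stacks ``(n_k, 2, nx, ny)``; returns a scalar or a per-k vector.
    """
    a = np.asarray(e_ill_plane)
    b = np.asarray(e_tot_plane)
    if a.shape != b.shape:
        raise ValueError("illumination and total field planes must share a shape")
    if a.shape[-3] != 2:
        raise ValueError("expected transverse field planes with leading component axis of 2")
    return (a * b).sum(axis=(-3, -2, -1)) * cell_size**2


def interference_power(coupling: CouplingSpectrum) -> np.ndarray:
    """Detected relative power spectrum (proportionality constant 1):
    ``i(k) = |alpha_tot - alpha_ill + alpha_ref - alpha_ill|^2``."""
    return np.abs(coupling.alpha_tot - coupling.alpha_ill
                  + coupling.alpha_ref - coupling.alpha_ill) ** 2


def apply_shot_noise(i_k: np.ndarray, detector: DetectorModel,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Poisson photon counts with mean ``eta * i(k)``."""
    i_k = np.asarray(i_k, dtype=float)
    if np.any(i_k < 0):
        raise ValueError("detected power must be non-negative")
    if rng is None:
        rng = np.random.default_rng(detector.seed)
    return rng.poisson(detector.eta * i_k).astype(float)


def reconstruct_ascan(n_tilde: np.ndarray, wavenumbers: np.ndarray,
                      z: np.ndarray, spectrum: np.ndarray | None = None,
                      n_group: float = 1.0) -> "AScan":
    """Complex A-scan from spectrally resolved counts.

    ``A(z) = (1/2pi) sum_k S(k) n(k) exp(i 2 k n_group z) dk`` — the factor 2
    accounts for the round trip; ``z`` is depth relative to the reference
    plane, in optical distance when ``n_group = 1`` or physical distance when
    the medium group index is supplied.  Uniform wavenumber sampling is
    required.
    """
    k = np.asarray(wavenumbers, dtype=float)
    dk = np.diff(k)
    if k.size < 2 or not np.allclose(dk, dk[0], rtol=1e-9):
        raise ValueError("wavenumbers must be uniformly sampled (resample first)")
    s = np.ones_like(k) if spectrum is None else np.asarray(spectrum, dtype=float)
    z = np.asarray(z, dtype=float)
    phase = np.exp(2j * np.outer(z, k) * n_group)
    amp = phase @ (s * np.asarray(n_tilde)) * dk[0] / (2.0 * np.pi)
    return AScan(z=z, amplitude=amp, n_group=n_group)


@dataclass
class AScan:
    """Depth-resolved complex reflectivity profile.

    ``z`` is the depth axis relative to the reference plane (um; physical
    distance when reconstructed with the medium group index), ``amplitude``
    the complex A-scan values.
    """

    z: np.ndarray
    amplitude: np.ndarray
    n_group: float = 1.0

    def snr_db(self, noise_floor: float) -> np.ndarray:
        return 20.0 * np.log10(np.abs(self.amplitude) / noise_floor)


def _roi_snr_db(spectra: np.ndarray, detector: DetectorModel, wavenumbers, z,
                roi_mask: np.ndarray, noise_mask: np.ndarray, n_draws: int,
                rng: np.random.Generator) -> float:
    """Mean ROI SNR (dB) of the reconstructed image under shot noise.

    ``spectra``: (n_ascan, n_k) noise-free detected powers, one column of
    the image per row.  SNR is the amplitude ratio between the ROI mean and
    the noise-region mean, in dB (20 log10), averaged over draws.
    """
    vals = []
    for _ in range(n_draws):
        img = np.stack([
            np.abs(reconstruct_ascan(apply_shot_noise(row, detector, rng),
                                     wavenumbers, z, detector.spectrum).amplitude)
            for row in spectra
        ])
        noise_mean = img[noise_mask].mean()
        roi_mean = img[roi_mask].mean()
        if noise_mean == 0 or roi_mean == 0:
            vals.append(-np.inf)
        else:
            vals.append(20.0 * np.log10(roi_mean / noise_mean))
    return float(np.mean(vals))


def calibrate_eta(spectra: np.ndarray, wavenumbers: np.ndarray, z: np.ndarray,
                  roi_mask: np.ndarray, noise_mask: np.ndarray,
                  target_snr_db: float, spectrum: np.ndarray | None = None,
                  seed: int | None = None, tol_db: float = 0.25,
                  n_draws: int = 4, max_expand: int = 40) -> float:
    """Choose the effective quantum efficiency so the reconstructed-image
    mean ROI SNR matches a target, by bisection on log eta.

    Shot-noise-limited SNR increases monotonically with eta, so the target
    is bracketed by scaling eta by powers of ten and then bisected until
    within ``tol_db``.  Every trial eta reuses the same random stream
    (common random numbers), making the searched function deterministic.
    """

    def snr(eta):
        det = DetectorModel(eta=eta, spectrum=spectrum)
        return _roi_snr_db(spectra, det, wavenumbers, z, roi_mask, noise_mask,
                           n_draws, np.random.default_rng(seed))

    lo, hi = 1.0, 1.0
    s_lo = s_hi = snr(1.0)
    n_try = 0
    while s_lo > target_snr_db:
        lo /= 10.0
        s_lo = snr(lo)
        n_try += 1
        if n_try > max_expand:
            raise RuntimeError("calibration failure: target SNR not bracketed from below")
    while s_hi < target_snr_db:
        hi *= 10.0
        s_hi = snr(hi)
        n_try += 1
        if n_try > max_expand:
            raise RuntimeError("calibration failure: target SNR not bracketed from above")
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        s_mid = snr(mid)
        if abs(s_mid - target_snr_db) <= tol_db:
            return float(mid)
        if s_mid < target_snr_db:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("calibration failure: bisection did not converge")
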