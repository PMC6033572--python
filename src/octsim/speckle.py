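"""Synthetic fully developed speckle from the system point-spread function.

A dense set of point scatterers with circular-Gaussian complex amplitudes
and uniform positions (many per resolution cell) is convolved with the
separable system PSF: the axial profile is the A-scan transform of the
Hann-windowed source band with depths scaled to physical distance by the
medium index, and the lateral profile is the square of the in-focus
Debye–Wolf amplitude profile — squared because the same fiber mode both
illuminates the sample and weights the detected field, so the lateral
system response of a point scatterer is ``e_ill(x)^2``.

The resulting amplitude images have Rayleigh statistics and speckle grain
sizes set by the PSF autocorrelation; their normalized-autocovariance FWHMs
are the desk-scale counterpart of the full solver pipeline's speckle
metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import autocovariance_fwhm
from .detection import hann_window
from .focusing import OpticalSystemSpec, lateral_amplitude_profile

__all__ = [
    "SpeckleModel",
    "axial_psf",
    "simulate_speckle_image",
    "speckle_autocovariance_fwhm",
]


def axial_psf(z_um: np.ndarray, band_um: tuple[float, float] = (1.180, 1.420),
              n_k: int = 512, n_medium: float = 1.42,
              window: np.ndarray | None = None) -> np.ndarray:
    """Complex axial amplitude PSF on a physical depth axis.

    ``a(z) = sum_k S(k) exp(i 2 k n z)`` — the round-trip A-scan kernel of a
    Hann-windowed band uniform in wavenumber, with depth scaled by the
    medium index.
    """
    lam_lo, lam_hi = min(band_um), max(band_um)
    k = np.linspace(2.0 * np.pi / lam_hi, 2.0 * np.pi / lam_lo, n_k)
    s = hann_window(n_k) if window is None else np.asarray(window)
    a = (s[None, :] * np.exp(2j * k[None, :] * n_medium * np.asarray(z_um)[:, None])).sum(axis=1)
    return a / np.abs(a).max()


@dataclass
class SpeckleModel:
    """Separable-PSF speckle image generator.

    ``pixel_z/pixel_x`` are the image sample spacings (um), ``extent_z/x``
    the image size (um), ``density`` the scatterer surface density
    (um^-2, >= 20 per resolution cell at the default).
    """

    system: OpticalSystemSpec = None  # type: ignore[assignment]
    n_medium: float = 1.42
    pixel_z: float = 0.25
    pixel_x: float = 0.5
    extent_z: float = 80.0
    extent_x: float = 120.0
    density: float = 4.0
    two_way_lateral: bool = True

    def __post_init__(self) -> None:
        if self.system is None:
            self.system = OpticalSystemSpec()

    def _psfs(self):
        z = np.arange(-self.extent_z / 2, self.extent_z / 2, self.pixel_z)
        x = np.arange(-self.extent_x / 2, self.extent_x / 2, self.pixel_x)
        band = tuple(b * 1e-3 for b in self.system.band)
        a_z = axial_psf(z, band_um=band, n_medium=self.n_medium)
        a_x = lateral_amplitude_profile(self.system, self.system.lambda0 * 1e-3,
                                        np.abs(x)).astype(complex)
        if self.two_way_lateral:
            a_x = a_x**2
        return z, x, a_z, a_x

    def image(self, seed: int) -> np.ndarray:
        """One amplitude speckle image (nz, nx) for the given seed."""
        rng = np.random.default_rng(seed)
        z, x, a_z, a_x = self._psfs()
        nz, nx = len(z), len(x)
        area = (nz * self.pixel_z) * (nx * self.pixel_x)
        n_scat = rng.poisson(self.density * area)
        iz = rng.integers(0, nz, n_scat)
        ix = rng.integers(0, nx, n_scat)
        amp = (rng.standard_normal(n_scat) + 1j * rng.standard_normal(n_scat)) / np.sqrt(2.0)
        fld = np.zeros((nz, nx), dtype=complex)
        np.add.at(fld, (iz, ix), amp)
        kern = np.fft.ifftshift(np.outer(a_z, a_x))
        out = np.fft.ifft2(np.fft.fft2(fld) * np.fft.fft2(kern))
        return np.abs(out)


def simulate_speckle_image(seed: int = 0, **kwargs) -> np.ndarray:
    return SpeckleModel(**kwargs).image(seed)


def speckle_autocovariance_fwhm(n_seeds: int = 10, seed0: int = 0,
                                model: SpeckleModel | None = None):
    """Mean (axial, lateral) normalized-autocovariance FWHM in um over
    independent speckle realizations."""
    model = model or SpeckleModel()
    ax, lat = [], []
    for s in range(n_seeds):
        img = model.image(seed0 + s)
        ax.append(autocovariance_fwhm(img, 0, model.pixel_z))
        lat.append(autocovariance_fwhm(img.T, 0, model.pixel_x))
    return float(np.mean(ax)), float(np.mean(lat))
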