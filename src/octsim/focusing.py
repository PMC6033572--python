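"""Vectorial focused illumination: Gaussian fiber mode, 4f relay, Debye–Wolf
focal field.

The fiber mode is the weakly-guiding Gaussian approximation with 1/e^2
intensity diameter equal to the mode field diameter (MFD).  The mode is
collimated by lens L1 (focal length f1), truncated by the aperture of radius
Ra, and focused by lens L2 (focal length f2); the focal field follows from
the Debye–Wolf (Richards–Wolf) integral with aplanatic sqrt(cos theta)
apodization.  For the linearly polarized input the field reduces to the
classic I0/I1/I2 Bessel-integral form, evaluated by Gauss–Legendre
quadrature over the aperture cone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import j0, j1, jn

from .grid import GridSpec, C_UM_FS
from .pstd import SourceSpec, gaussian_envelope_width

__all__ = [
    "OpticalSystemSpec",
    "FocusedField",
    "fiber_mode",
    "pupil_field",
    "debye_wolf_field",
    "illumination_on_plane",
]


@dataclass
class OpticalSystemSpec:
    """Fiber-coupled 4f focusing system.

    Focal lengths ``f1, f2`` and aperture radius ``Ra`` in mm, fiber mode
    field diameter ``mfd`` in um, vacuum band and centre wavelength in nm.
    ``polarization`` is a transverse Jones vector (z-component forbidden).
    """

    f1: float = 25.0
    f2: float = 36.0
    Ra: float = 3.5
    mfd: float = 9.2
    band: tuple[float, float] = (1180.0, 1420.0)
    lambda0: float = 1300.0
    n_k: int = 2048
    polarization: tuple[complex, complex] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.f1, self.f2, self.Ra, self.mfd) <= 0:
            raise ValueError("f1, f2, Ra, mfd must be positive")
        if not (min(self.band) <= self.lambda0 <= max(self.band)):
            raise ValueError("band must contain lambda0")
        p = np.asarray(self.polarization, dtype=complex)
        if p.shape != (2,) or np.allclose(p, 0):
            raise ValueError("polarization must be a transverse Jones vector")
        self.polarization = tuple(p / np.linalg.norm(p))

    @property
    def numerical_aperture(self) -> float:
        return self.Ra / self.f2

    @property
    def theta_max(self) -> float:
        return float(np.arcsin(self.numerical_aperture))

    @property
    def w0_um(self) -> float:
        """1/e^2 intensity radius of the fiber mode (um)."""
        return self.mfd / 2.0

    def pupil_waist_mm(self, lambda_vac_um: float) -> float:
        """1/e^2 intensity radius of the collimated beam at the aperture (mm)."""
        return lambda_vac_um * (self.f1 * 1e3) / (np.pi * self.w0_um) * 1e-3

    def band_wavenumbers(self, n_k: int | None = None) -> np.ndarray:
        """Vacuum wavenumbers (rad/um) uniform over the band, ascending."""
        lam = np.array(sorted(self.band)) * 1e-3
        return np.linspace(2.0 * np.pi / lam[1], 2.0 * np.pi / lam[0],
                           n_k or self.n_k)


@dataclass
class FocusedField:
    """Vector field sampled on a transverse plane at ``plane_z`` um from
    focus (positive toward the sample)."""

    plane_z: float
    x: np.ndarray
    y: np.ndarray
    e: np.ndarray  # complex, shape (3, nx, ny)

    def energy(self) -> float:
        dx = self.x[1] - self.x[0] if len(self.x) > 1 else 1.0
        dy = self.y[1] - self.y[0] if len(self.y) > 1 else 1.0
        return float(np.sum(np.abs(self.e) ** 2) * dx * dy)


def fiber_mode(mfd: float, r: np.ndarray) -> np.ndarray:
    """Unit-energy Gaussian fiber mode amplitude at radius ``r`` (um).

    The 1/e^2 intensity radius is ``mfd/2``:
    ``f(r) = sqrt(2/(pi w0^2)) exp(-r^2/w0^2)`` with ``w0 = mfd/2``.
    """
    if mfd <= 0:
        raise ValueError("mfd must be positive")
    w0 = mfd / 2.0
    return np.sqrt(2.0 / (np.pi * w0**2)) * np.exp(-np.asarray(r) ** 2 / w0**2)


def pupil_field(system: OpticalSystemSpec, lambda_vac_um: float,
                rho_mm: np.ndarray) -> np.ndarray:
    """Scalar field at the aperture plane (Fourier-optics image of the fiber
    mode through L1), hard-truncated at radius ``Ra``.

    The Gaussian fiber mode transforms to a Gaussian with 1/e^2 intensity
    radius ``lambda f1/(pi w0)``; energy is preserved (Parseval) up to the
    aperture truncation.
    """
    w_p = system.pupil_waist_mm(lambda_vac_um)
    if w_p > 3.0 * system.Ra:
        warnings.warn("pupil beam much wider than the aperture: severe truncation")
    rho = np.asarray(rho_mm, dtype=float)
    amp = np.sqrt(2.0 / (np.pi * (w_p * 1e3) ** 2)) * np.exp(-(rho / w_p) ** 2)
    return np.where(rho <= system.Ra, amp, 0.0)


def _rw_integrals(system: OpticalSystemSpec, k: float, r: np.ndarray,
                  z: float, n_quad: int = 96):
    """Richards–Wolf integrals I0, I1, I2 over the aperture cone.

    ``k`` vacuum wavenumber (rad/um), ``r`` radial offsets (um), ``z`` axial
    offset from focus (um).  Apodization sqrt(cos theta); pupil amplitude
    from the truncated Gaussian relay.
    """
    th_max = system.theta_max
    xg, wg = leggauss(n_quad)
    th = 0.5 * th_max * (xg + 1.0)
    wq = 0.5 * th_max * wg
    st, ct = np.sin(th), np.cos(th)
    w_p = system.pupil_waist_mm(2.0 * np.pi / k)
    l0 = np.exp(-((system.f2 * 1e-3 * st / w_p) * 1e3) ** 2)  # pupil amplitude vs angle
    apod = np.sqrt(ct)
    common = l0 * apod * st * np.exp(1j * k * z * ct) * wq
    kr = k * np.outer(np.asarray(r, dtype=float), st)
    i0 = (common * (1 + ct) * j0(kr)).sum(axis=1)
    i1 = (common * st * j1(kr)).sum(axis=1)
    i2 = (common * (1 - ct) * jn(2, kr)).sum(axis=1)
    return i0, i1, i2


def debye_wolf_field(system: OpticalSystemSpec, lambda_vac_um: float,
                     x: np.ndarray, y: np.ndarray, plane_z: float,
                     n_quad: int = 96) -> FocusedField:
    """Vector focal field on the transverse plane ``z = plane_z`` (um from
    focus) by the Debye–Wolf integral.

    For x-polarized input:
    ``Ex = I0 + I2 cos 2psi``, ``Ey = I2 sin 2psi``, ``Ez = -2i I1 cos psi``;
    a y-polarized component follows by 90-degree rotation.  Valid for
    NA < 0.5; the transverse sample spacing must resolve the focal spot
    (< lambda/(4 NA)).
    """
    na = system.numerical_aperture
    if na >= 0.5:
        raise ValueError("Debye-Wolf evaluation restricted to NA < 0.5")
    k = 2.0 * np.pi / lambda_vac_um
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    for arr in (x, y):
        if len(arr) > 1:
            d = np.diff(arr)
            if d.max() > lambda_vac_um / (4.0 * na):
                raise ValueError("transverse grid undersamples the focal field")
    xx, yy = np.meshgrid(x, y, indexing="ij")
    rr = np.hypot(xx, yy)
    psi = np.arctan2(yy, xx)
    r_flat, inv = np.unique(np.round(rr, 9).ravel(), return_inverse=True)
    i0, i1, i2 = _rw_integrals(system, k, r_flat, plane_z, n_quad)
    i0 = i0[inv].reshape(rr.shape)
    i1 = i1[inv].reshape(rr.shape)
    i2 = i2[inv].reshape(rr.shape)

    px, py = system.polarization
    e = np.zeros((3,) + rr.shape, dtype=complex)
    # x-polarized part
    e[0] += px * (i0 + i2 * np.cos(2 * psi))
    e[1] += px * i2 * np.sin(2 * psi)
    e[2] += px * (-2j) * i1 * np.cos(psi)
    # y-polarized part: rotate psi by -pi/2
    psi_y = psi - np.pi / 2.0
    e[0] += py * i2 * np.sin(2 * psi_y)
    e[1] += py * (i0 + i2 * np.cos(2 * psi_y))
    e[2] += py * (-2j) * i1 * np.cos(psi_y)
    return FocusedField(plane_z=plane_z, x=x, y=y, e=e)


def lateral_amplitude_profile(system: OpticalSystemSpec, lambda_vac_um: float,
                              r: np.ndarray, n_quad: int = 96) -> np.ndarray:
    """In-focus on-axis-normalized radial amplitude profile |I0(r)/I0(0)|."""
    i0, _, _ = _rw_integrals(system, 2.0 * np.pi / lambda_vac_um,
                             np.concatenate([[0.0], np.asarray(r, float).ravel()]),
                             0.0, n_quad)
    return np.abs(i0[1:] / i0[0]).reshape(np.shape(r))


def illumination_on_plane(system: OpticalSystemSpec, k0: float, grid: GridSpec,
                          source_plane_index: int, focus_z_um: float,
                          focus_xy_um: tuple[float, float] | None = None,
                          envelope_edge_amplitude: float = 0.1) -> SourceSpec:
    """Sample the Debye–Wolf field at carrier ``k0`` on a PSTD grid plane and
    package it as a planar magnetic-current source.

    ``focus_z_um`` is the z-coordinate (grid frame) of the intended focus;
    the source plane is ``z = (source_plane_index + 1/2) * cell_size``.  The
    envelope width W makes the source amplitude spectrum at least
    ``envelope_edge_amplitude`` of peak at both band edges.
    """
    if not (0 <= source_plane_index < grid.dims[2]):
        raise IndexError("source plane outside the grid")
    cx = grid.axis_coords(0)
    cy = grid.axis_coords(1)
    fx, fy = focus_xy_um if focus_xy_um is not None else (cx.mean(), cy.mean())
    z_plane = (source_plane_index + 0.5) * grid.cell_size
    lam = 2.0 * np.pi / k0
    ff = debye_wolf_field(system, lam, cx - fx, cy - fy, z_plane - focus_z_um)
    w_fs = gaussian_envelope_width(system.band, lam * 1e3, envelope_edge_amplitude)
    return SourceSpec(plane_index=source_plane_index, e_ill_plane=ff.e[:2],
                      k0=k0, W=w_fs)
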