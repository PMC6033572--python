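"""Lorenz–Mie solution for a homogeneous sphere in a homogeneous medium.

Conventions: all wavelengths passed to this module are *vacuum* wavelengths
in micrometres; the in-medium wavelength ``lambda/n_medium`` enters the size
parameter and the cross-section prefactor.  The time convention is
``exp(-i*omega*t)``, matching the solver's ``exp(+i*omega*t)`` running-DFT
accumulator.  The magnetic field is impedance-scaled (``Z0*H``), so an
incident unit plane wave in a medium of index ``n_b`` has ``|H| = n_b``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import spherical_jn, spherical_yn

__all__ = [
    "SphereSpec",
    "MieSolution",
    "mie_coefficients",
    "scattering_cross_section",
    "scattering_efficiency",
    "asymmetry_parameter",
    "amplitude_functions",
    "exterior_fields",
    "scattering_coefficient",
    "spectrum_weighted_mu_s",
    "hann_band_spectrum",
]


@dataclass
class SphereSpec:
    """Homogeneous sphere and suspension parameters.

    diameter in um, refractive indices dimensionless, concentration in
    particles per cubic micrometre.
    """

    diameter: float
    n_particle: float
    n_medium: float
    concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.n_particle < 1 or self.n_medium < 1:
            raise ValueError("refractive indices must be >= 1")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class MieSolution:
    m: float          # relative index n_particle / n_medium
    x: float          # size parameter pi * d * n_medium / lambda_vac
    a: np.ndarray     # electric multipole coefficients a_n, n = 1..n_max
    b: np.ndarray     # magnetic multipole coefficients b_n
    n_max: int


def _n_max(x: float) -> int:
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def mie_coefficients(sphere: SphereSpec, lambda_vac: float) -> MieSolution:
    """Mie coefficients via Riccati–Bessel functions, with the logarithmic
    derivative of ``psi(mx)`` evaluated by downward recurrence."""
    if lambda_vac <= 0:
        raise ValueError("lambda_vac must be positive")
    m = sphere.n_particle / sphere.n_medium
    x = np.pi * sphere.diameter * sphere.n_medium / lambda_vac
    nmax = _n_max(x)
    mx = m * x
    nmx = int(max(nmax, abs(mx)) + 16)
    d = np.zeros(nmx + 1)
    for n in range(nmx, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)
    if not np.all(np.isfinite(d)):
        raise ArithmeticError("log-derivative recurrence failed to converge")
    n = np.arange(1, nmax + 1)
    psi = x * spherical_jn(n, x)
    chi = -x * spherical_yn(n, x)
    xi = psi - 1j * chi
    psi_m = np.concatenate([[np.sin(x)], psi[:-1]])
    xi_m = np.concatenate([[np.sin(x) - 1j * np.cos(x)], xi[:-1]])
    dn = d[1:nmax + 1]
    a = ((dn / m + n / x) * psi - psi_m) / ((dn / m + n / x) * xi - xi_m)
    b = ((dn * m + n / x) * psi - psi_m) / ((dn * m + n / x) * xi - xi_m)
    return MieSolution(m=m, x=x, a=a, b=b, n_max=nmax)


def scattering_efficiency(mie: MieSolution) -> float:
    n = np.arange(1, mie.n_max + 1)
    return float((2.0 / mie.x**2) * np.sum((2 * n + 1) * (np.abs(mie.a) ** 2 + np.abs(mie.b) ** 2)))


def scattering_cross_section(mie: MieSolution, lambda_vac: float, n_medium: float) -> float:
    """sigma_s in um^2: ``(lambda_med^2 / 2 pi) * sum (2n+1)(|a_n|^2+|b_n|^2)``."""
    lam_med = lambda_vac / n_medium
    n = np.arange(1, mie.n_max + 1)
    return float((lam_med**2 / (2.0 * np.pi)) * np.sum((2 * n + 1) * (np.abs(mie.a) ** 2 + np.abs(mie.b) ** 2)))


def extinction_efficiency(mie: MieSolution) -> float:
    n = np.arange(1, mie.n_max + 1)
    return float((2.0 / mie.x**2) * np.sum((2 * n + 1) * np.real(mie.a + mie.b)))


def asymmetry_parameter(mie: MieSolution) -> float:
    """Mean scattering-angle cosine ``g`` from the coefficient series."""
    a, b = mie.a, mie.b
    n = np.arange(1, mie.n_max + 1)
    t1 = np.sum(n[:-1] * (n[:-1] + 2) / (n[:-1] + 1)
                * np.real(a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])))
    t2 = np.sum((2 * n + 1) / (n * (n + 1)) * np.real(a * np.conj(b)))
    qs = scattering_efficiency(mie)
    return float((4.0 / mie.x**2) * (t1 + t2) / qs) if qs > 0 else 0.0


def _pi_tau(n_max: int, mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Angular functions pi_n, tau_n for n = 1..n_max at cos(theta) = mu."""
    mu = np.asarray(mu, dtype=float)
    pi = np.zeros((n_max + 1,) + mu.shape)
    tau = np.zeros_like(pi)
    pi[1] = 1.0
    tau[1] = mu
    for n in range(2, n_max + 1):
        pi[n] = ((2 * n - 1) * mu * pi[n - 1] - n * pi[n - 2]) / (n - 1)
        tau[n] = n * mu * pi[n] - (n + 1) * pi[n - 1]
    return pi[1:], tau[1:]


def amplitude_functions(mie: MieSolution, mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Far-field amplitude functions ``S1(cos theta), S2(cos theta)``."""
    pi_n, tau_n = _pi_tau(mie.n_max, np.asarray(mu))
    n = np.arange(1, mie.n_max + 1)
    w = ((2 * n + 1) / (n * (n + 1)))[:, None]
    a = mie.a[:, None]
    b = mie.b[:, None]
    mu = np.atleast_1d(mu)
    s1 = np.sum(w * (a * pi_n + b * tau_n), axis=0)
    s2 = np.sum(w * (a * tau_n + b * pi_n), axis=0)
    return s1, s2


def phase_function(mie: MieSolution, mu: np.ndarray) -> np.ndarray:
    """Azimuthally averaged, unnormalized scattered intensity ``(|S1|^2+|S2|^2)/2``."""
    s1, s2 = amplitude_functions(mie, mu)
    return 0.5 * (np.abs(s1) ** 2 + np.abs(s2) ** 2)


def exterior_fields(mie: MieSolution, points: np.ndarray, lambda_vac: float,
                    n_medium: float, field: str = "total"):
    """E, Z0*H and the time-averaged Poynting vector outside the sphere.

    The incident wave is a unit-amplitude x-polarized plane wave travelling
    along +z (``E_inc = x_hat exp(i k_med z)``).  ``points`` are Cartesian
    positions (um) relative to the sphere centre, all outside the sphere.
    ``field`` selects ``"total"``, ``"scattered"`` or ``"incident"``.

    Returns ``(E, H, S)`` with shapes ``(n_points, 3)``; ``S = Re(E x H*)/2``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    k_med = 2.0 * np.pi * n_medium / lambda_vac
    radius = mie.x / k_med
    r = np.linalg.norm(pts, axis=1)
    if np.any(r <= radius):
        raise ValueError("all points must lie outside the sphere radius")

    e = np.zeros((len(pts), 3), dtype=complex)
    h = np.zeros_like(e)
    if field in ("incident", "total"):
        phase = np.exp(1j * k_med * pts[:, 2])
        e[:, 0] += phase
        h[:, 1] += n_medium * phase
    if field in ("scattered", "total"):
        es, hs = _scattered_vsh(mie, pts, r, k_med, n_medium)
        e += es
        h += hs
    s = 0.5 * np.real(np.cross(e, np.conj(h)))
    return e, h, s


def _scattered_vsh(mie: MieSolution, pts: np.ndarray, r: np.ndarray,
                   k_med: float, n_medium: float):
    """Scattered field from the outgoing vector-spherical-harmonic expansion."""
    theta = np.arccos(np.clip(pts[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    mu = np.cos(theta)
    sin_t = np.sin(theta)
    rho = k_med * r
    nmax = mie.n_max
    n = np.arange(1, nmax + 1)

    jn = spherical_jn(n[:, None], rho[None, :])
    yn = spherical_yn(n[:, None], rho[None, :])
    hn = jn + 1j * yn
    jnp = spherical_jn(n[:, None], rho[None, :], derivative=True)
    ynp = spherical_yn(n[:, None], rho[None, :], derivative=True)
    hnp = jnp + 1j * ynp
    # (1/rho) d(rho h_n)/d(rho) = h_n/rho + h_n'
    dh = hn / rho[None, :] + hnp
    hr = hn / rho[None, :]

    pi_n, tau_n = _pi_tau(nmax, mu)
    en = (1j ** n * (2 * n + 1) / (n * (n + 1)))[:, None]
    a = mie.a[:, None]
    b = mie.b[:, None]

    cph, sph = np.cos(phi), np.sin(phi)

    # E_s = sum E_n (i a_n N^(3)_e1n - b_n M^(3)_o1n)
    er = np.sum(en * 1j * a * cph[None, :] * n[:, None] * (n[:, None] + 1)
                * sin_t[None, :] * pi_n * hr, axis=0)
    et = np.sum(en * (1j * a * cph[None, :] * tau_n * dh
                      - b * cph[None, :] * pi_n * hn), axis=0)
    ep = np.sum(en * (-1j * a * sph[None, :] * pi_n * dh
                      + b * sph[None, :] * tau_n * hn), axis=0)
    # Z0 H_s = n_med * sum E_n (i b_n N^(3)_o1n + a_n M^(3)_e1n)
    hr_c = n_medium * np.sum(en * 1j * b * sph[None, :] * n[:, None] * (n[:, None] + 1)
                             * sin_t[None, :] * pi_n * hr, axis=0)
    ht = n_medium * np.sum(en * (1j * b * sph[None, :] * tau_n * dh
                                 - a * sph[None, :] * pi_n * hn), axis=0)
    hp = n_medium * np.sum(en * (1j * b * cph[None, :] * pi_n * dh
                                 - a * cph[None, :] * tau_n * hn), axis=0)

    def sph_to_cart(fr, ft, fp):
        st, ct = sin_t, mu
        fx = fr * st * cph + ft * ct * cph - fp * sph
        fy = fr * st * sph + ft * ct * sph + fp * cph
        fz = fr * ct - ft * st
        return np.stack([fx, fy, fz], axis=1)

    return sph_to_cart(er, et, ep), sph_to_cart(hr_c, ht, hp)


def scattering_coefficient(sphere: SphereSpec, lambda_vac: float) -> float:
    """mu_s = concentration * sigma_s, in mm^-1 (independent scattering)."""
    mie = mie_coefficients(sphere, lambda_vac)
    sigma = scattering_cross_section(mie, lambda_vac, sphere.n_medium)
    return sphere.concentration * sigma * 1e3  # (um^-3 * um^2) -> mm^-1


def hann_band_spectrum(band_um: tuple[float, float] = (1.180, 1.420), n_k: int = 2048):
    """Hann-weighted spectral samples uniform in wavenumber over the band.

    Returns ``(k, S)`` with k in rad/um ascending and Hann weights that
    vanish at the band edges.
    """
    lam_min, lam_max = min(band_um), max(band_um)
    k = np.linspace(2.0 * np.pi / lam_max, 2.0 * np.pi / lam_min, n_k)
    s = np.hanning(n_k + 2)[1:-1]
    return k, s


def spectrum_weighted_mu_s(sphere: SphereSpec, wavenumbers: np.ndarray,
                           spectrum: np.ndarray) -> float:
    """Spectrum-weighted scattering coefficient in mm^-1.

    ``mu_s_eff = rho * sum(S_m sigma_s(k_m)) / sum(S_m)`` with ``S`` the
    (non-negative) spectral weights at vacuum wavenumbers ``k`` (rad/um).
    """
    k = np.asarray(wavenumbers, dtype=float)
    s = np.asarray(spectrum, dtype=float)
    if np.any(s < 0):
        raise ValueError("spectrum weights must be non-negative")
    tot = s.sum()
    if tot == 0:
        raise ValueError("spectrum is identically zero")
    sig = np.array([
        scattering_cross_section(mie_coefficients(sphere, 2.0 * np.pi / ki), 2.0 * np.pi / ki, sphere.n_medium)
        for ki in k
    ])
    return float(sphere.concentration * np.sum(s * sig) / tot * 1e3)
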