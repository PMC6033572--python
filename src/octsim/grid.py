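"""Computational grid and per-cell material description.

The solver works on a uniform cubic grid of cell size ``cell_size`` (isotropic
``delta``).  Cell ``(i, j, k)`` is centred at ``((i+1/2), (j+1/2), (k+1/2)) *
cell_size`` measured from the grid corner; the ``z`` axis is the optical axis,
pointing from the illumination plane into the sample.  Degenerate 1D/2D grids
are expressed with singleton axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

C_UM_FS = 0.299792458  # vacuum speed of light, um/fs


@dataclass
class GridSpec:
    """Uniform cubic grid with a perfectly-matched-layer (PML) border.

    Parameters
    ----------
    cell_size : float
        Isotropic cell edge length in micrometres.
    dims : tuple of int
        Cells per axis ``(nx, ny, nz)``.  Singleton axes give reduced 1D/2D
        problems.
    pml_thickness : int
        PML thickness in cells on each face of every non-singleton axis.
    pml_order : int
        Polynomial grading exponent of the PML conductivity profile.
    pml_target_reflection_db : float
        Design power reflection of the PML at normal incidence, in dB
        (negative).  Sets the peak conductivity of the graded profile.
    background_index : float
        Refractive index of the homogeneous background medium.
    """

    cell_size: float
    dims: tuple[int, int, int]
    pml_thickness: int = 10
    pml_order: int = 3
    pml_target_reflection_db: float = -60.0
    background_index: float = 1.0

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError("dims must be three positive integers")
        if self.pml_thickness < 0:
            raise ValueError("pml_thickness must be non-negative")
        if self.background_index < 1:
            raise ValueError("background_index must be >= 1")
        for d in self.dims:
            if d > 1 and d <= 2 * self.pml_thickness:
                raise ValueError("interior region empty after removing PML")

    @property
    def n_dim(self) -> int:
        """Number of non-singleton axes."""
        return sum(1 for d in self.dims if d > 1)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Cell-centre coordinates along ``axis`` in micrometres."""
        n = self.dims[axis]
        return (np.arange(n) + 0.5) * self.cell_size

    def validate_sampling(self, lambda_min_vac: float, n_max: float) -> None:
        """Check Nyquist sampling of the shortest in-medium wavelength."""
        if self.cell_size > lambda_min_vac / (2.0 * n_max):
            raise ValueError(
                f"cell_size {self.cell_size} um exceeds the Nyquist bound "
                f"{lambda_min_vac / (2 * n_max):.4g} um for lambda_min="
                f"{lambda_min_vac} um, n_max={n_max}"
            )

    def pml_sigma(self, axis: int, dt: float) -> np.ndarray | None:
        """Graded PML damping-rate profile (1/fs) along ``axis``.

        The profile rises polynomially from zero at the interior interface to
        a peak value on the outer boundary chosen so that the theoretical
        round-trip power reflection at normal incidence equals
        ``pml_target_reflection_db``.
        """
        n = self.dims[axis]
        t = self.pml_thickness
        if n == 1 or t == 0:
            return None
        v = C_UM_FS / self.background_index
        length = t * self.cell_size
        r_amp = 10.0 ** (self.pml_target_reflection_db / 20.0)
        sigma_max = -np.log(r_amp) * v * (self.pml_order + 1) / (2.0 * length)
        prof = np.zeros(n)
        # depth measured from the interior interface toward the boundary,
        # evaluated at cell centres
        depth = (np.arange(t) + 0.5) / t
        ramp = sigma_max * depth**self.pml_order
        prof[:t] = ramp[::-1]
        prof[n - t:] = ramp
        return prof


@dataclass
class MaterialMap:
    """Per-cell refractive index volume.

    The index is assumed uniform within each cell; permittivity is
    ``n**2 * eps0`` and permeability is fixed at ``mu0`` (non-magnetic,
    non-dispersive media).
    """

    grid: GridSpec
    n: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n is None:
            self.n = np.full(self.grid.dims, self.grid.background_index)
        self.n = np.asarray(self.n, dtype=float)
        if self.n.shape != tuple(self.grid.dims):
            raise ValueError(f"index array shape {self.n.shape} != grid dims {self.grid.dims}")
        if not np.all(np.isfinite(self.n)) or np.any(self.n < 1):
            raise ValueError("refractive indices must be finite and >= 1")

    @property
    def eps_rel(self) -> np.ndarray:
        return self.n**2

    @property
    def n_max(self) -> float:
        return float(self.n.max())

    @property
    def n_min(self) -> float:
        return float(self.n.min())

    def copy(self) -> "MaterialMap":
        return MaterialMap(self.grid, self.n.copy())

    @classmethod
    def homogeneous(cls, grid: GridSpec, n: float | None = None) -> "MaterialMap":
        val = grid.background_index if n is None else n
        return cls(grid, np.full(grid.dims, float(val)))
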