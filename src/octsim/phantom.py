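"""Numerical phantom construction.

Phantoms are MaterialMap volumes: a homogeneous embedding medium (silicone,
n = 1.42) with discrete scatterer designs stamped at Poisson-distributed
random positions inside user-supplied region masks (e.g. rasterized letter
glyphs).  Variants: structured letter phantoms at the design concentration,
sparse phantoms for point-spread-function measurement, and low-contrast
calibration phantoms (stamp index 1.421) used to measure the confocal
function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .grid import GridSpec, MaterialMap
from .design import ScattererDesign

__all__ = [
    "PhantomSpec",
    "place_scatterers",
    "build_letter_phantom",
    "build_psf_phantom",
    "build_calibration_phantom",
]

STAMP_HALF = 3  # scatterer bounding cube is 7^3 cells


@dataclass
class PhantomSpec:
    """Phantom recipe.

    ``mask``: boolean cell mask (grid dims) of the region receiving
    scatterers, or None for the whole interior; ``concentration`` in
    particles per cubic micrometre; ``clear_margin`` keeps stamp bounding
    cubes away from the grid edge (PML, source and detection planes).
    """

    grid: GridSpec
    scatterer: ScattererDesign
    concentration: float
    background_index: float = 1.42
    mask: np.ndarray | None = None
    seed: int = 0
    clear_margin: int | None = None

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != tuple(self.grid.dims):
                raise ValueError("mask shape must equal grid dims")
        if self.clear_margin is None:
            self.clear_margin = self.grid.pml_thickness + STAMP_HALF + 1

    def region_mask(self) -> np.ndarray:
        m = np.ones(self.grid.dims, dtype=bool) if self.mask is None else self.mask.copy()
        c = self.clear_margin
        for ax, dim in enumerate(self.grid.dims):
            if dim == 1:
                continue
            sl = [slice(None)] * 3
            sl[ax] = slice(0, min(c, dim))
            m[tuple(sl)] = False
            sl[ax] = slice(max(dim - c, 0), dim)
            m[tuple(sl)] = False
        return m


def place_scatterers(spec: PhantomSpec, max_failure_fraction: float = 0.3) -> np.ndarray:
    """Random scatterer centre cells inside the region mask.

    The count is Poisson(concentration * region volume); positions are
    uniform over the region cells (snapped to the lattice).  Stamp
    bounding-cube overlaps are resolved by rejection resampling; if more
    than ``max_failure_fraction`` of placement attempts fail the requested
    density is considered unreachable.
    Returns integer centre indices, shape (n, 3).
    """
    rng = np.random.default_rng(spec.seed)
    region = spec.region_mask()
    n_region = int(region.sum())
    volume = n_region * spec.grid.cell_size**3
    n_target = rng.poisson(spec.concentration * volume)
    if n_target == 0 or n_region == 0:
        return np.empty((0, 3), dtype=int)
    # candidate sampling: direct rejection against the mask for well-filled
    # regions, an explicit cell list for sparse masks
    fill = n_region / region.size
    cells = np.argwhere(region) if fill < 0.05 else None
    dims = np.array(spec.grid.dims)

    def draw():
        if cells is not None:
            return cells[rng.integers(len(cells))]
        while True:
            c = rng.integers(0, dims)
            if region[tuple(c)]:
                return c

    taken = np.zeros(spec.grid.dims, dtype=bool)
    placed = []
    overlap_failures = 0
    while len(placed) < n_target:
        c = draw()
        sl = tuple(slice(max(int(ci) - STAMP_HALF, 0), int(ci) + STAMP_HALF + 1)
                   for ci in c)
        if taken[sl].any():
            overlap_failures += 1
            attempts = len(placed) + overlap_failures
            if attempts > 20 and overlap_failures / attempts > max_failure_fraction:
                raise ValueError(
                    f"requested concentration too dense for non-overlapping stamps "
                    f"({overlap_failures}/{attempts} failed placements)")
            continue
        taken[sl] = True
        placed.append(np.asarray(c, dtype=int))
    return np.array(placed, dtype=int)


def _stamp(n_arr: np.ndarray, cube: np.ndarray, centre: np.ndarray,
           grid: GridSpec) -> None:
    lo = centre - STAMP_HALF
    hi = centre + STAMP_HALF + 1
    if np.any(lo < 0) or np.any(hi > np.array(grid.dims)):
        warnings.warn("scatterer stamp clipped at the volume edge")
        src_lo = np.maximum(-lo, 0)
        src_hi = (2 * STAMP_HALF + 1) - np.maximum(hi - np.array(grid.dims), 0)
        lo_c = np.maximum(lo, 0)
        hi_c = np.minimum(hi, np.array(grid.dims))
        n_arr[lo_c[0]:hi_c[0], lo_c[1]:hi_c[1], lo_c[2]:hi_c[2]] = \
            cube[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
        return
    n_arr[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = cube


def build_letter_phantom(spec: PhantomSpec) -> MaterialMap:
    """Structured scattering phantom: background at ``background_index``
    with scatterer cubes stamped at Poisson positions inside the mask."""
    centres = place_scatterers(spec)
    n_arr = np.full(spec.grid.dims, float(spec.background_index))
    cube = spec.scatterer.cube
    for c in centres:
        _stamp(n_arr, cube, c, spec.grid)
    return MaterialMap(spec.grid, n_arr)


def isolation_probability(concentration: float, min_spacing_um: float) -> float:
    """Probability that a scatterer's nearest neighbour in a Poisson process
    of the given density is farther than ``min_spacing_um``."""
    return float(np.exp(-concentration * 4.0 / 3.0 * np.pi * min_spacing_um**3))


def build_psf_phantom(spec: PhantomSpec, lateral_psf_fwhm_um: float = 8.0,
                      min_isolation_probability: float = 0.95) -> MaterialMap:
    """Sparse phantom of isolated scatterers for PSF measurement.

    Warns if the concentration is too high for scatterers to be isolated
    (nearest neighbour beyond 5 lateral PSF widths with the requested
    probability).
    """
    p_iso = isolation_probability(spec.concentration, 5.0 * lateral_psf_fwhm_um)
    if p_iso < min_isolation_probability:
        warnings.warn(
            f"concentration {spec.concentration} too dense for isolated PSFs "
            f"(isolation probability {p_iso:.3f})")
    return build_letter_phantom(spec)


def build_calibration_phantom(spec: PhantomSpec, stamp_index: float = 1.421) -> MaterialMap:
    """Low-scattering calibration phantom: identical placement machinery
    with the scattering cells set to a near-background index (default
    1.421 on a 1.42 background), so the average image measures the confocal
    function rather than sample attenuation."""
    base = spec.scatterer.cube
    weak = np.where(base != spec.background_index, stamp_index, spec.background_index)
    from .design import extract_octant

    weak_design = ScattererDesign(extract_octant(weak), cell_size=spec.scatterer.cell_size)
    weak_spec = PhantomSpec(spec.grid, weak_design, spec.concentration,
                            spec.background_index, spec.mask, spec.seed,
                            spec.clear_margin)
    return build_letter_phantom(weak_spec)
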