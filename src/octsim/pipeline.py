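"""End-to-end OCT simulation pipelines at reduced dimensionality.

The full imaging model chains: focused (or normally incident) illumination
injected at S_ill -> PSTD propagation through the sample -> incremental
fiber-coupling spectra on S_det -> interference with a reference (mirror)
run -> shot noise -> A-scan reconstruction.  The 1D reduction keeps every
stage of that chain on a (1, 1, nz) grid and is the workhorse for
end-to-end verification: a mirror at a known depth must reconstruct to a
peak at that optical depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import CouplingSpectrum, overlap_coupling
from .grid import GridSpec, MaterialMap, C_UM_FS
from .pstd import PSTDSolver, SourceSpec, SpectralProbe

__all__ = ["OCT1DSetup", "simulate_coupling_1d"]


@dataclass
class OCT1DSetup:
    """Geometry of the 1D reduced OCT simulation.

    Cells: source plane at ``source_index``, detection plane two cells
    deeper, reference mirror (perfect electric conductor) at
    ``reference_index``, all in a homogeneous medium of index
    ``n_medium``.  ``wavenumbers`` are the probed vacuum wavenumbers.
    """

    nz: int = 360
    cell_size: float = 1.3 / 6
    n_medium: float = 1.0
    source_index: int = 12
    detection_index: int = 14
    reference_index: int = 40
    pml: int = 16
    pml_target_reflection_db: float = -100.0
    pulse_width_fs: float = 12.0
    dt: float = 0.2
    wavenumbers: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.wavenumbers is None:
            self.wavenumbers = np.linspace(2 * np.pi / 1.420, 2 * np.pi / 1.180, 256)

    def optical_depth_of(self, z_index: int) -> float:
        """One-way optical path from the reference plane to ``z_index``."""
        return (z_index - self.reference_index) * self.cell_size * self.n_medium


def _run(setup: OCT1DSetup, materials: MaterialMap, pec_planes,
         e_ill_spectral=None, extra_time_fs: float = 0.0):
    grid = materials.grid
    src = SourceSpec(setup.source_index, np.array([[[1.0]], [[0.0]]], dtype=complex),
                     k0=0.5 * (setup.wavenumbers[0] + setup.wavenumbers[-1]),
                     W=setup.pulse_width_fs)
    solver = PSTDSolver(grid, materials, source=src, dt=setup.dt,
                        pec_planes=pec_planes)
    probes = [SpectralProbe(setup.wavenumbers, "plane_E",
                            plane_index=setup.detection_index)]
    if e_ill_spectral is not None:
        probes.append(SpectralProbe(setup.wavenumbers, "coupling",
                                    plane_index=setup.detection_index,
                                    e_ill_spectral=e_ill_spectral))
    length = grid.dims[2] * grid.cell_size * setup.n_medium
    t_end = src.t0 + 5 * src.W + 3.0 * length / C_UM_FS + extra_time_fs
    solver.run(int(t_end / solver.dt), probes=probes)
    return probes


def simulate_coupling_1d(setup: OCT1DSetup, sample_mirror_index: int | None = None,
                         sample_materials: MaterialMap | None = None) -> CouplingSpectrum:
    """Run the three 1D simulations of the detection model.

    Illumination-only (homogeneous grid) gives the spectral illumination
    field on S_det and ``alpha_ill``; a mirror at the reference plane gives
    ``alpha_ref``; the sample run (a mirror at ``sample_mirror_index``
    and/or explicit materials) gives ``alpha_tot``.
    """
    grid = GridSpec(setup.cell_size, (1, 1, setup.nz), pml_thickness=setup.pml,
                    pml_target_reflection_db=setup.pml_target_reflection_db,
                    background_index=setup.n_medium)
    homog = MaterialMap.homogeneous(grid)

    ill_probe, = _run(setup, homog, ())
    e_ill = ill_probe.E  # (n_k, 2, 1, 1)
    alpha_ill = overlap_coupling(e_ill, e_ill, setup.cell_size)

    _, ref_probe = _run(setup, homog, (setup.reference_index,), e_ill_spectral=e_ill)
    alpha_ref = ref_probe.alpha

    pec = () if sample_mirror_index is None else (sample_mirror_index,)
    mats = sample_materials if sample_materials is not None else homog
    _, tot_probe = _run(setup, mats, pec, e_ill_spectral=e_ill)
    alpha_tot = tot_probe.alpha

    return CouplingSpectrum(setup.wavenumbers, alpha_tot, alpha_ref, alpha_ill)
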