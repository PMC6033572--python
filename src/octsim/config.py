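"""YAML configuration: solver, optics and detector blocks."""

from __future__ import annotations

import numpy as np
import yaml

from .detection import DetectorModel, hann_window
from .focusing import OpticalSystemSpec
from .grid import GridSpec

__all__ = ["load_config", "grid_from_config", "optics_from_config", "detector_from_config"]


def load_config(path_or_stream):
    """Parse a YAML configuration file into spec objects.

    Recognized blocks: ``solver`` (cell_size_um, dims, dt_fs optional,
    n_iterations, pml{thickness, order, target_reflection_db}), ``optics``
    (f1_mm, f2_mm, Ra_mm, mfd_um, band_nm, lambda0_nm, n_k, polarization)
    and ``detector`` (eta or target_snr_db, seed, window, n_k).
    """
    if hasattr(path_or_stream, "read"):
        raw = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as f:
            raw = yaml.safe_load(f)
    out = {}
    if "solver" in raw:
        out["grid"], out["dt_fs"], out["n_iterations"] = grid_from_config(raw["solver"])
    if "optics" in raw:
        out["optics"] = optics_from_config(raw["optics"])
    if "detector" in raw:
        out["detector"] = detector_from_config(raw["detector"])
    return out


def grid_from_config(block: dict):
    pml = block.get("pml", {})
    grid = GridSpec(
        cell_size=float(block["cell_size_um"]),
        dims=tuple(block["dims"]),
        pml_thickness=int(pml.get("thickness", 10)),
        pml_order=int(pml.get("order", 3)),
        pml_target_reflection_db=float(pml.get("target_reflection_db", -60.0)),
        background_index=float(block.get("background_index", 1.0)),
    )
    return grid, block.get("dt_fs"), block.get("n_iterations")


def optics_from_config(block: dict) -> OpticalSystemSpec:
    return OpticalSystemSpec(
        f1=float(block.get("f1_mm", 25.0)),
        f2=float(block.get("f2_mm", 36.0)),
        Ra=float(block.get("Ra_mm", 3.5)),
        mfd=float(block.get("mfd_um", 9.2)),
        band=tuple(block.get("band_nm", (1180.0, 1420.0))),
        lambda0=float(block.get("lambda0_nm", 1300.0)),
        n_k=int(block.get("n_k", 2048)),
        polarization=tuple(block.get("polarization", (1.0, 0.0))),
    )


def detector_from_config(block: dict) -> DetectorModel:
    n_k = int(block.get("n_k", 2048))
    window = block.get("window", "hann")
    spectrum = hann_window(n_k) if window == "hann" else np.ones(n_k)
    return DetectorModel(eta=float(block.get("eta", 1.0)), spectrum=spectrum,
                         seed=block.get("seed"))
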