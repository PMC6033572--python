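"""File I/O: HDF5 material maps and fields, TIFF image export, region masks."""

from __future__ import annotations

import numpy as np

from .grid import GridSpec, MaterialMap

__all__ = [
    "save_material_map",
    "load_material_map",
    "save_focused_field",
    "save_bscan_tiff",
    "save_bscan_h5",
    "load_mask_png",
    "load_mask_rle",
]


def save_material_map(path, materials: MaterialMap) -> None:
    """Write the refractive-index volume (index order x, y, z) with grid
    metadata as HDF5 attributes."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("refractive_index", data=materials.n)
        d.attrs["cell_size_um"] = materials.grid.cell_size
        d.attrs["background_index"] = materials.grid.background_index
        d.attrs["pml_thickness"] = materials.grid.pml_thickness


def load_material_map(path) -> MaterialMap:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["refractive_index"]
        grid = GridSpec(float(d.attrs["cell_size_um"]), tuple(d.shape),
                        pml_thickness=int(d.attrs.get("pml_thickness", 10)),
                        background_index=float(d.attrs["background_index"]))
        return MaterialMap(grid, d[...])


def save_focused_field(path, field) -> None:
    """Write a FocusedField (complex components + plane metadata)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("e_real", data=field.e.real)
        f.create_dataset("e_imag", data=field.e.imag)
        f.create_dataset("x_um", data=field.x)
        f.create_dataset("y_um", data=field.y)
        f.attrs["plane_z_um"] = field.plane_z


def save_bscan_tiff(path, image_db: np.ndarray) -> None:
    """32-bit float TIFF of a B-scan on a dB SNR scale."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image_db, dtype=np.float32))


def save_bscan_h5(path, amplitude: np.ndarray, z_um: np.ndarray, x_um: np.ndarray) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("amplitude_real", data=amplitude.real)
        f.create_dataset("amplitude_imag", data=amplitude.imag)
        f.create_dataset("z_um", data=z_um)
        f.create_dataset("x_um", data=x_um)


def load_mask_png(path) -> np.ndarray:
    """Binary 2D mask from a PNG image (nonzero = inside)."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].max(axis=-1)
    return img > 0


def load_mask_rle(path) -> np.ndarray:
    """Binary 2D mask from run-length text: ``row start end`` per line
    (half-open column ranges), preceded by a header ``rows cols``."""
    with open(path) as f:
        first = f.readline().split()
        rows, cols = int(first[0]), int(first[1])
        mask = np.zeros((rows, cols), dtype=bool)
        for line in f:
            parts = line.split()
            if len(parts) != 3:
                continue
            r, a, b = (int(p) for p in parts)
            mask[r, a:b] = True
    return mask
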