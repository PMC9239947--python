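"""Reading and writing image stacks and quantitative maps as NIfTI.

Stacks are stored as a single 4-D NIfTI volume of shape (nx, ny, 1, 8) with
the 8 frames ordered (te1,ti1)..(te1,ti4), (te2,ti1)..(te2,ti4); fitted maps
as 3-D float32 volumes with the unit (ms where applicable) recorded in the
header description.  Study metadata travels in a CSV manifest.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import QuantMaps

__all__ = ["save_stack", "load_stack", "save_maps", "load_maps",
           "write_manifest", "read_manifest"]

_STACK_ORDER = "frames ordered te1xti1..te1xti4, te2xti1..te2xti4"


def _affine(fov_mm: float, grid: int) -> np.ndarray:
    px = fov_mm / grid
    aff = np.diag([px, px, 1.0, 1.0])
    aff[:2, 3] = -fov_mm / 2.0 + px / 2.0
    return aff


def save_stack(path, stack: np.ndarray, fov_mm: float = 240.0) -> None:
    """Write an (8, ny, nx) stack as a 4-D NIfTI file."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] != 8:
        raise ValueError(f"expected (8, ny, nx) stack, got {stack.shape}")
    grid = stack.shape[-1]
    vol = np.transpose(stack, (2, 1, 0))[:, :, None, :].astype(np.float32)
    img = nib.Nifti1Image(vol, _affine(fov_mm, grid))
    img.header["descrip"] = _STACK_ORDER.encode()[:79]
    nib.save(img, str(path))


def load_stack(path) -> np.ndarray:
    """Read a 4-D NIfTI stack back to (8, ny, nx)."""
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if vol.ndim != 4 or vol.shape[2] != 1 or vol.shape[3] != 8:
        raise ValueError(f"expected a (nx, ny, 1, 8) volume, got {vol.shape}")
    return np.transpose(vol[:, :, 0, :], (2, 1, 0))


_MAP_FIELDS = {
    "t1_map": "T1 map, ms",
    "t2_map": "T2 map, ms",
    "m0_map": "M0 (A*PD) map, arbitrary units",
    "b1_map": "relative B1 map, dimensionless",
    "residual_map": "fit residual RMS, arbitrary units",
    "converged_mask": "fit convergence mask",
}


def save_maps(out_dir, maps: QuantMaps, fov_mm: float = 240.0) -> list[Path]:
    """Write each fitted map as <name>.nii in ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fov = maps.fov_mm or fov_mm
    grid = maps.shape[-1]
    paths = []
    for field, descrip in _MAP_FIELDS.items():
        arr = np.asarray(getattr(maps, field))
        img = nib.Nifti1Image(arr.T.astype(np.float32)[:, :, None], _affine(fov, grid))
        img.header["descrip"] = descrip.encode()[:79]
        p = out_dir / f"{field}.nii"
        nib.save(img, str(p))
        paths.append(p)
    return paths


def load_maps(map_dir, fov_mm: float | None = None) -> QuantMaps:
    map_dir = Path(map_dir)
    arrays = {}
    for field in _MAP_FIELDS:
        vol = np.asarray(nib.load(str(map_dir / f"{field}.nii")).dataobj, dtype=float)
        arrays[field] = vol[:, :, 0].T
    arrays["converged_mask"] = arrays["converged_mask"] > 0.5
    return QuantMaps(fov_mm=fov_mm, **arrays)


def write_manifest(path, rows: list[dict]) -> None:
    """Write the study manifest (family, protocol, repeat, seed, file path)."""
    pd.DataFrame(rows, columns=["family", "protocol", "repeat_index",
                                "seed_entropy", "path"]).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)
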