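"""NIfTI / FSL-gradient-table input and output.

Readers accept FSL-style whitespace-separated bval/bvec files in either 3xN
or Nx3 layout (auto-detected); writers emit float32 NIfTI parameter maps,
RGB directionally-encoded-color maps, and a plain-text ground-truth sidecar
for phantom exports.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .scheme import AcquisitionScheme

__all__ = [
    "read_bval_bvec",
    "read_dwi",
    "write_dwi",
    "write_maps",
    "write_truth_sidecar",
    "read_truth_sidecar",
]

logger = logging.getLogger(__name__)


def read_bval_bvec(
    bval_path, bvec_path, delta: float = 1.9e-3, Delta: float = 2.0e-3
) -> AcquisitionScheme:
    """FSL-dialect gradient table -> AcquisitionScheme.

    bvecs may be 3 rows x N columns (FSL convention) or N x 3; the layout is
    auto-detected from the shape.  b0 rows may carry the zero vector.  A
    diffusion-weighted direction whose norm deviates from 1 by more than 1e-3
    is a format error naming the offending entry; small deviations are
    renormalized.
    """
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL files put measurements in columns
        bvecs = bvecs.T
    elif bvecs.shape == (3, bvals.size):
        bvecs = bvecs.T
    elif bvecs.shape == (bvals.size, 3):
        pass
    else:
        raise ValueError(
            f"bvec shape {bvecs.shape} incompatible with {bvals.size} b-values"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    for i, (b, n) in enumerate(zip(bvals, norms)):
        if b > 0 and abs(n - 1.0) > 1e-3:
            raise ValueError(
                f"gradient direction {i} has norm {n:.5f} (b={b:g}); "
                "expected a unit vector"
            )
    dwi = (bvals > 0) & (norms > 0)
    bvecs[dwi] /= norms[dwi, None]
    bvecs[~dwi] = 0.0
    return AcquisitionScheme(bvals, bvecs, delta=delta, Delta=Delta)


def read_dwi(
    image_path, bval_path, bvec_path, delta: float = 1.9e-3, Delta: float = 2.0e-3
) -> Tuple[np.ndarray, "nib.Nifti1Image", AcquisitionScheme]:
    """Load a 4D DWI NIfTI and its gradient table.

    Returns (data, image, scheme); the number of volumes must equal the
    gradient-table length.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D DWI volume, got {data.ndim}D")
    scheme = read_bval_bvec(bval_path, bvec_path, delta, Delta)
    if data.shape[-1] != len(scheme):
        raise ValueError(
            f"{data.shape[-1]} volumes but {len(scheme)} gradient-table entries"
        )
    return data, img, scheme


def write_dwi(
    out_prefix,
    data: np.ndarray,
    scheme: AcquisitionScheme,
    affine: Optional[np.ndarray] = None,
) -> Dict[str, Path]:
    """Write a 4D volume + FSL bval/bvec triple with a common prefix."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    paths = {
        "dwi": out_prefix.with_suffix(".nii"),
        "bval": out_prefix.parent / (out_prefix.name + ".bval"),
        "bvec": out_prefix.parent / (out_prefix.name + ".bvec"),
    }
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), paths["dwi"])
    np.savetxt(paths["bval"], scheme.bvals[None, :], fmt="%g")
    np.savetxt(paths["bvec"], scheme.bvecs.T, fmt="%.8f")
    return paths


def write_maps(
    maps: Dict[str, np.ndarray],
    out_dir,
    affine: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
    reference: Optional["nib.Nifti1Image"] = None,
) -> Dict[str, Path]:
    """Write fitted parameter maps as float32 NIfTI files.

    3D maps are written directly; the principal-direction entries become
    FA-weighted RGB (directionally encoded color) 4D maps.  Masked-out voxels
    are zero.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if reference is not None:
        if affine is not None and not np.allclose(reference.affine, affine):
            raise ValueError("reference header and affine disagree")
        affine = reference.affine
    if affine is None:
        affine = np.eye(4)
    written = {}
    for name, arr in maps.items():
        arr = np.asarray(arr, dtype=np.float32)
        if name.startswith("dir_"):
            fa_key = "fa_" + name[len("dir_"):]
            weight = np.asarray(maps.get(fa_key, np.ones(arr.shape[:3])), dtype=np.float32)
            arr = np.abs(arr) * weight[..., None]
        if mask is not None:
            arr = arr * np.asarray(mask, bool)[..., None] if arr.ndim == 4 else arr * np.asarray(mask, bool)
        path = out_dir / f"{name}.nii"
        nib.save(nib.Nifti1Image(arr, affine), path)
        written[name] = path
    return written


def write_truth_sidecar(path, truth: Dict[str, np.ndarray]) -> Path:
    """Plain-text ground-truth table, one row per voxel.

    Columns: voxel indices, S0, f, six D* and six D Cholesky components.
    """
    path = Path(path)
    shape = truth["s0"].shape
    rows = []
    for ix in range(shape[0]):
        for iy in range(shape[1]):
            for iz in range(shape[2]):
                row = {
                    "ix": ix,
                    "iy": iy,
                    "iz": iz,
                    "s0": truth["s0"][ix, iy, iz],
                    "f": truth["f"][ix, iy, iz],
                }
                for k in range(6):
                    row[f"u{k + 1}"] = truth["d_star"][ix, iy, iz, k]
                    row[f"v{k + 1}"] = truth["d"][ix, iy, iz, k]
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_truth_sidecar(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
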