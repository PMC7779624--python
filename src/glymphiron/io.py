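"""Readers and writers: NIfTI volumes with a units sidecar, FSL-dialect
bval/bvec gradient files, label-map legends and cohort CSV tables.

Units ride in a JSON sidecar (``<stem>.units.json``) next to each volume
rather than in NIfTI header intent codes, which are unreliable across tools.
All voxel coordinates in this package are 0-based array indices.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .alps import GradientTable
from .cohort import COHORT_COLUMNS
from .errors import ValidationError
from .grids import VolumeGrid
from .qsm import NucleusLabelMap

logger = logging.getLogger(__name__)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".units.json")
    return path.with_suffix(".units.json")


def write_volume(vol: VolumeGrid, path: str | Path) -> Path:
    """Write a VolumeGrid as NIfTI-1 plus a units sidecar."""
    path = Path(path)
    affine = np.diag([*vol.voxel_size, 1.0])
    data = vol.data
    if vol.units == "mask":
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(vol.voxel_size))
    nib.save(img, path)
    sidecar = {"units": vol.units, "b0_dir": list(map(float, vol.b0_dir))}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path: str | Path, units: str | None = None) -> VolumeGrid:
    """Read a 3-D NIfTI volume (.nii or .nii.gz).

    Units come from the sidecar when present, else from the ``units``
    argument; with neither, the volume is tagged ``dimensionless``.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"volume not found: {path}")
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # corrupt header / not a NIfTI
        raise ValidationError(f"could not read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3-D volume, got ndim={data.ndim}")
    voxel = np.asarray(img.header.get_zooms()[:3], dtype=float)

    b0_dir = np.array([0.0, 0.0, 1.0])
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        units = meta.get("units", units)
        b0_dir = np.asarray(meta.get("b0_dir", b0_dir), dtype=float)
    if units is None:
        units = "dimensionless"
    data = np.asarray(data, dtype=np.uint8 if units == "mask" else float)
    return VolumeGrid(data=data, voxel_size=voxel, b0_dir=b0_dir, units=units)


def read_label_map(path: str | Path, legend_path: str | Path) -> NucleusLabelMap:
    """Integer NIfTI label volume plus JSON legend {label: nucleus-name}."""
    path, legend_path = Path(path), Path(legend_path)
    if not legend_path.exists():
        raise ValidationError(f"legend not found: {legend_path}")
    img = nib.load(path)
    labels = np.asanyarray(img.dataobj)
    if labels.ndim != 3:
        raise ValidationError(f"{path}: label map must be 3-D")
    if not np.allclose(labels, np.round(labels)):
        raise ValidationError(f"{path}: label map contains non-integer values")
    legend = {int(k): str(v) for k, v in json.loads(legend_path.read_text()).items()}
    return NucleusLabelMap(labels=labels.astype(np.int32), legend=legend)


def write_label_map(labels: NucleusLabelMap, path: str | Path, legend_path: str | Path,
                    voxel_size=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag([*voxel_size, 1.0])
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), affine), Path(path))
    Path(legend_path).write_text(
        json.dumps({str(k): v for k, v in labels.legend.items()}, indent=1)
    )


# ---------------------------------------------------------------------------
# Gradient tables (FSL dialect)
# ---------------------------------------------------------------------------

def read_gradients(bval_path: str | Path, bvec_path: str | Path) -> GradientTable:
    """Read FSL-style whitespace-separated .bval/.bvec files.

    bvec rows are the x, y, z components. Non-unit b > 0 directions are
    normalised with a warning; b = 0 rows get zero vectors.
    """
    bval_path, bvec_path = Path(bval_path), Path(bvec_path)
    try:
        bvals = np.loadtxt(bval_path, ndmin=1)
        bvecs = np.loadtxt(bvec_path, ndmin=2)
    except Exception as exc:
        raise ValidationError(f"could not parse gradient files: {exc}") from exc
    if bvecs.shape[0] != 3:
        raise ValidationError(
            f"{bvec_path}: expected 3 rows (x, y, z), got {bvecs.shape[0]}"
        )
    bvecs = bvecs.T
    if len(bvals) != len(bvecs):
        raise ValidationError(
            f"bval has {len(bvals)} entries but bvec has {len(bvecs)} columns"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    dwi = bvals > 0
    off = dwi & (np.abs(norms - 1.0) > 1e-6)
    if np.any(off):
        logger.warning("normalising %d non-unit gradient directions", int(off.sum()))
        bvecs[off] /= norms[off, None]
    bvecs[~dwi] = 0.0
    return GradientTable(bvals=bvals, bvecs=bvecs)


def write_gradients(gtab: GradientTable, bval_path: str | Path, bvec_path: str | Path) -> None:
    Path(bval_path).write_text(" ".join(f"{b:g}" for b in gtab.bvals) + "\n")
    rows = [" ".join(f"{v:.8f}" for v in gtab.bvecs[:, i]) for i in range(3)]
    Path(bvec_path).write_text("\n".join(rows) + "\n")


def write_dwi(volumes: np.ndarray, voxel_size, path: str | Path) -> None:
    affine = np.diag([*voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volumes, dtype=np.float32), affine), Path(path))


def read_dwi(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """4-D DWI volume; returns (data, voxel_size)."""
    img = nib.load(Path(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValidationError(f"{path}: expected a 4-D DWI series, got ndim={data.ndim}")
    return data, np.asarray(img.header.get_zooms()[:3], dtype=float)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path) -> pd.DataFrame:
    """Cohort CSV with the canonical column set."""
    df = pd.read_csv(Path(path))
    missing = sorted(set(COHORT_COLUMNS) - set(df.columns))
    if missing:
        raise ValidationError(f"cohort CSV lacks columns: {missing}")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), index=False)
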