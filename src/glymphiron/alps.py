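"""Diffusion-tensor fitting and the ALPS (diffusivity along the perivascular
space) index.

The ALPS construction rests on the anatomy at the level of the lateral
ventricle body: medullary veins (and their perivascular spaces) run
left-right (array x axis), projection fibres run superior-inferior (z) and
association fibres anterior-posterior (y). Water diffusivity measured along
x inside projection- and association-fibre ROIs is therefore perivascular
diffusivity unconfounded by the dominant fibre direction, and

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

is greater than 1 when perivascular diffusion is free, approaching 1 as it
becomes as restricted as the cross-fibre directions. Tensors are fitted by
log-linear least squares; ROIs are 5-mm-diameter in-plane disks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .errors import ComputeError, ValidationError
from .grids import VolumeGrid

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GradientTable:
    """Diffusion-encoding table: b-values (s/mm^2) and unit directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValidationError("bvecs must be an (n, 3) array")
        if len(self.bvals) != len(self.bvecs):
            raise ValidationError(
                f"bvals ({len(self.bvals)}) and bvecs ({len(self.bvecs)}) lengths differ"
            )
        dwi = self.bvals > 0
        if not np.any(~dwi):
            raise ValidationError("gradient table needs at least one b = 0 entry")
        norms = np.linalg.norm(self.bvecs[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValidationError("every b > 0 direction must be unit length within 1e-6")
        distinct = np.unique(np.round(self.bvecs[dwi], 6), axis=0)
        if len(distinct) < 6:
            raise ValidationError(
                f"need at least 6 distinct b > 0 directions, got {len(distinct)}"
            )

    def __len__(self) -> int:
        return len(self.bvals)


@dataclass
class DWISeries:
    """4-D diffusion-weighted signal with 3-D geometry carried by ``grid``."""

    volumes: np.ndarray
    grid: VolumeGrid

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim != 4:
            raise ValidationError("DWI series must be 4-D (x, y, z, acquisition)")
        if self.volumes.shape[:3] != self.grid.shape:
            raise ValidationError(
                f"DWI spatial shape {self.volumes.shape[:3]} does not match "
                f"grid {self.grid.shape}"
            )
        if np.any(self.volumes < 0):
            raise ValidationError("DWI signals must be non-negative")


# Lower-triangular component order used throughout.
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")
_IDX = {c: i for i, c in enumerate(TENSOR_COMPONENTS)}


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor (mm^2/s) with derived quantities.

    ``components`` stores (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) on the last axis.
    ``valid`` marks voxels with a usable fit; voxels with non-positive input
    signal are flagged invalid and excluded from ROI statistics. Negative
    eigenvalues are flagged, never silently clipped.
    """

    components: np.ndarray
    valid: np.ndarray
    grid: VolumeGrid

    def __post_init__(self) -> None:
        if self.components.shape[-1] != 6 or self.components.ndim != 4:
            raise ValidationError("components must have shape (x, y, z, 6)")
        if self.valid.shape != self.components.shape[:3]:
            raise ValidationError("valid mask shape must match the spatial shape")

    def component(self, name: str) -> np.ndarray:
        return self.components[..., _IDX[name]]

    @cached_property
    def _matrices(self) -> np.ndarray:
        c = self.components
        mat = np.empty(c.shape[:3] + (3, 3))
        mat[..., 0, 0] = c[..., 0]
        mat[..., 0, 1] = mat[..., 1, 0] = c[..., 1]
        mat[..., 0, 2] = mat[..., 2, 0] = c[..., 2]
        mat[..., 1, 1] = c[..., 3]
        mat[..., 1, 2] = mat[..., 2, 1] = c[..., 4]
        mat[..., 2, 2] = c[..., 5]
        return mat

    @cached_property
    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues sorted descending (l1 >= l2 >= l3) and eigenvectors.

        ``eigenvectors[..., :, i]`` is the unit eigenvector of eigenvalue i.
        """
        w, v = np.linalg.eigh(self._matrices)  # ascending
        return w[..., ::-1], v[..., :, ::-1]

    @cached_property
    def negative_eigenvalues(self) -> np.ndarray:
        """Boolean map of voxels whose fitted tensor is not positive definite."""
        return self.eigen[0][..., 2] < 0

    @cached_property
    def fa(self) -> np.ndarray:
        """Fractional anisotropy, clipped to [0, 1] (negative-eigenvalue voxels
        can otherwise exceed 1; they remain flagged separately)."""
        w = self.eigen[0]
        mean = w.mean(axis=-1, keepdims=True)
        num = np.sum((w - mean) ** 2, axis=-1)
        den = np.sum(w**2, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.sqrt(1.5 * num / den)
        fa = np.where(den > 0, fa, 0.0)
        return np.clip(fa, 0.0, 1.0)

    @cached_property
    def principal_direction(self) -> np.ndarray:
        """Unit eigenvector of the largest eigenvalue, shape (x, y, z, 3)."""
        return self.eigen[1][..., :, 0]


@dataclass(frozen=True)
class AlpsRois:
    """Placement of the two ALPS disks on one axial slice.

    Centres are 0-based in-plane voxel coordinates (i, j); the disks live on
    ``slice_index`` along the third array axis. Placement is an explicit
    input: the phantom generator emits ground-truth centres, and real use
    would take the radiologist's coordinates.
    """

    slice_index: int
    projection_center: tuple[float, float]
    association_center: tuple[float, float]
    diameter_mm: float = 5.0
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        if tuple(self.projection_center) == tuple(self.association_center):
            raise ValidationError("projection and association centres must be distinct")
        if not self.diameter_mm > 0:
            raise ValidationError("diameter_mm must be > 0")


@dataclass(frozen=True)
class AlpsResult:
    """The four ROI-mean diagonal diffusivities (mm^2/s) and the index."""

    d_xproj: float
    d_xassoc: float
    d_yproj: float
    d_zassoc: float
    alps_index: float
    n_proj: int
    n_assoc: int

    def to_dict(self) -> dict[str, float]:
        return {
            "Dxproj": self.d_xproj,
            "Dxassoc": self.d_xassoc,
            "Dyproj": self.d_yproj,
            "Dzassoc": self.d_zassoc,
            "alps_index": self.alps_index,
            "n_proj": self.n_proj,
            "n_assoc": self.n_assoc,
        }


# ---------------------------------------------------------------------------
# Tensor fitting
# ---------------------------------------------------------------------------

def design_matrix(gtab: GradientTable) -> np.ndarray:
    """Log-linear design: columns (ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)."""
    b = gtab.bvals
    g = gtab.bvecs
    return np.column_stack(
        [
            np.ones(len(gtab)),
            -b * g[:, 0] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -b * g[:, 1] ** 2,
            -2 * b * g[:, 1] * g[:, 2],
            -b * g[:, 2] ** 2,
        ]
    )


def fit_tensor(
    dwi: DWISeries,
    gtab: GradientTable,
    mask: VolumeGrid,
    weighted: bool = False,
) -> TensorField:
    """Fit a diffusion tensor per voxel by (optionally weighted) log-linear
    least squares.

    The model is ``ln S = ln S0 - b g^T D g`` with S0 estimated jointly. The
    unweighted fit solves one shared pseudo-inverse applied to all voxels;
    the weighted variant re-weights each voxel's residuals by its squared
    signal (the first-order variance correction for log-transformed data).
    Voxels containing any non-positive signal inside the mask are flagged
    invalid and excluded, never fitted.
    """
    dwi.grid.require_same_geometry(mask, "fit_tensor")
    if dwi.volumes.shape[3] != len(gtab):
        raise ValidationError(
            f"DWI has {dwi.volumes.shape[3]} volumes but the gradient table "
            f"has {len(gtab)} entries"
        )
    m = mask.data.astype(bool)
    signals = dwi.volumes[m]  # (nvox, nacq)
    positive = np.all(signals > 0, axis=1)
    n_bad = int(np.count_nonzero(~positive))
    if n_bad:
        logger.warning(
            "%d in-mask voxels contain non-positive signal and were excluded", n_bad
        )

    X = design_matrix(gtab)
    y = np.log(signals[positive])
    if not weighted:
        beta = y @ np.linalg.pinv(X).T
    else:
        w = signals[positive] ** 2  # (nvox, nacq)
        xtx = np.einsum("vk,ki,kj->vij", w, X, X)
        xty = np.einsum("vk,ki,vk->vi", w, X, y)
        beta = np.linalg.solve(xtx, xty[..., None])[..., 0]

    comps = np.zeros(dwi.grid.shape + (6,))
    flat_idx = np.flatnonzero(m.ravel())[positive]
    comps.reshape(-1, 6)[flat_idx] = beta[:, 1:]
    valid = np.zeros(dwi.grid.shape, dtype=bool)
    valid.ravel()[flat_idx] = True
    return TensorField(components=comps, valid=valid, grid=dwi.grid)


def color_fa(tensors: TensorField) -> np.ndarray:
    """Directionally encoded colour map: |principal direction| * FA.

    Red encodes left-right (x), green anterior-posterior (y), blue
    superior-inferior (z); values lie in [0, 1]^3.
    """
    rgb = np.abs(tensors.principal_direction) * tensors.fa[..., None]
    rgb[~tensors.valid] = 0.0
    return np.clip(rgb, 0.0, 1.0)


# ---------------------------------------------------------------------------
# ROI placement and the index
# ---------------------------------------------------------------------------

def circle_mask(rois: AlpsRois, grid: VolumeGrid) -> tuple[VolumeGrid, VolumeGrid]:
    """Binary masks of the two in-plane disks.

    A voxel belongs to a disk when its in-plane centre distance to the ROI
    centre is at most half the diameter (distances in mm). A diameter smaller
    than one voxel degenerates to the single centre voxel.
    """
    if not 0 <= rois.slice_index < grid.shape[2]:
        raise ValidationError(
            f"slice {rois.slice_index} outside volume of {grid.shape[2]} slices"
        )
    radius = rois.diameter_mm / 2.0
    vx, vy = grid.voxel_size[0], grid.voxel_size[1]
    masks = []
    for ci, cj in (rois.projection_center, rois.association_center):
        if not (0 <= ci < grid.shape[0] and 0 <= cj < grid.shape[1]):
            raise ValidationError(f"ROI centre ({ci}, {cj}) outside the volume")
        if (
            (ci - radius / vx) < -0.5 or (ci + radius / vx) > grid.shape[0] - 0.5
            or (cj - radius / vy) < -0.5 or (cj + radius / vy) > grid.shape[1] - 0.5
        ):
            raise ValidationError(
                f"5-mm disk at ({ci}, {cj}) exits the volume {grid.shape[:2]}"
            )
        ii = (np.arange(grid.shape[0]) - ci) * vx
        jj = (np.arange(grid.shape[1]) - cj) * vy
        inplane = ii[:, None] ** 2 + jj[None, :] ** 2 <= radius**2 + 1e-12
        if not inplane.any():  # sub-voxel diameter: keep the centre voxel
            inplane = np.zeros(grid.shape[:2], dtype=bool)
            inplane[int(round(ci)), int(round(cj))] = True
        vol = np.zeros(grid.shape, dtype=np.uint8)
        vol[:, :, rois.slice_index] = inplane
        masks.append(VolumeGrid(vol, grid.voxel_size, grid.b0_dir, units="mask"))
    return masks[0], masks[1]


def alps_index(tensors: TensorField, rois: AlpsRois) -> AlpsResult:
    """Compute the ALPS index from fitted tensors and ROI placement.

    Dxproj and Dyproj are means of Dxx and Dyy over the projection-fibre
    disk; Dxassoc and Dzassoc are means of Dxx and Dzz over the
    association-fibre disk. The index is
    ``(Dxproj + Dxassoc) / (Dyproj + Dzassoc)``.
    """
    proj, assoc = circle_mask(rois, tensors.grid)
    pm = proj.data.astype(bool) & tensors.valid
    am = assoc.data.astype(bool) & tensors.valid
    if not pm.any() or not am.any():
        raise ComputeError("an ALPS ROI contains no voxel with a valid tensor fit")
    d_xproj = float(tensors.component("Dxx")[pm].mean())
    d_yproj = float(tensors.component("Dyy")[pm].mean())
    d_xassoc = float(tensors.component("Dxx")[am].mean())
    d_zassoc = float(tensors.component("Dzz")[am].mean())
    denom = d_yproj + d_zassoc
    if denom <= 0:
        raise ComputeError(
            f"non-physical denominator Dyproj + Dzassoc = {denom:.3e} <= 0"
        )
    return AlpsResult(
        d_xproj=d_xproj,
        d_xassoc=d_xassoc,
        d_yproj=d_yproj,
        d_zassoc=d_zassoc,
        alps_index=(d_xproj + d_xassoc) / denom,
        n_proj=int(pm.sum()),
        n_assoc=int(am.sum()),
    )
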