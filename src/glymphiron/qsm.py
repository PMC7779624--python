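"""Quantitative susceptibility mapping (QSM).

The chain implemented here recovers a tissue susceptibility map (chi, in ppm)
from an unwrapped gradient-echo phase volume:

1. ``phase_to_frequency`` — divide phase by 2*pi*TE to obtain a raw frequency
   map (Hz), then ``frequency_to_ppm`` normalises by gamma*B0.
2. ``sharp_remove_background`` — remove the harmonic background field caused
   by sources outside the brain, exploiting the spherical mean value (SMV)
   property of harmonic functions, with a variable-radius kernel schedule and
   truncated deconvolution.
3. ``lsqr_invert`` — invert the k-space dipole convolution
   D(k) = 1/3 - (k . b0)^2 / |k|^2 by iterative least squares (LSQR).
4. ``roi_means`` — per-nucleus mean susceptibility over an integer label map.

Sign convention: paramagnetic (iron-rich) tissue is positive chi. The mean of
chi is unobservable when D(0) = 0, so maps are conventionally re-referenced to
the brain-mask mean (``reference_to_mask_mean``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import fft as sfft
from scipy import ndimage
from scipy.sparse.linalg import LinearOperator, lsqr

from .errors import ComputeError, ValidationError
from .grids import AcquisitionParams, VolumeGrid

logger = logging.getLogger(__name__)

#: The seven deep gray-matter nuclei quantified for iron content.
NUCLEI = (
    "caudate nucleus",
    "putamen",
    "globus pallidus",
    "thalamus",
    "red nucleus",
    "substantia nigra",
    "dentate nucleus",
)

#: Canonical cohort-table column per nucleus.
NUCLEUS_COLUMNS = {
    "caudate nucleus": "qsm_caudate",
    "putamen": "qsm_putamen",
    "globus pallidus": "qsm_pallidus",
    "thalamus": "qsm_thalamus",
    "red nucleus": "qsm_red",
    "substantia nigra": "qsm_nigra",
    "dentate nucleus": "qsm_dentate",
}


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SharpParams:
    """Background-removal settings.

    ``radii_mm`` is a strictly descending schedule of SMV kernel radii; each
    voxel uses the largest radius whose sphere fits inside the brain mask, so
    small radii keep the edge shell usable. ``svd_threshold`` truncates the
    deconvolution by ``1 - S(k)`` wherever its magnitude falls below the
    threshold. ``erosion`` (voxels) erodes the mask edge where even the
    smallest kernel exits the brain; ``None`` selects
    ``ceil(min(radii) / max(voxel size))``, the variable-radius convention
    that sacrifices only the shell no kernel can cover.
    """

    radii_mm: tuple[float, ...] = (5.0, 4.0, 3.0, 2.0, 1.0)
    svd_threshold: float = 0.05
    erosion: int | None = None

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii_mm)
        object.__setattr__(self, "radii_mm", radii)
        if len(radii) == 0 or any(r <= 0 for r in radii):
            raise ValidationError("radii_mm must be non-empty and all > 0")
        if any(a <= b for a, b in zip(radii, radii[1:])):
            raise ValidationError(f"radii_mm must be strictly descending, got {radii}")
        if not 0 < self.svd_threshold < 1:
            raise ValidationError(
                f"svd_threshold must lie in (0, 1), got {self.svd_threshold}"
            )
        if self.erosion is not None and self.erosion < 0:
            raise ValidationError("erosion must be >= 0")


@dataclass(frozen=True)
class InversionParams:
    """LSQR dipole-inversion settings.

    ``d_at_zero`` is the value assigned to the dipole kernel at k = 0, where
    the physical kernel is undefined; 0 leaves the volume mean of chi in the
    null space (the standard convention).
    """

    max_iter: int = 50
    atol: float = 1e-6
    d_at_zero: float = 0.0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if not self.atol > 0:
            raise ValidationError("atol must be > 0")


@dataclass
class NucleusLabelMap:
    """Integer label volume plus a legend mapping label -> nucleus name."""

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("label map must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("label map must be integer-valued")
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        names = list(self.legend.values())
        if len(set(names)) != len(names):
            raise ValidationError("legend nucleus names must be distinct")
        unknown = sorted(set(names) - set(NUCLEI))
        if unknown:
            raise ValidationError(f"legend contains unknown nuclei: {unknown}")
        present = np.unique(self.labels)
        present = present[present != 0]
        missing = sorted(set(present.tolist()) - set(self.legend))
        if missing:
            raise ValidationError(
                f"label values {missing} present in the volume but absent from the legend"
            )


# ---------------------------------------------------------------------------
# Frequency conversion
# ---------------------------------------------------------------------------

def phase_to_frequency(
    phase: VolumeGrid,
    acq: AcquisitionParams,
    mask: VolumeGrid | None = None,
    check_wraps: bool = True,
) -> VolumeGrid:
    """Convert an unwrapped phase volume (radians) to a frequency map (Hz).

    The voxelwise relation is ``f = phase / (2 pi TE)``. Phase is assumed
    already unwrapped; when ``check_wraps`` is set, neighbouring in-mask
    voxels differing by more than pi raise an error instead of being silently
    unwrapped.
    """
    if phase.units != "radians":
        raise ValidationError(f"expected phase in radians, got units={phase.units!r}")
    data = phase.data
    region = np.ones(phase.shape, dtype=bool)
    if mask is not None:
        phase.require_same_geometry(mask, "phase_to_frequency")
        region = mask.data.astype(bool)
    bad = int(np.count_nonzero(~np.isfinite(data) & region))
    if bad:
        raise ValidationError(f"phase contains {bad} non-finite voxels inside the mask")
    if check_wraps:
        _check_unwrapped(data, region)
    freq = data / (2.0 * np.pi * acq.te_s)
    return phase.with_data(freq, units="Hz")


def _check_unwrapped(phase: np.ndarray, region: np.ndarray) -> None:
    """Raise if any in-region neighbour pair jumps by more than pi."""
    for axis in range(3):
        d = np.abs(np.diff(phase, axis=axis))
        both = np.logical_and(
            np.take(region, range(0, region.shape[axis] - 1), axis=axis),
            np.take(region, range(1, region.shape[axis]), axis=axis),
        )
        if np.any(d[both] > np.pi):
            raise ValidationError(
                "phase jumps exceeding pi between neighbouring in-mask voxels "
                "suggest wrapped phase; unwrap before calling"
            )


def frequency_to_ppm(freq: VolumeGrid, acq: AcquisitionParams) -> VolumeGrid:
    """Normalise a frequency map (Hz) to parts-per-million field shift."""
    if freq.units != "Hz":
        raise ValidationError(f"expected frequency in Hz, got units={freq.units!r}")
    ppm = freq.data / (acq.gamma_hz_per_tesla * acq.b0_tesla) * 1e6
    return freq.with_data(ppm, units="ppm")


# ---------------------------------------------------------------------------
# Spherical-mean-value kernels
# ---------------------------------------------------------------------------

def _smv_wrapped(shape: tuple[int, ...], voxel: tuple[float, ...], radius: float) -> np.ndarray:
    """SMV kernel in wrapped (FFT) layout: centre at index (0, 0, 0)."""
    offs = [sfft.fftfreq(n, 1.0 / n) * v for n, v in zip(shape, voxel)]
    d2 = (
        offs[0][:, None, None] ** 2
        + offs[1][None, :, None] ** 2
        + offs[2][None, None, :] ** 2
    )
    inside = d2 <= radius**2 + 1e-12
    kernel = inside.astype(float)
    return kernel / kernel.sum()


@lru_cache(maxsize=64)
def _smv_rfft(shape: tuple[int, ...], voxel: tuple[float, ...], radius: float) -> np.ndarray:
    return sfft.rfftn(_smv_wrapped(shape, voxel, radius)).real


def smv_kernel(radius_mm: float, grid: VolumeGrid) -> np.ndarray:
    """Spherical-mean-value kernel on the grid, centred, summing to one.

    A voxel belongs to the sphere when its centre lies within ``radius_mm`` of
    the kernel centre (distances in mm via the grid's voxel size).
    """
    if radius_mm < float(np.max(grid.voxel_size)):
        raise ValidationError(
            f"SMV radius {radius_mm} mm is smaller than one voxel "
            f"(voxel size {grid.voxel_size} mm)"
        )
    wrapped = _smv_wrapped(grid.shape, tuple(grid.voxel_size), float(radius_mm))
    return np.fft.fftshift(wrapped)


# ---------------------------------------------------------------------------
# SHARP background removal
# ---------------------------------------------------------------------------

def sharp_remove_background(
    freq: VolumeGrid,
    mask: VolumeGrid,
    params: SharpParams = SharpParams(),
) -> tuple[VolumeGrid, VolumeGrid]:
    """Remove the harmonic background field with variable-radius SMV filtering.

    Harmonic fields (all fields generated by sources outside the mask) satisfy
    the spherical mean value property, so the high-pass residual
    ``f - SMV_r(f)`` annihilates them wherever the sphere of radius ``r`` fits
    inside the mask. Each voxel uses the largest radius of the schedule that
    fits; the combined residual is then deconvolved by ``1 - S(k)`` of the
    largest kernel, truncating frequencies where ``|1 - S|`` falls below the
    threshold.

    Returns the local (internal-source) field and the eroded mask on which it
    is defined; the output is zero outside that mask.
    """
    freq.require_same_geometry(mask, "sharp_remove_background")
    if mask.units != "mask":
        raise ValidationError("second argument must be a mask volume")
    shape, voxel = freq.shape, tuple(freq.voxel_size)
    max_vox = float(np.max(freq.voxel_size))

    radii = [r for r in params.radii_mm if r >= max_vox]
    dropped = [r for r in params.radii_mm if r < max_vox]
    if dropped:
        logger.info("dropping SMV radii %s mm smaller than the %.3g mm voxel", dropped, max_vox)
    if not radii:
        raise ValidationError(
            f"no SMV radius in {params.radii_mm} is at least one voxel ({max_vox} mm)"
        )

    erosion = params.erosion
    if erosion is None:
        erosion = math.ceil(min(radii) / max_vox)

    m = mask.data.astype(bool)
    eroded = ndimage.binary_erosion(m, iterations=erosion) if erosion else m.copy()
    if not eroded.any():
        raise ComputeError(
            f"mask is empty after eroding {erosion} voxels (radii {radii} mm)"
        )

    f = freq.data * m
    F = sfft.rfftn(f)
    Mf = sfft.rfftn(m.astype(float))

    high_pass = np.zeros(shape)
    assigned = np.zeros(shape, dtype=bool)
    for r in radii:  # descending: largest (most accurate) radius wins
        S = _smv_rfft(shape, voxel, float(r))
        fraction_inside = sfft.irfftn(S * Mf, s=shape)
        reliable = fraction_inside >= 1.0 - 1e-6
        sel = reliable & eroded & ~assigned
        if np.any(sel):
            smv_f = sfft.irfftn(S * F, s=shape)
            high_pass[sel] = f[sel] - smv_f[sel]
            assigned |= sel

    eroded &= assigned
    if not eroded.any():
        raise ComputeError(
            f"no voxel supports any SMV radius of {radii} mm after eroding "
            f"{erosion} voxels; enlarge the mask or shrink the radii"
        )

    S0 = _smv_rfft(shape, voxel, float(radii[0]))
    denom = 1.0 - S0
    # truncate at the threshold by clamping: frequencies where |1 - S| falls
    # below it are divided by the threshold instead of being zeroed, which
    # keeps (attenuated) low-frequency local-field content
    inv = np.sign(denom) / np.maximum(np.abs(denom), params.svd_threshold)
    inv[denom == 0.0] = 0.0
    local = sfft.irfftn(sfft.rfftn(high_pass * eroded) * inv, s=shape) * eroded

    eroded_grid = VolumeGrid(
        eroded.astype(np.uint8), freq.voxel_size, freq.b0_dir, units="mask"
    )
    return freq.with_data(local), eroded_grid


# ---------------------------------------------------------------------------
# Dipole kernel, forward model, inversion
# ---------------------------------------------------------------------------

def _dipole(
    shape: tuple[int, ...],
    voxel: tuple[float, ...],
    b0: tuple[float, ...],
    d_at_zero: float,
    half: bool,
) -> np.ndarray:
    freqs = [sfft.fftfreq(n, d=v) for n, v in zip(shape, voxel)]
    if half:
        freqs[2] = sfft.rfftfreq(shape[2], d=voxel[2])
    kx = freqs[0][:, None, None]
    ky = freqs[1][None, :, None]
    kz = freqs[2][None, None, :]
    k2 = kx**2 + ky**2 + kz**2
    kb = kx * b0[0] + ky * b0[1] + kz * b0[2]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 / 3.0 - kb**2 / k2
    d[k2 == 0] = d_at_zero
    return d


@lru_cache(maxsize=16)
def _dipole_rfft(shape, voxel, b0, d_at_zero) -> np.ndarray:
    return _dipole(shape, voxel, b0, d_at_zero, half=True)


def dipole_kernel(grid: VolumeGrid, d_at_zero: float = 0.0) -> np.ndarray:
    """Unit dipole response in k-space, D(k) = 1/3 - (k.b0)^2/|k|^2.

    The frequency grid is the one implied by the voxel size; the undefined
    value at k = 0 is set to ``d_at_zero``.
    """
    return _dipole(
        grid.shape, tuple(grid.voxel_size), tuple(grid.b0_dir), float(d_at_zero), half=False
    )


def forward_field(chi: VolumeGrid, d_at_zero: float = 0.0) -> VolumeGrid:
    """Field shift (ppm) induced by a susceptibility distribution (ppm).

    Spectral convolution of chi with the dipole kernel, using the array
    centre-free FFT convention (periodic boundaries).
    """
    if not np.all(np.isfinite(chi.data)):
        raise ValidationError("chi must be finite")
    D = _dipole_rfft(
        chi.shape, tuple(chi.voxel_size), tuple(chi.b0_dir), float(d_at_zero)
    )
    out = sfft.irfftn(D * sfft.rfftn(chi.data), s=chi.shape)
    return chi.with_data(out, units="ppm")


def lsqr_invert(
    local_field: VolumeGrid,
    mask: VolumeGrid,
    params: InversionParams = InversionParams(),
    support: VolumeGrid | None = None,
) -> VolumeGrid:
    """Invert the dipole convolution by LSQR.

    Solves ``min_chi || D * chi - f ||_2`` over the full grid, where ``f`` is
    the local field inside the data mask and zero outside it (the standard
    zero-filled LSQR formulation for dipole inversion: the local field decays
    quickly outside the brain, and treating the exterior as zero suppresses
    the large near-magic-angle null space that an exterior-blind fit would
    leave free). The k = 0 component (the volume mean when
    ``d_at_zero = 0``) stays at zero; use :func:`reference_to_mask_mean` to
    fix the reference.

    The returned map is zeroed outside ``support`` (default: the data mask).
    Non-convergence within ``max_iter`` logs a warning with the residual; it
    is not an error.
    """
    local_field.require_same_geometry(mask, "lsqr_invert")
    if mask.units != "mask":
        raise ValidationError("lsqr_invert mask argument must be a mask volume")
    shape = local_field.shape
    n = int(np.prod(shape))
    m = mask.data.astype(bool)
    mflat = m.ravel()
    D = _dipole_rfft(
        shape, tuple(local_field.voxel_size), tuple(local_field.b0_dir), params.d_at_zero
    )

    def conv(x: np.ndarray) -> np.ndarray:
        return sfft.irfftn(D * sfft.rfftn(x.reshape(shape)), s=shape).ravel()

    op = LinearOperator((n, n), matvec=conv, rmatvec=conv, dtype=float)
    b = (local_field.data * m).ravel()
    sol = lsqr(op, b, atol=params.atol, btol=params.atol, iter_lim=params.max_iter)
    chi, istop, itn, r1norm = sol[0], sol[1], sol[2], sol[3]
    bnorm = float(np.linalg.norm(b))
    masked_resid = float(np.linalg.norm((conv(chi) - b) * mflat))
    logger.info(
        "LSQR stopped after %d iterations (istop=%d, residual %.3e, "
        "in-mask residual %.3e, rel %.3e)",
        itn, istop, r1norm, masked_resid,
        masked_resid / bnorm if bnorm else 0.0,
    )
    if istop == 7:
        logger.warning(
            "LSQR reached the iteration cap (%d) with residual %.3e; the "
            "remaining misfit sits in the slowly converging near-cone modes",
            params.max_iter, r1norm,
        )
    sup = support.data.astype(bool) if support is not None else m
    out = chi.reshape(shape) * sup
    return local_field.with_data(out, units="ppm")


def reference_to_mask_mean(chi: VolumeGrid, mask: VolumeGrid) -> VolumeGrid:
    """Re-reference chi so the mask mean is zero; zero outside the mask."""
    chi.require_same_geometry(mask, "reference_to_mask_mean")
    m = mask.data.astype(bool)
    if not m.any():
        raise ValidationError("reference mask is empty")
    out = (chi.data - chi.data[m].mean()) * m
    return chi.with_data(out)


# ---------------------------------------------------------------------------
# ROI quantification
# ---------------------------------------------------------------------------

def roi_means(chi: VolumeGrid, labels: NucleusLabelMap) -> dict[str, tuple[float, int]]:
    """Mean susceptibility per nucleus over every labelled voxel.

    All slices and both hemispheres carrying a nucleus's label are pooled.
    Returns ``{nucleus: (mean_ppm, n_voxels)}`` in legend order; a legend
    nucleus with no labelled voxels is an error.
    """
    if chi.shape != labels.labels.shape:
        raise ValidationError(
            f"chi {chi.shape} and label map {labels.labels.shape} are not aligned"
        )
    out: dict[str, tuple[float, int]] = {}
    for value, name in labels.legend.items():
        sel = labels.labels == value
        count = int(np.count_nonzero(sel))
        if count == 0:
            raise ValidationError(f"nucleus {name!r} has zero labelled voxels")
        out[name] = (float(chi.data[sel].mean()), count)
    return out
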