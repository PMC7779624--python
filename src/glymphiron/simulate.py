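"""Synthetic data generators for every pipeline stage.

Three generators make the whole chain testable without any image download:

* ``make_susceptibility_phantom`` — a brain-shaped mask containing seven
  bilateral deep-nucleus ellipsoids with assigned susceptibilities, plus
  strong susceptibility sources *outside* the mask (sinus/skull-base-like)
  whose harmonic in-mask field the background-removal stage must eliminate.
  Phase is forward-simulated through the dipole model at the SWI acquisition
  defaults (TE 11.5 ms, 3 T).
* ``make_dwi_phantom`` — a volume split into projection-fibre (principal
  axis z), association-fibre (principal axis y) and isotropic background
  compartments, with the perivascular (x) diffusivity of both fibre regions
  scaled by a latent glymphatic factor ``glymph_g``; 30-direction b = 2000
  s/mm^2 signals with Rician noise, and the analytic ALPS index of the
  prescribed tensors for round-trip assertions.
* ``simulate_cohort`` — a 213-subject cohort whose marginals (age 60.1 +/- 7.3
  truncated to [43, 80], ALPS 1.4 +/- 0.2, nucleus susceptibilities per the
  published means/SDs) and rank-correlation structure (ALPS and age vs each
  nucleus) are induced by a single latent glymphatic variable via a Gaussian
  copula. In image mode it also emits per-subject phantom specs whose ground
  truths equal the tabulated values.

All generators are deterministic given their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import optimize
from scipy import stats as sstats

from .alps import AlpsRois, DWISeries, GradientTable
from .errors import ValidationError
from .grids import AcquisitionParams, VolumeGrid
from .qsm import NUCLEI, NucleusLabelMap, forward_field

# ---------------------------------------------------------------------------
# Susceptibility phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid, centre in mm relative to the grid centre."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValidationError("ellipsoid semi-axes must be positive")

    def contains(self, coords: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
        x, y, z = coords
        cx, cy, cz = self.center_mm
        ax, ay, az = self.semi_axes_mm
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


@dataclass(frozen=True)
class Sphere:
    center_mm: tuple[float, float, float]
    radius_mm: float
    chi_ppm: float


def default_nucleus_geometry() -> dict[str, tuple[Ellipsoid, Ellipsoid]]:
    """Bilateral ellipsoid pair per nucleus (left/right mirrored in x).

    Positions are schematic: deep nuclei sit near the volume centre well
    inside the mask, ordered roughly rostral (caudate) to cerebellar
    (dentate). Sizes give each nucleus a few hundred 1-mm voxels, a realistic
    fraction of the brain-scale mask.
    """
    layout = {
        "caudate nucleus": ((9.0, 10.0, 6.0), (3.5, 5.0, 4.0)),
        "putamen": ((16.0, 4.0, 0.0), (4.0, 6.0, 4.0)),
        "globus pallidus": ((11.0, 0.0, -5.0), (3.0, 4.0, 3.0)),
        "thalamus": ((6.0, -7.0, 3.0), (4.0, 5.0, 4.0)),
        "red nucleus": ((4.0, -14.0, -5.0), (2.5, 3.0, 3.0)),
        "substantia nigra": ((8.0, -14.0, -9.0), (3.0, 3.5, 2.5)),
        "dentate nucleus": ((8.0, -8.0, -12.0), (3.5, 4.0, 3.0)),
    }
    out = {}
    for name, (c, s) in layout.items():
        right = Ellipsoid(center_mm=c, semi_axes_mm=s)
        left = Ellipsoid(center_mm=(-c[0], c[1], c[2]), semi_axes_mm=s)
        out[name] = (left, right)
    return out


#: Published cohort means of nucleus susceptibility, in 1e-3 ppm.
PUBLISHED_NUCLEUS_CHI_E3 = {
    "caudate nucleus": 79.0,
    "putamen": 88.0,
    "globus pallidus": 75.0,
    "thalamus": 45.0,
    "red nucleus": 79.0,
    "substantia nigra": 66.0,
    "dentate nucleus": 61.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Susceptibility phantom recipe.

    ``nucleus_chi_e3`` assigns each nucleus its susceptibility in 1e-3 ppm on
    the brain-reference scale (i.e. relative to the brain-mask mean, the
    reference the reconstruction reports); the painter adds a self-consistent
    offset so that mask-mean-referencing the painted truth reproduces exactly
    these values. ``noise_sd`` is the phase noise SD as a fraction of the
    noiseless phase range.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask_semi_axes_mm: tuple[float, float, float] = (28.0, 26.0, 24.0)
    nucleus_chi_e3: dict[str, float] = field(default_factory=lambda: dict(PUBLISHED_NUCLEUS_CHI_E3))
    background_sources: tuple[Sphere, ...] = (
        Sphere(center_mm=(0.0, 24.0, -27.0), radius_mm=4.0, chi_ppm=1.5),
        Sphere(center_mm=(30.0, -8.0, 8.0), radius_mm=4.0, chi_ppm=-1.0),
    )
    noise_sd: float = 0.01
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = sorted(set(self.nucleus_chi_e3) - set(NUCLEI))
        if unknown:
            raise ValidationError(f"unknown nuclei in spec: {unknown}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class SusceptibilityPhantom:
    """Everything the susceptibility chain needs, plus ground truth."""

    chi: VolumeGrid            # painted truth, ppm (includes reference offset)
    mask: VolumeGrid
    labels: NucleusLabelMap
    phase: VolumeGrid          # radians, noiseless field + optional noise
    magnitude: VolumeGrid
    acq: AcquisitionParams
    truth_chi_e3: dict[str, float]  # mask-mean-referenced truth, 1e-3 ppm
    rois: None = None


@lru_cache(maxsize=8)
def _phantom_geometry(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
    mask_semi: tuple[float, float, float],
) -> tuple:
    """Coordinate grids (mm, centred), brain mask, per-nucleus voxel masks."""
    axes = [(np.arange(n) - n // 2) * v for n, v in zip(shape, voxel)]
    coords = (
        axes[0][:, None, None],
        axes[1][None, :, None],
        axes[2][None, None, :],
    )
    mask = Ellipsoid((0.0, 0.0, 0.0), mask_semi).contains(coords)
    nucleus_masks = {}
    for name, pair in default_nucleus_geometry().items():
        sel = np.zeros(shape, dtype=bool)
        for ell in pair:
            sel |= ell.contains(coords)
        nucleus_masks[name] = sel
    return coords, mask, nucleus_masks


def make_susceptibility_phantom(spec: PhantomSpec) -> SusceptibilityPhantom:
    """Paint the phantom, forward-simulate the field and synthesise phase.

    phase = 2 pi * gamma * B0 * TE * 1e-6 * field_ppm (+ Gaussian noise),
    where field_ppm is the dipole convolution of the painted susceptibility
    (nuclei plus outside-mask sources).
    """
    shape = tuple(spec.shape)
    voxel = tuple(float(v) for v in spec.voxel_size_mm)
    coords, mask, nucleus_masks = _phantom_geometry(
        shape, voxel, tuple(spec.mask_semi_axes_mm)
    )

    labels = np.zeros(shape, dtype=np.int16)
    legend: dict[int, str] = {}
    for value, name in enumerate(NUCLEI, start=1):
        if name not in spec.nucleus_chi_e3:
            continue
        sel = nucleus_masks[name]
        if not np.all(mask[sel]):
            raise ValidationError(f"nucleus {name!r} extends outside the brain mask")
        if np.any(labels[sel] != 0):
            raise ValidationError(f"nucleus {name!r} overlaps another nucleus")
        labels[sel] = value
        legend[value] = name

    # Self-consistent painting: offset m solves t_i + m - mask_mean = t_i.
    n_mask = int(mask.sum())
    counts = np.bincount(labels[mask], minlength=len(NUCLEI) + 1)
    weighted = sum(
        counts[v] * spec.nucleus_chi_e3[n] for v, n in legend.items()
    )
    total_fraction = sum(counts[v] for v in legend) / n_mask
    offset_e3 = (weighted / n_mask) / (1.0 - total_fraction) if legend else 0.0

    chi = np.zeros(shape)
    for value, name in legend.items():
        chi[labels == value] = (spec.nucleus_chi_e3[name] + offset_e3) * 1e-3

    for src in spec.background_sources:
        sel = Ellipsoid(src.center_mm, (src.radius_mm,) * 3).contains(coords)
        if np.any(mask[sel]):
            raise ValidationError(
                f"background source at {src.center_mm} mm intersects the brain mask"
            )
        chi[sel] += src.chi_ppm

    chi_grid = VolumeGrid(chi, np.asarray(voxel), units="ppm")
    field = forward_field(chi_grid)
    acq = spec.acq
    scale = 2.0 * np.pi * acq.gamma_hz_per_tesla * acq.b0_tesla * acq.te_s * 1e-6
    phase = field.data * scale
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        span = float(phase.max() - phase.min())
        phase = phase + rng.standard_normal(shape) * spec.noise_sd * span

    magnitude = ndimage.gaussian_filter(mask.astype(float), sigma=2.0) * 0.95 + 0.05

    vox = np.asarray(voxel)
    return SusceptibilityPhantom(
        chi=chi_grid.with_data(chi),
        mask=VolumeGrid(mask.astype(np.uint8), vox, units="mask"),
        labels=NucleusLabelMap(labels=labels, legend=legend),
        phase=VolumeGrid(phase, vox, units="radians"),
        magnitude=VolumeGrid(magnitude, vox, units="dimensionless"),
        acq=acq,
        truth_chi_e3={n: spec.nucleus_chi_e3[n] for n in legend.values()},
    )


# ---------------------------------------------------------------------------
# DWI phantom
# ---------------------------------------------------------------------------

def fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit directions (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def default_gradient_table(b: float = 2000.0, n_dirs: int = 30) -> GradientTable:
    """One b = 0 volume plus ``n_dirs`` directions at ``b`` s/mm^2."""
    bvals = np.concatenate([[0.0], np.full(n_dirs, b)])
    bvecs = np.vstack([[0.0, 0.0, 0.0], fibonacci_directions(n_dirs)])
    return GradientTable(bvals=bvals, bvecs=bvecs)


@dataclass(frozen=True)
class Box:
    """Half-open voxel-index box [lo, hi) per axis."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def select(self, shape: tuple[int, int, int]) -> np.ndarray:
        sel = np.zeros(shape, dtype=bool)
        sel[self.lo[0]:self.hi[0], self.lo[1]:self.hi[1], self.lo[2]:self.hi[2]] = True
        return sel


def _diag(dx: float, dy: float, dz: float) -> np.ndarray:
    return np.diag([dx, dy, dz])


@dataclass(frozen=True)
class DwiPhantomSpec:
    """Diffusion phantom recipe.

    ``glymph_g`` in [0, 1] sets the perivascular (x axis) diffusivity of both
    fibre regions to ``g * 1.0e-3`` mm^2/s; with the default cross-fibre
    diffusivities (0.5e-3 in each denominator direction) the analytic ALPS
    index equals ``2 g`` exactly, a strictly monotone link. Explicit region
    tensors override the ``glymph_g`` construction when given.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    glymph_g: float = 0.7
    projection_tensor: np.ndarray | None = None
    association_tensor: np.ndarray | None = None
    background_tensor: np.ndarray | None = None
    projection_box: Box = Box((8, 14, 6), (19, 25, 42))
    association_box: Box = Box((8, 27, 6), (19, 38, 42))
    mask_box: Box = Box((4, 4, 4), (44, 44, 44))
    roi_slice: int = 24
    projection_center: tuple[float, float] = (13.0, 19.0)
    association_center: tuple[float, float] = (13.0, 32.0)
    gradient_b: float = 2000.0
    n_directions: int = 30
    s0: float = 1.0
    snr: float | None = 30.0
    noise_model: str = "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.glymph_g <= 1.0:
            raise ValidationError(f"glymph_g must lie in [0, 1], got {self.glymph_g}")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValidationError("noise_model must be 'rician' or 'gaussian'")
        if self.snr is not None and self.snr <= 0:
            raise ValidationError("snr must be positive (or None for noiseless)")

    def tensors(self) -> dict[str, np.ndarray]:
        """Prescribed region tensors (mm^2/s), validated SPD."""
        dx = self.glymph_g * 1.0e-3
        out = {
            "projection": self.projection_tensor
            if self.projection_tensor is not None
            else _diag(dx, 0.5e-3, 1.4e-3),
            "association": self.association_tensor
            if self.association_tensor is not None
            else _diag(dx, 1.4e-3, 0.5e-3),
            "background": self.background_tensor
            if self.background_tensor is not None
            else _diag(0.7e-3, 0.7e-3, 0.7e-3),
        }
        for name, t in out.items():
            t = np.asarray(t, dtype=float)
            if t.shape != (3, 3) or not np.allclose(t, t.T, atol=1e-15):
                raise ValidationError(f"{name} tensor must be symmetric 3x3")
            if np.linalg.eigvalsh(t)[0] <= 0:
                raise ValidationError(f"{name} tensor is not positive definite")
            out[name] = t
        return out


@dataclass
class DwiPhantom:
    dwi: DWISeries
    gtab: GradientTable
    mask: VolumeGrid
    rois: AlpsRois
    analytic_alps: float
    region_tensors: dict[str, np.ndarray]


def analytic_alps_index(tensors: dict[str, np.ndarray]) -> float:
    """ALPS index implied directly by the prescribed region tensors."""
    p, a = tensors["projection"], tensors["association"]
    return float((p[0, 0] + a[0, 0]) / (p[1, 1] + a[2, 2]))


def make_dwi_phantom(spec: DwiPhantomSpec) -> DwiPhantom:
    """Synthesise region-wise mono-exponential DWI signals plus noise.

    S = S0 exp(-b g^T D g) per compartment; Rician noise replaces S by
    sqrt((S + n1)^2 + n2^2) with n1, n2 ~ N(0, S0/SNR), the magnitude-MRI
    noise model. The analytic ALPS index of the prescribed tensors is
    returned for round-trip assertions.
    """
    shape = tuple(spec.shape)
    tensors = spec.tensors()
    gtab = default_gradient_table(spec.gradient_b, spec.n_directions)

    mask = spec.mask_box.select(shape)
    proj = spec.projection_box.select(shape)
    assoc = spec.association_box.select(shape)
    if np.any(proj & assoc):
        raise ValidationError("projection and association regions overlap")
    if not (np.all(mask[proj]) and np.all(mask[assoc])):
        raise ValidationError("fibre regions must lie inside the mask")

    # Per-region attenuation profile over the acquisition axis.
    g, b = gtab.bvecs, gtab.bvals
    profiles = {
        name: spec.s0 * np.exp(-b * np.einsum("ki,ij,kj->k", g, D, g))
        for name, D in tensors.items()
    }
    volumes = np.zeros(shape + (len(gtab),))
    volumes[mask] = profiles["background"]
    volumes[proj] = profiles["projection"]
    volumes[assoc] = profiles["association"]

    if spec.snr is not None:
        # noise is only needed where signal is kept (inside the mask)
        rng = np.random.default_rng(spec.seed)
        sigma = spec.s0 / spec.snr
        inside = volumes[mask]
        if spec.noise_model == "rician":
            n1 = rng.standard_normal(inside.shape) * sigma
            n2 = rng.standard_normal(inside.shape) * sigma
            volumes[mask] = np.sqrt((inside + n1) ** 2 + n2**2)
        else:
            volumes[mask] = np.abs(inside + rng.standard_normal(inside.shape) * sigma)
    volumes[~mask] = 0.0

    vox = np.asarray(spec.voxel_size_mm, dtype=float)
    grid = VolumeGrid(np.zeros(shape), vox, units="dimensionless")
    rois = AlpsRois(
        slice_index=spec.roi_slice,
        projection_center=spec.projection_center,
        association_center=spec.association_center,
    )
    return DwiPhantom(
        dwi=DWISeries(volumes=volumes, grid=grid),
        gtab=gtab,
        mask=VolumeGrid(mask.astype(np.uint8), vox, units="mask"),
        rois=rois,
        analytic_alps=analytic_alps_index(tensors),
        region_tensors=tensors,
    )


# ---------------------------------------------------------------------------
# Cohort simulator
# ---------------------------------------------------------------------------

def pearson_from_spearman(rho_s: float) -> float:
    """Gaussian-copula conversion: rho_p = 2 sin(pi rho_s / 6)."""
    if not -1.0 <= rho_s <= 1.0:
        raise ValidationError(f"Spearman rho must lie in [-1, 1], got {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


#: (mean, sd, spearman vs ALPS, spearman vs age) per nucleus, 1e-3 ppm.
PUBLISHED_CALIBRATION = {
    "caudate nucleus": (79.0, 25.0, -0.289, 0.218),
    "putamen": (88.0, 28.0, -0.337, 0.373),
    "globus pallidus": (75.0, 27.0, -0.280, 0.180),
    "thalamus": (45.0, 22.0, -0.284, 0.164),
    "red nucleus": (79.0, 27.0, -0.307, 0.182),
    "substantia nigra": (66.0, 24.0, -0.267, 0.199),
    "dentate nucleus": (61.0, 32.0, -0.333, 0.213),
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort calibration constants.

    Defaults encode the published cohort: n = 213 with 107 women, age
    60.1 +/- 7.3 years truncated to [43, 80], ALPS 1.4 +/- 0.2, the seven
    nucleus susceptibility means/SDs, and the rank correlations of each
    nucleus with ALPS and with age. ALPS draws are clipped to
    [``alps_min``, ``alps_max``] so every subject maps onto a valid diffusion
    phantom (the latent factor must satisfy g = alps/2 in [0, 1]).
    """

    n: int = 213
    age_mean: float = 60.1
    age_sd: float = 7.3
    age_range: tuple[float, float] = (43.0, 80.0)
    female_fraction: float = 107.0 / 213.0
    alps_mean: float = 1.4
    alps_sd: float = 0.2
    alps_min: float = 0.6
    alps_max: float = 2.0
    r_age_alps: float = -0.263          # Spearman target
    nuclei: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(PUBLISHED_CALIBRATION)
    )
    wmh_mean: float = 9.7               # mL (units assumed; see docs)
    wmh_sd: float = 6.8
    wmh_age_loading: float = 0.3        # assumed weak positive age link
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValidationError("cohort needs n >= 3")
        if not set(self.nuclei) <= set(NUCLEI):
            raise ValidationError("nuclei keys must be the canonical nucleus names")


def _copula_loadings(spec: CohortSpec) -> dict[str, tuple[float, float, float]]:
    """Solve (beta_age, gamma_g, delta_noise) per nucleus on latent normals.

    The latent glymphatic variable is z_g = alpha z_age + sqrt(1-alpha^2) e;
    each nucleus latent is beta z_age + gamma z_g + delta e_i with unit
    variance. Raises before any sampling if a requested correlation pattern
    is infeasible under this one-factor model.
    """
    alpha = pearson_from_spearman(spec.r_age_alps)
    out: dict[str, tuple[float, float, float]] = {}
    for name, (_, _, r_alps, r_age) in spec.nuclei.items():
        pa = pearson_from_spearman(r_age)
        pg = pearson_from_spearman(r_alps)
        # corr with age: beta + alpha gamma = pa ; corr with g: alpha beta + gamma = pg
        det = 1.0 - alpha**2
        beta = (pa - alpha * pg) / det
        gamma = (pg - alpha * pa) / det
        var_explained = beta**2 + gamma**2 + 2.0 * alpha * beta * gamma
        if var_explained >= 1.0:
            raise ValidationError(
                f"infeasible correlation calibration for {name!r}: "
                f"requested (r_alps={r_alps}, r_age={r_age}) needs explained "
                f"variance {var_explained:.3f} >= 1 under the latent model"
            )
        out[name] = (beta, gamma, math.sqrt(1.0 - var_explained))
    return out


@lru_cache(maxsize=8)
def _truncnorm_parent_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Pre-truncation (mu, sigma) whose [lo, hi]-truncation has the given moments."""

    def moments(p):
        mu, sigma = p
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = sstats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = optimize.fsolve(moments, x0=[mean, sd], full_output=False)
    mu, sigma = float(sol[0]), float(sol[1])
    check = moments((mu, sigma))
    if max(abs(check[0]), abs(check[1])) > 1e-6:
        raise ValidationError(
            f"could not calibrate truncated-normal parent for mean={mean}, sd={sd}"
        )
    return mu, sigma


def _sample_truncated(
    rng: np.random.Generator, n: int, mu: float, sigma: float, lo: float, hi: float
) -> np.ndarray:
    """Rejection sampling from N(mu, sigma) restricted to [lo, hi]."""
    out = rng.normal(mu, sigma, size=n)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


@dataclass
class SubjectImageSpecs:
    """Per-subject phantom recipes whose ground truths equal the table row."""

    subject_id: str
    phantom: PhantomSpec
    dwi: DwiPhantomSpec


def simulate_cohort(
    spec: CohortSpec,
    images: bool = False,
    phantom_template: PhantomSpec | None = None,
    dwi_template: DwiPhantomSpec | None = None,
) -> pd.DataFrame | tuple[pd.DataFrame, list[SubjectImageSpecs]]:
    """Draw a cohort table (and, in image mode, per-subject phantom specs).

    Image mode returns lazily evaluable specs rather than volumes: each
    subject's susceptibility phantom is assigned that subject's tabulated
    nucleus values, and the diffusion phantom's latent factor is
    ``g = alps / 2``, so the images' analytic ground truths equal the table.
    """
    loadings = _copula_loadings(spec)  # validates feasibility before sampling
    rng = np.random.default_rng(spec.seed)

    lo, hi = spec.age_range
    mu0, sigma0 = _truncnorm_parent_params(spec.age_mean, spec.age_sd, lo, hi)
    age = _sample_truncated(rng, spec.n, mu0, sigma0, lo, hi)
    z_age = (age - spec.age_mean) / spec.age_sd

    alpha = pearson_from_spearman(spec.r_age_alps)
    z_g = alpha * z_age + math.sqrt(1.0 - alpha**2) * rng.standard_normal(spec.n)
    alps = np.clip(spec.alps_mean + spec.alps_sd * z_g, spec.alps_min, spec.alps_max)

    chi: dict[str, np.ndarray] = {}
    for name, (mean, sd, _, _) in spec.nuclei.items():
        beta, gamma, delta = loadings[name]
        z = beta * z_age + gamma * z_g + delta * rng.standard_normal(spec.n)
        chi[name] = mean + sd * z

    w_load = spec.wmh_age_loading
    z_w = w_load * z_age + math.sqrt(1.0 - w_load**2) * rng.standard_normal(spec.n)
    wmh = spec.wmh_mean + spec.wmh_sd * z_w
    neg = wmh < 0
    while np.any(neg):  # left-truncation at zero by rejection on the noise part
        z_w[neg] = w_load * z_age[neg] + math.sqrt(1.0 - w_load**2) * rng.standard_normal(
            int(neg.sum())
        )
        wmh[neg] = spec.wmh_mean + spec.wmh_sd * z_w[neg]
        neg = wmh < 0

    cuts = sstats.norm.ppf([1.0 / 3.0, 2.0 / 3.0])
    atrophy = {}
    for key in ("atrophy_cortical", "atrophy_central"):
        latent = (z_age + rng.standard_normal(spec.n)) / math.sqrt(2.0)
        atrophy[key] = np.digitize(latent, cuts).astype(int)

    n_female = int(round(spec.n * spec.female_fraction))
    sex = np.array(["female"] * n_female + ["male"] * (spec.n - n_female))
    rng.shuffle(sex)

    from .qsm import NUCLEUS_COLUMNS  # local import to avoid cycle at module load

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(spec.n)],
            "age": age,
            "sex": sex,
            "alps": alps,
            **{NUCLEUS_COLUMNS[n]: chi[n] for n in spec.nuclei},
            "wmh_volume": wmh,
            **atrophy,
        }
    )
    if not images:
        return table

    base_phantom = phantom_template if phantom_template is not None else PhantomSpec()
    base_dwi = dwi_template if dwi_template is not None else DwiPhantomSpec()
    subject_specs: list[SubjectImageSpecs] = []
    for i, row in table.iterrows():
        qsm_seed = int(rng.integers(2**31 - 1))
        dwi_seed = int(rng.integers(2**31 - 1))
        phantom = replace(
            base_phantom,
            nucleus_chi_e3={n: float(chi[n][i]) for n in spec.nuclei},
            seed=qsm_seed,
        )
        dwi = replace(base_dwi, glymph_g=float(row["alps"]) / 2.0, seed=dwi_seed)
        subject_specs.append(
            SubjectImageSpecs(subject_id=row["subject_id"], phantom=phantom, dwi=dwi)
        )
    return table, subject_specs
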