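"""End-to-end orchestration: per-subject reconstruction chains, the simulated
cohort study, and provenance records.

``reconstruct_susceptibility`` and ``alps_from_dwi`` are the two per-subject
chains (phase -> frequency -> background removal -> dipole inversion -> brain
referenced chi map; DWI -> tensor fit -> ALPS index). ``run_pipeline`` wires
them to the cohort simulator and the statistics stage: it simulates a cohort
in image mode, measures every subject's nucleus susceptibilities and ALPS
index from the images, and reports descriptive, correlation and adjusted
regression tables on the measured values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alps import AlpsResult, AlpsRois, DWISeries, GradientTable, alps_index, fit_tensor
from .cohort import run_table2, run_table3, table1_summary
from .errors import ComputeError, ValidationError
from .grids import AcquisitionParams, VolumeGrid
from .qsm import (
    InversionParams,
    NUCLEUS_COLUMNS,
    SharpParams,
    frequency_to_ppm,
    lsqr_invert,
    phase_to_frequency,
    reference_to_mask_mean,
    roi_means,
    sharp_remove_background,
)
from .simulate import (
    CohortSpec,
    DwiPhantomSpec,
    PhantomSpec,
    make_dwi_phantom,
    make_susceptibility_phantom,
    simulate_cohort,
)

logger = logging.getLogger(__name__)


def reconstruct_susceptibility(
    phase: VolumeGrid,
    mask: VolumeGrid,
    acq: AcquisitionParams,
    sharp: SharpParams = SharpParams(),
    inversion: InversionParams = InversionParams(),
) -> tuple[VolumeGrid, VolumeGrid]:
    """Full susceptibility chain on one subject.

    Returns the chi map (ppm, referenced to the brain-mask mean, zero outside
    the brain mask) and the eroded mask on which the local field was defined.
    """
    freq = phase_to_frequency(phase, acq, mask=mask)
    ppm = frequency_to_ppm(freq, acq)
    local, eroded = sharp_remove_background(ppm, mask, sharp)
    chi = lsqr_invert(local, eroded, inversion, support=mask)
    return reference_to_mask_mean(chi, mask), eroded


def alps_from_dwi(
    dwi: DWISeries,
    gtab: GradientTable,
    mask: VolumeGrid,
    rois: AlpsRois,
    weighted: bool = False,
) -> AlpsResult:
    """Tensor fit plus ALPS index on one subject."""
    tensors = fit_tensor(dwi, gtab, mask, weighted=weighted)
    return alps_index(tensors, rois)


def measure_subject_qsm(
    phantom_spec: PhantomSpec,
    sharp: SharpParams = SharpParams(),
    inversion: InversionParams = InversionParams(),
) -> dict[str, float]:
    """Simulate one subject's phase and measure nucleus chi (1e-3 ppm)."""
    ph = make_susceptibility_phantom(phantom_spec)
    chi, _ = reconstruct_susceptibility(ph.phase, ph.mask, ph.acq, sharp, inversion)
    means = roi_means(chi, ph.labels)
    return {name: mean * 1e3 for name, (mean, _) in means.items()}


def measure_subject_alps(
    dwi_spec: DwiPhantomSpec,
    roi_mask_only: bool = False,
    weighted: bool = False,
) -> AlpsResult:
    """Simulate one subject's DWI and measure the ALPS index.

    ``roi_mask_only`` restricts the tensor fit to the two ALPS disks (the
    only voxels the index uses), a pure speed optimisation with identical
    ROI statistics.
    """
    ph = make_dwi_phantom(dwi_spec)
    mask = ph.mask
    if roi_mask_only:
        from .alps import circle_mask

        proj, assoc = circle_mask(ph.rois, ph.dwi.grid)
        both = np.logical_or(proj.data.astype(bool), assoc.data.astype(bool))
        mask = VolumeGrid(
            both.astype(np.uint8), ph.dwi.grid.voxel_size, ph.dwi.grid.b0_dir, "mask"
        )
    return alps_from_dwi(ph.dwi, ph.gtab, mask, ph.rois, weighted=weighted)


# ---------------------------------------------------------------------------
# Run configuration and the cohort-level driver
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated settings for a full simulated-cohort run."""

    outdir: Path | None = None
    seed: int = 0
    n_subjects: int = 213
    cohort: CohortSpec = field(default_factory=CohortSpec)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    dwi: DwiPhantomSpec = field(default_factory=DwiPhantomSpec)
    sharp: SharpParams = field(default_factory=SharpParams)
    inversion: InversionParams = field(default_factory=InversionParams)
    alpha: float = 0.05
    family: int = 7
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValidationError("n_subjects must be >= 3")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.family < 1:
            raise ValidationError("family must be >= 1")
        if self.outdir is not None:
            self.outdir = Path(self.outdir)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.ndarray,)):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return repr(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def provenance_record(config: RunConfig) -> dict:
    import nibabel
    import scipy

    return {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "glymphiron": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "nibabel": nibabel.__version__,
        },
    }


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a cohort in image mode, measure every subject from the
    images, and run the statistics stage on the measured table.

    Returns a results bundle: the measured cohort table, descriptive
    summaries, the correlation results, the adjusted models, and a
    provenance record. When ``config.outdir`` is set, everything is also
    written there (cohort_measured.csv, results.json, provenance.json).
    """
    t0 = time.time()
    spec = dataclasses.replace(config.cohort, n=config.n_subjects, seed=config.seed)
    table, subjects = simulate_cohort(
        spec, images=True, phantom_template=config.phantom, dwi_template=config.dwi
    )

    rows = []
    for i, subj in enumerate(subjects):
        try:
            chi_e3 = measure_subject_qsm(subj.phantom, config.sharp, config.inversion)
            alps_res = measure_subject_alps(subj.dwi)
        except Exception as exc:
            raise ComputeError(
                f"stage failure for subject {subj.subject_id}: {exc}"
            ) from exc
        row = {"subject_id": subj.subject_id, "alps": alps_res.alps_index}
        row.update({NUCLEUS_COLUMNS[n]: v for n, v in chi_e3.items()})
        rows.append(row)
        if config.verbosity >= 1 and (i + 1) % 25 == 0:
            logger.info(
                "measured %d/%d subjects (%.1f s elapsed)",
                i + 1, len(subjects), time.time() - t0,
            )
    measured = pd.DataFrame(rows)

    # Demographics and covariates come from the simulated table; imaging
    # quantities are replaced by their image-measured counterparts.
    covars = table[["subject_id", "age", "sex", "wmh_volume",
                    "atrophy_cortical", "atrophy_central"]]
    cohort_measured = measured.merge(covars, on="subject_id")

    results = {
        "table1": table1_summary(cohort_measured),
        "table2": [dataclasses.asdict(r) for r in
                   run_table2(cohort_measured, config.alpha, config.family)],
        "table3": [dataclasses.asdict(r) for r in run_table3(cohort_measured)],
        "provenance": provenance_record(config),
        "elapsed_s": time.time() - t0,
    }

    if config.outdir is not None:
        config.outdir.mkdir(parents=True, exist_ok=True)
        cohort_measured.to_csv(config.outdir / "cohort_measured.csv", index=False)
        (config.outdir / "results.json").write_text(json.dumps(results, indent=1))
        (config.outdir / "provenance.json").write_text(
            json.dumps(results["provenance"], indent=1)
        )
    return {"cohort_measured": cohort_measured, **results}
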