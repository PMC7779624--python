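"""Common volumetric carriers.

`VolumeGrid` is the single 3-D container used throughout the susceptibility
chain: phase, frequency, local field, susceptibility, masks and label-backed
scalar maps all travel in it, tagged with physical units, voxel spacing and
the main-field (B0) direction expressed in array coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

#: Units a VolumeGrid may carry.
VALID_UNITS = ("radians", "Hz", "ppm", "dimensionless", "mask")

#: Default gyromagnetic ratio of the proton, Hz per tesla.
GAMMA_HZ_PER_TESLA = 42.576e6


@dataclass
class VolumeGrid:
    """A 3-D scalar field with acquisition geometry.

    Parameters
    ----------
    data
        3-D array of voxel values.
    voxel_size
        Spacing in mm along each array axis, all components positive.
    b0_dir
        Unit vector of the main magnetic field in array coordinates.
        Defaults to the third array axis.
    units
        One of :data:`VALID_UNITS`. Mask volumes must be binary.
    """

    data: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    b0_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    units: str = "dimensionless"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(
                f"VolumeGrid expects a 3-D array, got ndim={self.data.ndim}"
            )
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.voxel_size.shape != (3,) or not np.all(self.voxel_size > 0):
            raise ValidationError(
                f"voxel_size must be 3 positive components, got {self.voxel_size}"
            )
        self.b0_dir = np.asarray(self.b0_dir, dtype=float)
        if self.b0_dir.shape != (3,):
            raise ValidationError("b0_dir must be a 3-vector")
        norm = float(np.linalg.norm(self.b0_dir))
        if abs(norm - 1.0) > 1e-9:
            raise ValidationError(f"|b0_dir| must be 1 within 1e-9, got {norm!r}")
        if self.units not in VALID_UNITS:
            raise ValidationError(
                f"units must be one of {VALID_UNITS}, got {self.units!r}"
            )
        if self.units == "mask":
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValidationError(
                    "mask volumes must contain only {0, 1}; "
                    f"found values {vals[:5]}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, units: str | None = None) -> "VolumeGrid":
        """New grid with the same geometry but different voxel values."""
        return replace(self, data=data, units=units if units is not None else self.units)

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
            and np.allclose(self.b0_dir, other.b0_dir, atol=atol)
        )

    def require_same_geometry(self, other: "VolumeGrid", what: str) -> None:
        if not self.same_geometry(other):
            raise ValidationError(
                f"{what}: geometry mismatch "
                f"(shapes {self.shape} vs {other.shape}, "
                f"voxels {self.voxel_size} vs {other.voxel_size})"
            )


@dataclass(frozen=True)
class AcquisitionParams:
    """Gradient-echo acquisition parameters needed by the susceptibility chain.

    ``te_s`` is the echo time in seconds (the protocol default corresponds to
    an 11.5 ms SWI echo at 3 T); ``gamma_hz_per_tesla`` is the proton
    gyromagnetic ratio.
    """

    te_s: float = 11.5e-3
    b0_tesla: float = 3.0
    gamma_hz_per_tesla: float = GAMMA_HZ_PER_TESLA

    def __post_init__(self) -> None:
        if not self.te_s > 0:
            raise ValidationError(f"te_s must be > 0, got {self.te_s}")
        if not self.b0_tesla > 0:
            raise ValidationError(f"b0_tesla must be > 0, got {self.b0_tesla}")
        if not self.gamma_hz_per_tesla > 0:
            raise ValidationError("gamma_hz_per_tesla must be > 0")
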