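"""Core volumetric containers: calibrated tomograms and binary enamel masks.

Coordinate convention (repo-wide): voxel indices are 0-based; axis 0 is the
axial (cervical → occlusal) direction after reorientation; the physical
position of slice ``i`` is ``(i + 0.5) * voxel_um``; axial distances are
reported in mm from the cervical-most enamel-containing slice.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class Tomogram:
    """A calibrated 3D micro-CT density volume.

    Parameters
    ----------
    voxels
        3D array of mineral density in mg_HA/cm^3 (axis 0 = axial).
    voxel_um
        Isotropic voxel pitch in micrometres.
    calibration
        Optional ``(slope, intercept)`` of the raw-attenuation → density
        map that produced the values; ``slope`` must be positive.
    """

    voxels: np.ndarray
    voxel_um: float
    calibration: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError("tomogram must be a 3D array")
        if not np.isfinite(self.voxels).all():
            raise ValidationError("tomogram contains non-finite values")
        if not self.voxel_um > 0:
            raise ValidationError("voxel_um must be positive")
        if self.calibration is not None and not self.calibration[0] > 0:
            raise ValidationError("calibration slope must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def voxel_mm(self) -> float:
        return self.voxel_um / 1000.0


@dataclass
class EnamelMask:
    """A binary enamel label volume congruent with a :class:`Tomogram`."""

    voxels: np.ndarray
    voxel_um: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError("mask must be a 3D array")
        if self.voxels.dtype != bool:
            vals = np.unique(self.voxels)
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError("mask values must be binary")
            self.voxels = self.voxels.astype(bool)
        if not self.voxel_um > 0:
            raise ValidationError("voxel_um must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def voxel_mm(self) -> float:
        return self.voxel_um / 1000.0

    def count(self) -> int:
        return int(self.voxels.sum())


def require_congruent(tom: Tomogram, mask: EnamelMask) -> None:
    """Raise unless tomogram and mask share shape and voxel pitch."""
    if tom.shape != mask.shape:
        raise ValidationError(
            f"tomogram shape {tom.shape} != mask shape {mask.shape}"
        )
    if not np.isclose(tom.voxel_um, mask.voxel_um):
        raise ValidationError("tomogram and mask voxel pitch differ")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient between two binary volumes."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
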