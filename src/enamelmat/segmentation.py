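"""Enamel segmentation, density calibration and long-axis reorientation.

Real enamel density overlaps dentin near the cervical margin, which is why
learned segmenters are used on real scans; this module provides the classical
reference segmentation (threshold + morphological closing + component
filtering) that defines the mask *contract* the rest of the pipeline relies
on — any segmenter meeting the same Dice contract can be slotted in.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import (
    CalibrationError,
    EmptySegmentationError,
    OrientationAmbiguousError,
    ValidationError,
)
from .volume import EnamelMask, Tomogram, require_congruent


def calibrate_density(
    raw: Tomogram, pairs: list[tuple[float, float]]
) -> Tomogram:
    """Apply a least-squares linear raw-attenuation → mg_HA/cm^3 map.

    ``pairs`` are (raw_value, density) measurements of calibration phantoms;
    at least two with distinct raw values are required.
    """
    if len(pairs) < 2:
        raise CalibrationError("need at least 2 calibration pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise CalibrationError("calibration pairs have identical raw values")
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise CalibrationError("calibration slope must be positive")
    return Tomogram(
        slope * raw.voxels + intercept,
        raw.voxel_um,
        calibration=(float(slope), float(intercept)),
    )


def segment_enamel(
    tom: Tomogram,
    lo: float,
    hi: float,
    min_component_voxels: int = 64,
    closing_iterations: int = 1,
) -> EnamelMask:
    """Threshold-band segmentation with closing and small-component removal.

    Voxels with density in ``[lo, hi]`` are candidates; binary closing fills
    sub-voxel gaps; connected components smaller than
    ``min_component_voxels`` are removed. All surviving components are kept
    (enamel may be split, e.g. by wear). Raises
    :class:`EmptySegmentationError` rather than returning an empty mask.
    """
    if not lo < hi:
        raise ValidationError("lo must be below hi")
    cand = (tom.voxels >= lo) & (tom.voxels <= hi)
    if not cand.any():
        raise EmptySegmentationError("no voxels in the density band")
    if closing_iterations > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        cand = ndimage.binary_closing(
            cand, structure=structure, iterations=closing_iterations
        )
    labels, n = ndimage.label(cand)
    if n == 0:
        raise EmptySegmentationError("closing removed all candidate voxels")
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_component_voxels)
    keep = keep[keep != 0]
    if keep.size == 0:
        raise EmptySegmentationError(
            "all components below min_component_voxels"
        )
    mask = np.isin(labels, keep)
    return EnamelMask(mask, tom.voxel_um)


def principal_axis(mask: EnamelMask, separation_tol: float = 0.05) -> np.ndarray:
    """Unit vector of the mask's largest principal second moment.

    Raises :class:`OrientationAmbiguousError` when the two largest
    eigenvalues are within ``separation_tol`` relative (no unique long axis,
    e.g. a sphere).
    """
    coords = np.argwhere(mask.voxels).astype(float)
    if coords.shape[0] == 0:
        raise ValidationError("mask is empty")
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[2] <= 0 or (evals[2] - evals[1]) / evals[2] < separation_tol:
        raise OrientationAmbiguousError(
            "principal moments nearly isotropic; long axis undefined"
        )
    return evecs[:, 2]


def reorient_long_axis(
    tom: Tomogram,
    mask: EnamelMask,
    pad_voxels: int = 2,
    flat_density_rel_tol: float = 1e-3,
) -> tuple[Tomogram, EnamelMask]:
    """Rotate tomogram and mask so the enamel long axis lies along axis 0.

    The long axis is the principal axis of the mask's second-moment tensor.
    Its sign is chosen so the lower-mean-density half (the cervical, newest
    enamel in a maturing tooth) ends up at low slice indices; if the axial
    density contrast is below ``flat_density_rel_tol`` relative, the
    centroid-to-far-end direction is used instead. Density is resampled with
    trilinear interpolation, the mask with nearest-neighbour, and both are
    cropped to the rotated mask's bounding box plus ``pad_voxels``.
    """
    require_congruent(tom, mask)
    axis = principal_axis(mask)

    coords = np.argwhere(mask.voxels).astype(float)
    centre = coords.mean(axis=0)
    proj = (coords - centre) @ axis
    dens = tom.voxels[mask.voxels]
    hi_half = dens[proj > 0]
    lo_half = dens[proj < 0]
    scale = max(abs(dens.mean()), 1.0)
    if (
        hi_half.size
        and lo_half.size
        and abs(hi_half.mean() - lo_half.mean()) / scale > flat_density_rel_tol
    ):
        if hi_half.mean() < lo_half.mean():
            axis = -axis  # denser (older, occlusal) end toward +axis0
    else:
        # flat density: point from centroid toward the far end of the mask
        if proj[np.argmax(np.abs(proj))] < 0:
            axis = -axis

    ez = np.array([1.0, 0.0, 0.0])
    rot, _ = Rotation.align_vectors(ez[None, :], axis[None, :])
    rmat = rot.as_matrix()  # rmat @ axis ~= ez

    rotated = (coords - centre) @ rmat.T
    rmin = np.floor(rotated.min(axis=0)).astype(int) - pad_voxels
    rmax = np.ceil(rotated.max(axis=0)).astype(int) + pad_voxels
    out_shape = tuple((rmax - rmin + 1).tolist())
    # output voxel o maps to input coordinate rmat.T @ (o + rmin) + centre
    matrix = rmat.T
    offset = matrix @ rmin + centre
    new_vox = ndimage.affine_transform(
        tom.voxels.astype(np.float32), matrix, offset=offset,
        output_shape=out_shape, order=1, mode="constant", cval=0.0,
    )
    new_mask = ndimage.affine_transform(
        mask.voxels.astype(np.uint8), matrix, offset=offset,
        output_shape=out_shape, order=0, mode="constant", cval=0,
    )
    return (
        Tomogram(new_vox, tom.voxel_um, calibration=tom.calibration),
        EnamelMask(new_mask > 0, mask.voxel_um),
    )
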