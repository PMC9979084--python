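"""Axial and surface-shell mineral-density profiles.

The axial profile is the per-slice mean enamel density against distance from
the cervical margin — the primary densitometric readout. Slices whose enamel
cross-section falls below a minimum area (default 0.02 mm^2) are dropped
before any statistic is computed: near the cervical margin the enamel is
only a few voxels thick and slice means there are dominated by partial-volume
and segmentation error. The surface shell restricts the same computation to
the outer 30 um of enamel, where post-eruptive maturation is concentrated.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import (
    AlignmentError,
    EmptyBandError,
    EmptyProfileError,
    ValidationError,
)
from .volume import EnamelMask, Tomogram, require_congruent

#: slice area threshold from the measurement protocol, mm^2
DEFAULT_MIN_AREA_MM2 = 0.02
#: surface shell depth, um
DEFAULT_SHELL_UM = 30.0
#: moving-average width, samples
DEFAULT_WINDOW = 5


@dataclass
class SurfaceShellMask(EnamelMask):
    """Binary mask of the outer ``depth_um`` of an enamel mask."""

    depth_um: float = DEFAULT_SHELL_UM


@dataclass
class AxialDensityProfile:
    """Per-slice mean density and cross-sectional area vs. axial position.

    ``x_mm`` is measured from the cervical-most enamel-containing slice and
    is strictly increasing; slices removed by the area filter are absent,
    not zero-filled. ``gumline_mm`` registers the gingival emergence plane
    on the same axis (required for band statistics). ``sd`` is present on
    averaged profiles only.
    """

    x_mm: np.ndarray
    mean_density: np.ndarray
    area_mm2: np.ndarray
    axial_step_mm: float
    gumline_mm: float | None = None
    smoothed: bool = False
    window: int | None = None
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.mean_density = np.asarray(self.mean_density, dtype=float)
        self.area_mm2 = np.asarray(self.area_mm2, dtype=float)
        if not (np.diff(self.x_mm) > 0).all():
            raise ValidationError("x_mm must be strictly increasing")
        if (self.area_mm2 < 0).any():
            raise ValidationError("area_mm2 must be >= 0")
        if len({self.x_mm.size, self.mean_density.size, self.area_mm2.size}) != 1:
            raise ValidationError("profile arrays must have equal length")

    def __len__(self) -> int:
        return self.x_mm.size


def surface_shell(
    mask: EnamelMask,
    depth_um: float = DEFAULT_SHELL_UM,
    exclude: np.ndarray | None = None,
) -> SurfaceShellMask:
    """Enamel voxels within ``depth_um`` of the outer (exterior) surface.

    Distances are Euclidean between voxel centres, scaled by the pitch. Only
    the background component connected to the volume border counts as
    exterior, so internal cavities never contribute "surface" voxels.

    ``exclude`` marks non-enamel tissue (typically dentin, e.g. thresholded
    from the density volume) that must not count as exterior either:
    without it, a dentin core reaching the volume border would make the
    dentin-enamel junction look like an outer surface.
    """
    if not mask.voxels.any():
        raise ValidationError("mask is empty")
    if not depth_um > 0:
        raise ValidationError("depth_um must be positive")
    if depth_um < mask.voxel_um / 2:
        warnings.warn(
            "shell depth below half a voxel; shell may be empty", stacklevel=2
        )
    background = ~mask.voxels
    if exclude is not None:
        if exclude.shape != mask.shape:
            raise ValidationError("exclude volume shape differs from mask")
        background = background & ~np.asarray(exclude, bool)
    labels, _ = ndimage.label(background)
    border_labels = np.unique(
        np.concatenate(
            [
                labels[0].ravel(), labels[-1].ravel(),
                labels[:, 0].ravel(), labels[:, -1].ravel(),
                labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
            ]
        )
    )
    border_labels = border_labels[border_labels != 0]
    exterior = np.isin(labels, border_labels)
    dist_um = ndimage.distance_transform_edt(~exterior, sampling=mask.voxel_um)
    shell = mask.voxels & (dist_um <= depth_um + 1e-9)
    return SurfaceShellMask(shell, mask.voxel_um, depth_um=depth_um)


def axial_profile(
    tom: Tomogram,
    mask: EnamelMask,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
    gumline_mm: float | None = None,
) -> AxialDensityProfile:
    """Per-slice mean enamel density with the minimum-area filter applied.

    Area per slice is ``voxel_count * (voxel_um / 1000)^2``; slices below
    ``min_area_mm2`` are dropped. ``x = 0`` at the cervical-most
    enamel-containing slice (before filtering), per the repo convention.
    """
    require_congruent(tom, mask)
    counts = mask.voxels.sum(axis=(1, 2))
    nz = np.flatnonzero(counts)
    if nz.size == 0:
        raise EmptyProfileError("mask contains no enamel voxels")
    i0 = nz[0]
    area = counts * (tom.voxel_um / 1000.0) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        sums = np.where(mask.voxels, tom.voxels, 0.0).sum(axis=(1, 2))
        means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    keep = area >= min_area_mm2
    if not keep.any():
        raise EmptyProfileError("no slice meets the minimum-area threshold")
    idx = np.flatnonzero(keep)
    x_mm = (idx - i0) * (tom.voxel_um / 1000.0)
    return AxialDensityProfile(
        x_mm=x_mm,
        mean_density=means[idx],
        area_mm2=area[idx],
        axial_step_mm=tom.voxel_um / 1000.0,
        gumline_mm=gumline_mm,
    )


def smooth_profile(
    p: AxialDensityProfile, window: int = DEFAULT_WINDOW
) -> AxialDensityProfile:
    """Centred moving average of the density values.

    Edges use shrinking symmetric windows (widths 1, 3, 5, ... for window 5),
    so the profile keeps its length and its positions. The window must be
    odd and no longer than the profile.
    """
    if window % 2 == 0:
        raise ValidationError("window must be odd")
    if not 1 <= window <= len(p):
        raise ValidationError("window must be in [1, profile length]")
    half = window // 2
    y = p.mean_density
    n = y.size
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = y[i - k : i + k + 1].mean()
    return replace(p, mean_density=out, smoothed=True, window=window)


def band_mean(
    p: AxialDensityProfile, from_mm: float, to_mm: float
) -> tuple[float, float]:
    """Mean and sample SD of density over a gumline-relative axial band.

    The band is half-open: samples with
    ``from_mm <= x - gumline_mm < to_mm`` are included, so adjacent bands
    partition the axis. Requires a registered gumline.
    """
    if not from_mm < to_mm:
        raise ValidationError("from_mm must be below to_mm")
    if p.gumline_mm is None:
        raise ValidationError("profile has no registered gumline")
    rel = p.x_mm - p.gumline_mm
    sel = (rel >= from_mm) & (rel < to_mm)
    if not sel.any():
        raise EmptyBandError(f"band [{from_mm}, {to_mm}) mm is empty")
    vals = p.mean_density[sel]
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


def average_profiles(ps: list[AxialDensityProfile]) -> AxialDensityProfile:
    """Pointwise mean and sample SD over profiles aligned at the cervical margin.

    Profiles are linearly interpolated onto the first profile's grid,
    restricted to the x-range shared by all of them.
    """
    if len(ps) < 2:
        raise ValidationError("need at least 2 profiles to average")
    lo = max(p.x_mm[0] for p in ps)
    hi = min(p.x_mm[-1] for p in ps)
    if lo > hi:
        raise AlignmentError("profiles have disjoint axial ranges")
    base = ps[0]
    sel = (base.x_mm >= lo - 1e-12) & (base.x_mm <= hi + 1e-12)
    if not sel.any():
        raise AlignmentError("no shared grid points after alignment")
    grid = base.x_mm[sel]
    dens = np.vstack([np.interp(grid, p.x_mm, p.mean_density) for p in ps])
    area = np.vstack([np.interp(grid, p.x_mm, p.area_mm2) for p in ps])
    gums = {p.gumline_mm for p in ps}
    return AxialDensityProfile(
        x_mm=grid,
        mean_density=dens.mean(axis=0),
        area_mm2=area.mean(axis=0),
        axial_step_mm=base.axial_step_mm,
        gumline_mm=gums.pop() if len(gums) == 1 else None,
        smoothed=all(p.smoothed for p in ps),
        window=base.window,
        sd=dens.std(axis=0, ddof=1),
    )
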