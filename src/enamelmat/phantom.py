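"""Synthetic tooth phantoms with the kinematic structure of a growing incisor.

A continuously erupting incisor deposits new enamel at the cervical margin
and carries it occlusally as the tooth extends; maturation proceeds at a
fixed temporal rate, so a single scan shows a spatial record of the temporal
process ("space-for-time"). The phantom implements the closed-form density
field of that model, rasterizes it onto an axisymmetric enamel shell over a
dentin core, and also generates Vickers-hardness tables and fluorescein
stacks with matching statistical structure, so every downstream analysis
stage can be validated without real scans.

Model
-----
Let ``v`` be the crown extension rate (mm/wk), ``L`` the final crown length,
``rho0``/``rho1`` the density of freshly deposited and fully mature enamel,
and ``m`` the maturation ramp length. In a jaw-anchored frame with ``z``
increasing occlusally and ``z = 0`` at the final cervical margin position,

    rho(z, age) = clip(rho0 + s * (z - L + v * age), rho0, rho1),
    s = (rho1 - rho0) / m,

which satisfies the space-for-time identity
``rho(z, t + dt) = rho(z + v * dt, t)`` exactly for every age pair, reduces
to the linear ramp-plus-plateau profile while the crown is still growing,
and is uniformly at plateau once ``v * age - L >= m`` (fully mature limit).
The cervical margin sits at ``z = max(0, L - v * age)``; distances from the
margin are ``x = z - z_margin``.

The 30 um surface layer is hypomineralized and does *not* follow
space-for-time: its density is an age-dependent parameter
(``surface_rho_by_age``), emulating post-eruptive surface maturation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .errors import ValidationError, VolumeBudgetError
from .porosity import FluoresceinStack
from .volume import EnamelMask, Tomogram

__all__ = [
    "PhantomSpec",
    "DensityField",
    "HardnessDesign",
    "simulate_density_field",
    "surface_density",
    "render_tomogram",
    "make_hardness_table",
    "make_fluorescein_stack",
]

#: default age-resolved surface-layer densities, mg_HA/cm^3
DEFAULT_SURFACE_RHO = {2.0: 1644.0, 4.0: 1977.0, 16.0: 1959.0}

#: default cell means (HV) for the hardness design, (age_weeks, level)
DEFAULT_CELL_MEANS = {
    (2, "below"): 224.0, (2, "at"): 280.0, (2, "above"): 344.0,
    (4, "below"): 330.0, (4, "at"): 350.0, (4, "above"): 372.0,
    (16, "below"): 345.0, (16, "at"): 350.0, (16, "above"): 355.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of the synthetic tooth.

    Geometry is an idealized axisymmetric enamel shell around a cylindrical
    dentin core; enamel thickness tapers linearly to near zero over
    ``enamel_taper_mm`` at the cervical end (the thin cervical enamel is
    what the downstream minimum-area filter exists for).

    ``voxel_um`` defaults to the scanner pitch of 6 um; tests and examples
    render at 24-48 um to keep volumes in the 10^6-voxel range — the model
    is pitch-free.
    """

    crown_length_mm: float = 16.0
    enamel_thickness_mm: float = 0.6
    dentin_radius_mm: float = 1.0
    voxel_um: float = 6.0
    extension_rate_mm_per_wk: float = 5.0
    gumline_mm: float = 6.0
    rho_plateau: float = 2083.0
    rho_initial: float = 1600.0
    rho_dentin: float = 1200.0
    maturation_ramp_mm: float = 6.0
    surface_layer_um: float = 30.0
    surface_rho_by_age: Mapping[float, float] | None = field(
        default_factory=lambda: dict(DEFAULT_SURFACE_RHO)
    )
    enamel_taper_mm: float = 1.0
    noise_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "crown_length_mm", "enamel_thickness_mm", "dentin_radius_mm",
            "voxel_um", "extension_rate_mm_per_wk", "maturation_ramp_mm",
            "enamel_taper_mm",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.gumline_mm < 0 or self.surface_layer_um < 0 or self.noise_sd < 0:
            raise ValidationError("gumline_mm, surface_layer_um, noise_sd must be >= 0")
        if not self.rho_initial < self.rho_plateau:
            raise ValidationError("rho_initial must be below rho_plateau")
        if self.rho_initial < 0:
            raise ValidationError("rho_initial must be >= 0")
        if self.voxel_um > self.enamel_thickness_mm * 1000:
            raise ValidationError("voxel_um exceeds the enamel thickness")
        if self.surface_rho_by_age is not None and not self.surface_rho_by_age:
            raise ValidationError("surface_rho_by_age must be None or non-empty")

    @property
    def formation_end_age_wk(self) -> float:
        """Age at which the crown reaches its final length and growth stops."""
        return self.crown_length_mm / self.extension_rate_mm_per_wk

    @property
    def ramp_slope(self) -> float:
        """Maturation ramp slope, mg_HA/cm^3 per mm."""
        return (self.rho_plateau - self.rho_initial) / self.maturation_ramp_mm

    def with_(self, **kwargs) -> "PhantomSpec":
        """A copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DensityField:
    """Closed-form axial density field rho(x) at one age, plus a sampled grid.

    ``x_mm`` is distance from the cervical margin at this age;
    ``margin_z_mm`` places the margin in the fixed jaw frame so fields at
    different ages can be compared at matched physical positions.
    """

    x_mm: np.ndarray
    rho: np.ndarray
    axial_step_mm: float
    age_weeks: float
    length_mm: float
    margin_z_mm: float
    rho_initial: float
    rho_plateau: float
    slope: float
    shift_mm: float

    def at(self, x_mm) -> np.ndarray:
        """Exact density at distance ``x_mm`` from this age's cervical margin."""
        x = np.asarray(x_mm, dtype=float)
        return np.clip(
            self.rho_initial + self.slope * (x + self.shift_mm),
            self.rho_initial,
            self.rho_plateau,
        )

    def at_fixed(self, z_mm) -> np.ndarray:
        """Density at fixed-frame coordinate ``z_mm`` (jaw-anchored)."""
        return self.at(np.asarray(z_mm, dtype=float) - self.margin_z_mm)


def simulate_density_field(
    spec: PhantomSpec, age_weeks: float, axial_step_mm: float | None = None
) -> DensityField:
    """Axial mineral-density profile of the phantom at a given age.

    While the crown is still extending the profile is the steady-state
    linear ramp from ``rho_initial`` over ``maturation_ramp_mm`` followed by
    the plateau; after formation ends the ramp recedes cervically at speed
    ``v`` until the whole crown is at plateau.
    """
    if not age_weeks > 0:
        raise ValidationError("age_weeks must be positive")
    v = spec.extension_rate_mm_per_wk
    length = min(spec.crown_length_mm, v * age_weeks)
    shift = max(0.0, v * age_weeks - spec.crown_length_mm)
    step = spec.voxel_um / 1000.0 if axial_step_mm is None else float(axial_step_mm)
    if not step > 0:
        raise ValidationError("axial_step_mm must be positive")
    x = np.arange(0.0, length + step / 2, step)
    fld = DensityField(
        x_mm=x,
        rho=np.empty(0),
        axial_step_mm=step,
        age_weeks=float(age_weeks),
        length_mm=length,
        margin_z_mm=max(0.0, spec.crown_length_mm - v * age_weeks),
        rho_initial=spec.rho_initial,
        rho_plateau=spec.rho_plateau,
        slope=spec.ramp_slope,
        shift_mm=shift,
    )
    object.__setattr__(fld, "rho", fld.at(x))
    return fld


def surface_density(spec: PhantomSpec, age_weeks: float) -> float | None:
    """Surface-layer density at an age (linear interpolation between table ages).

    Returns None when the spec disables the distinct surface layer.
    """
    if spec.surface_rho_by_age is None:
        return None
    ages = np.array(sorted(spec.surface_rho_by_age))
    vals = np.array([spec.surface_rho_by_age[a] for a in ages])
    return float(np.interp(age_weeks, ages, vals))


def render_tomogram(
    spec: PhantomSpec,
    fld: DensityField,
    max_voxels: int = 40_000_000,
    pad_voxels: int = 3,
) -> tuple[Tomogram, EnamelMask]:
    """Rasterize a density field onto an axisymmetric shell-on-core phantom.

    Enamel voxels take the field value at the voxel's axial position, except
    voxels within ``surface_layer_um`` of the outer surface, which take the
    age-resolved surface density. Dentin is a uniform cylinder; Gaussian
    noise of sd ``noise_sd`` is added everywhere. The ground-truth enamel
    mask is returned alongside. Deterministic for a fixed ``spec.seed``.
    """
    pitch = spec.voxel_um / 1000.0  # mm
    n_ax = int(round(fld.length_mm / pitch))
    if n_ax < 2:
        raise ValidationError("field too short for this voxel pitch")
    r_out = spec.dentin_radius_mm + spec.enamel_thickness_mm
    half = int(np.ceil(r_out / pitch)) + pad_voxels
    n_tr = 2 * half + 1
    nz = n_ax + 2 * pad_voxels
    if nz * n_tr * n_tr > max_voxels:
        raise VolumeBudgetError(
            f"render of {nz}x{n_tr}x{n_tr} = {nz * n_tr * n_tr} voxels exceeds "
            f"budget {max_voxels}; coarsen voxel_um or raise max_voxels"
        )
    jj, kk = np.meshgrid(np.arange(n_tr), np.arange(n_tr), indexing="ij")
    r_mm = np.hypot(jj - half, kk - half) * pitch

    # axial position of slice centres, mm from the cervical-most enamel slice
    i = np.arange(nz)
    x_mm = (i - pad_voxels) * pitch
    in_crown = (i >= pad_voxels) & (i < pad_voxels + n_ax)
    # linear thickness taper at the cervical end, floored at 5% so the
    # cervical-most slice still carries a (thin, filterable) enamel ring
    th = spec.enamel_thickness_mm * np.clip(
        x_mm / spec.enamel_taper_mm, 0.05, 1.0
    )
    enamel = (
        in_crown[:, None, None]
        & (r_mm[None] > spec.dentin_radius_mm)
        & (r_mm[None] <= spec.dentin_radius_mm + th[:, None, None])
    )
    dentin = in_crown[:, None, None] & (r_mm[None] <= spec.dentin_radius_mm)

    vol = np.zeros((nz, n_tr, n_tr), dtype=np.float64)
    vol[dentin] = spec.rho_dentin
    rho_ax = fld.at(np.clip(x_mm, 0.0, fld.length_mm))
    vol += enamel * rho_ax[:, None, None]

    rho_surf = surface_density(spec, fld.age_weeks)
    if rho_surf is not None and spec.surface_layer_um > 0:
        exterior = ~(enamel | dentin)
        dist_um = ndimage.distance_transform_edt(
            ~exterior, sampling=spec.voxel_um
        )
        surf = enamel & (dist_um <= spec.surface_layer_um + 1e-9)
        vol[surf] = rho_surf

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol += rng.normal(0.0, spec.noise_sd, vol.shape)

    tom = Tomogram(vol.astype(np.float32), spec.voxel_um)
    mask = EnamelMask(enamel, spec.voxel_um)
    return tom, mask


@dataclass(frozen=True)
class HardnessDesign:
    """Balanced factorial design for synthetic Vickers-hardness tables.

    Factors are animal age (2/4/16 weeks) and position relative to the
    gingival emergence plane (below = pre-eruptive, at, above =
    post-eruptive). Nine indents per site mirrors the measurement protocol.
    """

    cell_means: Mapping[tuple[int, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CELL_MEANS)
    )
    residual_sd: float = 40.0
    replicates_per_cell: int = 9
    animals_per_age: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_cell < 2:
            raise ValidationError("replicates_per_cell must be >= 2")
        if any(m <= 0 for m in self.cell_means.values()):
            raise ValidationError("all cell means must be positive")
        if self.residual_sd < 0:
            raise ValidationError("residual_sd must be >= 0")
        if self.animals_per_age < 1:
            raise ValidationError("animals_per_age must be >= 1")


def make_hardness_table(design: HardnessDesign) -> "pandas.DataFrame":
    """Long-format HV table: cell mean + N(0, residual_sd), balanced.

    Columns: ``animal_id, age_weeks, level, region, side, hv``. Replicates
    within a cell cycle through animals, enamel regions (inner/mid/outer)
    and sides (buccal/lingual). Deterministic under the design seed.
    """
    import pandas as pd

    rng = np.random.default_rng(design.seed)
    regions = ("inner", "mid", "outer")
    sides = ("buccal", "lingual")
    rows = []
    for (age, level), mean in sorted(design.cell_means.items()):
        for rep in range(design.replicates_per_cell):
            rows.append(
                {
                    "animal_id": f"p{age}w{rep % design.animals_per_age + 1}",
                    "age_weeks": age,
                    "level": level,
                    "region": regions[rep % 3],
                    "side": sides[rep % 2],
                    "hv": mean + rng.normal(0.0, design.residual_sd),
                }
            )
    return pd.DataFrame(rows)


def make_fluorescein_stack(
    depth_constant_um: float,
    surface_intensity: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int, int] = (16, 128, 64),
    voxel_um: float = 2.0,
) -> FluoresceinStack:
    """Synthetic confocal stack with exponentially decaying penetration.

    Noise-free intensity at depth ``d`` from the surface plane (axis 1,
    row 0) is ``surface_intensity * exp(-d / depth_constant_um)``; Gaussian
    noise is added and clipped at zero (intensities are non-negative).
    """
    if not depth_constant_um > 0:
        raise ValidationError("depth_constant_um must be positive")
    if surface_intensity <= 0 or noise_sd < 0:
        raise ValidationError("surface_intensity > 0 and noise_sd >= 0 required")
    d = np.arange(shape[1]) * voxel_um
    signal = surface_intensity * np.exp(-d / depth_constant_um)
    vox = np.broadcast_to(signal[None, :, None], shape).astype(float).copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vox += rng.normal(0.0, noise_sd, shape)
    np.clip(vox, 0.0, None, out=vox)
    return FluoresceinStack(vox, voxel_um=voxel_um, surface_index=0)
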