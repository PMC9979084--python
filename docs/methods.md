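# Methods

`enamelmat` quantifies post-eruptive enamel maturation from calibrated
micro-CT volumes. This note records the models, the defaults and why they
hold, the numerical choices, and what the synthetic phantom does and does
not establish about real data.

## The space-for-time model

In a continuously growing incisor, enamel is deposited at the cervical
margin and carried occlusally as the crown extends at rate *v* (mm/wk).
If maturation proceeds at a fixed temporal rate, a single scan contains a
spatial record of the temporal process: a cross-section at position *x*
(measured from the cervical margin toward the cusp) will, after time *δt*,
have the density that the section at *x + v·δt* has now. The phantom
implements the closed-form density field of that kinematic model. In a
jaw-anchored frame with *z* increasing occlusally and *z = 0* at the final
cervical margin position,

    ρ(z, age) = clip( ρ0 + s·(z − L + v·age),  ρ0,  ρ1 ),     s = (ρ1 − ρ0)/m

where *L* is the final crown length, *ρ0*/*ρ1* the densities of freshly
deposited and fully mature enamel, and *m* the maturation ramp length.
This field satisfies the shift identity ρ(z, t+δt) = ρ(z + v·δt, t)
**exactly** for every age pair; while the crown is still growing it is the
steady-state profile — a linear ramp from ρ0 over *m* mm, then a plateau —
and once *v·age − L ≥ m* it is uniformly at plateau (the fully-mature
limit). The identity fails, by construction, only for the surface layer
(below).

`DensityField` exposes both margin coordinates (`at`, *x* from the current
cervical margin) and the fixed frame (`at_fixed`), so fields at different
ages can be compared at matched physical positions.

Δρ is a spatial proxy: it depends on the mineralization rate *and* on
growth/eruption speed. No conversion to a per-week rate is attempted
without a user-supplied extension rate.

## The mineral-addition-rate statistic Δρ

For a density profile ρ(x) and a step δx (default 1 mm):

* absolute mode: Δρ(x) = (ρ(x+δx) − ρ(x)) / δx, in mg_HA/cm³ per mm;
* relative mode: Δρ(x) = (ρ(x+δx) − ρ(x)) / (ρ(x)·δx), per mm.

Both normalizations circulate in the literature for this statistic — the
normalized form is sometimes written with the un-normalized form's units —
so both are first-class here, every output records which was used, and
absolute is the default. δx is applied on physical distance with linear
interpolation, not on sample counts, so results are pitch-independent.

## Phantom geometry and defaults

The phantom is an idealized axisymmetric enamel shell around a cylindrical
dentin core — the downstream statistics consume only per-slice summaries,
so anatomical shape fidelity buys nothing, while an analytic geometry keeps
every expected value computable by hand. Enamel thickness tapers linearly
to 5% over `enamel_taper_mm` at the cervical end, reproducing the thin,
artifact-prone cervical enamel that motivates the minimum-area filter.

Defaults, chosen once (values marked † are protocol constants; the rest
are geometric/kinematic choices that make the three modeled ages behave
like the study conditions):

| parameter | default | note |
|---|---|---|
| voxel_um | 6 † | scanner pitch; tests render at 24–48 µm, the model is pitch-free |
| rho_plateau | 2083 † | mature enamel, mg_HA/cm³ |
| surface_rho_by_age | 1644 / 1977 / 1959 † | surface-layer density at 2/4/16 wk |
| surface_layer_um | 30 † | distinct hypomineralized surface compartment |
| crown_length_mm | 16 | with v = 5: 10 mm crown at 2 wk, fully formed by ~3.2 wk |
| extension_rate (v) | 5 mm/wk | fast-erupting incisor; ramp reaches plateau at the gumline at 2 wk |
| gumline_mm | 6 | leaves ≥ 3 mm of erupted crown at 2 wk for the surface band |
| maturation_ramp_mm | 6 | at 4 wk the residual ramp sits ~4 mm below the gumline |
| rho_initial | 1600 | freshly deposited enamel, above dentin |
| rho_dentin | 1200 | below the segmentation band so the threshold contract is satisfiable |
| noise_sd | 50 | additive Gaussian, mg_HA/cm³ |

The surface layer takes the age-resolved density from
`surface_rho_by_age` (linear interpolation between table ages) and is the
one deliberate violation of space-for-time: post-eruptive surface
maturation depends on time in the oral cavity, not on axial position.
Setting `surface_rho_by_age=None` makes the surface follow the bulk field,
which is how the rendered space-for-time check avoids confounding.

Noise is additive Gaussian only; Poisson statistics, beam hardening, ring
artifacts and partial-volume blur are not modeled. Consequently, passing
recovery tests show the *estimators* are unbiased and correctly scaled
under the stated noise, not that real scans are free of systematic error.

## Segmentation and reorientation

Real enamel overlaps dentin in density near the cervical margin, which is
why learned segmenters are used on real scans. Here a classical reference
segmentation (density band [lo, hi] → binary closing → removal of
components below `min_component_voxels`; equally large components are all
kept, since enamel may be split by wear) defines the mask **contract** —
Dice ≥ 0.95 against ground truth at noise SD ≤ 50 — that any replacement
segmenter must meet.

Reorientation aligns the principal axis of the mask's second-moment tensor
with the slice axis. Sign convention: the lower-mean-density half (the
cervical, newest enamel) points toward low slice indices; for flat density
the centroid-to-far-end direction is used. Density is resampled
trilinearly, the mask nearest-neighbour; a relative eigenvalue gap below
5% raises an orientation-ambiguous error instead of guessing. Resampling
preserves mask volume within 2% and mean enamel density within 1%.

Coordinates, repo-wide: 0-based voxel indices, axis 0 axial; physical
position of slice *i* is (i + 0.5)·voxel_um; axial distances are reported
in mm from the cervical-most enamel-containing slice.

## Profiles, the area filter, bands

Per-slice mean density is computed over mask voxels; slice area is
count·(voxel_um/1000)². Slices below `min_area_mm2` (default 0.02 mm²,
i.e. ≥ 556 voxels at 6 µm) are dropped *before* smoothing — near the
cervical margin the enamel is a few voxels thin and slice means there are
partial-volume dominated. When the phantom is rendered at coarsened pitch
(24–48 µm) the same area corresponds to 16–64× fewer voxels, so
noise-bound tests at coarse pitch either restrict to full-thickness slices
or propagate the per-slice standard error explicitly; this is a property
of the desk-scale rendering, not of the method.

Smoothing is a centred 5-sample moving average; edges use shrinking
symmetric windows (widths 1, 3, 5, …), which preserves profile length and
positions and never overshoots the input range. The profile is smoothed on
whatever grid it carries (the grid pitch is recorded), since the original
protocol does not state its resampling.

The surface shell is the set of enamel voxels whose Euclidean
centre-to-centre distance to the nearest *exterior* voxel is ≤ 30 µm.
Exterior means the background component connected to the volume border,
minus an optional `exclude` volume of dense non-enamel tissue: a dentin
core that reaches the volume border is background in the mask's complement
but is not an outer surface, and without the exclusion the dentin–enamel
junction would be misread as one. The pipeline builds the exclusion by
thresholding the density volume at `exterior_max_density` (default
600 mg_HA/cm³, comfortably between air and dentin).

Band summaries (e.g. the surface band from the gumline to 3 mm above) are
half-open [from, to) relative to the registered gumline, so adjacent bands
partition the axis. The gumline is a required input — physically marked on
real specimens, known exactly for phantoms — and is never auto-detected.

Bulk-parameter recovery (plateau, ramp slope) is measured on the enamel
interior (mask minus the 30 µm shell): the surface layer is a distinct,
separately reported compartment, and at coarse pitch its single-voxel
shell would otherwise bias full-mask slice means by ~1% (plateau) and ~5%
(ramp slope).

## Hardness statistics

HV = 1854.4·load(gf)/d²(µm). Values outside 10–600 HV are flagged, not
rejected. The factorial analysis is a two-way ANOVA (age × gumline level)
with interaction, Type III sums of squares under sum-to-zero contrasts —
the convention of the commercial package this protocol family is analysed
in, and identical to the classical decomposition for balanced designs.
Degenerate inputs are handled explicitly: an all-constant response gives
F = 0, p = 1 for every effect; a perfect fit (zero residual SS with
non-zero effect SS) reports F = ∞ with an `infinite` flag rather than NaN.
Indent-level tables can be aggregated to per-animal cell means
(`aggregate="animal_id"`), the convention that yields the small residual
degrees of freedom typical of site-mean F tests. Pairwise comparisons use
the Tukey–Kramer studentized-range adjustment, by default on the factorial
model's residual variance; with two groups it reduces to the pooled
t-test.

## Fluorescein penetration

The assessment is made quantitative: from a maximum intensity projection,
mean intensity per depth bin from a straight surface line; the profile is
made non-increasing by a running maximum from deep to shallow (speckle
resistance); `depth_at_fraction` is the first depth below a stated
fraction (default 1/e) of the surface reference, defined as the mean of
the first three bins. The decay-length fit subtracts a constant background
estimated from the deepest 10% of bins (max-projection of noise has a
positive floor) and runs OLS on log intensity over bins above 5% of the
corrected surface reference. Depth is measured perpendicular to the
supplied surface line; curved-surface geodesic depth is out of scope.
Cross-specimen comparisons use depth constants, never raw intensities,
because staining and acquisition are not normalized across specimens.

## Problem sizes and determinism

Phantom-based checks render at 24 µm (parameter recovery, space-for-time,
segmentation Dice; ~10⁷ voxels) and 48 µm (reorientation; the padded
rotation resample cubes the volume). Monte-Carlo calibrations use 1000
null replicates (ANOVA type-I error, Tukey family-wise error) and 200
replicates for power. All randomness flows through explicit integer seeds
into `numpy.random.default_rng`; identical spec + seed gives bit-identical
volumes, and re-running the pipeline with the same config reproduces the
report byte-for-byte.

## Known limitations

* The phantom's geometry is axisymmetric; no cusp shape, wear facets, or
  curvature of the enamel ribbon. Per-slice statistics are exact for it.
* The maturation law is piecewise-linear; no sigmoid tail. The rendered
  surface compartment has a sharp inner boundary.
* Micro-CT artifacts (beam hardening, rings, partial volume) are absent;
  segmentation difficulty on real scans is understated by design.
* The ANOVA convention (Type III, sum-to-zero) matters only for unbalanced
  tables; other software defaults (Type I/II) will disagree there.
* Weight/volume mineral fractions are not modeled; the package works in
  mg_HA/cm³ throughout.
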