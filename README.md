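# enamelmat

Micro-CT densitometry and statistics for **post-eruptive enamel
maturation** — the continued hardening and mineral uptake of tooth enamel
after it has erupted into the mouth.

Teeth that erupt early (like pig first incisors, a model for fast human
primary-tooth formation) leave the gum with soft, hypomineralized, porous
enamel and finish mineralizing in the oral cavity. Quantifying that
process from 3D scans requires a small but specific toolchain, which this
package provides for image analysts and mineralized-tissue researchers:

* **Axial density profiling** — per-slice mean mineral density ρ
  (mg_HA/cm³) of a segmented enamel shell against distance *x* from the
  cervical margin, with a minimum cross-section area filter (0.02 mm²)
  and 5-point moving-average smoothing.
* **Surface-shell profiling** — the same statistic restricted to the outer
  30 µm of enamel, extracted with a Euclidean distance transform against
  the exterior (air-facing) surface.
* **The mineral-addition rate Δρ** — the spatial gradient statistic
  Δρ(x) = (ρ(x+δx) − ρ(x))/δx (default δx = 1 mm; a relative mode divides
  by ρ(x)). Under the space-for-time assumption — each cross-section
  replays its occlusal neighbour's history after a lag δx = v·δt set by
  the crown extension rate *v* — Δρ is a proxy for the temporal
  mineralization rate from a single scan.
* **Vickers microhardness statistics** — HV = 1854.4·F/d², two-way ANOVA
  (age × position relative to the gumline, Type III sums of squares) with
  Tukey HSD post hocs.
* **Fluorescein penetration depth** — a quantitative metric (threshold
  depth and exponential decay length from maximum intensity projections)
  for the porosity of erupted enamel.
* **A synthetic tooth-phantom generator** implementing the space-for-time
  kinematics in closed form, so the whole pipeline is testable without
  real scans: ρ(z, age) = clip(ρ0 + s·(z − L + v·age), ρ0, ρ1) satisfies
  ρ(z, t+δt) = ρ(z + v·δt, t) exactly.

Volumes travel as TIFF stacks or NIfTI, tables as CSV; see
`docs/methods.md` for the model, conventions and limitations.

## Worked example

Simulate a 2-week-old incisor analogue (still growing: ramp from fresh
enamel at the margin to the 2083 mg_HA/cm³ plateau at the gumline, with a
hypomineralized 1644 mg_HA/cm³ surface layer), then run the measurement
chain on the rendered volume:

```python
import numpy as np
from enamelmat import *
from enamelmat.phantom import PhantomSpec

spec = PhantomSpec(voxel_um=24.0, seed=0)          # 24 um test pitch
fld = simulate_density_field(spec, age_weeks=2.0)
tom, truth = render_tomogram(spec, fld)             # noisy volume + truth mask

mask = segment_enamel(tom, lo=1400.0, hi=2600.0)
print("dice vs truth:", round(dice(mask.voxels, truth.voxels), 4))

tissue = (~mask.voxels) & (tom.voxels >= 600.0)     # dentin is not "outside"
shell = surface_shell(mask, 30.0, exclude=tissue)
p_surf = axial_profile(tom, EnamelMask(shell.voxels, 24.0), 0.02, gumline_mm=6.0)
p_whole = axial_profile(tom, mask, 0.02, gumline_mm=6.0)

m, s = band_mean(smooth_profile(p_surf, 5), 0.0, 3.0)
print(f"surface band (gumline..+3 mm): {m:.0f} +/- {s:.0f} mg_HA/cm^3")

r = mineral_addition_rate(smooth_profile(p_whole, 5), 1.0, "absolute")
on_ramp = (r.x_mm >= 0.5) & (r.x_mm <= 4.5)
print(f"mean absolute rate on the ramp: {r.rate[on_ramp].mean():.1f} mg_HA/cm^3 per mm")
```

Output:

```
dice vs truth: 1.0
surface band (gumline..+3 mm): 1644 +/- 1 mg_HA/cm^3
mean absolute rate on the ramp: 77.0 mg_HA/cm^3 per mm
```

The segmentation recovers the ground-truth mask essentially exactly at
this noise level; the surface band reproduces the generator's 2-week
surface density (1644 mg_HA/cm³); and the whole-thickness Δρ on the ramp
sits a few percent below the generator's bulk slope (80.5 mg_HA/cm³ per
mm) because the whole-thickness profile includes the constant-density
surface compartment — measuring on the enamel interior recovers the slope
itself (see `docs/methods.md`).

There is also a CLI for shell use —
`enamelmat simulate|segment|reorient|profile|rate|hardness|fluorescein|run`
— each subcommand a thin wrapper over the functions above.

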