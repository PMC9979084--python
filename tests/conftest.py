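import numpy as np
import pytest

from enamelmat.phantom import PhantomSpec, render_tomogram, simulate_density_field


@pytest.fixture(scope="session")
def coarse_spec() -> PhantomSpec:
    """A small, fast phantom: 48 um pitch, 8 mm crown (model is pitch-free)."""
    return PhantomSpec(
        crown_length_mm=8.0,
        enamel_thickness_mm=0.6,
        dentin_radius_mm=0.8,
        voxel_um=48.0,
        extension_rate_mm_per_wk=2.5,
        gumline_mm=3.0,
        maturation_ramp_mm=4.0,
        enamel_taper_mm=0.5,
        noise_sd=50.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def clean_spec(coarse_spec) -> PhantomSpec:
    """Noise-free variant with the surface layer following the bulk field."""
    return coarse_spec.with_(noise_sd=0.0, surface_rho_by_age=None)


@pytest.fixture(scope="session")
def young_phantom(coarse_spec):
    """Rendered 2-week-analogue phantom (still growing, ramp visible)."""
    fld = simulate_density_field(coarse_spec, 2.0)
    tom, mask = render_tomogram(coarse_spec, fld)
    return coarse_spec, fld, tom, mask


@pytest.fixture(scope="session")
def mature_phantom(coarse_spec):
    """Rendered fully-mature phantom (16-week analogue, uniform plateau)."""
    fld = simulate_density_field(coarse_spec, 16.0)
    tom, mask = render_tomogram(coarse_spec, fld)
    return coarse_spec, fld, tom, mask
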