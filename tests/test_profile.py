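"""Surface shell, axial profiles, smoothing, bands and averaging."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enamelmat.errors import (
    AlignmentError,
    EmptyBandError,
    EmptyProfileError,
    ValidationError,
)
from enamelmat.profile import (
    AxialDensityProfile,
    average_profiles,
    axial_profile,
    band_mean,
    smooth_profile,
    surface_shell,
)
from enamelmat.volume import EnamelMask, Tomogram
from oracles import brute_force_shell, random_blob_mask


def _profile(x, y, gumline=None, step=1.0, **kw):
    return AxialDensityProfile(
        x_mm=np.asarray(x, float),
        mean_density=np.asarray(y, float),
        area_mm2=np.ones(len(x)),
        axial_step_mm=step,
        gumline_mm=gumline,
        **kw,
    )


class TestSurfaceShell:
    def test_thin_mask_equals_mask(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[4:6, 2:8, 2:8] = True  # 2 voxels thick everywhere
        shell = surface_shell(EnamelMask(mask, 6.0), depth_um=30.0)
        assert np.array_equal(shell.voxels, mask)

    def test_solid_cube_shell_count(self):
        # 20^3 cube at 6 um, depth 30 um = 5 voxel layers -> 20^3 - 10^3
        mask = np.zeros((26, 26, 26), bool)
        mask[3:23, 3:23, 3:23] = True
        shell = surface_shell(EnamelMask(mask, 6.0), depth_um=30.0)
        assert shell.voxels.sum() == 20**3 - 10**3

    def test_default_depth_and_subset_invariants(self, young_phantom):
        _, _, _, mask = young_phantom
        shell = surface_shell(mask)
        assert shell.depth_um == 30.0
        assert not (shell.voxels & ~mask.voxels).any()  # shell subset of mask
        full = surface_shell(mask, depth_um=1e9)
        assert np.array_equal(full.voxels, mask.voxels)  # depth -> inf

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_blob_mask(rng, side=20)
        if not mask.any():
            pytest.skip("degenerate blob")
        depth = rng.uniform(5.0, 40.0)
        shell = surface_shell(EnamelMask(mask, 6.0), depth_um=depth)
        oracle = brute_force_shell(mask, 6.0, depth)
        assert np.array_equal(shell.voxels, oracle)

    def test_internal_cavity_is_not_surface(self):
        # hollow cube: the cavity wall must not join the shell
        mask = np.zeros((20, 20, 20), bool)
        mask[2:18, 2:18, 2:18] = True
        mask[8:12, 8:12, 8:12] = False
        shell = surface_shell(EnamelMask(mask, 6.0), depth_um=6.0)
        assert not shell.voxels[7:13, 7:13, 7:13].any()

    def test_validation_and_warning(self):
        with pytest.raises(ValidationError):
            surface_shell(EnamelMask(np.zeros((4, 4, 4), bool), 6.0))
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4, 2:4, 2:4] = True
        with pytest.warns(UserWarning):
            surface_shell(EnamelMask(mask, 24.0), depth_um=5.0)


class TestAxialProfile:
    def test_area_threshold_at_6um_is_556_voxels(self):
        # 0.02 mm^2 / (6 um)^2 = 555.6 -> 555 voxels dropped, 556 kept
        vol = np.zeros((4, 40, 40))
        mask = np.zeros((4, 40, 40), bool)
        flat555 = np.unravel_index(np.arange(555), (40, 40))
        flat556 = np.unravel_index(np.arange(556), (40, 40))
        mask[1][flat555] = True
        mask[2][flat556] = True
        vol[mask] = 2000.0
        p = axial_profile(Tomogram(vol, 6.0), EnamelMask(mask, 6.0), 0.02)
        assert len(p) == 1
        assert p.x_mm[0] == pytest.approx(0.006)  # one slice above the first
        assert p.area_mm2[0] == pytest.approx(556 * 36e-6)

    def test_uniform_phantom_profile_is_plateau(self, clean_spec):
        from enamelmat.phantom import render_tomogram, simulate_density_field

        tom, mask = render_tomogram(
            clean_spec, simulate_density_field(clean_spec, 100.0)
        )
        p = axial_profile(tom, mask, 0.02)
        assert np.allclose(p.mean_density, clean_spec.rho_plateau)

    def test_invariant_to_values_outside_mask(self, clean_spec):
        from enamelmat.phantom import render_tomogram, simulate_density_field

        tom, mask = render_tomogram(
            clean_spec, simulate_density_field(clean_spec, 2.0)
        )
        p1 = axial_profile(tom, mask, 0.02)
        vol2 = tom.voxels.copy()
        vol2[~mask.voxels] = 9999.0
        p2 = axial_profile(Tomogram(vol2, tom.voxel_um), mask, 0.02)
        np.testing.assert_array_equal(p1.mean_density, p2.mean_density)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyProfileError):
            axial_profile(
                Tomogram(np.zeros((4, 4, 4)), 6.0),
                EnamelMask(np.zeros((4, 4, 4), bool), 6.0),
            )


class TestSmoothing:
    def test_hand_example_window_5(self):
        p = _profile(np.arange(7), [1, 2, 3, 4, 5, 6, 7])
        s = smooth_profile(p, 5)
        # interior positions carry full 5-point means; edges shrink (1, 3)
        np.testing.assert_allclose(s.mean_density, [1, 2, 3, 4, 5, 6, 7])
        p2 = _profile(np.arange(5), [10, 0, 10, 0, 10])
        s2 = smooth_profile(p2, 5)
        np.testing.assert_allclose(s2.mean_density, [10, 20 / 3, 6, 20 / 3, 10])

    def test_constant_profile_unchanged_and_window_validation(self):
        p = _profile(np.arange(6), np.full(6, 2000.0))
        assert np.allclose(smooth_profile(p, 5).mean_density, 2000.0)
        with pytest.raises(ValidationError):
            smooth_profile(p, 4)
        with pytest.raises(ValidationError):
            smooth_profile(p, 7)

    @settings(deadline=None, max_examples=40)
    @given(
        st.lists(st.floats(0, 3000), min_size=5, max_size=40),
        st.sampled_from([1, 3, 5]),
    )
    def test_bounds_and_interior_mean_preserved(self, values, window):
        p = _profile(np.arange(len(values)), values)
        s = smooth_profile(p, window)
        assert s.mean_density.min() >= min(values) - 1e-9
        assert s.mean_density.max() <= max(values) + 1e-9
        assert s.smoothed and s.window == window
        np.testing.assert_array_equal(s.x_mm, p.x_mm)


class TestBandMean:
    def test_constant_profile_any_band(self):
        p = _profile(np.arange(10) * 0.5, np.full(10, 2000.0), gumline=1.0)
        assert band_mean(p, 0.0, 3.0) == (2000.0, 0.0)
        assert band_mean(p, -1.0, 0.5) == (2000.0, 0.0)

    def test_linear_profile_matches_brute_force_average(self):
        x = np.arange(0.0, 3.0, 0.25)
        p = _profile(x, 1000.0 + 100.0 * x, gumline=0.0, step=0.25)
        mean, sd = band_mean(p, 0.0, 3.0)
        sel = x < 3.0
        assert mean == pytest.approx((1000.0 + 100.0 * x[sel]).mean())
        assert sd == pytest.approx(np.std(1000.0 + 100.0 * x[sel], ddof=1))

    def test_band_is_half_open_and_errors(self):
        p = _profile([0.0, 1.0, 2.0], [10.0, 20.0, 30.0], gumline=0.0)
        mean, _ = band_mean(p, 0.0, 2.0)  # x = 2 excluded
        assert mean == 15.0
        with pytest.raises(EmptyBandError):
            band_mean(p, 5.0, 6.0)
        with pytest.raises(ValidationError):
            band_mean(p, 2.0, 1.0)
        with pytest.raises(ValidationError):
            band_mean(_profile([0.0, 1.0], [1.0, 2.0]), 0.0, 1.0)


class TestAverageProfiles:
    def test_identical_profiles_mean_and_zero_sd(self):
        p = _profile(np.arange(5), [1.0, 2.0, 3.0, 4.0, 5.0], gumline=1.0)
        avg = average_profiles([p, p, p])
        np.testing.assert_allclose(avg.mean_density, p.mean_density)
        np.testing.assert_allclose(avg.sd, 0.0)
        assert avg.gumline_mm == 1.0

    def test_three_values_hand_arithmetic(self):
        ps = [
            _profile(np.arange(4), np.full(4, v)) for v in (1000.0, 2000.0, 3000.0)
        ]
        avg = average_profiles(ps)
        np.testing.assert_allclose(avg.mean_density, 2000.0)
        np.testing.assert_allclose(avg.sd, 1000.0)  # sample SD

    def test_restricts_to_shared_range_and_errors(self):
        p1 = _profile(np.arange(0, 6, 1.0), np.arange(6.0))
        p2 = _profile(np.arange(2, 8, 1.0), np.arange(6.0))
        avg = average_profiles([p1, p2])
        assert avg.x_mm[0] == 2.0 and avg.x_mm[-1] == 5.0
        p3 = _profile(np.arange(10, 14, 1.0), np.arange(4.0))
        with pytest.raises(AlignmentError):
            average_profiles([p1, p3])
        with pytest.raises(ValidationError):
            average_profiles([p1])
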