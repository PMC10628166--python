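"""Segmentation and feature formulas: threshold masks, centroid/radius,
volume, protein density, dry mass, and sectional RI features."""

import numpy as np
import pytest

from tomoshell.io import CellMask, Tomogram
from tomoshell.morphometry import (
    EmptySectionError,
    MorphometryConfig,
    NoCellFoundError,
    cell_center_and_radius,
    compute_volume,
    dry_mass,
    extract_features,
    protein_density,
    sectional_ri_features,
    segment,
)
from tomoshell.phantom import PhantomSpec, make_phantom

from conftest import brute_force_ellipsoid_count


def _uniform_tomogram(value=1.337, shape=(8, 8, 8), spacing=(0.2, 0.2, 0.2)):
    return Tomogram(np.full(shape, value, dtype=np.float32), spacing, 1.337)


class TestSegment:
    def test_uniform_medium_raises_no_cell(self):
        with pytest.raises(NoCellFoundError):
            segment(_uniform_tomogram())

    def test_zero_noise_mask_equals_membership_set(self, sphere_phantom, sphere_spec):
        mask = segment(sphere_phantom)
        expected = sphere_phantom.ri_volume > np.float32(sphere_spec.medium_ri)
        assert np.array_equal(mask.mask, expected)

    def test_noisy_mask_count_within_3pct_of_zero_noise(self, sphere_spec):
        from dataclasses import replace

        noisy = make_phantom(replace(sphere_spec, noise_sd=0.002), seed=3)
        clean_count = segment(make_phantom(sphere_spec, seed=3)).voxel_count
        noisy_count = segment(noisy).voxel_count
        assert abs(noisy_count - clean_count) / clean_count < 0.03

    def test_largest_component_wins_over_noise_speck(self):
        vol = np.full((16, 16, 16), 1.337, dtype=np.float32)
        vol[6:10, 6:10, 6:10] = 1.36  # 64-voxel cell
        vol[0, 0, 0] = 1.36  # disconnected speck
        mask = segment(Tomogram(vol, (0.2,) * 3, 1.337))
        assert mask.voxel_count == 64
        assert not mask.mask[0, 0, 0]


class TestCenterRadius:
    def test_single_voxel(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[3, 4, 5] = True
        center, radius = cell_center_and_radius(CellMask(m, 1.34))
        assert center == (3.0, 4.0, 5.0)
        assert radius == 0.0

    def test_symmetric_sphere_center(self, sphere_phantom, sphere_spec):
        mask = segment(sphere_phantom)
        center, _ = cell_center_and_radius(mask)
        assert np.allclose(center, sphere_spec.center_vox, atol=0.5)

    def test_hemisphere_center_equals_coordinate_mean(self, sphere_phantom):
        mask = segment(sphere_phantom)
        hemi = mask.mask.copy()
        hemi[:32] = False
        center, _ = cell_center_and_radius(CellMask(hemi, mask.threshold))
        coords = [
            (i, j, k)
            for i in range(64)
            for j in range(64)
            for k in range(64)
            if hemi[i, j, k]
        ]
        oracle = np.mean(coords, axis=0)
        assert np.allclose(center, oracle, atol=1e-12)

    def test_physical_radius_accounts_for_anisotropy(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = m[2, 2, 4] = m[4, 2, 2] = True
        _, r_vox = cell_center_and_radius(CellMask(m, 1.34))
        _, r_um = cell_center_and_radius(CellMask(m, 1.34), spacing_um=(1.0, 0.5, 0.25))
        assert r_um < r_vox

    def test_empty_mask_error(self):
        with pytest.raises(ValueError, match="empty"):
            cell_center_and_radius(CellMask(np.zeros((4, 4, 4), bool), 1.34))


class TestVolumeAndMass:
    def test_thousand_voxels_at_100nm_is_one_fl(self):
        m = np.zeros((10, 10, 10), dtype=bool)
        m[...] = True
        assert compute_volume(CellMask(m, 1.34), (0.1, 0.1, 0.1)) == pytest.approx(1.0)

    def test_sphere_volume_within_1pct_of_closed_form(self, sphere_phantom):
        mask = segment(sphere_phantom)
        v = compute_volume(mask, sphere_phantom.voxel_spacing_um)
        assert abs(v - 4 / 3 * np.pi * 125.0) / (4 / 3 * np.pi * 125.0) < 0.01

    def test_volume_scales_with_spacing_cubed(self, sphere_phantom):
        mask = segment(sphere_phantom)
        v1 = compute_volume(mask, (0.2, 0.2, 0.2))
        v2 = compute_volume(mask, (0.4, 0.4, 0.4))
        assert v2 == pytest.approx(8 * v1)

    def test_dry_mass_formula(self):
        assert dry_mass(10.0, 100.0) == pytest.approx(10.0)
        assert dry_mass(10.0, 523.6) == pytest.approx(52.36)
        assert dry_mass(0.0, 100.0) == 0.0

    def test_extracted_mass_consistent_to_machine_precision(self, small_cohort):
        toms, _ = small_cohort
        for tom in toms[:6]:
            m = extract_features(tom)
            assert m.dry_mass_pg == m.protein_density_g_dl * m.volume_fl * 1e-2


class TestProteinDensity:
    def test_linear_formula(self):
        vol = np.full((4, 4, 4), 1.337 + 0.019, dtype=np.float64)
        tom = Tomogram(vol, (0.2,) * 3, 1.337)
        mask = CellMask(np.ones((4, 4, 4), bool), 1.342)
        c = protein_density(tom, mask, MorphometryConfig(alpha_ml_per_g=0.19))
        assert c == pytest.approx(10.0, abs=1e-4)

    def test_zero_excess_gives_zero_density(self):
        tom = _uniform_tomogram(1.337)
        mask = CellMask(np.ones((8, 8, 8), bool), 1.3)
        assert protein_density(tom, mask) == pytest.approx(0.0, abs=1e-4)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            MorphometryConfig(alpha_ml_per_g=-0.1)

    def test_noisy_phantom_density_matches_mixture_mean(self, nucleated_spec):
        from dataclasses import replace

        noise_sd = 0.002
        noisy = make_phantom(replace(nucleated_spec, noise_sd=noise_sd), seed=9)
        mask = segment(noisy)
        c = protein_density(noisy, mask)
        # closed-form mixture mean over the zero-noise membership sets
        clean = make_phantom(nucleated_spec, seed=9)
        clean_mask = segment(clean)
        mixture_mean = float(clean.ri_volume[clean_mask.mask].mean())
        c_expected = 100 * (mixture_mean - nucleated_spec.medium_ri) / 0.19
        sd_equiv = 100 * noise_sd / 0.19 / np.sqrt(mask.voxel_count)
        assert abs(c - c_expected) < 2 * sd_equiv + 0.2  # 0.2 g/dL mask-jitter margin


class TestSectionalFeatures:
    def test_nuclear_ri_exact_at_zero_noise(self, nucleated_phantom):
        mask = segment(nucleated_phantom)
        overall, nuclear, frac, _ = sectional_ri_features(nucleated_phantom, mask)
        assert nuclear == pytest.approx(1.390, abs=1e-6)
        assert 0 < frac < 1

    def test_no_super_threshold_pixels_flagged_absent(self, sphere_phantom):
        mask = segment(sphere_phantom)
        _, nuclear, frac, _ = sectional_ri_features(sphere_phantom, mask)
        assert nuclear is None
        assert frac == 0.0

    def test_overall_mean_matches_pixel_enumeration_oracle(self, nucleated_phantom):
        mask = segment(nucleated_phantom)
        center, _ = cell_center_and_radius(mask)
        overall, _, _, section = sectional_ri_features(nucleated_phantom, mask)
        z = int(round(center[0]))
        acc, n = 0.0, 0
        for j in range(section.shape[0]):
            for k in range(section.shape[1]):
                if mask.mask[z, j, k]:
                    acc += float(nucleated_phantom.ri_volume[z, j, k])
                    n += 1
        assert overall == pytest.approx(acc / n, abs=1e-9)

    def test_section_missing_mask_raises(self, sphere_phantom):
        mask = segment(sphere_phantom)
        with pytest.raises(EmptySectionError):
            sectional_ri_features(
                sphere_phantom, mask, center=(0.0, 31.5, 31.5)
            )


class TestInvariances:
    def test_translation_and_rotation_leave_volume_and_mass_unchanged(self):
        spec = PhantomSpec(
            cell_radius_um=(2.0, 2.5, 3.0), grid_shape=(48, 48, 48), noise_sd=0.0
        )
        base = extract_features(make_phantom(spec, seed=0))
        from dataclasses import replace

        shifted = extract_features(
            make_phantom(replace(spec, center_offset_vox=(3, -2, 4)), seed=0)
        )
        # integer-voxel offsets translate the membership set exactly
        assert shifted.volume_fl == pytest.approx(base.volume_fl, rel=1e-12)
        assert shifted.dry_mass_pg == pytest.approx(base.dry_mass_pg, rel=1e-9)
        tom = make_phantom(spec, seed=0)
        rotated = Tomogram(
            np.ascontiguousarray(np.rot90(tom.ri_volume, k=1, axes=(1, 2))),
            tom.voxel_spacing_um,
            tom.medium_ri,
        )
        rot = extract_features(rotated)
        assert rot.volume_fl == pytest.approx(base.volume_fl, rel=1e-12)
        assert rot.dry_mass_pg == pytest.approx(base.dry_mass_pg, rel=1e-9)

    def test_density_monotone_in_cytoplasm_ri(self):
        from dataclasses import replace

        spec = PhantomSpec(cell_radius_um=(2.0, 2.0, 2.0), grid_shape=(32, 32, 32))
        feats = [
            extract_features(
                make_phantom(replace(spec, cytoplasm_ri=ri, nucleus_ri=1.39), seed=0)
            )
            for ri in (1.350, 1.356, 1.362)
        ]
        c = [f.protein_density_g_dl for f in feats]
        m = [f.dry_mass_pg for f in feats]
        ri = [f.mean_overall_ri for f in feats]
        assert c[0] < c[1] < c[2]
        assert m[0] < m[1] < m[2]
        assert ri[0] < ri[1] < ri[2]

    def test_full_3d_feature_space_available(self, nucleated_phantom):
        m2 = extract_features(nucleated_phantom, MorphometryConfig())
        m3 = extract_features(
            nucleated_phantom, MorphometryConfig(feature_space="full_3d")
        )
        assert m3.mean_overall_ri == pytest.approx(m2.mean_overall_ri, abs=5e-3)
        assert m3.mean_nuclear_ri == pytest.approx(1.390, abs=1e-6)


def test_random_ellipsoid_volumes_match_lattice_oracle():
    """Segmented voxel counts equal independent brute-force lattice counts."""
    rng = np.random.default_rng(42)
    for _ in range(4):
        radii = tuple(rng.uniform(1.2, 2.8, size=3))
        spec = PhantomSpec(
            cell_radius_um=radii, grid_shape=(32, 32, 32), noise_sd=0.0
        )
        mask = segment(make_phantom(spec, seed=1))
        assert mask.voxel_count == brute_force_ellipsoid_count(spec)
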