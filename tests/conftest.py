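import numpy as np
import pytest

from tomoshell.phantom import PhantomSpec, GroupEffectSpec, make_cohort, make_phantom


@pytest.fixture(scope="session")
def sphere_spec():
    """Zero-noise sphere, r = 5 µm, 0.2 µm isotropic spacing, uniform cell RI."""
    return PhantomSpec(
        cell_radius_um=(5.0, 5.0, 5.0),
        nucleus_radius_fraction=0.5,
        cytoplasm_ri=1.356,
        nucleus_ri=1.356,
        medium_ri=1.337,
        noise_sd=0.0,
        voxel_spacing_um=(0.2, 0.2, 0.2),
        grid_shape=(64, 64, 64),
    )


@pytest.fixture(scope="session")
def sphere_phantom(sphere_spec):
    return make_phantom(sphere_spec, seed=0)


@pytest.fixture(scope="session")
def nucleated_spec():
    """Zero-noise sphere with a distinct super-1.38 nucleus."""
    return PhantomSpec(
        cell_radius_um=(4.0, 4.0, 4.0),
        nucleus_radius_fraction=0.5,
        cytoplasm_ri=1.356,
        nucleus_ri=1.390,
        medium_ri=1.337,
        noise_sd=0.0,
        voxel_spacing_um=(0.2, 0.2, 0.2),
        grid_shape=(48, 48, 48),
    )


@pytest.fixture(scope="session")
def nucleated_phantom(nucleated_spec):
    return make_phantom(nucleated_spec, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-group cohort (H vs T1) with modest separation, small grids."""
    base = PhantomSpec(
        cell_radius_um=(2.0, 2.0, 2.0),
        grid_shape=(32, 32, 32),
        noise_sd=0.002,
        nucleus_ri=1.385,
    )
    groups = [
        GroupEffectSpec("H", n_cells=12, n_subjects=4),
        GroupEffectSpec(
            "T1", "survivor", radius_scale=1.25, ri_offset=0.006,
            peripheral_weight=0.6, n_cells=12, n_subjects=4,
        ),
    ]
    return make_cohort(groups, [], base, seed=11)


def brute_force_ellipsoid_count(spec: PhantomSpec) -> int:
    """Independent lattice-point count of voxel centers inside the cell
    ellipsoid, written as explicit loops over a bounding box."""
    center = spec.center_vox
    count = 0
    ranges = []
    for g, c, s, r in zip(
        spec.grid_shape, center, spec.voxel_spacing_um, spec.cell_radius_um
    ):
        lo = max(int(np.floor(c - r / s)) - 1, 0)
        hi = min(int(np.ceil(c + r / s)) + 1, g - 1)
        ranges.append(range(lo, hi + 1))
    for i in ranges[0]:
        for j in ranges[1]:
            for k in ranges[2]:
                t = (
                    ((i - center[0]) * spec.voxel_spacing_um[0] / spec.cell_radius_um[0]) ** 2
                    + ((j - center[1]) * spec.voxel_spacing_um[1] / spec.cell_radius_um[1]) ** 2
                    + ((k - center[2]) * spec.voxel_spacing_um[2] / spec.cell_radius_um[2]) ** 2
                )
                if t <= 1.0:
                    count += 1
    return count
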