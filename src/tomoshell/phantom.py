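"""Synthetic RI tomogram phantoms and cohort generation.

The generator emulates the statistical structure of a holotomographic CD8+
T-cell study of sepsis without requiring any measured data: ellipsoidal cells
with a concentric high-RI nucleus embedded in medium, four status groups
(healthy H and sepsis time points T1/T2/T3) differing in size and RI, a
survivor vs non-survivor contrast expressed as peripherally displaced dense
material, and per-subject clinical covariates generated at configured Pearson
correlations with the subject's mean cellular RI.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
specs and seed give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from tomoshell.io import Tomogram

RI_BOUNDS = (1.30, 1.45)


class PhantomSizeError(ValueError):
    """The requested cell does not fit inside the voxel grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and optics of a single-cell phantom.

    The cell is an axis-aligned ellipsoid of cytoplasm RI containing a
    concentric ellipsoid nucleus whose semi-axes are
    ``nucleus_radius_fraction`` times the cell's.  A voxel belongs to a
    compartment iff its *center* lies inside the ellipsoid — an unambiguous
    rule that a brute-force lattice count can reproduce exactly.

    ``peripheral_weight`` in [0, 1] linearly raises the RI of a rim band of
    the cytoplasm (normalized ellipsoidal radius in ``rim_band``) from
    cytoplasm RI toward nucleus RI, modelling dense material displaced toward
    the cell periphery; 0 leaves the cytoplasm homogeneous.
    """

    cell_radius_um: tuple[float, float, float] = (4.0, 4.0, 4.0)  # (z, y, x)
    nucleus_radius_fraction: float = 0.6
    cytoplasm_ri: float = 1.356
    nucleus_ri: float = 1.385
    medium_ri: float = 1.337
    noise_sd: float = 0.0
    voxel_spacing_um: tuple[float, float, float] = (0.2, 0.2, 0.2)
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    center_offset_vox: tuple[int, int, int] = (0, 0, 0)
    peripheral_weight: float = 0.0
    rim_band: tuple[float, float] = (0.72, 0.95)

    def __post_init__(self) -> None:
        if not (0 < self.nucleus_radius_fraction < 1):
            raise ValueError("nucleus_radius_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.peripheral_weight <= 1):
            raise ValueError("peripheral_weight must lie in [0, 1]")
        for name in ("cytoplasm_ri", "nucleus_ri", "medium_ri"):
            ri = getattr(self, name)
            if not (RI_BOUNDS[0] <= ri <= RI_BOUNDS[1]):
                raise ValueError(
                    f"{name}={ri} outside plausible RI range {RI_BOUNDS}"
                )
        if any(r <= 0 for r in self.cell_radius_um):
            raise ValueError("cell radii must be positive")
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError("voxel spacing must be positive")
        if any(int(g) <= 0 for g in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        for r, s, g, o in zip(
            self.cell_radius_um,
            self.voxel_spacing_um,
            self.grid_shape,
            self.center_offset_vox,
        ):
            if r / s + abs(o) >= g / 2:
                raise PhantomSizeError(
                    f"cell radius {r} µm at spacing {s} µm with offset {o} vox "
                    f"does not fit in grid extent {g}"
                )

    @property
    def center_vox(self) -> tuple[float, float, float]:
        """Real-valued grid coordinates of the cell center."""
        return tuple(
            (g - 1) / 2 + o for g, o in zip(self.grid_shape, self.center_offset_vox)
        )


def _normalized_radius_sq(spec: PhantomSpec) -> np.ndarray:
    """Per-voxel squared ellipsoidal radius (1.0 on the cell surface)."""
    center = spec.center_vox
    axes = [
        (np.arange(g, dtype=np.float64) - c) * s / r
        for g, c, s, r in zip(
            spec.grid_shape, center, spec.voxel_spacing_um, spec.cell_radius_um
        )
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return zz**2 + yy**2 + xx**2


def make_phantom(spec: PhantomSpec, seed: int, cell_id: str = "phantom") -> Tomogram:
    """Render a phantom tomogram from ``spec``; deterministic given ``seed``."""
    r2 = _normalized_radius_sq(spec)
    volume = np.full(spec.grid_shape, spec.medium_ri, dtype=np.float64)
    cell = r2 <= 1.0
    volume[cell] = spec.cytoplasm_ri
    if spec.peripheral_weight > 0:
        lo, hi = spec.rim_band
        rim = cell & (r2 >= lo**2) & (r2 <= hi**2)
        volume[rim] = spec.cytoplasm_ri + spec.peripheral_weight * (
            spec.nucleus_ri - spec.cytoplasm_ri
        )
    nucleus = r2 <= spec.nucleus_radius_fraction**2
    volume[nucleus] = spec.nucleus_ri
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        volume = volume + rng.normal(0.0, spec.noise_sd, size=volume.shape)
        np.clip(volume, 1.0, None, out=volume)
    return Tomogram(
        ri_volume=volume.astype(np.float32),
        voxel_spacing_um=spec.voxel_spacing_um,
        medium_ri=spec.medium_ri,
        cell_id=cell_id,
    )


@dataclass(frozen=True)
class GroupEffectSpec:
    """Group-level shifts applied on top of a base phantom spec.

    ``radius_scale`` multiplies all cell radii, ``ri_offset`` is added to both
    cytoplasm and nucleus RI, and ``peripheral_weight`` feeds straight into
    :class:`PhantomSpec`.  Defaults elsewhere order the groups
    T1 > T2 > T3 ≈ H in size and RI and give non-survivors at T1 a higher
    peripheral weight than survivors.
    """

    group: str
    outcome: str = "not-applicable"
    radius_scale: float = 1.0
    ri_offset: float = 0.0
    peripheral_weight: float = 0.0
    n_cells: int = 20
    n_subjects: int = 4

    def __post_init__(self) -> None:
        if self.group not in ("H", "T1", "T2", "T3"):
            raise ValueError(f"unknown group label {self.group!r}")
        if self.outcome not in ("survivor", "non-survivor", "not-applicable"):
            raise ValueError(f"unknown outcome label {self.outcome!r}")
        if not (self.n_cells >= self.n_subjects >= 1):
            raise ValueError("need n_cells >= n_subjects >= 1")
        if not (0 <= self.peripheral_weight <= 1):
            raise ValueError("peripheral_weight must lie in [0, 1]")


@dataclass(frozen=True)
class ClinicalCovariateSpec:
    """A clinical covariate with a target correlation to subject mean RI."""

    name: str
    target_rho: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if abs(self.target_rho) > 1:
            raise ValueError(f"|target correlation| must be <= 1, got {self.target_rho}")
        if self.sd <= 0:
            raise ValueError("covariate sd must be positive")


def default_cohort_groups(cells_per_group: int = 100) -> list[GroupEffectSpec]:
    """Cohort layout mirroring the study design: 20 healthy subjects sampled
    once and 8 sepsis subjects sampled at three time points, with the sepsis
    subjects split into survivors and non-survivors at T1.

    Effect directions: T1 cells are the largest and densest, T2 intermediate,
    T3 close to healthy; non-survivors at T1 carry more peripherally displaced
    dense material than survivors.  Magnitudes are a design choice (the
    contrasts' directions, not sizes, are what downstream analyses assume).
    """
    n_t1 = max(cells_per_group // 2, 1)
    s_h = min(20, cells_per_group)
    s_t1 = min(4, n_t1)
    s_t = min(8, cells_per_group)
    return [
        GroupEffectSpec("H", n_cells=cells_per_group, n_subjects=s_h),
        GroupEffectSpec(
            "T1", "survivor", radius_scale=1.30, ri_offset=0.006,
            peripheral_weight=0.25, n_cells=n_t1, n_subjects=s_t1,
        ),
        GroupEffectSpec(
            "T1", "non-survivor", radius_scale=1.30, ri_offset=0.006,
            peripheral_weight=0.75, n_cells=n_t1, n_subjects=s_t1,
        ),
        GroupEffectSpec(
            "T2", "survivor", radius_scale=1.15, ri_offset=0.003,
            peripheral_weight=0.15, n_cells=cells_per_group, n_subjects=s_t,
        ),
        GroupEffectSpec(
            "T3", "survivor", radius_scale=1.02, ri_offset=0.0005,
            peripheral_weight=0.05, n_cells=cells_per_group, n_subjects=s_t,
        ),
    ]


def default_covariates() -> list[ClinicalCovariateSpec]:
    """Clinical covariates of the study, with positive coupling to mean RI for
    the inflammatory markers and cytokines and a negative one for lymphocyte
    percentage (which rises as the others fall during recovery)."""
    return [
        ClinicalCovariateSpec("CRP", 0.88, 80.0, 60.0),
        ClinicalCovariateSpec("WBC", 0.68, 12000.0, 5000.0),
        ClinicalCovariateSpec("neutrophil_pct", 0.76, 75.0, 12.0),
        ClinicalCovariateSpec("lymphocyte_pct", -0.81, 15.0, 8.0),
        ClinicalCovariateSpec("CCL2_MCP1", 0.944, 300.0, 150.0),
        ClinicalCovariateSpec("IL10", 0.994, 25.0, 15.0),
        ClinicalCovariateSpec("IL2", 0.995, 8.0, 4.0),
        ClinicalCovariateSpec("TNFa", 0.991, 20.0, 10.0),
    ]


# Subject- and cell-level dispersion of the generator.  Gaussian on log-radius
# keeps radii positive; additive on RI.
SUBJECT_LOG_RADIUS_SD = 0.04
SUBJECT_RI_SD = 0.0015
CELL_LOG_RADIUS_SD = 0.03
CELL_RI_SD = 0.0008


def make_cohort(
    groups: Sequence[GroupEffectSpec],
    covariates: Sequence[ClinicalCovariateSpec],
    base: PhantomSpec,
    seed: int,
) -> tuple[list[Tomogram], pd.DataFrame]:
    """Generate per-cell tomograms and the cohort table.

    Each subject draws a log-radius scale and an additive RI offset shared by
    all of its cells; each cell adds smaller jitter on both.  Covariates are
    per-subject values ``a · (subject mean RI) + ε`` with the slope and noise
    variance solved in closed form from the target correlation and marginal
    sd, so the expected sample correlation equals the target.

    Returns ``(tomograms, table)`` where the table has one row per cell with
    columns ``cell_id, subject_id, group, outcome, subject_mean_ri`` plus one
    column per covariate.  Deterministic given ``seed``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    tomograms: list[Tomogram] = []
    rows: list[dict] = []
    subject_latent: dict[str, float] = {}

    for gi, g in enumerate(groups):
        subj_log_r = rng.normal(0.0, SUBJECT_LOG_RADIUS_SD, size=g.n_subjects)
        subj_ri = rng.normal(0.0, SUBJECT_RI_SD, size=g.n_subjects)
        tag = g.group if g.outcome == "not-applicable" else f"{g.group}_{g.outcome[:3]}"
        for ci in range(g.n_cells):
            si = ci % g.n_subjects
            subject_id = f"{tag}_s{si:02d}"
            cell_log_r = rng.normal(0.0, CELL_LOG_RADIUS_SD)
            cell_ri = rng.normal(0.0, CELL_RI_SD)
            scale = g.radius_scale * math.exp(subj_log_r[si] + cell_log_r)
            ri_shift = g.ri_offset + subj_ri[si] + cell_ri
            spec = replace(
                base,
                cell_radius_um=tuple(r * scale for r in base.cell_radius_um),
                cytoplasm_ri=base.cytoplasm_ri + ri_shift,
                nucleus_ri=base.nucleus_ri + ri_shift,
                peripheral_weight=g.peripheral_weight,
            )
            cell_id = f"{tag}_c{ci:04d}"
            cell_seed = int(rng.integers(0, 2**31 - 1))
            tom = make_phantom(spec, seed=cell_seed, cell_id=cell_id)
            tom.labels.update(
                {"group": g.group, "outcome": g.outcome, "subject_id": subject_id}
            )
            tomograms.append(tom)
            # latent subject mean RI: cytoplasm RI the subject's cells center on
            subject_latent[subject_id] = base.cytoplasm_ri + g.ri_offset + subj_ri[si]
            rows.append(
                {
                    "cell_id": cell_id,
                    "subject_id": subject_id,
                    "group": g.group,
                    "outcome": g.outcome,
                }
            )

    table = pd.DataFrame(rows)
    subjects = sorted(subject_latent)
    latent = np.array([subject_latent[s] for s in subjects])
    cov_table = pd.DataFrame({"subject_id": subjects, "subject_mean_ri": latent})
    sd_latent = latent.std(ddof=1) if len(subjects) > 1 else 0.0
    z = (latent - latent.mean()) / sd_latent if sd_latent > 0 else np.zeros_like(latent)
    for cov in covariates:
        eps = rng.normal(0.0, 1.0, size=len(subjects))
        rho = cov.target_rho
        # Orthogonalize the noise against z in-sample: the realized Pearson
        # correlation of the covariate with subject mean RI is then exactly
        # the target (up to subject-count degeneracies).
        if sd_latent > 0 and len(subjects) > 2:
            eps = eps - (eps @ z) / (z @ z) * z
            eps_sd = eps.std(ddof=1)
            if eps_sd > 0:
                eps = (eps - eps.mean()) / eps_sd
        cov_table[cov.name] = cov.mean + cov.sd * (
            rho * z + math.sqrt(1.0 - rho**2) * eps
        )
    table = table.merge(cov_table, on="subject_id", how="left")
    return tomograms, table
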