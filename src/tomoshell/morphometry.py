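"""RI-threshold segmentation and single-cell morphological features.

The feature set follows standard quantitative-phase-imaging practice: the cell
is segmented from the medium by an RI threshold; volume ``V`` (fL) is the
voxel count times the voxel volume; protein density ``C`` (g/dL) comes from
the linear relation between RI excess over the medium and protein
concentration via the refraction increment ``α`` (mL/g),

    C = 100 · (⟨n⟩_cell − n_medium) / α ,

and dry mass ``m`` (pg) is ``C · V · 10⁻²``.  Overall and nuclear mean RI are
measured on the central cross-section through the cell center by default
(``feature_space='section_2d'``); a full-3D variant is available for
sensitivity analysis.  Voxels above the nuclear threshold (RI > 1.38) are
treated as nuclear material.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from skimage import measure

from tomoshell.io import Tomogram, CellMask

_AXES = {"z": 0, "y": 1, "x": 2}


class NoCellFoundError(ValueError):
    """No voxel exceeds the segmentation threshold."""


class EmptySectionError(ValueError):
    """The central cross-section contains no in-mask pixels."""


@dataclass(frozen=True)
class MorphometryConfig:
    """Thresholds and conventions of the feature extraction.

    tau_seg:
        Segmentation threshold RI; ``None`` means ``medium_ri + 0.005``,
        which separates cell from medium robustly for RI noise up to ~0.002.
    tau_nuc:
        Nuclear-component threshold RI (default 1.38).
    alpha_ml_per_g:
        Protein refraction increment in mL/g (default 0.19; the physiological
        range is 0.18-0.21).
    section_axis:
        Axis along which the central cross-section is taken.
    feature_space:
        ``section_2d`` (default) measures mean RI on the central section;
        ``full_3d`` over the whole segmented volume.
    physical_radius:
        If True (default) the cell radius is the maximum spacing-scaled
        (µm) distance from center to a mask voxel; else plain voxel units.
    """

    tau_seg: float | None = None
    tau_nuc: float = 1.38
    alpha_ml_per_g: float = 0.19
    section_axis: str = "z"
    feature_space: str = "section_2d"
    physical_radius: bool = True

    def __post_init__(self) -> None:
        if self.alpha_ml_per_g <= 0:
            raise ValueError("refraction increment must be positive")
        if self.section_axis not in _AXES:
            raise ValueError(f"section_axis must be one of {sorted(_AXES)}")
        if self.feature_space not in ("section_2d", "full_3d"):
            raise ValueError("feature_space must be 'section_2d' or 'full_3d'")

    def resolve_tau_seg(self, medium_ri: float) -> float:
        tau = self.tau_seg if self.tau_seg is not None else medium_ri + 0.005
        if not (tau > medium_ri):
            warnings.warn(
                f"segmentation threshold {tau} does not exceed medium RI "
                f"{medium_ri}; the mask will include background",
                stacklevel=2,
            )
        if self.tau_nuc <= tau:
            warnings.warn(
                f"nuclear threshold {self.tau_nuc} <= segmentation threshold "
                f"{tau}; nuclear features will cover the whole cell",
                stacklevel=2,
            )
        return tau


@dataclass
class CellMorphology:
    """Derived per-cell features; ``dry_mass_pg == protein_density_g_dl *
    volume_fl * 1e-2`` holds exactly by construction."""

    cell_id: str
    volume_fl: float
    protein_density_g_dl: float
    dry_mass_pg: float
    mean_overall_ri: float
    mean_nuclear_ri: float | None
    nuclear_pixel_fraction: float
    center_vox: tuple[float, float, float]
    radius: float

    def to_row(self) -> dict:
        row = asdict(self)
        cz, cy, cx = row.pop("center_vox")
        row.update(center_z=cz, center_y=cy, center_x=cx)
        return row


def segment(tomogram: Tomogram, config: MorphometryConfig | None = None) -> CellMask:
    """Largest 26-connected component of voxels above the RI threshold."""
    cfg = config or MorphometryConfig()
    tau = cfg.resolve_tau_seg(tomogram.medium_ri)
    fg = tomogram.ri_volume > tau
    if not fg.any():
        raise NoCellFoundError(
            f"no cell found: no voxel exceeds threshold {tau:.4f}"
        )
    labels = measure.label(fg, connectivity=3)
    sizes = np.bincount(labels.ravel())[1:]
    mask = labels == (int(sizes.argmax()) + 1)
    return CellMask(mask=mask, threshold=tau)


def cell_center_and_radius(
    mask: CellMask,
    spacing_um: tuple[float, float, float] | None = None,
) -> tuple[tuple[float, float, float], float]:
    """Mask centroid (real-valued voxel coordinates) and maximum distance from
    the centroid to any mask voxel.

    If ``spacing_um`` is given the radius is in micrometres (anisotropy-aware);
    otherwise in voxel units.
    """
    coords = np.argwhere(mask.mask)
    if coords.size == 0:
        raise ValueError("empty mask")
    center = coords.mean(axis=0)
    delta = coords - center
    if spacing_um is not None:
        delta = delta * np.asarray(spacing_um)
    radius = float(np.sqrt((delta**2).sum(axis=1)).max())
    return tuple(float(c) for c in center), radius


def compute_volume(mask: CellMask, spacing_um: tuple[float, float, float]) -> float:
    """Cell volume in fL: voxel count × voxel volume (µm³ ≡ fL)."""
    n = mask.voxel_count
    if n == 0:
        raise ValueError("empty mask")
    sz, sy, sx = spacing_um
    return n * sz * sy * sx


def protein_density(
    tomogram: Tomogram, mask: CellMask, config: MorphometryConfig | None = None
) -> float:
    """Protein density C in g/dL from mean RI excess over the medium."""
    cfg = config or MorphometryConfig()
    mean_ri = float(tomogram.ri_volume[mask.mask].mean(dtype=np.float64))
    c = 100.0 * (mean_ri - tomogram.medium_ri) / cfg.alpha_ml_per_g
    if c < 0:
        warnings.warn(
            f"negative protein density {c:.3f} g/dL (mean cell RI below medium)",
            stacklevel=2,
        )
    return c


def dry_mass(protein_density_g_dl: float, volume_fl: float) -> float:
    """Dry mass in pg: C (g/dL) × V (fL) × 10⁻²."""
    return protein_density_g_dl * volume_fl * 1e-2


def sectional_ri_features(
    tomogram: Tomogram,
    mask: CellMask,
    config: MorphometryConfig | None = None,
    center: tuple[float, float, float] | None = None,
) -> tuple[float, float | None, float, np.ndarray]:
    """Overall / nuclear mean RI on the central cross-section.

    Returns ``(mean_overall_ri, mean_nuclear_ri, nuclear_pixel_fraction,
    section_image)``.  The section is the 2D plane at the rounded center index
    along ``section_axis``; overall RI averages in-mask pixels, nuclear RI
    averages section pixels with RI above ``tau_nuc`` (``None`` when there are
    none, in which case the fraction is 0).
    """
    cfg = config or MorphometryConfig()
    if center is None:
        center, _ = cell_center_and_radius(mask, tomogram.voxel_spacing_um)
    axis = _AXES[cfg.section_axis]
    idx = int(round(center[axis]))
    idx = min(max(idx, 0), tomogram.shape[axis] - 1)
    section = np.take(tomogram.ri_volume, idx, axis=axis)
    section_mask = np.take(mask.mask, idx, axis=axis)
    if not section_mask.any():
        raise EmptySectionError(
            f"central section at index {idx} along {cfg.section_axis} misses the mask"
        )
    mean_overall = float(section[section_mask].mean(dtype=np.float64))
    nuclear = section_mask & (section > cfg.tau_nuc)
    n_nuc = int(nuclear.sum())
    mean_nuclear = float(section[nuclear].mean(dtype=np.float64)) if n_nuc else None
    fraction = n_nuc / int(section_mask.sum())
    return mean_overall, mean_nuclear, fraction, section


def _volumetric_ri_features(
    tomogram: Tomogram, mask: CellMask, cfg: MorphometryConfig
) -> tuple[float, float | None, float]:
    vals = tomogram.ri_volume[mask.mask]
    nuclear = vals[vals > cfg.tau_nuc]
    mean_nuc = float(nuclear.mean(dtype=np.float64)) if nuclear.size else None
    return float(vals.mean(dtype=np.float64)), mean_nuc, nuclear.size / vals.size


def extract_features(
    tomogram: Tomogram, config: MorphometryConfig | None = None
) -> CellMorphology:
    """Segment one tomogram and compute the full feature vector."""
    cfg = config or MorphometryConfig()
    mask = segment(tomogram, cfg)
    spacing = tomogram.voxel_spacing_um
    center, radius = cell_center_and_radius(
        mask, spacing if cfg.physical_radius else None
    )
    v = compute_volume(mask, spacing)
    c = protein_density(tomogram, mask, cfg)
    m = dry_mass(c, v)
    if cfg.feature_space == "section_2d":
        overall, nuclear, frac, _ = sectional_ri_features(tomogram, mask, cfg, center)
    else:
        overall, nuclear, frac = _volumetric_ri_features(tomogram, mask, cfg)
    return CellMorphology(
        cell_id=tomogram.cell_id,
        volume_fl=v,
        protein_density_g_dl=c,
        dry_mass_pg=m,
        mean_overall_ri=overall,
        mean_nuclear_ri=nuclear,
        nuclear_pixel_fraction=frac,
        center_vox=center,
        radius=radius,
    )


def extract_cohort_features(
    tomograms, config: MorphometryConfig | None = None
) -> pd.DataFrame:
    """One feature row per tomogram, joined with each tomogram's labels."""
    rows = []
    for tom in tomograms:
        row = extract_features(tom, config).to_row()
        row.update(tom.labels)
        rows.append(row)
    return pd.DataFrame(rows)
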