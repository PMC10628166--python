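"""Equal-count radial shell partition of a cell cross-section and the
per-shell density statistic.

Pixels of the analyzed section are ranked by Euclidean distance from the cell
center and the ranked list is split into eight contiguous blocks of
near-equal size — Shell 1 innermost, Shell 8 outermost.  The shell density is
the fraction of pixels in a shell whose value exceeds an intensity threshold;
with the segmentation threshold it tracks where the cell's mass sits
radially, with the nuclear threshold (RI > 1.38) where the dense nuclear
material sits.  With anisotropic pixel spacing, distances are computed in
physical units, making the iso-distance contours (and hence the shells)
elliptical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tomoshell.io import Tomogram
from tomoshell.morphometry import (
    MorphometryConfig,
    cell_center_and_radius,
    segment,
    sectional_ri_features,
    _AXES,
)

DEFAULT_N_SHELLS = 8


@dataclass
class ShellProfile:
    """Ordered shell densities (innermost first) and provenance."""

    densities: np.ndarray
    pixel_counts: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.pixel_counts = np.asarray(self.pixel_counts, dtype=int)
        if self.densities.shape != self.pixel_counts.shape:
            raise ValueError("densities and counts must align")
        if np.any((self.densities < 0) | (self.densities > 1)):
            raise ValueError("shell densities must lie in [0, 1]")


def shell_partition(
    section_shape: tuple[int, int],
    center: tuple[float, float],
    n_shells: int = DEFAULT_N_SHELLS,
    spacing: tuple[float, float] = (1.0, 1.0),
    restrict_mask: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Partition section pixels into ``n_shells`` equal-count distance ranks.

    Pixels (all of them by default, or those of ``restrict_mask``) are sorted
    by Euclidean distance from ``center`` — distance ties broken by row-major
    pixel index — and the ranked list is cut into ``n_shells`` contiguous
    blocks whose sizes differ by at most one; a remainder of ``r`` pixels
    assigns one extra pixel to each of the ``r`` innermost shells.

    Returns a list of flat (row-major) pixel index arrays, innermost first.
    """
    h, w = section_shape
    if not (0 <= center[0] <= h - 1 and 0 <= center[1] <= w - 1):
        raise ValueError(f"center {center} outside section bounds {section_shape}")
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d2 = ((yy - center[0]) * spacing[0]) ** 2 + ((xx - center[1]) * spacing[1]) ** 2
    flat = np.arange(h * w)
    if restrict_mask is not None:
        if restrict_mask.shape != (h, w):
            raise ValueError("restrict_mask shape mismatch")
        flat = flat[restrict_mask.ravel()]
    n = flat.size
    if n < n_shells:
        raise ValueError(f"need at least {n_shells} pixels, got {n}")
    # stable sort on row-major order implements the documented tie-break
    order = flat[np.argsort(d2.ravel()[flat], kind="stable")]
    base, rem = divmod(n, n_shells)
    sizes = [base + 1 if k < rem else base for k in range(n_shells)]
    bounds = np.cumsum([0] + sizes)
    return [order[bounds[k] : bounds[k + 1]] for k in range(n_shells)]


def shell_density(
    section_image: np.ndarray,
    shells: list[np.ndarray],
    intensity_threshold: float,
) -> ShellProfile:
    """Fraction of super-threshold pixels per shell."""
    flat = section_image.ravel()
    counts = np.array([s.size for s in shells])
    if np.any(counts == 0):
        raise RuntimeError("internal error: empty shell after partition")
    dens = np.array([(flat[s] > intensity_threshold).mean() for s in shells])
    return ShellProfile(densities=dens, pixel_counts=counts, threshold=intensity_threshold)


def shell_profile_for_cell(
    tomogram: Tomogram,
    config: MorphometryConfig | None = None,
    n_shells: int = DEFAULT_N_SHELLS,
    restrict_to_cell: bool = False,
) -> dict[str, ShellProfile]:
    """Overall- and nuclear-threshold shell profiles of one cell.

    The section is the central cross-section through the cell center (as in
    the morphometry module).  ``overall`` uses the segmentation threshold,
    ``nuclear`` the nuclear threshold.  By default all section pixels are
    analyzed; ``restrict_to_cell`` limits the ranked list to in-mask pixels.
    """
    cfg = config or MorphometryConfig()
    mask = segment(tomogram, cfg)
    center, _ = cell_center_and_radius(mask, tomogram.voxel_spacing_um)
    _, _, _, section = sectional_ri_features(tomogram, mask, cfg, center)
    axis = _AXES[cfg.section_axis]
    keep = [i for i in range(3) if i != axis]
    center2d = (center[keep[0]], center[keep[1]])
    spacing2d = (
        tomogram.voxel_spacing_um[keep[0]],
        tomogram.voxel_spacing_um[keep[1]],
    )
    restrict = None
    if restrict_to_cell:
        restrict = np.take(mask.mask, int(round(center[axis])), axis=axis)
    shells = shell_partition(
        section.shape, center2d, n_shells=n_shells, spacing=spacing2d,
        restrict_mask=restrict,
    )
    tau_seg = mask.threshold
    return {
        "overall": shell_density(section, shells, tau_seg),
        "nuclear": shell_density(section, shells, cfg.tau_nuc),
    }


def shell_profiles_for_cohort(
    tomograms,
    config: MorphometryConfig | None = None,
    n_shells: int = DEFAULT_N_SHELLS,
    restrict_to_cell: bool = False,
) -> pd.DataFrame:
    """Long table of shell profiles: one row per cell × component, columns
    ``cell_id, component, d1..d8`` plus the tomogram labels."""
    rows = []
    for tom in tomograms:
        profiles = shell_profile_for_cell(tom, config, n_shells, restrict_to_cell)
        for component, prof in profiles.items():
            row = {"cell_id": tom.cell_id, "component": component}
            row.update(
                {f"d{k + 1}": prof.densities[k] for k in range(len(prof.densities))}
            )
            row.update(tom.labels)
            rows.append(row)
    return pd.DataFrame(rows)
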