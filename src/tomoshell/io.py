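"""Tomogram containers, TIFF + JSON-sidecar I/O, and automated QC filtering.

A tomogram is a 3D array of refractive indices (RI) in axis order ``(z, y, x)``
together with the voxel spacing in micrometres and the RI of the surrounding
medium.  On disk a tomogram is a multi-page 32-bit float TIFF (one page per z
slice) plus a JSON sidecar of the same stem carrying the metadata; this pair is
a lossless round-trip of the in-memory object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import tifffile
from skimage import measure


class SidecarError(ValueError):
    """Sidecar file missing or missing a required metadata key."""


class ShapeMismatchError(ValueError):
    """TIFF page count/shape disagrees with the sidecar declaration."""


REQUIRED_SIDECAR_KEYS = ("voxel_spacing_um", "medium_ri", "shape")


@dataclass
class Tomogram:
    """A single-cell 3D RI volume with physical metadata.

    Parameters
    ----------
    ri_volume:
        3D float array of refractive indices, axis order (z, y, x).
    voxel_spacing_um:
        Positive (z, y, x) voxel edge lengths in micrometres.
    medium_ri:
        Refractive index of the surrounding medium (``n_m``).
    cell_id:
        Stable identifier used in feature tables and file names.
    labels:
        Free-form metadata (cohort group, outcome, subject id, ...).
    """

    ri_volume: np.ndarray
    voxel_spacing_um: tuple[float, float, float]
    medium_ri: float
    cell_id: str = ""
    labels: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vol = np.asarray(self.ri_volume, dtype=np.float32)
        if vol.ndim != 3:
            raise ValueError(f"ri_volume must be 3D, got ndim={vol.ndim}")
        if not np.all(np.isfinite(vol)):
            raise ValueError("ri_volume contains non-finite values")
        if float(vol.min()) < 1.0:
            raise ValueError(
                f"refractive indices must be >= 1.0, found min {vol.min():.4f}"
            )
        spacing = tuple(float(s) for s in self.voxel_spacing_um)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"voxel spacing must be a positive triple, got {spacing}")
        self.ri_volume = vol
        self.voxel_spacing_um = spacing
        self.medium_ri = float(self.medium_ri)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ri_volume.shape  # type: ignore[return-value]

    @property
    def voxel_volume_fl(self) -> float:
        """Volume of one voxel in µm³ ≡ fL."""
        z, y, x = self.voxel_spacing_um
        return z * y * x


@dataclass
class CellMask:
    """Binary cell mask with the threshold that produced it."""

    mask: np.ndarray
    threshold: float
    parent_shape: tuple[int, int, int] = ()  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.parent_shape:
            self.parent_shape = m.shape  # type: ignore[assignment]
        if tuple(self.parent_shape) != m.shape:
            raise ValueError(
                f"mask shape {m.shape} does not match parent {self.parent_shape}"
            )
        self.mask = m

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_tomogram(tomogram: Tomogram, path: str | Path) -> Path:
    """Write ``tomogram`` as a multi-page float32 TIFF plus JSON sidecar.

    ``path`` may end in ``.tif``/``.tiff`` or be a stem; the sidecar is placed
    alongside with extension ``.json``.  Returns the TIFF path.
    """
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        path = path.with_suffix(".tif")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, tomogram.ri_volume.astype(np.float32))
    sidecar = {
        "voxel_spacing_um": list(tomogram.voxel_spacing_um),
        "medium_ri": tomogram.medium_ri,
        "shape": list(tomogram.shape),
        "cell_id": tomogram.cell_id,
        "labels": tomogram.labels,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_tomogram(path: str | Path) -> Tomogram:
    """Read a TIFF + sidecar pair back into a :class:`Tomogram`.

    Raises
    ------
    SidecarError
        If the sidecar is absent or lacks a required key (the message names
        the missing key).
    ShapeMismatchError
        If the TIFF stack shape disagrees with the sidecar's declaration.
    ValueError
        If the volume contains non-finite values.
    """
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise SidecarError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in REQUIRED_SIDECAR_KEYS:
        if key not in meta:
            raise SidecarError(f"sidecar {sidecar_path} missing required key '{key}'")
    volume = tifffile.imread(path)
    if volume.ndim == 2:  # single page
        volume = volume[None]
    declared = tuple(meta["shape"])
    if volume.shape != declared:
        raise ShapeMismatchError(
            f"TIFF shape {volume.shape} does not match sidecar shape {declared}"
        )
    return Tomogram(
        ri_volume=volume,
        voxel_spacing_um=tuple(meta["voxel_spacing_um"]),
        medium_ri=meta["medium_ri"],
        cell_id=meta.get("cell_id", path.stem),
        labels=meta.get("labels", {}),
    )


def write_cohort(tomograms: Sequence[Tomogram], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    paths = []
    for i, tom in enumerate(tomograms):
        name = tom.cell_id or f"cell_{i:05d}"
        paths.append(write_tomogram(tom, out_dir / f"{name}.tif"))
    return paths


def read_cohort(in_dir: str | Path) -> list[Tomogram]:
    paths = sorted(Path(in_dir).glob("*.tif")) + sorted(Path(in_dir).glob("*.tiff"))
    return [read_tomogram(p) for p in paths]


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the automated quality-control filter.

    ``threshold_offset`` sets the foreground RI threshold to
    ``medium_ri + threshold_offset``.  A volume is rejected when more than one
    connected foreground component exceeds ``min_component_fraction`` of the
    largest component (two adjoined cells), when the largest component touches
    the volume border (truncated cell), or when the foreground fraction falls
    outside ``[min_foreground_fraction, max_foreground_fraction]``.
    """

    threshold_offset: float = 0.005
    min_component_fraction: float = 0.2
    min_foreground_fraction: float = 0.001
    max_foreground_fraction: float = 0.60


def qc_filter(
    tomograms: Sequence[Tomogram], config: QCConfig | None = None
) -> tuple[list[Tomogram], list[tuple[Tomogram, str]]]:
    """Automated stand-in for manual image quality filtering.

    Returns ``(kept, rejected)`` where ``rejected`` pairs each discarded
    tomogram with a human-readable reason.  Pure function: identical inputs
    give identical verdicts.
    """
    cfg = config or QCConfig()
    kept: list[Tomogram] = []
    rejected: list[tuple[Tomogram, str]] = []
    for tom in tomograms:
        reason = _qc_reason(tom, cfg)
        if reason is None:
            kept.append(tom)
        else:
            rejected.append((tom, reason))
    return kept, rejected


def _qc_reason(tom: Tomogram, cfg: QCConfig) -> str | None:
    fg = tom.ri_volume > tom.medium_ri + cfg.threshold_offset
    n_fg = int(fg.sum())
    frac = n_fg / fg.size
    if frac < cfg.min_foreground_fraction:
        return f"foreground fraction {frac:.4%} below minimum"
    if frac > cfg.max_foreground_fraction:
        return f"foreground fraction {frac:.2%} above maximum"
    labels = measure.label(fg, connectivity=3)
    sizes = np.bincount(labels.ravel())[1:]
    largest = sizes.max()
    n_big = int((sizes >= cfg.min_component_fraction * largest).sum())
    if n_big > 1:
        return f"multiple components ({n_big} of comparable size)"
    main = labels == (int(sizes.argmax()) + 1)
    if (
        main[0].any()
        or main[-1].any()
        or main[:, 0].any()
        or main[:, -1].any()
        or main[:, :, 0].any()
        or main[:, :, -1].any()
    ):
        return "border contact"
    return None
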