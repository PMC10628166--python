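"""Classifier stage: preprocessing, dataset split, training protocol, and the
bootstrap few-cell AUROC evaluation.

The classification tasks are *diagnosis* (septic-shock T1 cells vs healthy H
cells) and *prognosis* (T1 survivor vs non-survivor cells).  Each cell volume
is centre-cropped to its own bounding box (center ± radius per axis, padded
with medium RI where the box leaves the volume), min–max normalized per
image, and trilinearly resized to a fixed target shape — by default the
per-axis median of the training-set crop shapes.  Training uses cross-entropy
loss, SGD with momentum, a cosine-annealed learning rate, per-epoch flip/90°
rotation augmentation, and early stopping on validation loss.

Evaluation follows the few-cell protocol: per bootstrap iteration, k cells
are sampled per subject (or per class when no subject ids exist), their
positive-class probabilities averaged into one score per unit, and the AUROC
computed by pairwise concordance with ties counted 0.5; the 95% CI is the
2.5/97.5 percentile over iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import zoom

from tomoshell.io import Tomogram
from tomoshell.morphometry import MorphometryConfig, extract_features
from tomoshell.nn import (
    SGD,
    DenseNet3D,
    ModelConfig,
    cosine_annealing_lr,
    cross_entropy_grad,
    grad_cam,
)

TASK_LABELS = {
    "diagnosis": ("H", "T1"),  # negative, positive
    "prognosis": ("survivor", "non-survivor"),
}


@dataclass(frozen=True)
class PreprocessConfig:
    """Crop / normalization / resize conventions.

    ``nominal_extent`` is the instrument's native volume size; phantoms are
    smaller, so the crop is always clipped and padded with medium RI.
    ``resize_target`` is either an explicit (z, y, x) triple or ``"median"``,
    meaning the per-axis median of the *training-set* crop shapes, fixed
    before training and reused at inference.
    """

    nominal_extent: tuple[int, int, int] = (210, 276, 276)
    resize_target: tuple[int, int, int] | str = "median"
    pad_mode: str = "medium_ri"

    def __post_init__(self) -> None:
        if isinstance(self.resize_target, str) and self.resize_target != "median":
            raise ValueError("resize_target must be a triple or 'median'")
        if not isinstance(self.resize_target, str) and any(
            int(t) <= 0 for t in self.resize_target
        ):
            raise ValueError("resize target extents must be positive")


def crop_cell(
    tomogram: Tomogram,
    center_vox: Sequence[float],
    radius_um: float,
) -> np.ndarray:
    """Axis-aligned crop of center ± radius per axis, padded with medium RI."""
    if radius_um <= 0:
        raise ValueError("cell radius must be positive")
    vol = tomogram.ri_volume
    lo, hi, pad = [], [], []
    for ax in range(3):
        r_vox = max(int(np.ceil(radius_um / tomogram.voxel_spacing_um[ax])), 1)
        c = int(round(center_vox[ax]))
        a, b = c - r_vox, c + r_vox + 1
        lo.append(max(a, 0))
        hi.append(min(b, vol.shape[ax]))
        pad.append((max(0, -a), max(0, b - vol.shape[ax])))
    crop = vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    if any(p != (0, 0) for p in pad):
        crop = np.pad(crop, pad, constant_values=tomogram.medium_ri)
    return crop


def minmax_normalize(volume: np.ndarray) -> np.ndarray:
    """Per-image min–max to [0, 1]; a constant volume maps to all zeros."""
    vmin, vmax = float(volume.min()), float(volume.max())
    if vmax == vmin:
        return np.zeros_like(volume, dtype=np.float32)
    return ((volume - vmin) / (vmax - vmin)).astype(np.float32)


def resize_volume(volume: np.ndarray, target: tuple[int, int, int]) -> np.ndarray:
    """Trilinear resize to ``target`` (exact output shape guaranteed)."""
    factors = [t / s for t, s in zip(target, volume.shape)]
    out = zoom(volume.astype(np.float32), factors, order=1)
    pads = [(0, max(0, t - s)) for t, s in zip(target, out.shape)]
    out = np.pad(out, pads, mode="edge")
    return out[: target[0], : target[1], : target[2]]


def median_crop_shape(
    crop_shapes: Sequence[tuple[int, int, int]], multiple: int = 16
) -> tuple[int, int, int]:
    """Per-axis median of crop shapes, rounded to the nearest positive
    multiple of ``multiple`` (the network halves each spatial extent once at
    the stem and once per transition, so inputs must divide by
    ``2 ** n_blocks``)."""
    arr = np.asarray(crop_shapes)
    med = np.median(arr, axis=0)
    out = []
    for m in med:
        k = int(round(m / multiple)) * multiple
        out.append(max(k, multiple))
    return tuple(out)


def preprocess_cells(
    tomograms: Sequence[Tomogram],
    cfg: PreprocessConfig,
    morph_cfg: MorphometryConfig | None = None,
    resize_target: tuple[int, int, int] | None = None,
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Crop, normalize, and resize every cell; returns the stacked array and
    the resize target actually used."""
    morph_cfg = morph_cfg or MorphometryConfig()
    crops = []
    for tom in tomograms:
        m = extract_features(tom, morph_cfg)
        radius = m.radius if morph_cfg.physical_radius else m.radius * min(
            tom.voxel_spacing_um
        )
        crops.append(minmax_normalize(crop_cell(tom, m.center_vox, radius)))
    if resize_target is None:
        if cfg.resize_target == "median":
            resize_target = median_crop_shape([c.shape for c in crops])
        else:
            resize_target = tuple(cfg.resize_target)  # type: ignore[arg-type]
    stack = np.stack([resize_volume(c, resize_target) for c in crops])
    return stack, resize_target


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters.

    Defaults mirror the protocol this evaluation models: cross-entropy loss,
    SGD with batch size 16, cosine-annealed learning rate (initial 1e-3,
    period 64 epochs), flip/rotation augmentation once per image per epoch,
    8:1:1 train/val/test split, early stopping on validation loss with
    patience 30.  Desk-scale runs typically raise ``lr0`` and cap
    ``max_epochs`` — both are free parameters.
    """

    batch_size: int = 16
    lr0: float = 0.001
    cosine_period: int = 64
    momentum: float = 0.9
    weight_decay: float = 0.0
    max_epochs: int = 64
    patience: int = 30
    augment: bool = True
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    by_subject: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split}")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


class SplitError(RuntimeError):
    """A class is absent from one of the partitions after reshuffling."""


def split_dataset(
    labels: np.ndarray,
    cfg: TrainConfig,
    subject_ids: Sequence[str] | None = None,
    max_tries: int = 50,
) -> dict[str, np.ndarray]:
    """Deterministic 8:1:1 (configurable) train/val/test index split.

    Cell-level by default; with ``cfg.by_subject`` whole subjects are assigned
    to a single partition so no subject spans partitions.  If any partition
    misses a class the shuffle is retried, then a :class:`SplitError` raised.
    """
    labels = np.asarray(labels)
    n = len(labels)
    rng = np.random.default_rng(cfg.seed)
    classes = np.unique(labels)
    for _ in range(max_tries):
        if cfg.by_subject:
            if subject_ids is None:
                raise ValueError("by_subject split needs subject ids")
            subject_ids = np.asarray(subject_ids)
            subjects = np.unique(subject_ids)
            perm_s = rng.permutation(subjects)
            n_s = len(perm_s)
            n_train = int(round(cfg.split[0] * n_s))
            n_val = int(round(cfg.split[1] * n_s))
            parts_s = {
                "train": perm_s[:n_train],
                "val": perm_s[n_train : n_train + n_val],
                "test": perm_s[n_train + n_val :],
            }
            parts = {
                k: np.flatnonzero(np.isin(subject_ids, v)) for k, v in parts_s.items()
            }
        else:
            perm = rng.permutation(n)
            n_train = int(round(cfg.split[0] * n))
            n_val = int(round(cfg.split[1] * n))
            parts = {
                "train": perm[:n_train],
                "val": perm[n_train : n_train + n_val],
                "test": perm[n_train + n_val :],
            }
        if all(
            len(part) > 0 and set(classes) <= set(labels[part])
            for part in parts.values()
        ):
            return {k: np.sort(v) for k, v in parts.items()}
    raise SplitError(
        "could not produce a split containing every class in every partition"
    )


def augment_volume(vol: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random axis-aligned 90° rotation in a random plane plus random
    horizontal/vertical flips (interpolation-free)."""
    planes = [(0, 1), (0, 2), (1, 2)]
    k = int(rng.integers(0, 4))
    plane = planes[int(rng.integers(0, 3))]
    out = np.rot90(vol, k=k, axes=plane)
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[:, :, ::-1]
    return np.ascontiguousarray(out)


@dataclass
class ClassifierBundle:
    """Trained model plus everything needed to reuse it consistently."""

    model: DenseNet3D
    model_config: ModelConfig
    train_config: TrainConfig
    resize_target: tuple[int, int, int]
    history: dict = field(default_factory=dict)
    split: dict[str, np.ndarray] = field(default_factory=dict)
    best_epoch: int = -1


class DivergenceError(RuntimeError):
    pass


def train(
    volumes: np.ndarray,
    labels: np.ndarray,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    resize_target: tuple[int, int, int] | None = None,
    split: dict[str, np.ndarray] | None = None,
    subject_ids: Sequence[str] | None = None,
) -> ClassifierBundle:
    """Train the dense-block network with the configured protocol.

    ``volumes`` are preprocessed (normalized, fixed-shape) cell volumes,
    ``labels`` integer class labels.  Early stopping restores the parameters
    of the best validation epoch.  Deterministic given the config seed.
    """
    volumes = np.asarray(volumes, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)
    if split is None:
        split = split_dataset(labels, train_cfg, subject_ids)
    for part in ("train", "val"):
        if len(np.unique(labels[split[part]])) < 2:
            raise ValueError(f"{part} partition must contain at least two classes")
    rng = np.random.default_rng(train_cfg.seed + 1)
    net = DenseNet3D(model_cfg, seed=train_cfg.seed)
    opt = SGD(
        net.parameters(), lr=train_cfg.lr0, momentum=train_cfg.momentum,
        weight_decay=train_cfg.weight_decay,
    )
    x_train, y_train = volumes[split["train"]], labels[split["train"]]
    x_val, y_val = volumes[split["val"]], labels[split["val"]]
    history: dict = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_state = net.get_state()
    best_epoch = -1
    for epoch in range(train_cfg.max_epochs):
        lr = cosine_annealing_lr(epoch, train_cfg.lr0, train_cfg.cosine_period)
        opt.lr = lr
        order = rng.permutation(len(x_train))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            if len(idx) < 2:
                continue  # batch statistics need >= 2 samples
            xb = x_train[idx]
            if train_cfg.augment:
                xb = np.stack([augment_volume(v, rng) for v in xb])
            logits = net.forward(xb, train=True)
            loss, dlogits = cross_entropy_grad(logits, y_train[idx])
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"last valid epoch {epoch - 1}"
                )
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val_logits = net.forward(x_val, train=False)
        val_loss, _ = cross_entropy_grad(val_logits, y_val)
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = net.get_state()
            best_epoch = epoch
        elif epoch - best_epoch >= train_cfg.patience:
            break
    net.set_state(best_state)
    return ClassifierBundle(
        model=net,
        model_config=model_cfg,
        train_config=train_cfg,
        resize_target=resize_target or tuple(volumes.shape[1:]),
        history=history,
        split=split,
        best_epoch=best_epoch,
    )


# --- AUROC ------------------------------------------------------------------


def concordance_auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUROC by pairwise concordance: fraction of (positive, negative) pairs
    where the positive scores higher, ties counted 0.5."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes to compute AUROC")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


@dataclass
class AUROCResult:
    k: int
    auroc: float
    ci_low: float
    ci_high: float
    iterations: int

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low


def bootstrap_auroc(
    scores: np.ndarray,
    labels: np.ndarray,
    k: int,
    iterations: int = 1000,
    subject_ids: Sequence[str] | None = None,
    subject_labels: dict[str, int] | None = None,
    seed: int = 0,
    aggregate: str = "mean",
) -> AUROCResult:
    """Few-cell bootstrap AUROC.

    Per iteration, k cells are drawn per subject (with replacement when a
    subject holds fewer than k cells) and their positive-class probabilities
    aggregated (mean by default, ``aggregate='vote'`` for majority vote) into
    one score per subject; AUROC is computed across subjects by pairwise
    concordance.  Without subject ids each class is one sampling unit.
    Reports the mean AUROC and percentile 95% CI over iterations.
    """
    if not 1 <= k:
        raise ValueError("k must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    if subject_ids is not None:
        subject_ids = np.asarray(subject_ids)
        units = []
        for s in np.unique(subject_ids):
            idx = np.flatnonzero(subject_ids == s)
            lab = (
                subject_labels[s]
                if subject_labels is not None
                else int(np.round(labels[idx].mean()))
            )
            units.append((idx, lab))
    else:
        units = [(np.flatnonzero(labels == c), int(c)) for c in (0, 1)]
    unit_labels = np.array([lab for _, lab in units])
    if not ({0, 1} <= set(unit_labels.tolist())):
        raise ValueError("need both classes among sampling units")
    aurocs = np.empty(iterations)
    for it in range(iterations):
        unit_scores = np.empty(len(units))
        for u, (idx, _) in enumerate(units):
            pick = rng.choice(idx, size=k, replace=len(idx) < k)
            vals = scores[pick]
            if aggregate == "vote":
                unit_scores[u] = (vals > 0.5).mean()
            else:
                unit_scores[u] = vals.mean()
        aurocs[it] = concordance_auroc(unit_labels, unit_scores)
    lo, hi = np.percentile(aurocs, [2.5, 97.5])
    return AUROCResult(
        k=k,
        auroc=float(aurocs.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        iterations=iterations,
    )


def saliency(
    bundle: ClassifierBundle, volume: np.ndarray, class_idx: int = 1, block: int = -1
) -> np.ndarray:
    """Grad-CAM heat map over the input spatial shape (max-normalized to 1)."""
    return grad_cam(bundle.model, volume, class_idx, block=block)
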