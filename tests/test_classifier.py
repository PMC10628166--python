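"""Classifier stage: preprocessing contracts, splits, the concordance AUROC
against brute-force and sklearn oracles, bootstrap evaluation, and training
behaviour on separable data."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from tomoshell.classifier import (
    AUROCResult,
    PreprocessConfig,
    SplitError,
    TrainConfig,
    bootstrap_auroc,
    concordance_auroc,
    crop_cell,
    median_crop_shape,
    minmax_normalize,
    preprocess_cells,
    resize_volume,
    saliency,
    split_dataset,
    train,
)
from tomoshell.io import Tomogram
from tomoshell.morphometry import extract_features
from tomoshell.nn import ModelConfig
from tomoshell.phantom import PhantomSpec, make_phantom


def brute_force_auroc(y, s):
    """Direct double loop over all (positive, negative) pairs."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestPreprocess:
    def test_normalized_crop_spans_unit_interval(self, nucleated_phantom):
        m = extract_features(nucleated_phantom)
        crop = minmax_normalize(crop_cell(nucleated_phantom, m.center_vox, m.radius))
        assert crop.min() == 0.0
        assert crop.max() == 1.0

    def test_constant_crop_maps_to_zeros(self):
        assert np.all(minmax_normalize(np.full((4, 4, 4), 1.337)) == 0.0)

    def test_zero_radius_rejected(self, nucleated_phantom):
        with pytest.raises(ValueError, match="radius"):
            crop_cell(nucleated_phantom, (24, 24, 24), 0.0)

    def test_crop_contains_entire_cell_mask(self, nucleated_phantom):
        from tomoshell.morphometry import segment

        m = extract_features(nucleated_phantom)
        crop = crop_cell(nucleated_phantom, m.center_vox, m.radius)
        mask = segment(nucleated_phantom)
        # every super-threshold voxel count must be preserved in the crop
        n_in_crop = int((crop > mask.threshold).sum())
        assert n_in_crop >= mask.voxel_count

    def test_crop_pads_with_medium_at_border(self):
        spec = PhantomSpec(cell_radius_um=(2.8, 2.8, 2.8), grid_shape=(32, 32, 32))
        tom = make_phantom(spec, seed=0)
        crop = crop_cell(tom, (15.5, 15.5, 15.5), 3.5)  # box exceeds the volume
        assert crop.shape == (37, 37, 37)
        assert crop[0, 0, 0] == np.float32(spec.medium_ri)

    def test_resize_hits_exact_target(self):
        vol = np.random.default_rng(0).random((23, 29, 17)).astype(np.float32)
        out = resize_volume(vol, (16, 16, 16))
        assert out.shape == (16, 16, 16)

    def test_median_crop_shape_rounds_to_pool_granularity(self):
        shapes = [(21, 25, 25), (25, 27, 29), (23, 25, 27)]
        assert median_crop_shape(shapes, multiple=16) == (16, 32, 32)

    def test_preprocess_cells_fixed_target(self, small_cohort):
        toms, _ = small_cohort
        vols, target = preprocess_cells(
            toms[:4], PreprocessConfig(resize_target=(16, 16, 16))
        )
        assert vols.shape == (4, 16, 16, 16)
        assert target == (16, 16, 16)
        assert vols.min() >= 0.0 and vols.max() <= 1.0


class TestSplit:
    def test_ratio_8_1_1(self):
        labels = np.repeat([0, 1], 50)
        parts = split_dataset(labels, TrainConfig(seed=0))
        assert len(parts["train"]) == 80
        assert len(parts["val"]) == 10
        assert len(parts["test"]) == 10

    def test_same_seed_same_split(self):
        labels = np.repeat([0, 1], 30)
        a = split_dataset(labels, TrainConfig(seed=5))
        b = split_dataset(labels, TrainConfig(seed=5))
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_partitions_disjoint_and_exhaustive(self):
        labels = np.repeat([0, 1], 35)
        parts = split_dataset(labels, TrainConfig(seed=1))
        allidx = np.concatenate(list(parts.values()))
        assert sorted(allidx) == list(range(70))

    def test_by_subject_split_never_splits_a_subject(self):
        # subjects are class-pure, so val/test need at least 2 subjects each
        labels = np.repeat([0, 1], 40)
        subjects = np.array([f"s{i // 8}" for i in range(80)])
        parts = split_dataset(
            labels,
            TrainConfig(seed=2, by_subject=True, split=(0.6, 0.2, 0.2)),
            subject_ids=subjects,
        )
        seen = {}
        for part, idx in parts.items():
            for s in subjects[idx]:
                assert seen.setdefault(s, part) == part

    def test_impossible_split_raises(self):
        labels = np.array([0] * 98 + [1] * 2)  # class 1 cannot fill 3 partitions
        with pytest.raises(SplitError):
            split_dataset(labels, TrainConfig(seed=0), max_tries=5)


class TestConcordanceAUROC:
    def test_printed_toy_case(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([0.8, 0.4, 0.6, 0.2])
        assert concordance_auroc(y, s) == pytest.approx(0.75)

    def test_exhaustive_small_sets_match_brute_force(self):
        """All score assignments from {0, 0.5, 1} for all class splits of
        size <= 8 agree with the double-loop oracle (ties = 0.5)."""
        alphabet = (0.0, 0.5, 1.0)
        for n in range(2, 9):
            for scores in itertools.product(alphabet, repeat=n):
                y = np.array([1] * (n // 2) + [0] * (n - n // 2))
                got = concordance_auroc(y, np.array(scores))
                assert got == pytest.approx(brute_force_auroc(y, scores))

    def test_matches_sklearn_on_tie_free_scores(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = rng.normal(size=n)
            assert concordance_auroc(y, s) == pytest.approx(roc_auc_score(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            concordance_auroc(np.ones(4), np.arange(4))


class TestBootstrapAUROC:
    def test_perfect_separation_gives_unit_auroc_zero_width(self):
        scores = np.array([0.9, 0.95, 0.8, 0.1, 0.2, 0.05])
        labels = np.array([1, 1, 1, 0, 0, 0])
        res = bootstrap_auroc(scores, labels, k=2, iterations=100, seed=0)
        assert res.auroc == 1.0
        assert res.ci_width == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        scores = rng.random(40)
        labels = np.tile([0, 1], 20)
        a = bootstrap_auroc(scores, labels, k=3, iterations=50, seed=9)
        b = bootstrap_auroc(scores, labels, k=3, iterations=50, seed=9)
        assert (a.auroc, a.ci_low, a.ci_high) == (b.auroc, b.ci_low, b.ci_high)

    def test_random_scores_center_near_half(self):
        rng = np.random.default_rng(2)
        scores = rng.random(200)
        labels = np.tile([0, 1], 100)
        res = bootstrap_auroc(scores, labels, k=1, iterations=400, seed=3)
        assert 0.35 < res.auroc < 0.65
        assert res.ci_low <= 0.5 <= res.ci_high

    def test_subject_units_aggregate_cells(self):
        # 4 subjects x 3 cells; subject-level scores are means over k cells
        scores = np.array([0.9, 0.8, 0.85, 0.7, 0.75, 0.8, 0.3, 0.2, 0.1, 0.4, 0.35, 0.3])
        labels = np.array([1] * 6 + [0] * 6)
        subjects = np.repeat(["a", "b", "c", "d"], 3)
        res = bootstrap_auroc(
            scores, labels, k=3, iterations=50, subject_ids=subjects, seed=0
        )
        assert res.auroc == 1.0

    def test_oversampling_k_beyond_cells_allowed(self):
        scores = np.array([0.9, 0.1])
        labels = np.array([1, 0])
        res = bootstrap_auroc(scores, labels, k=5, iterations=20, seed=0)
        assert res.auroc == 1.0


def _separable_volumes(n_per_class=20, shape=(16, 16, 16), seed=0):
    """Two classes differing in a bright central blob amplitude."""
    rng = np.random.default_rng(seed)
    vols, labels = [], []
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    blob = np.exp(-(((zz - 8) ** 2 + (yy - 8) ** 2 + (xx - 8) ** 2) / 18.0))
    for cls in (0, 1):
        for _ in range(n_per_class):
            amp = 0.25 if cls == 0 else 1.0
            vols.append(
                (amp * blob + rng.normal(0, 0.05, shape)).astype(np.float32)
            )
            labels.append(cls)
    return np.stack(vols), np.array(labels)


class TestTraining:
    def test_separable_data_trains_to_high_accuracy(self):
        vols, labels = _separable_volumes(n_per_class=20)
        cfg = TrainConfig(
            lr0=0.05, max_epochs=10, patience=8, seed=0, split=(0.7, 0.15, 0.15)
        )
        bundle = train(vols, labels, ModelConfig(), cfg)
        tr = bundle.split["train"]
        probs = bundle.model.predict_proba(vols[tr])[:, 1]
        acc = ((probs > 0.5).astype(int) == labels[tr]).mean()
        assert acc >= 0.95
        # early-stop contract
        assert len(bundle.history["val_loss"]) <= bundle.best_epoch + cfg.patience + 1

    def test_training_deterministic_given_seed(self):
        vols, labels = _separable_volumes(n_per_class=8)
        cfg = TrainConfig(
            lr0=0.05, max_epochs=3, patience=3, seed=4, split=(0.5, 0.25, 0.25)
        )
        a = train(vols, labels, ModelConfig(), cfg)
        b = train(vols, labels, ModelConfig(), cfg)
        assert a.history["train_loss"] == b.history["train_loss"]
        assert all(np.array_equal(x, y) for x, y in zip(a.split.values(), b.split.values()))

    def test_saliency_localizes_inside_discriminative_region(self):
        vols, labels = _separable_volumes(n_per_class=20)
        cfg = TrainConfig(
            lr0=0.05, max_epochs=10, patience=8, seed=0, split=(0.7, 0.15, 0.15)
        )
        bundle = train(vols, labels, ModelConfig(), cfg)
        zz, yy, xx = np.meshgrid(*[np.arange(16)] * 3, indexing="ij")
        inside = ((zz - 8) ** 2 + (yy - 8) ** 2 + (xx - 8) ** 2) <= 25
        ratios = []
        for i in np.flatnonzero(labels == 1)[:5]:
            # first dense block: finest spatial resolution for localization
            cam = saliency(bundle, vols[i], class_idx=1, block=0)
            assert cam.shape == vols[i].shape and cam.min() >= 0 and cam.max() <= 1
            if cam.max() > 0:
                ratios.append(cam[inside].mean() - cam[~inside].mean())
        # the class evidence lives in the central blob
        assert ratios and np.mean(ratios) > 0
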