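"""Orchestration: simulate → qc → extract → shells → stats → train → eval.

One YAML/dict config with per-stage sections and a single global seed drives
the whole run; per-stage seeds derive from it by fixed offsets so one number
reproduces everything.  Each stage writes its outputs under the run directory
and records them in a manifest (config hash, seeds, paths, timings); a
completed stage whose outputs exist under an unchanged config hash is skipped
on re-run, making the manifest sufficient to resume bit-compatibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from tomoshell import io as tio
from tomoshell import phantom as ph
from tomoshell.classifier import (
    PreprocessConfig,
    TrainConfig,
    bootstrap_auroc,
    preprocess_cells,
    train,
    TASK_LABELS,
)
from tomoshell.morphometry import MorphometryConfig, extract_cohort_features
from tomoshell.nn import ModelConfig
from tomoshell.shells import shell_profiles_for_cohort
from tomoshell.stats import compare_groups, correlate_features, shell_comparisons

log = logging.getLogger("tomoshell.pipeline")

STAGES = ("simulate", "qc", "extract", "shells", "stats", "train", "eval")
SEED_OFFSETS = {name: 1000 + 17 * i for i, name in enumerate(STAGES)}
REQUIRED_KEYS = ("seed", "cohort")

MORPH_FEATURES = ("volume_fl", "dry_mass_pg", "mean_overall_ri", "mean_nuclear_ri")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> None:
    for key in REQUIRED_KEYS:
        if key not in config:
            raise ConfigError(f"config missing required key '{key}'")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_seed(config: dict, stage: str) -> int:
    return (int(config["seed"]) + SEED_OFFSETS[stage]) % (2**31 - 1)


def _build_cohort_inputs(config: dict):
    c = dict(config.get("cohort", {}))
    base = ph.PhantomSpec(**c.get("base_phantom", {}))
    if "groups" in c:
        groups = [ph.GroupEffectSpec(**g) for g in c["groups"]]
    else:
        groups = ph.default_cohort_groups(c.get("cells_per_group", 40))
    if "covariates" in c:
        covs = [ph.ClinicalCovariateSpec(**v) for v in c["covariates"]]
    else:
        covs = ph.default_covariates()
    return groups, covs, base


class Pipeline:
    """Stateful runner holding intermediate products of one run."""

    def __init__(self, config: dict, out_dir: str | Path):
        validate_config(config)
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest: dict[str, Any] = {
            "config_hash": config_hash(config),
            "seed": int(config["seed"]),
            "stage_seeds": {s: _stage_seed(config, s) for s in STAGES},
            "stages": {},
        }
        if self.manifest_path.exists():
            old = json.loads(self.manifest_path.read_text())
            if old.get("config_hash") == self.manifest["config_hash"]:
                self.manifest["stages"] = old.get("stages", {})
        self.tomograms: list[tio.Tomogram] = []
        self.cohort_table: pd.DataFrame | None = None
        self.features: pd.DataFrame | None = None
        self.shells: pd.DataFrame | None = None

    # -- helpers -------------------------------------------------------------
    def _done(self, stage: str) -> bool:
        rec = self.manifest["stages"].get(stage)
        if not rec:
            return False
        return all(Path(p).exists() for p in rec.get("outputs", []))

    def _record(self, stage: str, outputs: list[Path], t0: float) -> None:
        self.manifest["stages"][stage] = {
            "outputs": [str(p) for p in outputs],
            "seconds": round(time.time() - t0, 3),
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))

    def _run_stage(self, stage: str, fn) -> None:
        t0 = time.time()
        log.info("stage %s: start", stage)
        try:
            outputs = fn()
        except Exception as exc:  # halt with stage name and cause
            raise StageError(stage, exc) from exc
        self._record(stage, outputs, t0)
        log.info("stage %s: done (%.1fs)", stage, time.time() - t0)

    # -- stages --------------------------------------------------------------
    def simulate(self) -> list[Path]:
        groups, covs, base = _build_cohort_inputs(self.config)
        seed = _stage_seed(self.config, "simulate")
        self.tomograms, self.cohort_table = ph.make_cohort(groups, covs, base, seed)
        tom_dir = self.out / "tomograms"
        paths = tio.write_cohort(self.tomograms, tom_dir)
        table_path = self.out / "cohort.csv"
        self.cohort_table.to_csv(table_path, index=False)
        return [table_path, tom_dir]

    def qc(self) -> list[Path]:
        self._require_tomograms()
        cfg = tio.QCConfig(**self.config.get("qc", {}))
        kept, rejected = tio.qc_filter(self.tomograms, cfg)
        self.tomograms = kept
        report = self.out / "qc_report.csv"
        pd.DataFrame(
            [{"cell_id": t.cell_id, "reason": r} for t, r in rejected]
        ).to_csv(report, index=False)
        return [report]

    def extract(self) -> list[Path]:
        self._require_tomograms()
        cfg = MorphometryConfig(**self.config.get("morphometry", {}))
        feats = extract_cohort_features(self.tomograms, cfg)
        if self.cohort_table is not None:
            covs = [
                c
                for c in self.cohort_table.columns
                if c not in ("cell_id", "subject_id", "group", "outcome")
            ]
            feats = feats.merge(
                self.cohort_table[["cell_id"] + covs], on="cell_id", how="left"
            )
        self.features = feats
        path = self.out / "features.csv"
        feats.to_csv(path, index=False)
        return [path]

    def shells_stage(self) -> list[Path]:
        self._require_tomograms()
        cfg = MorphometryConfig(**self.config.get("morphometry", {}))
        opts = self.config.get("shells", {})
        self.shells = shell_profiles_for_cohort(
            self.tomograms,
            cfg,
            n_shells=opts.get("n_shells", 8),
            restrict_to_cell=opts.get("restrict_to_cell", False),
        )
        path = self.out / "shells.csv"
        self.shells.to_csv(path, index=False)
        return [path]

    def stats(self) -> list[Path]:
        if self.features is None or self.shells is None:
            raise RuntimeError("extract and shells stages must run before stats")
        out_paths = []
        rows = []
        for feat in MORPH_FEATURES:
            if feat not in self.features or self.features[feat].isna().all():
                continue
            res = compare_groups(self.features.dropna(subset=[feat]), feat)
            rows.append(
                {"feature": feat, "f_statistic": res.f_statistic, "anova_p": res.anova_p}
            )
            pw = res.pairwise.assign(feature=feat)
            pw_path = self.out / f"posthoc_{feat}.csv"
            pw.to_csv(pw_path, index=False)
            out_paths.append(pw_path)
        anova_path = self.out / "anova.csv"
        pd.DataFrame(rows).to_csv(anova_path, index=False)
        out_paths.append(anova_path)
        for component in ("overall", "nuclear"):
            sc = shell_comparisons(self.shells, component=component)
            p = self.out / f"shell_stats_{component}.csv"
            sc.to_csv(p, index=False)
            out_paths.append(p)
        cov_names = [c.name for c in ph.default_covariates()]
        cov_names = [c for c in cov_names if c in self.features.columns]
        if cov_names:
            mode = self.config.get("stats", {}).get("correlation_mode", "timepoint_means")
            corr = correlate_features(self.features, cov_names, mode=mode)
            corr_path = self.out / "correlations.csv"
            pd.DataFrame([asdict(c) for c in corr]).to_csv(corr_path, index=False)
            out_paths.append(corr_path)
        return out_paths

    def train_stage(self) -> list[Path]:
        self._require_tomograms()
        ccfg = self.config.get("classifier", {})
        task = ccfg.get("task", "diagnosis")
        neg, pos = TASK_LABELS[task]
        if task == "diagnosis":
            cells = [t for t in self.tomograms if t.labels.get("group") in (neg, pos)]
            labels = np.array(
                [1 if t.labels["group"] == pos else 0 for t in cells]
            )
        else:
            cells = [
                t
                for t in self.tomograms
                if t.labels.get("group") == "T1"
                and t.labels.get("outcome") in (neg, pos)
            ]
            labels = np.array(
                [1 if t.labels["outcome"] == pos else 0 for t in cells]
            )
        pre_cfg = PreprocessConfig(**ccfg.get("preprocess", {}))
        morph_cfg = MorphometryConfig(**self.config.get("morphometry", {}))
        model_cfg = ModelConfig(task=task, **ccfg.get("model", {}))
        train_cfg = TrainConfig(
            seed=_stage_seed(self.config, "train"), **ccfg.get("train", {})
        )
        subject_ids = [t.labels.get("subject_id", t.cell_id) for t in cells]
        split = None
        volumes, target = preprocess_cells(cells, pre_cfg, morph_cfg)
        self._clf = train(
            volumes,
            labels,
            model_cfg,
            train_cfg,
            resize_target=target,
            subject_ids=subject_ids,
        )
        self._clf_data = (volumes, labels, np.asarray(subject_ids))
        hist_path = self.out / "training_history.json"
        hist_path.write_text(
            json.dumps(
                {
                    "task": task,
                    "best_epoch": self._clf.best_epoch,
                    "resize_target": list(target),
                    "history": self._clf.history,
                    "split": {k: v.tolist() for k, v in self._clf.split.items()},
                }
            )
        )
        return [hist_path]

    def eval_stage(self) -> list[Path]:
        if not hasattr(self, "_clf"):
            raise RuntimeError("train stage must run before eval")
        ccfg = self.config.get("classifier", {})
        ks = ccfg.get("eval", {}).get("cells", [1, 2, 3, 4, 5])
        iters = ccfg.get("eval", {}).get("iterations", 1000)
        volumes, labels, subject_ids = self._clf_data
        test = self._clf.split["test"]
        probs = self._clf.model.predict_proba(volumes[test])[:, 1]
        subj_lab = {
            s: int(np.round(labels[test][subject_ids[test] == s].mean()))
            for s in np.unique(subject_ids[test])
        }
        rows = []
        for k in ks:
            res = bootstrap_auroc(
                probs,
                labels[test],
                k=k,
                iterations=iters,
                subject_ids=subject_ids[test],
                subject_labels=subj_lab,
                seed=_stage_seed(self.config, "eval") + k,
            )
            rows.append(asdict(res))
        path = self.out / "auroc.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return [path]

    # -- driver --------------------------------------------------------------
    def _require_tomograms(self) -> None:
        if not self.tomograms:
            # resume path: reload from disk
            tom_dir = self.out / "tomograms"
            if not tom_dir.exists():
                raise RuntimeError("simulate stage has not produced tomograms")
            self.tomograms = tio.read_cohort(tom_dir)
            cohort_csv = self.out / "cohort.csv"
            if cohort_csv.exists():
                self.cohort_table = pd.read_csv(cohort_csv)

    def run_all(self, stages: tuple[str, ...] = STAGES) -> dict:
        fns = {
            "simulate": self.simulate,
            "qc": self.qc,
            "extract": self.extract,
            "shells": self.shells_stage,
            "stats": self.stats,
            "train": self.train_stage,
            "eval": self.eval_stage,
        }
        # stages with pure on-disk outputs can be skipped when already done;
        # in-memory state is rebuilt lazily from those outputs
        resumable = {"simulate", "qc", "extract", "shells", "stats"}
        for stage in stages:
            if stage in resumable and self._done(stage):
                log.info("stage %s: up to date, skipping", stage)
                self._load_stage_outputs(stage)
                continue
            self._run_stage(stage, fns[stage])
        return self.manifest

    def _load_stage_outputs(self, stage: str) -> None:
        if stage == "simulate":
            self._require_tomograms()
        elif stage == "qc":
            report = self.out / "qc_report.csv"
            if report.exists() and report.stat().st_size > 1:
                rejected = set(pd.read_csv(report).get("cell_id", []))
                self._require_tomograms()
                self.tomograms = [
                    t for t in self.tomograms if t.cell_id not in rejected
                ]
        elif stage == "extract":
            self.features = pd.read_csv(self.out / "features.csv")
        elif stage == "shells":
            self.shells = pd.read_csv(self.out / "shells.csv")


def run_all(config: dict, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns the manifest."""
    return Pipeline(config, out_dir).run_all()
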