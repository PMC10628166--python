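#!/usr/bin/env python
"""Cohort statistics: group comparisons, shell comparison families, and
morphology–covariate correlations.

One-way ANOVA across H/T1/T2/T3 with Bonferroni-corrected Student's t
post-hoc pairs for each morphological feature; per-shell ANOVA plus a T1
survivor-vs-non-survivor t-test for each component; Pearson correlation of
per-time-point mean RI with each clinical covariate.  Writes the result
tables and two summary figures under results/run/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from tomoshell.pipeline import Pipeline, load_config

ROOT = Path(__file__).resolve().parents[1]


def figures(out: Path) -> None:
    feats = pd.read_csv(out / "features.csv")
    shells = pd.read_csv(out / "shells.csv")
    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)

    order = ["H", "T1", "T2", "T3"]
    fig, axes = plt.subplots(1, 4, figsize=(14, 3.2))
    for ax, feat in zip(
        axes, ["volume_fl", "dry_mass_pg", "mean_overall_ri", "mean_nuclear_ri"]
    ):
        data = [feats.loc[feats.group == g, feat].dropna() for g in order]
        ax.boxplot(data, tick_labels=order)
        ax.set_title(feat)
    fig.tight_layout()
    fig.savefig(figdir / "morphology_by_group.png", dpi=120)

    dcols = [f"d{k}" for k in range(1, 9)]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
    for ax, component in zip(axes, ("overall", "nuclear")):
        sub = shells[shells.component == component]
        for g in order:
            ax.plot(range(1, 9), sub[sub.group == g][dcols].mean(), marker="o", label=g)
        ax.set_xlabel("shell")
        ax.set_title(component)
    axes[0].set_ylabel("density")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(figdir / "shell_profiles.png", dpi=120)


def main() -> None:
    cfg = load_config(ROOT / "analysis" / "run_config.yaml")
    out = ROOT / "results" / "run"
    pipe = Pipeline(cfg, out)
    pipe.run_all(stages=("simulate", "qc", "extract", "shells", "stats"))

    print("feature ANOVA across H/T1/T2/T3:")
    print(pd.read_csv(out / "anova.csv").round(3))
    shell_stats = pd.read_csv(out / "shell_stats_overall.csv")
    sig = shell_stats[shell_stats.anova_p_adj < 0.001]
    print(f"\noverall shells with ANOVA p_adj < 0.001: {sorted(sig.shell)}")
    print("\nper-time-point correlations with mean RI:")
    print(pd.read_csv(out / "correlations.csv").round(3))
    figures(out)
    print("\nfigures written to results/run/figures/")


if __name__ == "__main__":
    main()
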