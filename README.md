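# tomoshell

Label-free 3D morphometry of single immune cells from refractive-index (RI)
tomograms, built around the question of whether CD8+ T-cell morphology can
serve as a sepsis biomarker.  The package provides an end-to-end, fully
synthetic-testable pipeline: phantom tomogram simulation, quality control,
morphological feature extraction, radial shell-density statistics,
cohort-level statistics, and a dense-block 3D convolutional classifier
evaluated with a few-cell bootstrap AUROC protocol.

It is aimed at quantitative-phase-imaging / holotomography practitioners who
want a reproducible reference implementation of these analyses that runs on a
laptop, with every step validated against independent oracles on synthetic
cohorts — no measured data required.

## The quantities at the core

For a cell segmented from its medium by an RI threshold:

- **Volume** `V = N_vox · v_z v_y v_x` (µm³ ≡ fL), the voxel count times the
  voxel volume.
- **Protein density** `C = 100 · (⟨n⟩_cell − n_m) / α` (g/dL), from the linear
  relation between RI excess over the medium `n_m` and protein concentration,
  with refraction increment `α` (default 0.19 mL/g).
- **Dry mass** `m = C · V · 10⁻²` (pg).
- **Overall / nuclear mean RI** on the central cross-section; pixels with
  RI > 1.38 count as nuclear material.
- **Shell density** `d_k`: the section's pixels are ranked by distance from
  the cell center and split into eight equal-count shells (Shell 1 innermost);
  `d_k` is the fraction of pixels in shell `k` above an RI threshold.
- **Few-cell AUROC**: per bootstrap iteration, k ∈ {1..5} cells are sampled
  per subject, their positive-class probabilities averaged into one score per
  subject, and the AUROC computed by pairwise concordance (ties 0.5); the 95%
  CI is the 2.5/97.5 percentile over 1000 iterations.

The cohort structure mirrors a sepsis-recovery design: healthy controls (H)
sampled once and sepsis subjects sampled at septic-shock diagnosis (T1),
shock resolution (T2), and pre-discharge (T3), with T1 split into survivors
and non-survivors.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (240 cells, seeded; ~1 minute total) and write tables under
`results/run/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_qc_and_extract.py
python analysis/03_shell_profiles.py
python analysis/04_cohort_stats.py
python analysis/05_train_classifier.py
```

`02_qc_and_extract.py` prints the group means, showing the configured effect
directions — T1 cells are the largest and densest, T2 intermediate, T3 back
near healthy:

```
       volume_fl  dry_mass_pg  mean_overall_ri  mean_nuclear_ri
group
H        34.7948       4.6211           1.3665           1.3851
T1       80.8352      16.1319           1.3774           1.3887
T2       47.3921       7.4855           1.3707           1.3876
T3       36.5508       4.7467           1.3656           1.3840
```

`04_cohort_stats.py` reports highly significant one-way ANOVAs for all four
features (F = 397, 411, 376, 101), mid/outer shells whose density separates
the groups, and per-time-point Pearson correlations between mean RI and the
clinical covariates (e.g. CRP ρ = 0.98, lymphocyte % ρ = −0.99 — the
lymphocyte fraction rises during recovery while the inflammatory markers
fall).  `05_train_classifier.py` trains the diagnosis (T1 vs H) and
prognosis (T1 survivor vs non-survivor) models and prints the few-cell
AUROC table; on this strongly separated synthetic cohort both reach AUROC
1.0 for k = 1..5 with zero-width CIs.

The same machinery is available as a library (`tomoshell.phantom`,
`tomoshell.morphometry`, `tomoshell.shells`, `tomoshell.stats`,
`tomoshell.classifier`, `tomoshell.pipeline`); `tomoshell.pipeline.run_all`
executes every stage from one YAML config and seed, writing a manifest that
makes completed stages resumable.

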