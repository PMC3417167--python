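# socmap

Annotation-driven mapping of social perception networks in naturalistic fMRI.

Subjects watch a continuous stream of short movie clips while whole-brain BOLD
is acquired (TR 2.112 s). Independent raters continuously score how prominently
each of 14 stimulus features — 8 social (faces, human bodies, biological
motion, goal-oriented action, emotion, social interaction, pain, speech) and 6
non-social fillers (places, objects, rigid motion, people not interacting,
non-goal-oriented action, non-human sounds) — is present, on a 1–5 scale at
5 Hz. `socmap` turns those rating tracks into GLM regressors and runs the full
analysis chain:

1. **Ratings → regressors.** Average the two raters per clip, concatenate
   clips in presentation order, down-sample to the TR grid by within-TR
   averaging, optionally convolve with the canonical double-gamma HRF.
2. **First level.** Mass-univariate GLM per voxel with a discrete-cosine
   high-pass drift basis (cutoff 128 s) and exact AR(1) prewhitening
   (y*₁ = √(1−ρ²)·y₁, y*ₜ = yₜ − ρ·yₜ₋₁), which equals generalized least
   squares under Σᵢⱼ ∝ ρ^|i−j|. Features are fitted one-per-GLM (default) or
   jointly; regressors can be mutually orthogonalized first (each feature
   residualized against the other 13, with a weight ledger).
3. **Second level.** Voxelwise one-sample t across subjects (df = n−1),
   Benjamini–Hochberg FDR over all in-mask voxels (q = 0.05), and cumulative
   **overlap maps** counting, per voxel, how many of the 8 social features are
   significantly activated (t > 0).
4. **ROIs and connectivity.** Spherical ROIs in MNI mm (3 mm for beta
   summaries with t-based 95% CIs, 6 mm for time series); per-subject ROI
   correlation matrices averaged through the Fisher z-transform
   (tanh(mean(atanh r))); edges thresholded at the maximum |group mean r| of
   a circular-shift permutation null (each permutation shifts a random seed
   ROI per subject by ≥ 10 samples, preserving autocorrelation).
5. **Communities.** Two-level map equation
   L = q·H(Q) + Σₘ pₘ·H(Pₘ) on the weighted undirected graph (visit rates ∝
   node strength), minimized by a greedy local-move + agglomeration search
   from 100 random restarts; the lowest description length wins and the modal
   fraction of restarts is reported.

Because no real recordings ship with the package, `socmap.synth` generates the
whole study with known ground truth — 137 clips (16.6 ± 2.7 s), two noisy
raters calibrated to inter-rater r ≈ 0.78 and between-feature |r| ≈ 0.18, and
19-subject BOLD cohorts (770 volumes, first two discarded) with AR(1) noise
(ρ = 0.4) and planted regions, including a "hub" responsive to all 8 social
features — so every stage is verified by recovering what was planted.

## Worked example

```bash
python analysis/01_simulate_ratings.py   --seed 1
python analysis/02_build_regressors.py   --seed 1
python analysis/03_first_level_and_overlap.py --seed 1
python analysis/04_roi_beta_summary.py
python analysis/05_connectivity_communities.py
python analysis/06_orthogonalization_report.py
```

With seed 1 this prints (abridged):

```
mean inter-rater r = 0.781 (target ~0.78)
mean between-feature |r| = 0.178 (target ~0.18)
pooled AR(1) estimate: 0.400 (planted 0.4)
original: hub overlap 8/8; specialized {'fronto_parietal': 5,
  'temporo_amygdalar': 3, 'fronto_insular': 6, 'fronto_temporal': 3}
orthogonalized: hub overlap 8/8; specialized {'fronto_parietal': 4,
  'temporo_amygdalar': 3, 'fronto_insular': 4, 'fronto_temporal': 3}
hub: all social betas positive: True; all filler betas non-positive: True
permutation threshold |r| = 0.051 (10000 permutations)
spatial t-map correlation range: [0.55, 0.90]; mean 0.75
```

Reading: the rating generator hits its calibration targets; the prewhitening
recovers the planted noise model; only the planted hub reaches overlap 8
(significant activation for all eight social features) in both the original
and the orthogonalized analysis, while the specialized regions stay below 8;
the hub's beta profile is social-selective; and orthogonalization leaves the
t-maps of weakly shared features nearly unchanged while reshaping the
redundant ones.

The same stages are exposed as a CLI (`socmap simulate|ratings|run-all`, with
`--config`, `--seed`, `--out-dir`, `--log-level`) and, of course, as the
library functions under `socmap.*` that the scripts are thin wrappers around.

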