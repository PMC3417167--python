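# Methods

## The model

Each voxel's BOLD series y (T = 768 retained volumes at TR 2.112 s) is modeled
as

    y = X β + D γ + ε,     ε ~ AR(1)(ρ) Gaussian noise,

where X holds one regressor per rated stimulus feature (the rater-averaged,
presentation-ordered, TR-resampled prominence track, optionally convolved
with the canonical double-gamma HRF) and D is an orthonormal discrete-cosine
drift basis with periods above the 128 s cutoff (K = ⌊2·T·TR/cutoff⌋ = 25
columns at full scale) plus an intercept.

A single pooled ρ per subject is estimated from the lag-1 autocorrelation of
OLS residuals over in-mask voxels. Projecting out the ~40 design columns
(the drift columns in particular, which carry exactly the high-autocorrelation
content) biases that raw statistic downward — measurably, 0.33 for a true
0.40 at full scale — so the pipeline inverts the analytically expected
residual autocorrelation E[r₁ | ρ] for the actual residual-forming matrix
(an O(T·k²) computation per grid point, done once per design) before
whitening. Data and design are then exactly whitened (first-sample scaling
included) and fitted by OLS; the tests verify bit-level agreement with dense
GLS under Σᵢⱼ = ρ^|i−j| up to T = 50 and beta bias < 2% with 95% CI coverage
95% ± 2% at full study scale.

Two first-level strategies are provided. `per_feature` (default) fits each
feature in its own GLM alongside the nuisance columns, via Frisch–Waugh–Lovell
residualization so the (expensive) nuisance projection of the data is shared
across the 14 fits. `combined` fits all 14 jointly. The per-feature strategy
is what overlap maps and beta summaries use; the combined strategy is the
correctly specified model when several effects coexist, and is what the
parameter-recovery calibration uses — per-feature betas are *by construction*
contaminated by whatever the other features explain, which is the scientific
point of comparing the two.

Mutual orthogonalization residualizes each feature simultaneously against the
other 13 originals plus an intercept (not sequentially: a Gram–Schmidt chain
would depend on feature order, which a single per-feature weight vector
cannot express). The ledger stores the least-squares weights and the R² of
each fit; re-orthogonalization is a no-op, and the weights plus residual
reconstruct each original regressor exactly. Orthogonalization happens on
rating time courses before HRF convolution; convolution then slightly bends
exact orthogonality (a smoothing operator does not commute with projections),
which is visible but harmless at the default SNR.

Second-level inference is a voxelwise one-sample t against zero (two-sided
p, df = n−1; zero-variance voxels are conservatively non-significant),
Benjamini–Hochberg FDR over all in-mask voxels (independence variant,
p* = max{p₍ₖ₎ ≤ k·q/m}), and positive-effect masking (t > 0) before overlap
counting — overlap maps count activation, not deviation. No correction across
the 14 features is applied by default.

ROIs are closed balls in world (MNI mm) coordinates; a voxel belongs if its
center does (no partial-volume weighting — 19 voxels for 3 mm and 123 for
6 mm on a 2 mm grid). Beta summaries use t-based 95% CIs across subjects.

Connectivity: per-subject Pearson matrices of 6-mm-sphere mean series are
averaged entrywise through atanh → mean → tanh. The edge threshold is the
maximum |group mean r| in a circular-shift permutation null: per permutation,
every subject independently gets a uniformly chosen seed ROI and a uniform
shift k ∈ [10, T−10]; the seed-to-target correlations are Fisher-z averaged
over subjects (a subject is excluded for the target that is its own seed) and
the max is taken over targets and permutations. Shifting preserves each
series' marginal distribution and autocorrelation while destroying
cross-correlation, so every null exceedance is a false positive and the max
statistic gives a p < 1/n_perm threshold. The implementation evaluates all
shifts at once via FFT circular cross-correlation (verified against a literal
shift-and-correlate loop) — one million permutations on 14 ROIs take seconds.
A per-subject-pooled null variant is available behind a flag; it is strictly
more conservative than the group-mean default, which matches the statistic
actually thresholded.

Communities minimize the two-level map equation on the undirected weighted
graph (edge weight |mean r|, visit rates ∝ node strength, no teleportation):

    L = q·H(Q) + Σₘ p⟳ₘ·H(Pₘ),

with q the total module-exit flow and p⟳ₘ the module codebook rate. The
search is greedy: sweeps of single-node moves to neighboring modules until no
move lowers L, then exhaustive pairwise module merges, repeated to a fixed
point; 100 restarts with randomized sweep orders, lowest L wins (ties broken
by the lexicographically smallest canonical labeling), and the modal fraction
of restarts returning the winner is reported. Recovery is cross-checked
against an independent Infomap implementation on planted graphs.

## The synthetic study

The generator reproduces the study conditions so recovery is meaningful:

- **Ratings.** 137 clips, durations 16.6 ± 2.7 s (clipped to the observed
  10.3–27.3 s range), 14 features, 5 Hz, two raters. Latent prominence
  tracks are correlated Gaussian processes (squared-exponential kernel,
  length-scale 2 s — raters dragged a cursor, so tracks are smooth) mapped
  through 3 + 2·tanh(0.8·z) into (1, 5). Rater noise (a smooth GP, sd 0.5 in
  latent units) is added before squashing; the defaults land at inter-rater
  r ≈ 0.78 and mean between-feature |r| ≈ 0.18. The correlation structure
  puts social features near mutual independence (the stimulus set was built
  to separate them), fillers in a correlated block (0.45; objects–rigid
  motion 0.55) and social×filler mildly negative (−0.25): clips dominated by
  social content dwell less on scenery. This structure is also what makes
  hub recovery well-posed: strongly correlated social features would make
  per-feature maps indistinguishable at any sample size.
- **Session.** 137 × 16.6 s of rated material more than covers the 770-volume
  acquisition; regressors are truncated to the 768 retained volumes, so both
  design numbers hold simultaneously.
- **Geometry.** Desk scale: 24³ voxels at 4 mm, an ellipsoidal brain mask
  (~6400 voxels), seven 27-voxel cubic regions: one hub (all 8 social betas
  +1, all 6 filler betas −0.3), four specialized social regions (proper
  subsets of 3–4 social features), two filler-responsive regions.
- **BOLD.** Voxel series = Σ_f β_f·regressor_f + AR(1) noise (ρ = 0.4,
  marginal sd 3), spatially smoothed (FWHM 6 mm, variance-renormalized,
  wrap-around boundary) to mimic preprocessing; per-subject betas jittered
  N(0, 0.2²) around truth where truth is non-zero (random-effects structure);
  regions in the same functional network additionally share a latent AR(1)
  series (sd 2) — intrinsic fluctuations, without which ROI connectivity
  would be purely stimulus-driven. Noise is generated in float32 (signal and
  noise are unit-scale; fitting is float64 throughout).
- **Effect size.** sd 3 noise against regressors of sd ≈ 0.55 puts
  single-subject, single-feature t around 3–4 — the realistic voxel-level
  regime. The choice is load-bearing: per-feature GLM cross-talk through
  empirical regressor correlations (amplified by HRF convolution) is a bias
  *shared across subjects*, so its second-level t grows with √n unless
  per-subject first-level noise dilutes it. At realistic SNR true hub effects
  reach second-level t ≈ 12 while cross-talk stays safely below the FDR
  threshold; at implausibly high SNR no between-subject variance setting
  separates them, for any analysis of this family.

What the generator does **not** emulate: motion and physiological artifacts,
scanner drift beyond what the DCT basis absorbs, field inhomogeneity,
anatomical variability, non-AR(1) long-memory noise, or rater idiosyncrasies
beyond smooth additive noise. Passing recovery tests therefore demonstrates
the correctness and calibration of the estimators under their stated
assumptions, not robustness to real-data pathology.

## Numerical choices and edge cases

- Orthogonality assertions at 1e-8 relative to column norms; community-move
  acceptance at ΔL < 1e-12.
- Down-sampling drops the partial final TR window (the acquisition grid is
  authoritative); window membership by rating-sample center time.
- Zero-variance voxels at second level: t = 0, p = 1, never significant.
- BH threshold p* = 0 (nothing passes) is distinguished from p* = p₍₁₎.
- Fisher averaging refuses |r| = 1 off-diagonal (saturated atanh).
- Edge weights are |mean r|; the map equation requires non-negative flow.
- Degenerate graphs: no edges → every node its own module at L = 0;
  modules with zero exit flow contribute no index-codebook bits (0·log 0 = 0).
- The permutation null draws seed-ROI and shift streams from separate child
  generators, so the null for n permutations is a prefix of the null for any
  larger n at the same seed, making the threshold monotone in n.

## Problem sizes in the tests and the acceptance script

Full study scale (137 clips, 768 volumes, 19 subjects, 24³ grid) is used for
the hub-recovery criterion (20 seeded cohorts, both regressor modes), the
beta bias/coverage calibration (one 19-subject cohort, combined GLM,
between-subject jitter off so first-level CIs target the planted values), and
the permutation-null calibration (100 replicate white-noise experiments at
10⁴ permutations each; the 10⁶-permutation default remains available and
cheap via the FFT path). Unit and plumbing tests use an 8-subject cohort and
smaller grids. These sizes are the package's chosen verification scale; every
run derives from an explicit seed.

## Known limitations

- One pooled AR(1) per subject (no voxelwise or higher-order noise models).
- Two-level (not hierarchical) map equation; greedy search is exact only in
  the sense of the restart protocol — on dense near-uniform graphs the
  description-length optimum is genuinely the single-module partition, which
  is what the desk-scale connectivity stage returns (community *recovery* is
  verified on planted sparse graphs, where the optimum is the planted one;
  at ~7% rate a 0.9/0.05 realization destroys a small module's only evidence
  and no detector can recover it).
- Per-feature GLM betas are deliberately model-misspecified under coexisting
  effects; quantitative recovery claims use the combined model.
- No cluster-extent or permutation-based voxel inference; FDR only.
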