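# Methods

## Overview

`ecmap` analyses how the hub structure of brain functional networks differs
between psychological states (rest versus a working-memory task) and across
development. The chain is:

1. **Eigenvector centrality mapping (ECM).** Each fMRI run is turned into a
   weighted graph on in-mask voxels with edge weights `|r_ij|`, the absolute
   Pearson correlation of voxel time series — positive and negative
   correlations count equally. Voxel centrality is the Perron (leading)
   eigenvector of this nonnegative matrix: a voxel is central when it is
   strongly connected to other central voxels.
2. **Spatial ICA of the EC maps.** All runs' EC maps are stacked into a
   runs-by-voxels matrix and decomposed into K spatially independent
   component maps with one mixing weight per run ("subject weights").
3. **Dual regression on the task runs** extracts per-component time series,
   which are fit with a block-design GLM; task engagement is summarized by
   `(β_1back + β_2back)/2 − β_0back`.
4. **Group statistics.** Per component: a paired t test on task-minus-rest
   weights, age regressions (adjusting for sex), a task-by-age interaction,
   behavioral associations (hit rate, false alarms, d-prime), activation
   tests, and the across-component correlation between centrality change
   and activation; all with Benjamini–Hochberg FDR. Voxel-wise: the same
   contrasts with threshold-free cluster enhancement (TFCE) and
   permutation-based family-wise error control.

Because the motivating cohort is access-restricted, a synthetic-cohort
generator defines the test bed. It is first-class, tested code whose
ground truth drives all recovery checks.

## Eigenvector centrality

* **Preprocessing.** In-mask series are linearly detrended, high-pass
  filtered at 0.01 Hz (second-order zero-phase Butterworth; skipped with a
  warning if the cutoff reaches Nyquist), and standardized to zero mean and
  unit *sample* variance (denominator T−1), so `r_ij = x_i·x_j/(T−1)`.
  Zero-variance voxels are flagged, removed from the working index, and
  assigned centrality 0.
* **Matrix-free solver.** The V×V |correlation| matrix is never formed;
  matrix–vector products run in row blocks (`block_rows` at a time), so
  peak memory is O(block_rows × V). Power iteration starts from the uniform
  positive vector and stops when the relative L2 change falls below the
  tolerance (default 1e-6; the validation battery uses 1e-12 when it
  compares against dense eigendecompositions). The eigenvalue is the
  Rayleigh quotient.
* **Diagonal.** The unit diagonal of |corr| is kept by default. It shifts
  every eigenvalue by one and leaves eigenvectors unchanged; the
  equivalence is asserted to 1e-9 in the tests.
* **Normalization.** EC maps are unit Euclidean norm. Nonnegativity and
  unit norm are invariants (Perron–Frobenius).
* **Degenerate graphs.** If any voxel has exactly zero |correlation| to
  every other voxel the graph is reducible and the leading eigenvector is
  not unique; the solver raises a diagnostic error rather than silently
  picking a component. With continuous data this almost surely never
  happens.

## Decomposition

* **Stacking normalization.** Rows (runs) enter as unit-norm EC maps;
  columns (voxels) are demeaned across runs. Row z-scoring is available
  (`row_zscore=True`) but off by default: an EC map's spatial dispersion
  rises with hub cross-network coupling (measured r ≈ 0.6–0.75 against the
  planted coupling in synthetic cohorts), so dividing each row by its own
  SD cancels much of the between-run signal the subject weights must carry.
  This choice was made after measuring that effect; it is the main place
  where group-ICA dialects genuinely differ.
* **ICA.** PCA whitening to K dimensions followed by fixed-point ICA
  (logcosh contrast), voxels as samples. Tolerance 1e-4 with up to 1000
  iterations and three seeded restarts before raising — tighter tolerances
  routinely fail to converge on realistic stacked EC maps. Deterministic
  given the seed.
* **Canonicalization.** Components are sign-flipped to positive spatial
  skewness (ties: the largest-|value| voxel is made positive) and ordered
  by descending contribution `‖w_k‖²‖s_k‖²`. Idempotent; the
  reconstruction is unchanged. All downstream t statistics are invariant to
  the ICA scale ambiguity (asserted by test).
* **Artifact exclusion.** In the original setting artifact components are
  recognized anatomically (white matter / CSF); the synthetic stand-in
  retains a component iff its best absolute spatial correlation against
  the planted signal references exceeds its best against the planted
  artifact references. With no references everything is retained with a
  warning.
* **Clustering.** Retained components are clustered on the Pearson
  correlation of their weight columns across all runs (distance 1−r,
  average linkage), with a configurable flat cut.
* **K.** Default 40 for real-scale cohorts; synthetic validation uses
  planted k + artifacts + 2 — slight over-extraction absorbs noise and
  stabilizes the hub component across seeds.

## Task GLM

* **HRF.** Canonical double-gamma: response gamma shape 6, undershoot
  shape 16, undershoot ratio 1/6, unit peak, 32 s support. Regressors are
  rasterized at 10× the TR, convolved, and sampled at the TR.
* **Design.** Nine 30 s blocks alternating 0/1/2-back, each preceded by a
  10 s instruction period (120 volumes at TR 3 s); 20 trials per block of
  which 5 are targets, giving 45 targets and 135 non-targets per run.
  Timing is configurable; the counts are fixed paradigm properties.
  Empty regressors are dropped with a warning.
* **Dual regression, stage 1.** Each volume and each retained map is
  spatially demeaned, then all maps are regressed on the volume jointly.
  Demeaning makes the series invariant to global offsets; rank-deficient
  map sets raise an error naming near-duplicate pairs.
* **Stage 2.** OLS without prewhitening — a documented simplification; the
  emulated noise is white, and group inference uses only the per-subject
  contrast. Instructions/responses stay in the model as nuisance columns
  and out of the contrast.
* **Behavior.** Hit and false-alarm rates are clamped to
  [1/(2n), 1−1/(2n)] before the z-transform, so perfect scores give finite
  d-prime = z(hit) − z(FA).

## Group statistics

Component families: `task_effect` (paired one-sample t), `age_task`,
`age_rest` (OLS with sex), `interaction` (age effect on the difference
score), `perf_hit`/`perf_fp`/`perf_dprime` (difference score on the
behavioral score, adjusting for age and sex), `activation_task`
(one-sample t on contrasts), `activation_age`. FDR is applied per family
by default (matching a per-column reading of the component tables);
a single global family is selectable. The centrality–activation
correlation uses the two families' group t statistics, which are invariant
to component scaling; group means are selectable.

## Voxel-wise inference

* **TFCE.** Per voxel, the integral of `e(h)^E · h^H` over thresholds h,
  with E = 0.5, H = 2, 100 steps, 6-connectivity by default (18/26
  selectable). The integral uses midpoint quadrature, whose O(n⁻²) bias
  keeps the uniform-cluster closed form `e^E h^{H+1}/(H+1)` within a
  fraction of a percent at 100 steps. Negative statistics are enhanced by
  applying TFCE to the negated map.
* **Permutations.** One-sample tests permute by random sign flips;
  regressions use Freedman–Lane (fit the nuisance-only model, permute its
  residuals, refit the full model). Each permutation records the maximum
  TFCE over both signs and all voxels; corrected p-values are
  `(1 + #{max ≥ observed})/(n_perm + 1)`, so the smallest attainable p is
  `1/(n_perm+1)` and p never reports 0. Default 500 permutations,
  configurable up to 5000.

## Synthetic cohort

Each subject contributes a rest run (124 volumes) and a task run
(120 volumes) at TR 3 s on a common grid with an ellipsoidal mask. Voxel
signals are `Σ_k map_k(v)·s_k(t)` plus i.i.d. Gaussian noise (SD 0.5,
emulating spatially smoothed data); the network courses `s_k` are Gaussian
with a planted correlation structure:

* **Networks.** k unit-peak Gaussian blobs (σ = 1.7 voxels) placed with
  minimum separation and pairwise map correlation < 0.5, plus artifact
  sources with independent courses. Roles: network 0 is the hub, network 1
  sensory-like, the rest filler; artifacts last.
* **Coupling.** Signal networks share a baseline correlation of 0.15. The
  hub's cross-network coupling is the subject latent: at rest
  `0.2 + 0.03·(age − 15) + ε`, ε ~ N(0, 0.03²); under task it gains
  `0.25 + η`, η ~ N(0, 0.3²). The sensory network's coupling to everything
  (including the hub) drops to 0.15 − 0.25 = −0.1 under task — suppression
  takes precedence on the hub–sensory pair. Matrices are projected to the
  nearest PSD correlation when needed.
* **Individual differences.** Each subject scales each network's course by
  a stable strength factor ~ N(1, 0.15²) (clipped at 0.3). These latents
  are what make the group decomposition identifiable — without them
  fixed-point ICA oscillates on EC-map stacks — and they cancel in the
  task-minus-rest difference scores.
* **Activation.** Task runs add an HRF-convolved block regressor with load
  weights 0.5/1.0/1.25 for 0/1/2-back, scaled by +0.05 for the hub, −0.05
  for the sensory network, ±0.02 for filler networks. The amplitude is
  deliberately modest: task-evoked coactivation enters the |correlation|
  graph as connectivity, and larger amplitudes overwhelm the planted
  coupling changes (at amplitude 0.25 the sensory centrality decrease
  inverts).
* **Behavior.** `logit(p_hit) = 0.5 + 0.05·(age − 15) + 6·(c_task − mean)`;
  hits ~ Binomial(45), false alarms ~ Binomial(135) with a decreasing
  logit at half strength. Because behavior loads on the task-state
  coupling, d-prime tracks the subject's task modulation η and hence the
  task-rest centrality difference.
* **Determinism.** Every run, behavior draw, and demographic draw derives
  from the cohort seed via independent named substreams; regeneration is
  bit-identical, and `GroundTruth` stores the atlas, per-subject couplings,
  amplitudes, and effect signs for recovery tests.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes — two
conditions, network-mixture signals, condition/age/behavior-dependent
coupling, artifact sources — but not head motion, scanner drift,
physiological noise, anatomy, or registration error (the denoising and
normalization chain that would handle them is out of scope). Passing
recovery tests therefore demonstrates the correctness and calibration of
the pipeline, not robustness to real-world confounds.

## Problem sizes in the validation battery

Recovery and calibration runs are sized for a single desktop CPU: the
planted-pattern cohorts use n = 40 subjects on a 14×14×9 grid (~900
in-mask voxels, 5 + 2 networks, K = 9, 20 replicates); FWE calibration
uses 100 replicates of 500 permutations on an 8×8×5 grid with 32 TFCE
steps (the closed-form check runs at the default 100 steps); the
determinism check runs a 6-subject pipeline twice. The reproduction
script reports each measured value together with the size it used.

## Known limitations

* OLS GLM without autocorrelation modeling; adequate for white synthetic
  noise, anticonservative for real fMRI.
* Artifact classification requires reference maps; it is a synthetic
  stand-in for anatomical exclusion.
* The EC response to coupling saturates at high coupling (unit-norm
  renormalization), so planted effect sizes are specified on the coupling
  scale, not the EC scale.
* Permutation p-values are exchangeability-based; no variance smoothing or
  exchangeability blocks.
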