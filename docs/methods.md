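# Methods

## Problem setting

Paired mRNA/miRNA expression studies give, for each sample, a predictor
vector (mRNA, typically 10⁴–10⁵ features) and a response vector (miRNA,
10²–10³ features), with samples labeled control or diseased and group sizes
of 3–10. The package fits mappings from mRNA to miRNA profiles and evaluates
them two ways: *within-data* (train and evaluate on the same samples — an
optimistic upper bound) and *cross-study* (train on study A, predict study
B's miRNA from its mRNA).

## Preprocessing

All stages operate on features × samples matrices with a declared scale.

* **voom-style log-CPM** (counts only): `log2((c + 0.5)/(libsize + 1)·1e6)`.
  Precision weights are not computed — downstream models are unweighted, so
  only the variance-stabilizing transform is of use.
* **Quantile normalization**: each column's values are replaced by the
  across-sample means of the column-sorted values at their rank positions;
  ties receive the mean of the reference values their rank range spans.
  Idempotent by construction.
* **[0, 1] compression**: a single global (min, max) per matrix maps every
  entry to `(v − min)/(max − min)`. Global rather than per-feature scaling
  is the default because per-feature scaling destroys relative expression
  levels and amplifies low-variance noise; a per-feature mode exists
  (`fit_compression(..., per_feature=True)`). In cross-study mode the
  *training* parameters are re-used on the test matrices and out-of-range
  values are clipped (counted and logged): the model was trained on that
  scale.
* **Low-expression filter** (optional, off by default): drops the
  `floor(f·n)` features with the lowest mean expression (default f = 0.2
  when enabled); ties at the cut are broken by input order. Off by default
  because its benefit is dataset-specific.

## Data augmentation

Training cohorts are grown by appending whole-cohort copies with i.i.d.
Gaussian noise, sd 0.01 **on the compressed scale** (a fixed sd is only
meaningful on a bounded common scale), until each condition group has at
least 100 samples; the originals are kept (discarding real samples from a
10-sample study is indefensible). Paired mRNA/miRNA copies get independent
noise but share the new sample ID and the group label. The per-group reading
of the 100-sample target matches the need of condition-specific models to
see ≥100 samples each; a cohort-total mode exists (`per_group=False`).
Values pushed outside [0, 1] by noise are left unclipped to preserve the
noise distribution.

## Neural network

Architecture and training exactly as in the README (1024/512/256/128, batch
norm after each dense layer and before ReLU, dropout 0.4, L2 on every dense
kernel, Adam lr 0.001, MSE/MAE, ≤150 epochs, batch 32, 20% validation
split, ReduceLROnPlateau factor 0.5). Choices the architecture description
leaves open, fixed here:

* **L2 coefficient** 1e-4 (config-exposed); **plateau patience** 5 epochs on
  validation loss, minimum lr 1e-6. No early stopping — only the epoch cap.
* **Initialization**: He-normal for ReLU layers, Glorot-uniform for the
  linear output. All randomness (init, shuffling, dropout) flows from one
  seed; on a single thread, training is bit-reproducible.
* **Batch-norm calibration**: running means/variances are maintained with
  momentum 0.99 during training, but with small data (≈450 optimizer steps)
  the exponentially smoothed estimates lag the statistics the weights were
  actually trained against, which degrades inference-mode predictions.
  Training therefore ends with one deterministic pass that sets the running
  statistics to the exact activation moments of the full training data.
  Inference uses these fixed statistics and no dropout, so prediction is
  deterministic and per-sample independent.
* float32 arithmetic throughout the network: the default architecture
  trains on one CPU in ~10–25 s per model at the simulator's default size.

Training requires at least 5 samples (so the 20% validation split is
non-empty); smaller cohorts should be augmented first.

## Per-miRNA LASSO

One L1-penalized linear model per miRNA, full mRNA matrix as predictors.
Internally predictors are standardized (mean 0, sd 1, 1/n convention) and
the response centered; the objective `(1/2n)‖y − β₀ − Xβ‖² + λ‖β‖₁` is
minimized by cyclic coordinate descent with soft-thresholding, warm starts
along the path, and active-set iteration after each full sweep; convergence
when the largest coefficient change in a sweep is < 1e-7. Coefficients are
returned de-standardized. The λ path is 100 log-equispaced values from
`λ_max = max_j |⟨x_j, y⟩|/n` down to `0.01·λ_max`; at `λ_max` the solution
is exactly zero by the KKT conditions. λ is never tuned by cross-validation;
the two reported operating points are the path minimum ("minimal") and the
10th-largest value (path index 9, 0-based). Constant miRNA responses are
recorded as skipped and predicted by their training mean. The inner loop is
JIT-compiled (numba); correctness is established in the test suite against
closed forms (orthonormal designs), KKT residuals, and an independent convex
solver on the same objective.

## Differential expression

Two-group empirical-Bayes moderated t-test, raw p-values only (no
multiplicity adjustment anywhere — downstream metrics correlate the p-value
vectors, which any monotone adjustment would only rescale). Per feature:
logFC = mean(diseased) − mean(control); pooled residual variance s² with
d = n₁+n₂−2 df; prior (d0, s0²) by method of moments on
`e = log s² − ψ(d/2) + log(d/2)`: d0 solves
`ψ′(d0/2) = var(e) − ψ′(d/2)` (Newton on the monotone trigamma equation),
with d0 = ∞ — i.e. all posterior variances equal s0² and the reference
distribution becomes normal — when the observed log-variances scatter no
more than sampling alone explains; posterior variance
`s̃² = (d0·s0² + d·s²)/(d0 + d)`; t = logFC/(s̃·√(1/n₁+1/n₂)); two-sided p
with d + d0 df. Setting `d0_override=0` recovers the ordinary pooled t
exactly (tested to 1e-9). Zero-variance features are excluded from the
prior fit but still receive a moderated statistic.

DEA runs on the compressed [0, 1] scale for both true and predicted data, so
"log2FC" here is a group-mean difference of linearly rescaled
log-intensities. All reported correlations are invariant to that common
linear rescaling, which is why the scale is fixed rather than
back-transformed (predictions only exist on the compressed scale).

## Concordance metrics

Pearson r of (i) each sample's predicted vs. true profile across miRNAs,
(ii) the two logFC vectors, (iii) the two raw p-value vectors (a −log10
option exists behind a flag). Constant columns yield a missing per-sample r;
non-finite feature pairs are dropped pairwise. Correlations require ≥3
non-constant observations.

## Pipelines

`run_within`: filter? → compress (own params) → augment? → train → predict
the **original** (non-augmented) samples → DEA pair → report. With separate
condition handling, one model per condition is trained and each sample is
predicted by its condition's model before the predictions are re-assembled
in original sample order. `run_cross_study`: case-insensitive feature-ID
intersection of both omics layers (no probe→gene mapping — cross-platform
translation is out of scope), training compression re-used on the test side,
prediction and evaluation on the test study. `compare_settings`: the 2×2
grid augmentation × condition handling, with Δr(logFC) against the
no-augmentation/joint baseline.

LASSO models are fitted per condition by default (a joint fit needs an
explicit `allow_lasso_joint=True`).

## Synthetic data

The simulator draws a linear-Gaussian world on a log-intensity scale:
miRNA g has baseline μ_g ~ U(4, 12); a fraction (default 0.2) of miRNAs
shift by δ (default 1.0, random sign) in the diseased group; measurement
noise sd 0.2. Each miRNA represses a random set of 20 target mRNAs (overlap
allowed): mRNA m has baseline b_m ~ U(4, 12) minus β (default 0.4) times the
sum of the *centered* expression of the miRNAs targeting it, plus noise sd
0.3. Centering keeps mRNA baselines unshifted by repression. Group sizes
default to 5+5, the common design of small paired infection studies; the
baseline range and noise levels give compressed-scale DE effects (~0.1)
about 5× the group-mean noise, i.e. clearly detectable but not trivial.

`SimConfig.seed` drives the *structure* (baselines, target map, DE set,
signs); `simulate_paired_dataset(cfg, sample_seed=…)` redraws only the
samples. Two calls with the same config and different sample seeds are the
package's model of two independent studies of the same disease — shared
biology, independent cohorts — which is what cross-study evaluation needs.
With the default `sample_seed = cfg.seed`, the same seed yields bit-identical
data.

What the simulator does **not** emulate: count noise (negative binomial),
batch effects, platform differences between studies, nonlinear regulation,
and correlated (network-structured) mRNA co-expression beyond shared miRNA
targets. A green recovery test therefore establishes that the estimation
machinery recovers a recoverable signal — not that real cross-platform
transfer works; the cross-study numbers on real data in the literature are
far lower than on this linear world.

### A note on the cross-study dissociation check

The test suite verifies that when the *test* study's repression strength is
set to 0 (mRNA carries no miRNA information), sample-level correlations stay
high — they are driven by the shared miRNA baselines — while logFC
concordance collapses. This dissociation is only observable with a **joint**
model: with condition-specific models, the test sample sheet selects the
model at prediction time, and each condition model's intercept encodes its
training group's mean, so the group difference leaks into the predictions
through the labels regardless of whether the mapping works. The dissociation
check therefore uses joint LASSO.

## Numerical details and limitations

* Quantile-normalization ties: averaged reference quantiles (deterministic).
* Filter tie-break: earlier input feature removed first (stable sort).
* LASSO: coefficients with |β| < 1e-10 after convergence are snapped to 0
  (float-epsilon activations at λ_max).
* Top-5% weight set: `ceil(0.05·n)` features, stable tie-break by input
  order; mean *absolute* first-layer weights by default (signed means cancel
  and would rank noise; a signed mode exists).
* Duplicate feature IDs on load are collapsed by mean; rows with non-finite
  values are dropped, never imputed.
* The MLP's multi-threaded BLAS can introduce run-to-run float noise on some
  platforms; tests pin single-process determinism via seeds and tolerate
  1e-6 on final losses.
* Within-data evaluation is an optimistic bound by design; it is reported as
  such and never interpreted as generalization.
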