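# Methods

## The problem

A two-class expression study delivers a `p × n` matrix `X` (rows = biological
samples, columns = genes, `p ~ 50–200`, `n ~ 10³–10⁴`) with labels
`y ∈ {+1 (cancer), −1 (control)}`. Classifiers applied directly to gene space
struggle because only a small fraction of genes carries class signal, samples
share strong global structure (baseline expression, array effects), and the
measurements are noisy. Transform-based reductions such as PCA or classic ICA
build every component as a combination of *all* genes and therefore favor
exactly that shared global structure — the part that does not separate the
classes.

## The multi-resolution ICA transform

The transform treats each sample as a 1-D signal along the gene axis and
chains four stages:

1. **Multilevel DWT.** An `L`-level discrete wavelet transform of every
   sample (default wavelet `db8`, default `L = 12`, symmetric boundary
   extension) yields detail coefficient matrices `D_1 … D_L` (level 1 = the
   first decomposition step = the highest-frequency band) and an
   approximation matrix. The requested depth is capped at the maximum the
   signal length supports (`⌊log2(n / (filter_len − 1))⌋`), with a logged
   warning, so the `L = 12` default is usable at any `n`. Any orthogonal
   wavelet is accepted; biorthogonal families need an explicit override
   because they break the energy partition.

2. **Rank-1 suppression of fine bands.** For levels `j ≤ τ` (default
   `τ = 3`), `D_j` is replaced by its rank-1 PCA reconstruction: columns
   (coefficients) are centered by their means `μ`, the centered matrix is
   projected on its first principal direction `u₁`, and the means are
   re-added: `D_j ← (D_j − 1μᵀ)u₁u₁ᵀ + 1μᵀ`. Samples are the observations
   of the PCA; the first component keeps only the structure *shared across
   samples* in that band, deleting per-sample high-frequency variation —
   which for white noise is most of the noise energy (levels 1–3 carry 87.5%
   of it). Bands above `τ` and the approximation matrix are kept verbatim
   (reconstruction at 100% explained variance is the identity, so the "keep
   everything" rule is exact, not approximate). Degenerate bands (a single
   sample, or zero variance) pass through unchanged. The operation is an
   orthogonal projection per band, hence idempotent.

3. **Inverse DWT.** Inverting the updated coefficients gives the
   *meta-profile* `X*`, a denoised approximation of `X` with the same shape.
   With `τ = 0` the pipeline is the identity to machine precision.

4. **ICA.** The mean row (`offset`, the average meta-profile) is removed;
   the residual is whitened by SVD to `k` dimensions (`k = "auto"` means
   `p − 1`, the rank after centering, further capped by the numerical rank);
   a FastICA fixed point (logcosh contrast, symmetric decorrelation,
   tolerance `1e−4`, 400 iterations, seed-controlled initialization)
   supplies the rotation to maximally independent components. The result is

       X* = offset + A Z,

   `Z (k × n)` the independent components ("eigen-genes"), `A (p × k)` the
   mixing matrix. Row `i` of `A` is the **meta-sample** of biological sample
   `i`. At `k = rank` the factorization reproduces `X*` exactly (relative
   Frobenius error at machine precision), which the tests assert at `1e−6`.

### Scale and canonicalization conventions

ICA determines `(A, Z)` only up to per-component scale, sign, and order. The
package fixes:

- **Scale.** Mixing-matrix columns have unit Euclidean norm; each
  component's energy is carried on its row of `Z`. Under the textbook
  convention (unit-variance sources) `Z` is exactly white and its condition
  number is identically 1, which would make the threshold-selection rule
  below vacuous; putting the energy on `Z` makes `δ` measure the spread of
  component energies. **Classifiers**, however, consume the
  classic-convention coordinates `A·diag(‖Z_i‖)` (the mixing matrix of
  unit-variance sources): under the unit-column convention a weak noise
  component spans the same numeric range as the dominant structure and
  distorts the SVM's margin geometry — in development this cost several
  accuracy points on otherwise perfectly separable splits.
- **Sign.** Each row of `Z` has its largest-magnitude entry positive (the
  paired column of `A` flips with it).
- **Order.** Components are sorted by decreasing energy
  `‖A col‖·‖Z row‖`, stably.

With these conventions the whole fit is a pure function of (data,
parameters, seed) and serialized models are byte-stable. Predictions are
invariant to signed permutations of the components — the transformations ICA
is genuinely identifiable up to; they are *not* invariant to arbitrary joint
rotations of `(A, Z)`, because the energy scale is not rotation-equivariant.

### Convergence policy

The symmetric FastICA iteration has no fixed point on directions that are
essentially Gaussian, and on small training halves (`p ≈ 12–30`) it can
oscillate indefinitely. The fit therefore attempts up to 5 deterministic
re-initializations (seeds derived from the user seed by a fixed odd stride);
if none meets the tolerance it keeps the final rotation with a logged
warning. The rotation is orthogonal regardless of convergence, so the
reconstruction contract and all downstream algebra are unaffected — only
approximate independence is lost. `on_nonconvergence="raise"` converts the
situation into a `ConvergenceError` carrying iteration diagnostics.

## Out-of-sample projection

New samples pass through the *same* wavelet suppression (the rank-1 PCA is
refit on the new batch; for a single sample it is a no-op by the degeneracy
rule), the stored offset is removed, and coordinates solve the least-squares
problem `a' = argmin ‖x'* − offset − aZ‖²` via the normal equations.
Training samples project back exactly onto their stored meta-samples. A
*transductive* mode (refit the transform on pooled train+test, split the
mixing-matrix rows) is available because small-cohort studies sometimes pool;
the default is inductive, which never lets test data touch the fit.

## Level-threshold selection

`δ(τ) = S_max/S_min` over the singular values of `Z_τ` (∞ if rank
deficient). A small `δ` means component energies are balanced — a stable
basis. `select_level_threshold` fits one model per candidate `τ` with a
shared seed and returns the minimizer; candidates whose `δ` is within a
relative `1e−6` of the minimum are tied, and the lowest tied threshold
strictly greater than 1 wins (falling back to the lowest tie). The default
`τ = 3` used everywhere else is a robust all-purpose setting; the selector
exists for per-dataset tuning.

## Classifiers and evaluation

`mica-svm` / `mica-lda` fit the transform on the training profile and a
linear-kernel soft-margin SVM (cost `C = 1` by default) or LDA on the
meta-sample coordinates. Baselines: raw-space `svm`/`lda`, and
`pca-svm`/`pca-lda`/`ica-svm` with the same component count `k` for
like-for-like comparison. The SVM quadratic program is delegated to
scikit-learn's `SVC`; LDA falls back to the lsqr solver with Ledoit–Wolf
shrinkage if the pooled scatter is degenerate. Gaussian kernels are disabled
for these wide-data classifiers unless explicitly overridden: with `n ≫ p`
every training point becomes a support vector and the machine predicts the
majority class.

Evaluation protocols: repeated 50% holdout (default 100 trials; each trial a
fresh plain-random split, transform refit on the training half only) and
k-fold CV (seeded random partition, fold sizes differing by at most one).
Metrics per trial: classification rate `(tp+tn)/total`, sensitivity
`tp/(tp+fn)`, specificity `tn/(tn+fp)` with `+1` (cancer) the positive
class; a zero denominator yields NaN, excluded from the `mean ± SD`
(`ddof = 1`) summary with a logged warning. Training halves that miss a
class are redrawn (logged).

## Biomarker discovery

A filter-wrapper search over genes:

- **Filter.** Per-gene two-sample Bayes factor via the BIC approximation on
  Gaussian models with a shared variance:
  `BF = exp((BIC_alt − BIC_null)/2)`, null = equal class means. Small values
  (≪ 1) are strong evidence of a class difference; genes are ranked
  ascending and the top `filter_size` survive. Constant genes are degenerate
  (scalar API raises; the vectorized ranking assigns `+∞`).
- **Wrapper.** Greedy forward selection maximizing the panel's leave-one-out
  rbf-SVM classification rate (`gamma = 'scale'`, `C = 1`). Ties resolve to
  the smaller Bayes factor, then input order; the panel rate is
  nondecreasing by construction, and selection stops when every remaining
  candidate would strictly lower the rate or `max_panel` is reached.
  Continuing through rate ties (rather than demanding strict improvement)
  is deliberate: once two true markers saturate the LOOCV rate, the Bayes
  factor tie-break is what admits further genuinely differential genes ahead
  of noise genes; demanding strict improvement would freeze every saturated
  panel at size ≤ 2.
- **Reported per gene:** the Bayes factor, the *single-gene* rbf-SVM LOOCV
  rate, and the gene's weight in the independent-component basis (Euclidean
  norm of its column of `Z`; invariant to component signs and order). All
  three scorers are pluggable.

## The synthetic-data generator

`generate_two_class_profile` draws
`sample = shared smooth baseline (≤ 5 low-order cosines, seeded amplitudes)
+ per-sample global shift (SD = global_shift, class-independent)
+ effect_size · noise_sd on the signal blocks (class +1 only)
+ N(0, noise_sd²) noise`.
Defaults — 30 samples per class, 1024 genes, three 32-gene blocks at 10/40/70%
of the gene axis, effect size 3, unit noise, unit global shift — are the
study conditions used throughout the tests and the acceptance script: large
enough for stable CV statistics, small enough that the whole suite runs in
minutes on one core. The generator captures what the method relies on
(shared global structure, localized class signal, white noise) and omits
what it does not model (heavy-tailed intensities, batch structure,
gene–gene correlation beyond the baseline, missing values), so green tests
demonstrate the mechanism, not clinical performance.

`generate_denoising_profile` stacks independent noisy replicates of a fixed
smooth signal; replicates are needed because the band suppression is a
cross-sample PCA (a single sample passes through unchanged).

`planted_marker_spec` hides three single-gene markers (effect size 4) among
500 null genes with a deliberately weak global confound (0.3 × noise): in
that regime pairs of true markers saturate the wrapper's LOOCV rate and
recovery is decided by the Bayes-factor ranking, which is the behaviour the
discovery procedure is designed around. With confounds at or above the noise
scale the third marker's realized evidence drops below the null-gene noise
floor and no selection rule could recover it reliably.

## Numerical choices and edge cases

- Whitening rank threshold: singular values below `s_max · 1e−10` are
  treated as zero; `k` is capped there with a warning.
- `condition_number` returns `+∞` (documented sentinel, not an exception)
  when the smallest singular value is numerically zero
  (`≤ s_max · max(shape) · eps`).
- Decision values of exactly 0 predict `+1`.
- Loader: delimiter auto-detected among tab/comma; ragged rows and
  non-numeric cells raise errors naming the offending row/column; NaN/Inf
  are rejected rather than imputed; gene order is preserved (an opt-in flag
  sorts by id).
- All randomness flows from explicit integer seeds; derived seeds stay below
  `2³¹`.

## Problem sizes

Test and acceptance runs use `p = 20–60`, `n = 256–4096`, 10–50 seeds,
20 CV trials — sizes chosen so each property is measured with comfortable
margins while the full suite stays a few minutes on a single core. The same
code paths scale directly to cohort-scale matrices (`p ~ 200`,
`n ~ 25 000`).

## Known limitations

- The method's output depends on the ordering of genes along the axis; the
  package preserves file order and leaves the choice of a biologically
  meaningful ordering to the user.
- The condition-number rule depends on the scale convention described above;
  other conventions make `δ` uninformative.
- The Bayes-factor and independent-component gene scores are one reasonable
  formalization of the discovery procedure's reported outputs; both are
  pluggable precisely because other formalizations exist.
- Binary classification only; no probability calibration; no multiclass.
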