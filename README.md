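# micasel

Multi-resolution independent component analysis (MICA) for two-class gene
expression profiles: wavelet-domain suppression of redundant global
structure, ICA extraction of low-dimensional *meta-samples*, SVM/LDA
classification, cross-validation, condition-number model selection, and
filter-wrapper biomarker discovery.

## Who it is for

Researchers classifying tumor expression cohorts (`p ~ 50–200` samples,
`n ~ 10³–10⁴` genes) where the two classes share strong global expression
structure and differ in localized gene groups — the regime where PCA/ICA-style
reductions, which favor global structure, add little over a raw-space SVM.

## The method

Each sample (a row of the `p × n` matrix `X`) is decomposed with an `L`-level
discrete wavelet transform along the gene axis. The `τ` finest detail bands
(level 1 = highest frequency) carry per-sample noise and redundant global
features; each such coefficient matrix `D_j` is replaced by its rank-1 PCA
reconstruction over samples. Inverting the transform gives the denoised
meta-profile `X*`, which classic ICA then factors as

    X* = offset + A Z,        A ∈ R^{p×k},  Z ∈ R^{k×n},  k ≤ p

with statistically independent rows of `Z`. Row `a_i` of the mixing matrix is
the **meta-sample** of sample `i`; a linear soft-margin SVM (or LDA) on the
meta-samples separates `+1` (cancer) from `−1` (control). The suppression
depth `τ` can be selected per dataset as the minimizer of the condition
number `δ = S_max(Z)/S_min(Z)`, with ties going to the lowest threshold
greater than 1. A Bayes-factor filter plus greedy rbf-SVM leave-one-out
wrapper extracts small biomarker panels. Details, conventions and edge cases:
[docs/methods.md](docs/methods.md).

## Worked example

```python
import micasel as mcs

profile = mcs.generate_two_class_profile(
    mcs.SyntheticSpec(p_per_class=30, n=1024, effect_size=3.0, seed=0))

model, meta = mcs.fit_mica(profile, wavelet_name="db8", level=12, tau=3, seed=0)
print(model.level, model.k, round(model.delta, 3))
# 6 59 6.283     <- depth capped at 6 for n=1024; 59 components; delta of Z

raw = mcs.within_between_distance_ratio(profile.values, profile.labels)
met = mcs.within_between_distance_ratio(mcs.meta_samples(model), profile.labels)
print(round(raw, 3), round(met, 3))
# 0.871 0.829    <- same-class samples sit relatively closer in meta-space

report = mcs.holdout_cv(profile, dict(method="mica-svm", level=12, tau=3),
                        trials=20, fraction=0.5, seed=42)
print(round(report.mean(), 3))
# 1.0            <- mean held-out classification rate over 20 half-splits
```

The first block prints the capped decomposition depth, the number of
independent components (`p − 1` by default) and the condition number of `Z`;
the second shows the self-clustering effect (lower within/between distance
ratio for meta-samples than raw samples); the third is the mean held-out
classification rate of MICA-SVM under repeated 50% holdout CV.

The `examples/` directory holds one short script per capability (simulation,
fitting and self-clustering, threshold selection, cross-validation, biomarker
discovery); each prints the numbers it computes with a line on what they
mean.

## Command line

A thin CLI wraps the same functions:

```sh
micasel simulate --p-per-class 30 --n-genes 1024 --seed 0 \
        --out prof.tsv --labels-out labels.tsv
micasel fit prof.tsv --labels labels.tsv --tau 3 --model-out model.json
micasel select-threshold prof.tsv --taus 1,2,3,4,5 --level 5
micasel evaluate prof.tsv --labels labels.tsv --method mica-svm \
        --protocol holdout --trials 100 --out report.json
micasel biomarkers prof.tsv --labels labels.tsv --filter-size 100 --out panel.tsv
```

Options may also live in a YAML file (`--config`); precedence is
flag > file > default. Input matrices are delimited text with a header row
and a row-id column, either orientation (`--orientation genes-by-samples`
transposes). Exit codes: 0 success, 2 usage, 3 malformed input, 4 label/data
error, 5 convergence failure.

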