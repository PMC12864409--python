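# Methods

This note records the statistical conventions implemented by `panelnet`, in
pipeline order. All estimators are deterministic given their seeds.

## Synthetic two-wave panel

`make_default_truth()` defines a 10-node ground truth over three craving
subscales (D1–D3), three compulsive-seeking subscales (O1–O3), three
impulsivity subscales (B1–B3), and a stop-signal reaction time (SSRT).

- **Baseline (T0) structure.** Latent scores are multivariate normal with
  precision matrix `Omega = I − R`, where `R` holds 10 sparse symmetric
  entries (e.g. D1–D2 = 0.45, O1–O2 = 0.45, O2–B1 = −0.15). Because the
  diagonal of `Omega` is 1, the nonzero partial correlations equal the `R`
  entries exactly, and `Omega` is diagonally dominant, hence positive
  definite.
- **Follow-up (T1) structure.** `z1_std @ Bmat + noise`, a linear
  cross-lagged map with autoregressive diagonal (0.35–0.50) and four
  cross-lagged entries (D2→D1 = 0.25, O3→B1 = −0.20, O3→B3 = −0.18,
  O1→B1 = 0.18). Default innovation SDs calibrate the wave-2 latent
  variance to 1, so the standardized lagged matrix equals `Bmat`.
- **Observed scales.** Latent z-scores are mapped to instrument ranges via
  `Phi(z)^skew` (a skewed probability-integral transform) and rounded to
  integer item-sum ranges; SSRT is linear (mean 260, SD 40, clipped at 50 ms).
  `identity_marginals()` skips this step and exposes the latent scale.
- **Attrition.** 209 of 361 subjects are retained at T1, missing completely
  at random by default (a score-dependent mechanism is available behind a
  flag).

## Redundancy screen

Before estimation, near-duplicate nodes are flagged with a dependent
overlapping-correlations test: for each candidate pair (a, b) with
`r_ab ≥ r_min = 0.50`, Steiger's z (using the backtransformed average
correlation) compares `r_ak` vs `r_bk` for every third node k. A pair is
flagged when fewer than `prop_threshold = 0.25` of those comparisons differ
significantly at `alpha = 0.05`.

## Network estimation

Per-wave networks are Gaussian graphical models:

1. Pearson (or Spearman) correlation matrix on listwise-complete rows,
   clipped to the nearest PSD matrix when needed.
2. Graphical lasso (block coordinate descent, L1 penalty on off-diagonal
   precision entries only) along a 100-point log-spaced path from
   `lambda_max = max |S_offdiag|` down to `lambda_max / 100`.
3. Model selection by EBIC, `−2·loglik + E·log(n) + 4·gamma·E·log(p)` with
   `gamma = 0.5`. Each candidate support along the path is scored at its
   **support-constrained unpenalized MLE** (the "refit" EBIC variant), which
   removes the shrinkage bias that otherwise inflates dense models. Ties
   resolve toward the sparser (larger-lambda) model. The log-likelihood at
   the penalized estimate is available via `selection_loglik="penalized"`.
4. Reported edge weights are partial correlations
   `−Theta_ij / sqrt(Theta_ii·Theta_jj)` from the constrained-MLE refit on
   the selected support (`refit_weights=True`), so weights are unshrunken
   conditional associations. Penalized weights are available via the flag.

## Centrality

Strength is the sum of absolute incident edge weights; one-step expected
influence (EI) is the signed sum. Tables include within-network z-scores.
On all-positive networks EI equals strength.

## Resampling

- **Edge accuracy.** Nonparametric bootstrap (`B = 1000` by default):
  resample subjects with replacement, re-estimate the full network, report
  percentile 95% CIs per edge. Degenerate resamples (zero-variance columns)
  are redrawn.
- **Centrality stability.** Case-dropping subset bootstrap over a drop grid
  of 5%–75% in 5% steps, `B_per_drop` subsamples per grid point. The CS
  coefficient is the largest drop proportion q such that, at every grid
  point up to q, the 5th percentile of the subsample-vs-full centrality
  correlation is ≥ 0.7. Benchmarks: 0.25 minimum, 0.5 good; the grid caps
  CS at 0.75. Subsamples too small to estimate (fewer than p+1 rows) are
  skipped with a warning; constant centrality vectors contribute a
  correlation of 0.

## Cross-lagged panel network

On completers only, each T1 node is regressed on all ten T0 nodes
(z-standardized on both sides, no intercept) with LASSO, the penalty chosen
by 10-fold cross-validation over a 100-point alpha path. Fold assignment is
seeded and shared across the ten outcome regressions. `W[i, j]` is the
standardized effect of T0 node i on T1 node j; the diagonal holds
autoregressive effects. Cross-lagged edges with `|b| > 0.1` are reported
with sign; in-EI/out-EI sum incoming/outgoing cross-lagged weights.

## Paired wave comparisons

Per node, on completers: Shapiro–Wilk on the paired differences decides the
branch at `alpha_normality = 0.05` — paired t-test when normality is not
rejected, otherwise the Wilcoxon signed-rank test (zeros dropped, mid-ranked
ties, exact p when ≤ 25 nonzero differences and no ties, else a
continuity-corrected normal approximation). Summaries report mean ± SD with
the t-test and median (IQR) otherwise. Descriptive quartiles use the linear
interpolation convention.

## Pipeline & reproducibility

`run_pipeline` executes describe → screen → estimate → centrality →
bootstrap → stability → compare → clpn, writing CSV/JSON artifacts and a
manifest (config hash, package version, per-stage status). All seeds are
explicit in the config; identical configs reproduce byte-identical numeric
outputs (floats formatted with `%.10g`).
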