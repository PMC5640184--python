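# Methods

This note documents the statistical models, the numerical choices and
the synthetic-data conditions behind `icaflow`, in the spirit of the
methods appendices that accompany simulation and omics-analysis
packages.

## Study design and data model

The package targets paired pre/post intervention designs with a
continuous exposure.  A *sample* carries a subject id, a timepoint
(pre/post), a gender and a completed distance in km; the covariate
encoding is `g = 0` female / `1` male and `d = 0` for every pre-race
sample, the subject's completed kilometres for the post-race sample.
Zero is the only physically meaningful pre-race baseline for a
"completed distance" exposure, so it is fixed rather than configurable.
Expression is a features × samples matrix of log2 intensities;
features (microarray transcript clusters) map to zero, one or several
genes, and only unambiguous (single-gene) annotations enter gene-level
analyses — multi-annotated features are counted and reported separately
rather than expanded, which avoids double-counting genes in enrichment
universes.

## Quality screening and filtering

*Relative log expression* per sample is the distribution of
`x[i,j] − median_i` (gene-wise medians); its per-sample median and IQR
summarise array bias and spread.  The PCA screen scores samples on the
first two principal components of the feature-centered matrix and flags
robust z-scores `|z − median| / (1.4826·MAD) > z_cut`.  The screening
function defaults to `z_cut = 3`; the pipeline driver uses `z_cut = 5`
because genuine biology (strong expression modes with heavy-tailed
activations) produces legitimate PC-score outliers at 3 robust SDs, and
the driver should only discard grossly aberrant arrays.  The published
exclusion this mimics was a visual call; the numeric rule is this
package's operationalisation and is configurable.

The low-expression filter keeps feature *i* iff
`#{j : x[i,j] > grand mean} > min_samples`, both inequalities strict.
`min_samples` defaults to the fraction 12/28 of the post-QC sample
count (12 with the reference design's 28 arrays).  The grand mean is
recomputed from the input matrix, so the filter is intentionally applied
exactly once, after sample exclusion.

## Differential expression

Per feature, ordinary least squares on the design
`[1, g, d]` gives `(β0, β1, β2)`, residual variance
`s² = RSS/(m − 3)` and the unscaled coefficient variances from
`diag((XᵀX)⁻¹)`.  Variance moderation follows the standard
empirical-Bayes scheme: with `z = log s²`,

```
E[z] = log s₀² + ψ(df/2) − log(df/2) − ψ(d₀/2) + log(d₀/2)
Var[z] = ψ'(df/2) + ψ'(d₀/2)
```

so `d₀` solves `ψ'(d₀/2) = var(e) − ψ'(df/2)` (Newton iteration on the
trigamma, tolerance 1e-8, with the asymptotic branches `1/√y` and `1/y`
for extreme arguments) and `s₀²` follows from the mean.  When the
observed excess variance is non-positive, or inversion fails, `d₀ = ∞`
and all variances shrink to `s₀²` (a warning is raised).  The posterior
variance `(d₀ s₀² + df s²)/(d₀ + df)` yields moderated t-statistics on
`d₀ + df` degrees of freedom; `d₀ = 0` reproduces ordinary t exactly.
One `(d₀, s₀²)` pair serves both tested coefficients, since moderation
acts on the residual variance, not per coefficient.  The implementation
is cross-checked against Bioconductor limma (via Rscript) to 1e-8 on the
t-statistics in the test suite.

Benjamini–Hochberg adjustment is the step-up `p_(i)·m/i` with
monotonicity enforced from the largest rank and capped at 1, applied
within coefficient; ties share the adjusted value through the stable
sort.  A feature is differential at `adj_p < 0.05` (configurable).
Direction is the sign of the coefficient; regulation percentages are
reported over distinct genes, each gene's direction decided by its
best-ranked feature.

*Strong effects* for the heatmap are features with
`|β2| > μ + 2σ`, where μ and σ are by default the moments of the
*signed* β2 over the differential set (the literal reading of the
published rule); the alternative convention (moments of |β2|) is
available via a switch because the published wording is ambiguous.
Heatmap ordering uses complete-linkage agglomerative clustering on
Euclidean distances of row-standardised values (standardisation
configurable; the publication does not state it).

## Decomposition

Internally all decomposition code uses samples-as-rows (`Xᵀ`, m × n);
public I/O stays genes × samples.  PCA is the SVD of the gene-centered
matrix; scores `z = U·Σ`, loadings `φ = V` (orthonormal), eigenvalues
`σ²/(m−1)`.

The number of components minimises

```
GCV(k) = n·m·RSS_k / (n·m − df_k)²,   df_k = m + n·k + m·k − k² − k
```

with `RSS_k` the squared Frobenius residual of the rank-k
reconstruction; `k = 0` (centering only) is included in the search.
The criterion is only meaningful while the parameter count is well
below the number of data cells: as `df_k → n·m` the denominator
collapses and the criterion rewards saturated fits, so the driver caps
the search at the largest k with `df_k ≤ n·m/2` (and always two below
full rank, where the residual would vanish identically).  The
alternative `smooth` method is an eigen-gap heuristic — the k
maximising the ratio of successive smoothed scree drops — kept as a
documented second opinion; the driver logs both and uses GCV.

Deflation subtracts the rank-1 reconstruction of PC1:
`Y = z₁ ⊗ φ₁`, `X̂ = X_centered − Y`.  The residual is orthogonal to
`φ₁` (≤ 1e-8 in tests) and total variance drops by exactly the first
eigenvalue.  ICA then runs with `k − 1` components, a constraint the
driver enforces (the deflated matrix has one less signal dimension).

FastICA uses simultaneous (parallel) fixed-point iteration with
`g(u) = tanh(α₁u)`, `α₁ = 1`, whitening to exactly k components,
convergence tolerance 1e-4 and at most 1000 iterations; non-convergence
returns a flagged result rather than an error.  The fixed-point solver
is scikit-learn's FastICA; this package wraps it with the study's
settings, gene-centering, and a determinism convention: each component
is sign-flipped so its largest-|weight| gene is positive (ICA signs are
unidentifiable).  Input is centered but not variance-standardised per
gene by default (a switch exists), matching the referenced fastICA
defaults.

*Contributors*: per component, the top `⌈n/10⌉` genes by |mixing
weight| — a rank-based cut, never a threshold on the weight value, so
the set size is identical across components (509 at the reference
n = 5,084) and reproducible under ties, which break by stable input
gene order.

## Enrichment

One engine serves pathway and regulator analyses: a regulator→target
database is viewed as a gene-set database whose universe is the union
of target sets.  For list size n and term size K inside a background of
N genes, the score is the inclusive upper tail
`P(X ≥ k), X ~ Hypergeometric(N, K, n)`, summed in log space from
gammaln-based log-pmf terms (exact to 1e-12 against rational-arithmetic
enumeration for all geometries with N ≤ 12).  Backgrounds are stage
dependent: the database universe for the global differential list; the
differential∩universe set for each component's contributors.  List
genes absent from the background are dropped (and counted); terms with
no background annotation are excluded *before* BH adjustment, which is
applied per database and stage, never pooled.  The per-term
up-regulated percentage is computed over overlap genes present in the
regulation map.  Stars encode adjusted p-values
(`*** < 0.001, ** < 0.01, * < 0.05`).

## Synthetic studies

`simulate_dataset` emulates the reference design:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | features (desk-scale stand-in for ~25k) |
| `n_subjects` / `post_fraction` | 16 / 0.75 | 16 pre-race, 12 post-race samples |
| `distances_km` | observed 14–82 km list | exposure values, drawn per subject |
| `pi_diff` | 0.10 | fraction of true distance-responsive genes |
| `effect_floor_snr` / `effect_excess_snr` | 3 / 1 | per-gene `|β2|·d_ref / σ_g = 3 + Exp(1)` |
| `down_fraction` | 0.63 | sign split of true effects (down:up 63:37) |
| `d0`, `s0_squared` | 4, 0.05 | variance prior: `σ²_g ~ s₀²·d₀/χ²_d₀` |
| `k_modes` | 3 | planted latent modes, Laplace activations |
| `mode_sparsity` / `mode_amplitude` | 0.10 / 1.5 | decile-sized modules, log2 weight SD |
| `dominant_mode_scale` | 5 | mode 1 is the masking signal |
| `subject_sd` | 0.2 | shared pre/post subject baseline SD |

Expression is baseline + subject baseline + β1·g + β2·d + Σ modes +
Gaussian noise.  Effect magnitudes are anchored to each gene's own
noise SD so that the planted response is detectable by construction
(≥ 3 noise SDs at the mean completed distance); effects are planted on
genes carrying *no* mode loading, so each planted structure is
attributable to exactly one mechanism — with decile-sized strong modes,
a mode-loaded gene's residual variance is dominated by the mode, and an
effect calibrated to its noise draw alone would no longer be in the
detectable regime.  Mode activations are Laplace (super-Gaussian) so
ICA identifiability holds; Gaussian activations exist only for negative
controls.  Mode amplitude and sparsity were chosen so the planted modes
occupy the identifiable regime at m = 28 samples: with 28 samples, even
perfectly recovered sources match their planted activations at
|r| ≈ 0.9–0.95, because independent Laplace draws of length 28 already
correlate at ~0.2 — a small-sample ceiling, not an algorithmic one.
All randomness flows from one `numpy` generator seeded by `seed`.

`simulate_databases` plants enrichment ground truth: most terms sample
the gene universe uniformly; designated terms oversample the true
differential genes (or a chosen mode's genes) with sampling odds
`enrichment_odds`.  The regulator layout defaults to 196 regulators
whose target universe can be padded to an exact size (23,991 in the
reference layout) with every universe gene a target of at least one
regulator; target-set sizes are log-uniform between 0.5 % and 25 % of
the universe, spanning the orders of magnitude seen in curated
regulator databases.

What the generator does **not** emulate: probe-level intensities and
array batch artifacts, correlated gene-gene noise beyond the planted
modes, annotation errors, and overlap between planted modes and planted
covariate effects.  Passing tests therefore demonstrate correctness of
the machinery and calibration under the stated model, not performance
on real arrays.

## Problem sizes used in the checks

The test-suite conditions are: variance-prior recovery at 5,000 genes;
FDR/recall of the planted response averaged over 20 seeded replicates
of the default 2,000-gene study; GCV rank recovery on 50 replicates of
a 30 × 200 rank-3 matrix at 10 % noise; ICA source recovery on a
100-sample, 200-gene two-source mixture at 10:1 SNR; the
deflation-vs-no-deflation comparison averaged over 10 default-config
replicates; and byte-level determinism of two same-seed pipeline runs.
These sizes keep a full run of the suite under a minute on one CPU
while leaving each statistical check comfortably powered.

## Known limitations

- The GCV degrees-of-freedom formula is the bilinear parameter count of
  the cited approximation; other conventions exist and shift the
  criterion curve, though rarely the argmin within the capped range.
- The `smooth` component-count method is a heuristic; it is logged, not
  used for decisions.
- Reconciliation when GCV and the eigen-gap heuristic disagree is
  simply "use GCV"; the reference analysis reported both agreeing.
- Enrichment treats gene sets as flat; no ontology-graph propagation or
  topology-aware scoring.
- With `m` around 28 samples, ICA source estimates are intrinsically
  noisy; contributor sets of weakly expressed modes should be read as
  rankings, not crisp membership.
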