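# Methods

This note records the statistical models behind each stage, the defaults
and why they were chosen, the numerical conventions that make outputs
reproducible, and what the synthetic fixtures do and do not demonstrate.

## Data model

A `Study` bundles one metadata table (n samples × clinical variables),
J omics matrices (n × p_j, fully numeric, no missing values) and a
categorical response with a declared reference level. Alignment is
positional: every file must carry the samples in the same order. When a
sample-id column is detected (first column non-numeric and unique) the
ids are used as a cross-check only, never for reordering. Missing values
are a hard error at load time — no imputation is performed anywhere,
because imputing before cross-validation leaks held-out information into
training folds.

Metadata variables are classified automatically: categorical if any
value fails numeric parsing, or if numeric with ≤ 5 distinct values
(configurable); otherwise numerical. The 5-level cutoff captures
0/1-coded clinical flags and small ordinal codes without stealing
genuinely continuous variables.

## Metadata association tests

Numerical variables: one-way OLS of the variable on response-group
indicators; the reported statistic is the overall F with (g−1, n−g)
degrees of freedom, and summaries are group means ± sd. The
nonparametric alternative is Kruskal–Wallis (tie-corrected H referred to
χ²(g−1); no exact small-sample tables), with min/median/max summaries.
Categorical variables: Pearson chi-square of independence with Yates
continuity correction applied only to 2×2 tables (configurable),
reported as counts and column percentages.

Regression assumptions are validated globally on the residuals by a sum
of four χ²(1) components, referred to χ²(4):

* skewness n·g₁²/6 and kurtosis n·(g₂−3)²/24 of residuals standardized
  by the maximum-likelihood scale (the Jarque–Bera decomposition);
* a link-function score test, n·R² from regressing residuals on squared
  fitted values;
* a Breusch–Pagan heteroscedasticity test, n·R² from regressing squared
  scaled residuals on fitted values.

When the fitted values are constant the last two components are
undefined and the global degrees of freedom shrink to the number of
applicable components. The verdict (violated iff global p < 0.05) is
reported alongside the regression row; there is no automatic fallback to
the rank test — the choice of method stays with the analyst. Validation
requires ≥ 8 residuals; below that the report is omitted. The
Monte-Carlo size of the global test at α = 0.05 on normal residuals sits
in [0.02, 0.09] (it is conservative because the four components are not
exactly independent at moderate n), which the suite verifies with 1000
seeded replicates.

## PCA and variance attribution

Each dataset is centered (always) and optionally unit-scaled, then
decomposed by SVD. Variance proportions are σ_i²/Σσ² over the full
decomposition, so they sum to one. At most five components are retained
— beyond that, score-plot matrices stop being readable and the
association heatmap dilutes. Sign convention: each loading column is
flipped so its largest-magnitude entry is positive, which pins down the
otherwise arbitrary SVD signs across BLAS implementations.

Associations: each retained PC score is regressed on each metadata
variable (indicator coding for categoricals) and the overall model
F-test p fills one cell of the variables × PCs grid — one p per cell
regardless of the number of category levels. BH correction, when
requested, is applied jointly across the whole grid (the heatmap carries
one FDR toggle, not one per column). The response itself appears as a
row: it is a metadata variable, and its association with the leading PCs
is exactly what the score plot shows qualitatively.

## Differential expression

All three methods share a cell-means linear model on *all* response
levels, so the residual degrees of freedom d = n − g come from the full
model even when a single pairwise contrast is displayed. The effect for
contrast (a, b) is the difference of fitted group means, oriented a − b.
Inputs to the OLS and moderated fits are assumed to be **already on
log2 scale**; the group-mean difference is then the log2 fold-change.
The package does not transform non-count data for the user.

Moderation: with per-feature residual variances s²_g on d df, define
e_g = log s²_g − ψ(d/2) + log(d/2). Method-of-moments gives
ψ′(d₀/2) = var(e) − ψ′(d/2), inverted by Newton iteration on the
trigamma function; no excess spread means d₀ = ∞, in which case s₀² is
the geometric mean of the s²_g (this is the limit that recovers the
common value when all variances are equal). Otherwise
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). The moderated statistic uses
the posterior variance s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d) and gains d₀
degrees of freedom (normal reference when d₀ = ∞). The estimator is
validated by parameter recovery from its own generative model
(scaled-inverse-χ², d₀ = 4, s₀² = 2, 5000 features) and by type-I
calibration on fully null data.

Counts: log-CPM y = log2((count + 0.5)/(L_i + 1)·10⁶) with L_i the
library size. The mean-variance trend is a lowess fit (span 0.5, the
conventional default) of √(residual sd) on mean log2-count; each
observation's fitted log2-count (fitted log-CPM shifted by its own
sample's log2(L_i + 1) − log2 10⁶) is mapped through the trend by
piecewise-linear interpolation with flat extrapolation, and the weight
is the inverse fourth power, capped so max/min ≤ 10⁶. Weighted least
squares then feeds the same moderation machinery. Library-size CPM is
the only normalization — no TMM or quantile factors.

BH adjustment is one shared step-up implementation
(`diffexp.benjamini_hochberg`) used by every module, applied per dataset
per contrast (each dataset gets its own dashboard and its own error-rate
guarantee).

## Gene-set and drug-reversal analysis

ORA is the hypergeometric upper tail P(X ≥ k) with N = |universe|,
K = |set ∩ universe|, n_q = |query|. The universe is the list of
features actually tested in the DE stage — using all annotated genes as
background would overstate enrichment for well-measured pathways. Query
genes outside the universe are dropped (and counted); sets empty after
universe intersection are dropped (and counted). Gene symbols are
upper-cased on GMT read; a dataset is eligible for enrichment when ≥ 50%
of its feature ids match an uppercase symbol pattern (configurable).

Drug reversal: up-regulated query genes are tested against each
perturbation's *down* set and vice versa (outer join on perturbation
names, missing side contributing p = 1), and
combined_score = −log₁₀(adj p, up-vs-down) + −log₁₀(adj p, down-vs-up).
The sum is symmetric in the two directions and monotone in both; it is a
declared convention of this package, not a community standard. Ties are
broken by perturbation name, which makes rankings deterministic but
means tied null scores systematically go to the alphabetically first
name — the null-uniformity test therefore conditions on strict winners.

## Biomarker discovery

Per dataset, a binary elastic-net model for (chosen level) vs
(reference level); with more than two response levels the remaining
samples are dropped for this stage. The default family regresses the
0/1 indicator under squared loss with predictions clipped to [0, 1] —
the classical fast path for roughly Gaussian omics data — with penalized
logistic regression available (`family="binomial"`).

Objective: (1/2n)‖y − b₀ − Xb‖² + λ(α‖b‖₁ + (1−α)/2·‖b‖₂²).
Features are standardized internally — training-fold statistics only,
applied to held-out folds — so the selected panel is invariant to affine
rescaling of raw inputs. α = 0 is solved in closed form via SVD (ridge);
α > 0 by coordinate descent with warm starts along the λ path.

Tuning: repeated stratified k-fold CV (defaults folds = 5, repeats = 5),
folds drawn deterministically from the seed. The "auto" λ grid is, per
α, 50 values log-spaced from λ_max (the smallest λ zeroing every
coefficient; α floored at 10⁻³ for the ridge end) down to 10⁻³·λ_max,
anchored on the full standardized data so every fold scores the same
grid. Default α grid {0, 0.1, …, 1.0}. The winner maximizes the mean
metric (AUC by default; accuracy available) over folds × repeats; exact
ties break toward the largest λ (sparsest panel), then the largest α.
The final model is refit on all samples at the winner.

ROC and AUC are always computed from out-of-fold predictions averaged
over repeats, never from in-sample refits: in-sample ROC of a tuned
model is optimistically biased, and the out-of-fold surface is the
defensible one. The ensemble prediction is the unweighted arithmetic
mean of member out-of-fold probabilities; its ROC is computed the same
way. Panel summaries: importance = |standardized coefficient| ranking
(ties alphabetical); intersections = exact-subset counts of panel
membership by feature name; panel PCA and an average-linkage
(Euclidean) clustered heatmap of standardized panel values; a network
whose edges are biomarker–pathway (biomarker in a significant set's
overlap) and biomarker–biomarker (|Pearson r| ≥ cutoff, default 0.75,
computed across all samples, cross-dataset pairs allowed because samples
align).

The whole stage is a pure function of (Study, grid, CV config): two runs
with the same seed produce byte-identical outputs, which the suite
checks end-to-end through the CLI.

## Synthetic data

The generator emits aligned studies whose structure every stage can be
scored against. Gaussian mode: null features iid N(0, 1); planted
features shifted ±δ/2 by group (δ in sd units). Negative-binomial mode:
gamma-Poisson counts with feature base means log-normal around e⁵
(≈ 150 counts), dispersion 0.2, and a group log2-fold-change of δ on
planted features. Metadata carries the response, a binary batch
variable (optionally shifting all features of batch-1 samples to plant a
batch axis), and null numeric/categorical covariates. An optional
equicorrelation within blocks of 10 stresses the grouping behaviour of
the elastic net. Everything is a deterministic function of the seed.

Fixture sizes used by the checks: the planted-signal recovery study is
n = 120, p = 400 per modality, 10 planted features at δ = 1.5 sd; the
complementary-signal study (each modality predictive of a different half
of the cases) is n = 100, p = 100 per modality, 10 planted at δ = 2,
evaluated over 20 seeds with a reduced grid (α ∈ {0.1, 0.55, 1.0}, 20
λ values, 5×2 CV) — sizes chosen as the smallest at which the
statistical contrasts of interest are unambiguous at desk scale.

What the fixtures do **not** emulate: realistic feature covariance,
heavy-tailed or batch-confounded noise, missingness, or annotation
structure in gene-set membership. Passing tests demonstrate the
correctness and calibration of the machinery under its own assumptions,
not performance on any particular real cohort.

## Numerical conventions and edge cases

* CSV parsing goes through exact strtod conversion, so write/read
  round-trips are bit-exact; delimiters are sniffed from {comma, tab,
  semicolon} and the decimal point is fixed as ".".
* PCA sign fixing as above; hierarchical-clustering leaf order is
  deterministic given the input.
* Zero-variance features: excluded from elastic-net fitting (coefficient
  0) and from correlation edges (kept as nodes); zero-variance metadata
  variables yield not-applicable association cells.
* Degenerate tests: identical groups give F = 0/p = 1; all-tied values
  are an error for the rank test; a zero contingency margin is an error.
* Hypergeometric p's are clamped to (0, 1]; −log₁₀ uses a 1e-300 floor.
* Coordinate-descent tolerance defaults to 1e-4 (the solver's standard);
  closed-form comparisons in the suite tighten it locally.

## Known limitations

* No intermediate integration (shared latent factors) and no missing-
  modality handling at prediction time; late integration here requires
  every modality for every sample.
* OLS/moderated DE trusts the caller that values are log2-scale; no
  automatic transformation or normalization beyond CPM for counts.
* The binomial family is fit per grid point (no warm-started logistic
  path), so it is markedly slower than the default family on large
  grids.
* ORA treats gene sets as flat symbol lists: no id mapping, orthology,
  or set-overlap correction; rank-based enrichment (GSEA-style) is out
  of scope.
* The report renders markdown only; word-processor conversion requires
  an external converter on PATH.
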