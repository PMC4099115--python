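# Methods

This note documents the statistical models implemented in `minmet`, the
choices made where the design was genuinely open, and what the synthetic
cohort does and does not emulate.

## Study design and data model

The design is a balanced completely randomised 2 × 2 factorial — genotype
(wild-type `WT` vs. Apc-mutant `MU`) by diet (low-fat `LF` vs. high-fat
`HF`) — with five mice per cell (n = 20) and repeated measurements on two
tissues (plasma, liver), for 40 observations.  The intensity matrix holds
p ≈ 220 metabolites in rows and samples in columns, with an explicit
missingness mask; every statistic ignores masked cells.  Analyses are per
tissue; the repeated-measures structure is not modelled (each tissue is
analysed as an independent 20-sample experiment).

## Preprocessing

**Missingness filter.**  Metabolites are retained when their missing-cell
count is at most a threshold ν chosen to maximise
`J(ν) = R(ν) − M(ν)` — retained metabolites minus missing cells among them
— subject to the feasibility bound `ν < n − min_g(n_g)/2` (with n = 20 and
n_g = 5 the bound is ν ≤ 17).  Because J only changes when ν crosses an
observed missing count, ν is searched over the observed per-metabolite
missing counts (0 always eligible); ties resolve to the largest such ν
("nearest upper integer"), and when no observed count is feasible the bound
itself is reported with an empty retained set.  The objective trace over
every feasible integer is recorded for QC.

**Imputation** runs on the log₂ scale in two stages.  Stage 1 treats a
missing cell as left-censored: if the metabolite is observed in ≥ k
(default 2) samples of the same genotype × diet × tissue group, the cell
becomes `E[Y | Y < c_j]` under `Y ~ N(μ̂, σ̂²)` with the group mean/sd of
those neighbours, where the detection-limit proxy `c_j` is the metabolite's
minimum observed intensity anywhere.  The truncated-normal mean
`μ − σ φ(α)/Φ(α)`, α = (c−μ)/σ, is evaluated through `log Φ` so deep-tail
cells do not underflow; imputed values are strictly below `c_j` by
construction.  Stage 2 (whole-group absences, or degenerate neighbour
spread) fills the background level: the global minimum observed intensity
minus 1 log₂ unit, i.e. half the minimum on the raw scale — a common
metabolomics convention.  Observed cells are never altered.

**Regularization.**  Homoscedasticity across metabolites is approximated by
trend standardisation: per-metabolite means m_j and standard deviations s_j
are computed, a smooth trend ŝ(m) is fitted by a sliding-window median over
metabolites ordered by (m_j, id) — the id tie-break makes the result
invariant to row order — with window `max(20, p/10)`, and each row is
replaced by `(y − m_j)/ŝ(m_j) + m_j`.  This is a surrogate for joint
adaptive mean–variance regularization: it fulfils the same contract
(variance stabilisation plus normalisation; output values may be negative)
without reproducing that package's internal clustering algorithm.  On
default synthetic cohorts the Spearman correlation between rank(m_j) and
the post-regularization variances is ≈ 0 (|ρ| < 0.1).

## Moderated two-way ANOVA

Each metabolite is fitted by OLS with sum-to-zero (±1) factor coding, so
the coefficients are classical main/interaction effects and the reported
contrasts are marginal-mean differences on log₂ scale: genotype
logFC = 2β_G, diet logFC = 2β_D, and the interaction logFC is the
difference-of-differences 4β_GD.  Residual df is n − 4 = 16 per tissue.

Variance moderation follows the standard empirical-Bayes scheme: log s_j²
is moment-matched to a scaled-F model using digamma/trigamma identities,
with the trigamma inverted by Newton iteration; a non-positive excess
variance yields d₀ = ∞ (complete shrinkage).  Posterior variances are
`s̃_j² = (d₀s₀² + d_j s_j²)/(d₀ + d_j)`, moderated t statistics use
`d₀ + d_j` df, and forcing d₀ = 0 reproduces classical per-metabolite t
tests exactly (a tested identity).  The B statistic is the log posterior
odds of differential concentration under a two-component normal model: the
prior probability of a differential metabolite defaults to p_prior = 0.01,
and the prior effect variance v₀ is estimated by quantile-matching the top
|t̃| tail against its expected order statistics (floored at zero).  B is
reported in base 2 (`b_base2=False` switches to natural log).  Metabolite
lists are always sorted by adjusted p ascending, then B descending.

## Positive FDR

q-values use the tail estimator `π̂₀(λ) = #{p > λ}/(m(1−λ))` on the default
grid λ = 0.05…0.95 (step 0.05), smoothed by a cubic polynomial evaluated at
the largest λ and clipped to `[1/m, 1]` so q-values are never zero.  Then
`q_i = min_{t ≥ p_i} π̂₀ m t / #{p ≤ t}`, enforced monotone; with π̂₀ = 1
this is exactly Benjamini–Hochberg, which is also exposed separately for
enrichment adjustment.  Fewer than 10 p-values fall back to π̂₀ = 1 with a
warning.

## Polyp-count model

Counts per mouse follow the zero-inflated negative-binomial mixture
`Pr(C=c|x) = π I₀(c) + (1−π) f(c|x)` with `f` parameterised by mean
`exp(x'β)` and dispersion θ (variance μ + μ²/θ).  The count covariates are
`[1, G, D, G·D·Y]` with 0/1 coding (reference WT-LF) and Y the plasma level
of one metabolite on the regularized scale; the zero component is an
intercept-only logit (the canonical binomial link; a log link would not
keep π in (0,1)).  The intercept is included although the minimal covariate
list omits it — without one the reference-cell mean would be pinned at 1.
No lower-order Y or G·D terms are added.

Numerical and inferential choices, each of which mattered in practice:

- Y is mean-centred before entering the three-way term.  The MU-HF cell has
  its own effective intercept (β₀+β_G+β_D), so centring is a pure
  reparametrisation — but without it the clamp (below) absorbs
  `−slope·mean(Y)` into β_D and corrupts the Wald statistics.
- The likelihood is maximised by L-BFGS-B over (β, γ₀, log θ) with an
  analytic gradient, from data-driven starting values (log mean of the
  positive counts; logit of the observed zero fraction; θ = 1).
  Coefficients are clamped to |·| ≤ 20: all-zero wild-type cells separate
  the likelihood along a (β₀, β_G, γ₀) ridge, and the clamp keeps those
  fits finite and reportable, flagged via `boundary_flag` (also set when
  the zero probability estimates at a boundary).  Line-search stalls on the
  ridge with a vanishing projected gradient are accepted as converged.
- The covariance comes from the observed information (central differences
  of the analytic gradient) over the *interior* parameter block; clamped
  parameters are held fixed and get no standard error, which keeps the Wald
  test of the three-way coefficient well defined under separation.
- Wald p-values are referred to a t distribution with n − 6 residual df
  rather than the normal: at n = 20 the normal reference is measurably
  anticonservative (the null fraction of q ≤ 0.05 calls roughly doubles).

Fits that do not converge are excluded from significance calls and reported
separately; per-metabolite Wald p-values for the three-way coefficient are
adjusted to q-values across metabolites.

The per-group summaries report the least-squares line of counts on Y, r²
and Pearson ρ for each genotype × diet cell; for constant count vectors
(wild-type cells) r² is 0 and ρ is returned as an undefined (NaN) sentinel,
never an exception.  The 2 × 2 independence test is Pearson's chi-square
without continuity correction; a zero row or column margin makes the
expected counts undefined and is rejected with a named margin — note that a
genotype-by-diet table of polyp totals with an all-zero wild-type row is
exactly such a degenerate table.

## Set overlap and enrichment

All hypergeometric masses are computed via log-gamma and summed with
`logsumexp`, so any representable probability is obtained without overflow
or underflow (e.g. the (x=45, y=124, L=249, N=2136) overlap evaluates to a
finite log-probability near −30.1 rather than 0).  The overlap/intersection
p-value is the *point* mass at the observed overlap, exactly as the formula
is written; pathway enrichment uses the right tail (one-sided Fisher exact
test for over-representation), an explicit universe (never an implicit
all-compounds default), the ratio x/L, BH adjustment across sets, and a
`−log₁₀ p` network score (base 10, the common convention when the base is
unstated).

## Acyl-CoA summaries

Group cells report mean and SEM = sd/√n (NaN for singleton cells);
relative concentrations divide by the reference group (default WT-LF, whose
relative means are identically 1); fold changes are ratios of means with
ratios below one rendered in reciprocal form (`1/2.53`).  Per-mouse
[Acyl-CoA]/[CoASH] ratios divide the summed acyl species by free CoA, with
an undefined sentinel when CoASH is zero or absent.  Two-group tests use
the pooled-variance t (homoscedasticity is the working assumption
throughout, not Welch); "group vs. overall" is implemented as a deviation
contrast inside the one-way ANOVA (the omnibus F is returned separately,
since the wording admits both readings).

## PCA

Covariance PCA (metabolite-wise centering, no scaling by default — scaling
is a flag) via SVD of the sample × metabolite matrix.  PEV is
100·σ_k²/Σσ² over all components and sums to 100; loadings are additionally
ranked per component by absolute correlation with the component scores.
Component signs are fixed by making the largest-magnitude loading positive,
so plots are reproducible.

## Synthetic cohort

The generator draws per-metabolite log₂ baselines μ_j ~ N(10, 2²) with a
decreasing mean–variance trend sd(μ) = a·e^{−bμ} + c (a = 2, b = 0.25,
c = 0.35: low-abundance metabolites are noisier, as in MS intensity data).
Of 220 metabolites, 97 / 82 / 65 carry genotype / diet / interaction
effects with signed log₂ sizes uniform in [0.5, 2] (up-fractions 61/97,
44/82, 46/65); interaction metabolites overlap the main-effect sets by 50%.
Missingness is informative: an instrument detection limit at the pooled 5%
quantile of the latent intensities censors low-abundance cells (so
missingness concentrates in weak metabolites and the filter removes roughly
the expected share of metabolites), plus 2% missing-completely-at-random.
Wild-type polyp counts are structurally zero; mutant counts are negative
binomial (θ = 4) with log-mean `β₀ + β_D D + β_GDY G·D·Z`, where Z is the
standardised level of a designated driver metabolite, β₀ = ln(51/5),
β_GDY = 1.2 per SD, and β_D is set so the expected mutant/high-fat cell
total is 273 after the lognormal correction exp(β_GDY²/2).  The driver is
the highest-abundance effect-free metabolite and is exempt from MCAR
dropout — the counts condition on its values, so recovery tests must
measure the estimator, not missingness.  The acyl-CoA table draws lognormal
concentrations (CV = 0.44) around group means whose long-chain totals are
1.16 / 0.41 / 1.27 / 1.52 nmol·mg⁻¹ for WT-LF / MU-LF / WT-HF / MU-HF.

What the generator does **not** emulate: cross-tissue correlation (tissues
are independent draws), batch/run-order effects, correlated metabolite
blocks (pathway co-regulation), peak-identification ambiguity, and
technical replicates (the study has none).  Passing tests therefore show
that the estimators recover the assumed generating structure — not that
real GC-MS data satisfy those assumptions.

## Known limitations

- The within-block correlation device for borrowing information across
  repeated tissue measurements is not implemented; analyses are per tissue.
- With five informative mice per cell, the per-metabolite ZINB ranking is
  dominated by best-of-p overfitting noise: among ~200 candidate
  metabolites, some null metabolite's values regularly align with the count
  noise better than the true driver, so the driver is *significant* in
  essentially every cohort but *top-ranked* in only a minority.  At this
  sample size the association list should be read as a significant set, not
  a ranking.
- The q-value π̂₀ estimator uses a cubic polynomial rather than a smoothing
  spline; on 19 grid points the two agree closely.
- Moderated inference assumes exchangeable residual variances after
  regularization; gross heteroscedasticity would violate the scaled-F
  ensemble model.
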