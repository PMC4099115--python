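# minmet

Statistical analysis pipeline for untargeted metabolomics of a mouse
intestinal-neoplasia cohort: Apc-mutant vs. wild-type littermates on low-
vs. high-fat diet, with plasma/liver metabolite intensities and per-animal
intestinal polyp counts as the clinical outcome.

The package re-implements, as tested and reusable components, the full
statistical chain such a study needs:

- **Preprocessing** of a metabolite × sample intensity matrix with
  informative (left-censored) missingness: a missingness-threshold variable
  filter (choose the per-metabolite missing-count cap ν maximising
  `retained metabolites − retained missing cells` subject to
  `ν < n − min_g(n_g)/2`), two-stage censoring-aware imputation
  (truncated-normal conditional means below the detection limit, background
  fill for whole-group absences), log₂ transformation, and mean–variance
  regularization by trend standardisation.
- **Per-metabolite moderated two-way ANOVA**
  `y_ij = μ_j + (G)_j G_i + (D)_j D_i + (GD)_j G_i D_i + ε_ij` with
  empirical-Bayes variance shrinkage: residual variances are pooled through
  a scaled-F prior `(d₀, s₀²)` estimated by moment matching, giving
  moderated t statistics `t̃ = β̂_c / (s̃_j √v_c)` with `d₀ + d_j` degrees of
  freedom and a log₂ posterior-odds **B statistic**.
- **Positive-FDR control**: Storey-style q-values with a smoothed π̂₀
  estimate, plus plain Benjamini–Hochberg adjustment for enrichment tests.
- **Zero-inflated negative-binomial regression** of polyp counts,
  `Pr(C=c|x) = π·I₀(c) + (1−π)·NB(c; e^{x'β}, θ)` with count covariates
  `[1, G, D, G·D·Y_j]` and an intercept-only logit zero component, applied
  per metabolite to find plasma compounds whose association with polyp
  burden depends on the genotype × diet combination.
- **Hypergeometric set statistics**: the point overlap probability
  `P(X=x|y,N,L) = C(y,x)C(N−y,L−x)/C(N,L)`, right-tailed enrichment,
  IPA-style ratios and `−log₁₀ p` network scores.
- **PCA diagnostics** (scores, percentage of explained variance, loading
  rankings) and **acyl-CoA group summaries** (means ± SEM, relative
  concentrations, [Acyl-CoA]/[CoASH] ratios, pooled-t / ANOVA tests).
- A **synthetic-cohort generator** reproducing the study design (2
  genotypes × 2 diets × 5 mice, two tissues, 220 metabolites, planted
  effects, left-censored missingness, structurally-zero wild-type polyp
  counts), so the entire pipeline runs and is tested with no external data.

## Worked example

```python
from minmet import ModeratedANOVA, ZeroInflatedNB, polyp, simulate_cohort
from minmet.preprocess import preprocess_tissue

cohort = simulate_cohort(seed=11)
plasma = cohort.design.subset_tissue("PLA")
regularized, filt = preprocess_tissue(cohort.intensity["PLA"], plasma)
print(f"nu = {filt.nu}, retained {len(filt.retained_ids)} of 220 metabolites")

results = ModeratedANOVA(regularized, plasma).fit()
print(results.summary())

driver = ZeroInflatedNB.from_cohort(cohort.polyps, plasma,
                                    cohort.truth.driver_z).fit()
print(driver.summary())
```

prints (exact numbers for seed 11):

```
nu = 1, retained 178 of 220 metabolites
Moderated two-way ANOVA (genotype x diet)
  metabolites: 178, residual df: 16
  prior df d0: 17, prior variance s0^2: 0.4507, p_prior: 0.01
  significance threshold (adjusted p): 0.05
  genotype     significant:   70 (up 48, down 22)
  diet         significant:   65 (up 36, down 29)
  interaction  significant:   39 (up 22, down 17)
Zero-inflated negative-binomial fit
  n = 20, loglik = -35.3924, converged = True, boundary = True
  beta0       -17.7808  se   0.2155  z  -82.494  p 3.22e-20
  beta_G       20.0000  se      nan  z      nan  p nan
  beta_D        0.9138  se   0.3364  z    2.716  p 0.0167
  beta_GDY      1.4736  se   0.2189  z    6.732  p 9.6e-06
  theta         8.0911
  pi (zero)     0.0000  (gamma0 -20.0000)
```

Reading the output: the filter kept metabolites with at most ν = 1 missing
cells; the planted genotype/diet/interaction effects (97/82/65, sizes
0.5–2 on log₂ scale) are recovered in large part at an adjusted-p threshold
of 0.05; and the polyp model estimates the planted three-way coefficient
(true value 1.2) with a clearly significant Wald test.  The `nan` row and
the boundary flag are expected: wild-type mice have structurally zero
counts, which separates the genotype coefficient onto the +20 clamp, so its
standard error is deliberately not reported.

The same chain is available from the shell:

```bash
minmet run-all --simulate --seed 11 --out run/
```

which writes the regularized matrix, PCA tables, three effect tables,
the polyp association table, enrichment results, acyl-CoA summaries and a
JSON manifest of every numeric design choice.

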