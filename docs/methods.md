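# Methods

## The statistical problem

Wheat breeding programs evaluate hundreds of candidate lines for grain yield
across a handful of field sites, with each line replicated within each site.
Genomic prediction replaces some of this phenotyping with marker-based
prediction: a mixed model links SNP genotypes to yields and predicts, for
any genotyped line, a breeding value at every site — including sites (or
lines) never phenotyped.  Two modelling questions drive the design of this
package: how the genetic covariance *between sites* (genotype-by-environment
interaction) is represented, and whether adding an additive×additive
epistatic kernel improves prediction over a purely additive one.

## Model

For the yield record of genotype *i* at site *j*, replicate *r*:

```
y_ijr = b_j + r_jr + u_ij + e_ijr
```

* `b_j` — fixed site effects.
* `r_jr ~ N(0, σ²_r[j])` — replicate-within-site effects; the replicate
  covariance is `Σ_r ⊗ I` with `Σ_r` diagonal per site.  Sites with a single
  replicate level have `σ²_r` pinned to zero.
* `e_ijr ~ N(0, σ²_e[j])` — heterogeneous residuals per site (`Σ_e ⊗ I`).
* `u_ij` — genotype-within-site genetic effect, the sum of one or two
  kernel terms.  Term *t* has covariance

  ```
  Cov(u_t[i,j], u_t[i',j']) = Σ_t[j,j'] · K_t[i,i']
  ```

  where `K_t` is a genomic kernel and `Σ_t = Δ_t Δ_t' + D_t` is a
  factor-analytic, FA(q), site covariance: `Δ_t` a sites×q loading matrix
  and `D_t` a diagonal of site-specific variances.

A deliberate design choice: the genotype main effect and the G×E
interaction are **not** split into separate model terms.  A common-loading
FA structure over sites absorbs the main effect (a factor with equal
loadings is exactly a main effect), and the split of one kernel's effect
into "main" and "interaction" parts with a joint FA treatment is not
identifiable.  One genotype-within-site effect per kernel term is the
standard factor-analytic MET formulation and estimates the same total
genetic value.

Model variants mirror standard practice: `FA` (identity kernel — lines
i.i.d.), `FA+G` (additive kernel), `FA+GG` (epistatic kernel), `FA+G+GG`
(both, each with its own independent FA structure; independence is the less
restrictive reading when nothing forces the two terms to share loadings).

### Kernels

The additive relationship matrix uses Hardy–Weinberg-expectation centering
of the {1, 0, −1} marker codes:

```
G_A = (X − μ_E)(X − μ_E)' / (2 Σ_j p_j (1 − p_j)),   μ_E[j] = 1 − 2 p_j
```

with `p_j` the minor-allele frequency.  With frequencies estimated from the
panel itself the centered columns sum to zero, so `G_A` always has a zero
eigenvalue; `stabilize` adds a recorded `1e-6` diagonal shift when the
minimum eigenvalue falls below `1e-8`.  The first-order additive×additive
kernel is the Hadamard square `G_A # G_A` (elementwise), positive
semidefinite by the Schur product theorem.  No rescaling of the Hadamard
product is applied (some toolkits divide by the mean diagonal); a plain
product is the definition used here, and Σ absorbs the scale anyway.
Note the HWE-based centering and denominator are applied to inbred material
exactly as defined — inbred lines then show a mean kernel diagonal near 2
rather than 1, which is expected and harmless because the FA covariance is
estimated on the kernel's own scale.

### Identifiability

`Σ = ΔΔ' + D` is invariant to rotation of Δ and, for one site, to trading
variance between Δ and D.  Constraints: for q ≥ 2, entries above the
diagonal of the first q rows of Δ are fixed at zero and the first nonzero
entry of each column is made nonnegative after fitting (an LQ rotation, which
leaves Σ unchanged); for a single-site model D is pinned (to 1e-8) and Δ
carries the variance; D has a floor of 1e-8 everywhere so Σ stays invertible.

## REML engine

The restricted likelihood is evaluated in the Harville form (constants
included):

```
−2 ℓ_R = (N − p) log 2π + log|V| + log|X' V⁻¹ X| + y' P y
```

`V` is never formed densely.  Residuals are diagonal; the genetic part acts
through the covariance `Γ` among *observed* genotype-site cells and the
replicate part through a handful of indicator columns, so `V = E + Ũ Ũ'`
with `Ũ = [Z_cell L_Γ, Z_rep diag(σ_r)]` and `L_Γ` the (jittered) Cholesky
factor of `Γ`.  The Woodbury identity and the matrix-determinant lemma
reduce every evaluation to one Cholesky of an
(n_cells + n_rep_levels)-sized matrix plus O(N·m) products.

Gradients are fully analytic.  For any covariance parameter θ,
`d(−2ℓ_R)/dθ = tr(P ∂V/∂θ) − (Py)' ∂V/∂θ (Py)`; because every ∂V/∂θ is
constant within site-pair blocks of cells, both terms collapse to
site-block aggregates of the cell-level projection matrix
`P̃ = Z_cell' P Z_cell` Hadamard-multiplied with the kernel — all computed
from the same factorization.  The gradient was verified against central
finite differences (max abs error ~1e-6 on a two-term FA(2)+FA(1) model).

Optimization is bounded L-BFGS-B on transformed parameters (log variances,
free loading entries), with seeded multi-start (default 3 restarts; the
cross-validation driver uses 1).  Phenotypes are standardized to unit
variance internally so loadings and log-variances share a scale, and
estimates are mapped back exactly afterwards.  Starting values come from
moment estimates: within-cell spread for residuals, the leading eigenpair
of the between-site covariance of cell means for Δ, its diagonal remainder
for D.  `converged` requires optimizer success *and* a projected-gradient
norm below `tol` (default 1.0 on the −2ℓ scale); non-converged fits are
returned flagged, and the cross-validation driver excludes them from
accuracy averages with a logged count.

BLUPs use the standard conditional mean `û = C Z' V̂⁻¹(y − X b̂)` where `C`
covers **all** genotype×site cells, so unobserved cells receive genuine
kernel-mediated predictions; `b̂` is the GLS estimate of the site means.

Numerical guards: Γ carries a jitter of `1e-10·var(y)`; kernels are
stabilized before use; a Cholesky failure inside optimization returns a
large objective value rather than raising, so the line search backs off.

## Marker QC and imputation

Markers are removed first when their missing fraction exceeds 0.40
(strictly), then when the minor-allele frequency — recomputed on the
survivors — is strictly below 0.05 (a marker at exactly 0.05 survives; the
rule is read literally).  Missingness is filtered before MAF because MAF
estimates on heavily missing markers are unreliable; both counts are
logged.  Imputation is mean-initialized iterative low-rank EM: fit the
leading singular subspace of the column-centered matrix, replace missing
cells with the reconstruction, repeat until the largest change is below
1e-4 (rank chosen to explain 80% of variance, capped at 20, overridable).
Imputed values stay fractional in [−1, 1] — rounding back to {1, 0, −1}
would discard dosage information — and observed calls are never altered.

## Cross-validation designs

Genotypes are shuffled once per plan (seeded) and split into 5 near-equal
folds.

* **CV1** — each fold's test genotypes are masked at *all* sites
  (new-line prediction).  With 162 lines the smallest test fold is 32
  lines against a 130-line training complement.
* **CV2** — test genotypes are masked at a designated subset of sites and
  keep their own records at the rest.  The masked subset defaults to a
  seeded rotation of ⌈s/2⌉ sites per fold; a fixed subset can be supplied.
* **CV3** — a single fold at one focal site: exactly `n_train_focal`
  genotypes (default 20) keep their focal-site records, everyone else is
  predicted there; all genotypes are fully observed at the other sites.
  The design is parameterized by the explicit training count rather than a
  fraction because the two published descriptions of the split disagree
  (10% of lines for training vs 20 of 162 in the worked example); the
  count matches the worked example.

"Observed breeding value" of a test cell is the line's replicate mean
centered by the site mean (two-stage practice; a switch returns raw
means).  When simulator truth is available the correlation against true
genetic values is reported alongside.  Accuracy is the Pearson correlation
per site and fold over test cells (at least 3 required; zero-variance
vectors reported missing), summarized as mean ± sd across folds — sd, not
standard error, and labelled as such.  A leakage guard asserts on every
fold that no masked cell's records reach the training table.

## Synthetic-data generator

The generator emulates what the analysis assumes, with ground truth kept:

* **Markers** — per marker, an allele frequency `p_j ~ U(0.05, 0.5)`; each
  line is homozygous minor (−1) with probability `p_j`, else homozygous
  major (1), flipped to heterozygous (0) with a small residual rate
  (default 0.01 — inbred lines), then masked missing at `missing_rate`.
  Independent RNG streams per component (markers, heterozygosity,
  missingness, QTL effects, specific deviations, trial noise) are derived
  from the master seed, so changing the missing rate never perturbs the
  genetic values.
* **Genetic values** — factor scores per line are linear combinations of
  causal marker codes (`n_qtl_add` additive QTL) plus products of marker
  pairs (`n_qtl_pairs_epi` epistatic QTL), standardized to exactly unit
  sample variance and zero cross-factor correlation; site values are
  `Σ_k λ_jk δ_i(k) + d_ij` with `d_ij ~ N(0, ψ_j)`, so the realized
  between-site genetic covariance equals `ΛΛ' + Ψ` up to the ψ draws.
  Epistatic values come from explicit marker-pair products, *not* from
  sampling the analysis kernel — generator and analysis stay independent,
  avoiding circular validation.  The additive/epistatic decomposition of
  the total is exact; the marker-free specific deviation `d` is counted
  with the additive component and also exposed separately.
* **Trial** — `y = site_mean_j + rep_jr + g_ij + e_ijr`, replicate effects
  drawn once per (site, replicate), residuals per plot.  Alpha-lattice
  incomplete blocks are not simulated — the analysis model contains no
  block term, so the generator produces exactly what the model can absorb.

Defaults mirror one target population of environments: 162 lines, 1000
SNPs, 6 sites, 2 replicates, site means 4.5–5.9 t/ha, per-site genetic
variance ≈ 0.12 (genetic CV ≈ 6%), replicate variance 0.02, plot residual
0.12 — a line-mean heritability near 0.6.  The plot-variance magnitudes are
configuration defaults chosen as typical for irrigated South-Asian wheat
yield trials, not claims about any particular dataset.

What the generator does **not** emulate: linkage/LD along chromosomes,
family or pedigree relatedness among lines (lines are exchangeable draws),
dominance, higher-order epistasis, incomplete blocks, year effects.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative behaviour of the designs, not the accuracy levels reachable on
real breeding panels, where kinship structure substantially lifts CV1
accuracy.

## Choices for the validation studies

Problem sizes for the stochastic suites are the package's own test design
(stated here so they are not mistaken for claims):

* Site-covariance recovery: 300 lines × 4 sites, FA(1) truth, median of
  fitted correlation matrices over 3 seeds, tolerance ±0.15 elementwise.
  Because the generator standardizes factor scores across lines exactly,
  the identity-kernel FA fit is the correctly specified estimator for this
  check; a marker-kernel fit recovers the same correlations more noisily.
* Null recovery: 150 lines × 3 sites, zero loadings and ψ; the mean (over
  6–10 seeds) of `max|Σ̂|/σ²_e` must stay below 0.1.
* Likelihood ordering of the model variants: the `FA` and `FA+G` models are
  not nested (identity vs marker kernel), so their ranking is an empirical
  expectation, not a theorem; on sparse-QTL panels with many markers the
  two kernels are nearly indistinguishable and the ordering can flip by a
  couple of log-likelihood units.  The ordering check therefore uses a
  dense polygenic architecture on a compact panel (100 lines, 120 markers,
  all causal), where the realized genetic covariance is close to `G_A` and
  `FA+G` wins decisively; `FA+G ≤ FA+G+GG` is a true nesting and holds
  everywhere.
* Cross-validation properties: 90 lines × 4 sites × 500 SNPs at
  heritability ≈ 0.6, 5-fold, 5 seeds: CV2 must beat CV1 by > 0.05 mean
  accuracy; the additive and additive+epistatic models must agree within
  0.05; null trials (160 lines, zero signal) must give per-site mean
  accuracies within ±0.12 of zero.
* `scripts/acceptance.py` recomputes all of the above (3 seeds for the
  CV block) plus the fold arithmetic and the kernel/REML diagnostics,
  deriving every stream from `--seed`.

## Known limitations

* Two kernel terms at most; no dominance kernel, no spatial row-column
  models, no environmental-covariate kernels.
* Variance-component standard errors are not computed (point estimates and
  the REML log-likelihood only); no AIC tables.
* The FA order q is a configuration choice (default 1); with s sites only
  q ≤ s is accepted, and small trials (3 sites) support little beyond q=1.
* The EM imputer assumes an approximately low-rank panel; on unstructured
  noise it hits the iteration cap and returns with a warning, which is
  expected behaviour rather than failure.
* REML evaluation scales with the cube of the number of observed
  genotype-site cells (~n·s); panels beyond a few thousand cells per fit
  call for a dedicated average-information implementation.
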