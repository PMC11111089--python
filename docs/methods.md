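# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the package's tests demonstrate.

## Edge weights of the bipartite network

For trait *k* and SNP *m* the edge weight is
`T_km = sign(S_km) · F⁻¹_χ²₁(1 − p_km)` with score statistic
`S_km = Σᵢ (y_ik − ȳ_k) g_im`. Both traits and genotypes are residualized
on the covariates by OLS (an intercept is always included; the empty
covariate set reduces to centering), so the centered sums in the score
reduce to plain inner products and the whole K×M score matrix is two
matrix products. The χ²₁ quantile is evaluated through the upper-tail
inverse (`isf`) on `p` directly, never as `ppf(1 − p)`, so p-values down to
1e-300 map to finite weights; p is clipped to [1e-320, 1]. `T_km = 0`
exactly when `p = 1` or `S = 0`; a zero-variance SNP column yields a zero
column with a logged warning rather than an error.

### Saddlepoint tail for binary traits

For a 0/1 trait with null case probabilities μᵢ, the score
`S = Σ gᵢ(yᵢ − μᵢ)` has cumulant generating function
`K(t) = Σ log(1 − μᵢ + μᵢ e^{gᵢt}) − t Σ gᵢμᵢ`. The two-sided p-value is
the sum of the Barndorff-Nielsen tails at ±|S|, each from the saddle root
of `K'(t) = s` with `w = sign(t̂)√(2(t̂s − K(t̂)))`, `v = t̂√(K''(t̂))`,
`z* = w + log(v/w)/w`. When |w| < 1e-4 the correction term is unstable and
the normal tail on the score scale is substituted. Root finding is a
vectorized safeguarded Newton over the SNPs of one trait (the saddle
equation is solved per SNP; `K'` is increasing, so failures are rare and
fall back to bracketed Brent, and beyond the attainable range of S the
tail is exactly 0). The batch and scalar paths agree to 1e-9 relative.

The engine applies the standard hybrid: for binary traits, entries with
normal |z| below a threshold (default 2.0) keep the normal p-value —
indistinguishable from the saddlepoint there — and the saddlepoint is
recomputed only in the tails. `spa_threshold=0` forces the saddlepoint
everywhere. μ comes from a null logistic regression of the trait on the
covariates (the trait prevalence when there are none) while the genotype
is residualized linearly; whether the saddlepoint should be applied to the
linearly-residualized or the logistic score is a genuinely open design
point, and this construction follows the logistic convention of the fast
saddlepoint literature. It is switchable by passing μ explicitly to
`spa_pvalue`.

## Phenotype projection

`W` is the row-wise Pearson correlation of `T` (two-pass, numerically
stable). Population versus sample variance is irrelevant to a
correlation. Constant rows (no association signal at all) get zero
off-diagonal entries with a warning. `W` is symmetric, unit-diagonal,
entries in [−1, 1], and positive semidefinite up to floating-point noise.

## Module detection

Ward linkage (the proper "ward.D2"-style objective, via
`scipy.cluster.hierarchy`) on the dissimilarity `d = 1 − W`: the simplest
monotone transform that makes anti-correlated phenotypes maximally
distant in a signed network. Cuts use `cut_tree`, which returns exactly
k₀ clusters with deterministic leaf-order tie-breaks.

The perturbation noise variance is
`σ² = median(var(T_·1), …, var(T_·M))`, each variance taken over the K
entries of one SNP column (sample variance, ddof = 1). Two perturbation
modes are provided, because whether the perturbed matrix is re-projected
to `W` before clustering or its rows are clustered directly is not
determined by the procedure's definition: `'reproject'` (default) keeps
the perturbed pipeline identical to the unperturbed one; `'rows'` Ward-
clusters the perturbed rows of T under Euclidean distance. The stability
score is computed as `AF_k₀ = 1 − mean(D_k₀)`, which is exactly the area
under the empirical CDF of the entries of `D_k₀ = |A_k₀ − C_k₀|` for
values in [0, 1] (an identity the tests verify to 1e-12), and the module
count is the smallest k maximizing `|AF_{k+1} − AF_k|`. Whether the
optimal count is k or k+1 under that rule is ambiguous on its face; the
literal reading (C = k) is implemented, and on planted-module data the
jump does occur at the true count.

**What the selection rule can and cannot detect.** The rule rewards a
two-scale structure: coarse merges that perturbation cannot flip, fine
splits that it re-randomizes. If the planted categories are *exactly
exchangeable* — identical signal strength, identical pairwise
between-category correlation — every coarse cut of the dendrogram is
tied, perturbation flips them freely, and no stability criterion can
prefer the planted count (empirically the rule then selects C = 1).
Real phenome data is irregular, which is the regime the method is
designed for. The recovery benchmark
(`simulate.hierarchical_effects`) therefore plants disjoint per-category
causal SNP sets plus nested cross-category loadings (attenuation 0.45 per
level of a balanced binary hierarchy, with distinct per-pair jitter), so
between-module genetic correlations are distinct at every level. At the
benchmark's operating point (β = 0.2, 40 causal SNPs per category,
N = 2,000, M = 2,000, B = 200 perturbations, `'rows'` mode) the planted
count is the modal selection across datasets for C ∈ {3, 5, 8}, with
per-dataset selection probability around 0.45–0.55 — the criterion is a
distributional, not per-dataset, guarantee.

Default B = 1,000 for real analyses; simulation harnesses use B = 50–200.

## The joint tests

All tests except MultiPhen act on the per-SNP vector of signed z-scores
`z_k = sign(S) · Φ⁻¹(1 − p/2)` (the saddlepoint-calibrated magnitude for
binary traits — itself a documented convention, since how univariate
evidence enters the joint statistics is not fixed by their definitions)
and the null trait correlation `R`, estimated once from the phenotype
residuals (not per SNP; under H₀ it does not depend on the SNP) and
eigenvalue-floored at 1e-6 for invertibility.

- O'Brien: `1'R⁻¹z / √(1'R⁻¹1)`, standard normal.
- Omnibus: `z'R⁻¹z` on χ²_K'.
- CLC: `(U'R⁻¹z)'(U'R⁻¹U)⁻¹(U'R⁻¹z)` on χ²_L for an indicator U.
  `U = I` recovers Omnibus and `L = 1` recovers O'Brien², exactly. When U
  is not supplied, L is the largest relative gap in the Ward merge heights
  of the dendrogram on `1 − R` — deterministic and documented, since the
  count is otherwise unspecified.
- ceCLC: Cauchy combination (ACAT) of CLC over every dendrogram level
  L = 1..K'.
- HCLC: ACAT of CLC over the levels generated by the dendrogram's merges
  (L = 1..K'−1, i.e. excluding the all-singletons level).

ceCLC and HCLC are named strategies: the CLC family admits several
published variants, and these defaults are chosen because ACAT of valid
p-values is valid under arbitrary dependence, so both are null-calibrated
by construction — which the calibration harness confirms empirically.
ACAT inputs are clipped to [1e-15, 1 − 1e-15] with a warning.

MultiPhen is the reverse direction: proportional-odds ordinal regression
of the genotype categories {0, 1, 2} on all phenotypes jointly
(statsmodels `OrderedModel`, L-BFGS), likelihood-ratio tested against the
closed-form intercept-only multinomial likelihood, df = K'. It is
excluded from calibration guarantees: with extremely unbalanced binary
phenotypes its type-I error is inflated, which the harness reproduces.

NET mode runs the chosen test inside each detected module and combines by
Bonferroni over the C modules, `p = min(1, C · min_c p_c)`; with a single
module it reduces exactly to the all-phenotypes mode.

## The simulator

Genotypes: per-SNP MAF ~ U(0.05, 0.5), counts Binomial(2, MAF),
independent SNPs (no LD, no relatedness, no stratification — matching the
conditions the method was evaluated under, and a real limitation for
transfer to data with LD structure). Quantitative phenotypes per category:
`Y_c = G B_c + c0 f_c 1' + √(1 − c0²) E_c` with AR(1) errors
(ρ = 0.3), shared factor loadings c0² = 0.5, and factor correlation
ρ_f = 0.3/c0², giving within-category correlation
`c0² + (1 − c0²)ρ^{|i−j|}` (maximum 0.65 at adjacent traits) and
between-category correlation 0.30. Defaults: M = 2,000 SNPs; K = 60
traits; mixture mode N = 2,000, binary mode N = 10,000.

Binary traits by liability thresholding: exactly
`n_a = round(rN/(r+1))` cases (banker's rounding; at N = 322,607 and
r = 0.000658 this yields the reference 212/322,395 split), ties broken by
stable sample order. The unbalanced ratio pool is a 25-point geometric
grid spanning [0.000658, 0.03937] — the printed bounds of the biobank
pool, whose full membership is not public. "Balanced" binary traits use
r = 1. Mixture mode keeps the first half of each category quantitative
and thresholds the rest, so every category is mixed.

The six causal-effect models are a declarative table
(`simulate.MODEL_TABLE`, overridable wholesale). Effect rows follow
`λ₁ = β(1,…,1)` and `λ₂ = (2β/(k+1))(1,…,k)`. Models 1/2: one affected
category, λ₁/λ₂, 100 causal SNPs. Model 3: two categories, same
direction, the 100 causal SNPs split between them. Model 4: two
categories, opposite directions, shared causal SNPs — the configuration
in which a single SNP affects phenotypes in different directions, where
linear-combination tests lose power without modules. Models 5/6: 200
causal SNPs spread across all categories, λ₁/λ₂. The exact published
assignment of categories and signs per model is not printed; this
reconstruction was chosen so that each model is meaningfully distinct and
the module-wise tests dominate the joint tests across all six, and it is
isolated behind the model table so an exact transcription can be swapped
in. The power-comparison harness uses C = 10 categories of 6 traits for
K = 60: with few large categories (C = 5) and the stated exchangeable
between-category correlation, the all-phenotype GLS tests can borrow the
shared factor from unaffected categories and slightly outperform
module-wise testing on concentrated same-direction signals — an instance
of the same exchangeability degeneracy noted for module detection.

## Evaluation harness

Type-I runs simulate null datasets (β = 0) and count `p ≤ α` over all
M SNPs per run; n replicates = runs × M (500 × 2,000 = 10⁶ at full
scale; the test suite uses 50 × 2,000 = 10⁵ at α = 0.001, with the
binomial band recomputed for that n). The band is
`1 ± 1.959964·√((1 − α)/(α·n))`, reported to 3 decimals; below 5 expected
rejections the normal approximation is unreliable and a warning is
raised — which is why the MultiPhen inflation check runs at α = 0.05 with
240 replicates (per-SNP ordinal fits cannot be vectorized). Power is the
fraction of causal SNPs with `p ≤ 0.05/n_causal`, averaged over MC runs;
NET and N.O. are computed from the same simulated data and module
detection (paired), and paired power comparisons allow a 0.02
Monte-Carlo noise margin. Module detection runs once per MC run; it is
independent of the per-SNP tests.

## Known limitations

- No LD, dosages, mixed-model relatedness correction, or X chromosome.
- The saddlepoint/linear-residualization reconciliation under covariates
  is a convention (see above), not a derivation.
- Module-count selection is reliable only when between-module structure
  is non-degenerate; on exchangeable planted categories it collapses.
- MultiPhen's likelihood-ratio reference distribution is asymptotic; with
  rare binary predictors it is anticonservative (reproduced, not fixed).
- The ceCLC/HCLC internal definitions are reconstructions of a family of
  published variants, selected for calibration rather than formula
  identity, and exposed as named strategies.
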