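# gpn — genotype-and-phenotype network analysis for multi-trait GWAS

`gpn` implements a network-based approach to jointly analysing many
correlated phenotypes in a genome-wide association study. It is aimed at
statistical geneticists working with biobank-style data: dozens of traits,
many of them binary diagnoses with extremely unbalanced case–control ratios
(down to a few hundred cases among hundreds of thousands of controls),
where single-trait tests are underpowered and naive multi-trait tests are
miscalibrated.

## The method

**1. Signed bipartite network (GPN).** For each trait *k* and SNP *m* the
association strength is

```
T_km = sign(S_km) · F⁻¹_χ²₁(1 − p_km)
```

where `S_km = Σᵢ (y_ik − ȳ_k) g_im` is the score statistic after linear
covariate residualization of both trait and genotype, and `p_km` its
two-sided p-value — from the normal approximation
`S ~ N(0, Σ(y−ȳ)²·Σ(g−ḡ)²/n)` for quantitative traits, or from a
saddlepoint approximation to the score distribution for binary traits,
which stays accurate deep in the tails where the normal approximation
inflates type-I error under case–control imbalance. A positive edge means
the minor allele is protective. The same matrix can be assembled from GWAS
summary statistics (per-pair effect direction + p-value); individual-level
data are not required.

**2. Phenotype projection (PPN).** `W_kl` is the Pearson correlation of
rows *k* and *l* of `T` across the M SNPs — a signed genetic-correlation
network over phenotypes.

**3. Network modules.** Phenotypes are partitioned by Ward clustering on
`1 − W`. The number of modules C is chosen by perturbation stability:
B noisy copies `T + N(0, σ²)` (σ² = median per-SNP-column variance of T)
are re-clustered at every candidate count k₀; the stability score
`AF_k₀ = 1 − mean|A_k₀ − C_k₀|` compares the average perturbed
co-membership matrix with the unperturbed one, and C maximizes the jump
`|AF_{k+1} − AF_k|`.

**4. Module-wise tests.** Per SNP, multi-phenotype tests (O'Brien, Omnibus,
CLC, ceCLC, HCLC, MultiPhen) run inside each module on the vector of
signed, saddlepoint-calibrated z-scores; the per-module p-values are
Bonferroni-combined: `p = min(1, C · min_c p_c)` ("NET" mode, versus the
all-phenotypes "N.O." mode).

A factor-model simulator (AR(1) within-category errors, a shared
between-category factor, Binomial(2, MAF) genotypes, liability-threshold
binary traits) and a Monte-Carlo type-I/power harness reproduce the study
conditions the method was evaluated under.

## Worked example

```python
import numpy as np
from gpn import GPN, ModuleDetector, batch_test, estimate_R
from gpn.simulate import simulate_planted_modules

data = simulate_planted_modules(C=3, k=8, beta=0.5, N=600, M=600, seed=4)
net = GPN(engine="normal").fit(data.genotypes, data.phenotypes)
det = ModuleDetector(n_perturb=200, random_state=0, perturb_mode="rows").fit(net.T_)
print("modules:", det.n_modules_, "labels:", det.labels_)

z = net.T_.zscores().T
R = estimate_R(data.phenotypes.values - data.phenotypes.values.mean(0))
p_net = batch_test(z[data.causal_snps], R, labels=det.labels_, tests=("ceclc",))
p_no = batch_test(z[data.causal_snps], R, tests=("ceclc",))
print("NET hits:", int((p_net["ceclc"] < 5e-4).sum()),
      " NO hits:", int((p_no["ceclc"] < 5e-4).sum()),
      "of", len(data.causal_snps))
```

prints

```
modules: 3 labels: [0 0 0 0 0 0 0 0 1 1 1 1 1 1 1 1 2 2 2 2 2 2 2 2]
NET hits: 32  NO hits: 25 of 120
```

— the detector recovers the three planted trait categories from the
genetic network alone, and at a stringent Bonferroni-style threshold the
module-wise ("NET") Cauchy-combined CLC test flags more of the planted
causal SNPs than the same test run jointly on all 24 traits ("N.O.").

The same pipeline is available from the shell:

```sh
gpn simulate --model 1 --beta 0.3 --n 600 --m 600 --k 24 --c 3 --out-prefix sim/
gpn build --geno sim/genotypes.tsv --geno-dialect tsv --pheno sim/phenotypes.tsv --out T.tsv
gpn project --t T.tsv --out W.tsv
gpn --seed 1 modules --t T.tsv --b 1000 --out modules.tsv
gpn test --geno sim/genotypes.tsv --geno-dialect tsv --pheno sim/phenotypes.tsv \
    --modules modules.tsv --tests ceclc,omnibus --mode net --out results.tsv
```

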