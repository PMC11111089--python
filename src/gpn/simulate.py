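"""Factor-model phenotype simulator with planted category structure.

Genotypes are independent SNPs, counts ~ Binomial(2, MAF) with
MAF ~ U(0.05, 0.5) (Hardy-Weinberg).  Quantitative phenotypes come from the
factor model, per category ``c`` of ``k = K/C`` traits:

    Y_c = G B_c + c0 * f_c 1_k' + sqrt(1 - c0^2) * E_c,

with AR(1) within-category errors (rows of E_c ~ MVN(0, Sigma),
Sigma_ij = rho^|i-j|), an exchangeable shared factor across categories
(f ~ MVN(0, (1 - rho_f) I + rho_f J) per individual), and SNP effects B_c.
Under the null (B = 0) the implied phenotype correlation is
``c0^2 + (1 - c0^2) rho^|i-j|`` within a category and ``c0^2 rho_f``
between categories.  The defaults rho = 0.3, c0^2 = 0.5,
rho_f = 0.3 / c0^2 put the maximum within-category correlation at 0.65 and
the between-category correlation at 0.30.

Binary traits are made by liability thresholding: for a case-control ratio
``r`` the top ``n_a = r N / (r + 1)`` liabilities are cases.  The unbalanced
ratio pool spans [0.000658, 0.03937] (biobank-style extreme imbalance);
"balanced" binary traits use r = 1.

Six causal-effect models are encoded declaratively; effect rows follow the
two patterns ``lambda1 = beta * (1, ..., 1)`` and
``lambda2 = (2 beta / (k+1)) * (1, ..., k)``.  Models 1/2 load one category
(lambda1 / lambda2); model 3 loads two categories in the same direction
with the causal SNPs split between them; model 4 loads two categories in
opposite directions with shared causal SNPs (each causal SNP is protective
for one category and a risk factor for the other); models 5/6 spread twice
as many causal SNPs across all categories (lambda1 / lambda2).  The table
is a plain mapping and can be overridden wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import (
    BINARY,
    QUANTITATIVE,
    GenotypeDataset,
    PhenotypeDataset,
    SimulatedDataset,
)

#: printed bounds of the biobank case-control-ratio pool; the default pool is
#: a geometric grid spanning them.
RATIO_BOUNDS = (0.000658, 0.03937)
DEFAULT_RATIO_POOL = tuple(np.geomspace(*RATIO_BOUNDS, num=25))


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one causal-effect model."""

    n_causal: int
    pattern: str  # 'lambda1' or 'lambda2'
    categories: tuple[int, ...]  # affected categories (indices; empty = all)
    signs: tuple[int, ...] = ()  # per affected category; default all +1
    split_across: bool = False  # split causal SNPs across the categories


#: The six standard models.  Overridable by a user-supplied mapping.
MODEL_TABLE: dict[int, ModelSpec] = {
    1: ModelSpec(100, "lambda1", (0,)),
    2: ModelSpec(100, "lambda2", (0,)),
    3: ModelSpec(100, "lambda1", (0, 1), (1, 1), split_across=True),
    4: ModelSpec(100, "lambda1", (0, 1), (1, -1)),
    5: ModelSpec(200, "lambda1", (), split_across=True),
    6: ModelSpec(200, "lambda2", (), split_across=True),
}


@dataclass
class FactorModelConfig:
    """Study conditions for one simulated dataset."""

    N: int = 2000
    M: int = 2000
    K: int = 60
    C: int = 5
    c0_sq: float = 0.5
    rho: float = 0.3
    rho_f: float = None  # defaults to 0.3 / c0_sq
    maf_low: float = 0.05
    maf_high: float = 0.5
    model_id: int = 1
    beta: float = 0.0
    mode: str = "quantitative"  # 'quantitative' | 'mixture' | 'binary'
    ratio_pool: tuple = DEFAULT_RATIO_POOL
    model_table: dict = field(default_factory=lambda: MODEL_TABLE)

    def __post_init__(self) -> None:
        if self.rho_f is None:
            self.rho_f = 0.3 / self.c0_sq if self.c0_sq > 0 else 0.0
        if self.K % self.C != 0:
            raise ValueError("K must be a multiple of C (equal-size categories)")
        if not (0.0 <= self.c0_sq < 1.0):
            raise ValueError("c0^2 must lie in [0, 1)")
        if not (0.0 <= self.rho < 1.0 and 0.0 <= self.rho_f * self.c0_sq < 1.0):
            raise ValueError("correlation parameters out of range")

    @property
    def k_per_category(self) -> int:
        return self.K // self.C


def within_category_correlation(lag: int, c0_sq: float = 0.5, rho: float = 0.3) -> float:
    """Closed-form null correlation of two traits ``lag`` apart in a category."""
    return c0_sq + (1.0 - c0_sq) * rho**lag


def between_category_correlation(c0_sq: float = 0.5, rho_f: float = 0.6) -> float:
    """Closed-form null correlation of traits in different categories."""
    return c0_sq * rho_f


def gen_genotypes(N, M, maf_low=0.05, maf_high=0.5, seed=None):
    """Independent HWE genotypes: per-SNP MAF ~ U(maf_low, maf_high),
    counts ~ Binomial(2, MAF).  Returns (GenotypeDataset, drawn MAF)."""
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_low, maf_high, size=M)
    counts = rng.binomial(2, maf, size=(N, M)).astype(float)
    width = len(str(M))
    ds = GenotypeDataset(
        [f"s{i}" for i in range(N)],
        [f"snp{j:0{width}d}" for j in range(M)],
        counts,
    )
    return ds, maf


def effect_matrix(model_id, beta, C, k, M, seed=None, model_table=None):
    """Per-model SNP effect matrix B (M x K) and the causal SNP indices."""
    table = model_table or MODEL_TABLE
    if model_id not in table:
        raise ValueError(f"unknown model id {model_id!r}")
    spec = table[model_id]
    if spec.n_causal > M:
        raise ValueError("more causal SNPs requested than SNPs simulated")
    rng = np.random.default_rng(seed)
    causal = np.sort(rng.choice(M, size=spec.n_causal, replace=False))
    if spec.pattern == "lambda1":
        row = beta * np.ones(k)
    elif spec.pattern == "lambda2":
        row = (2.0 * beta / (k + 1)) * np.arange(1, k + 1)
    else:
        raise ValueError(f"unknown effect pattern {spec.pattern!r}")
    b = np.zeros((M, C * k))
    cats = spec.categories if spec.categories else tuple(range(C))
    signs = spec.signs if spec.signs else tuple(1 for _ in cats)
    if spec.split_across:
        chunks = np.array_split(causal, len(cats))
        for chunk, cat, sgn in zip(chunks, cats, signs):
            b[np.ix_(chunk, np.arange(cat * k, (cat + 1) * k))] = sgn * row
    else:
        for cat, sgn in zip(cats, signs):
            b[np.ix_(causal, np.arange(cat * k, (cat + 1) * k))] = sgn * row
    return b, causal


def gen_quantitative(config: FactorModelConfig, G: np.ndarray, B: np.ndarray, seed=None):
    """Draw the factor-model phenotype matrix Y (N x K)."""
    rng = np.random.default_rng(seed)
    N, C, k = config.N, config.C, config.k_per_category
    c0 = np.sqrt(config.c0_sq)
    # AR(1) error covariance within a category
    idx = np.arange(k)
    sigma = config.rho ** np.abs(idx[:, None] - idx[None, :])
    chol_e = np.linalg.cholesky(sigma)
    sigma_f = (1.0 - config.rho_f) * np.eye(C) + config.rho_f * np.ones((C, C))
    vals = np.linalg.eigvalsh(sigma_f)
    if vals.min() < -1e-10:
        raise ValueError("factor covariance Sigma_f is not positive semidefinite")
    chol_f = np.linalg.cholesky(sigma_f + 1e-12 * np.eye(C))
    f = rng.standard_normal((N, C)) @ chol_f.T
    y = np.empty((N, C * k))
    for c in range(C):
        e = rng.standard_normal((N, k)) @ chol_e.T
        cols = slice(c * k, (c + 1) * k)
        y[:, cols] = G @ B[:, cols] + c0 * f[:, [c]] + np.sqrt(1.0 - config.c0_sq) * e
    return y


def _tree_join_depth(c1: int, c2: int) -> int:
    d = 0
    while c1 != c2:
        c1 //= 2
        c2 //= 2
        d += 1
    return d


def hierarchical_effects(
    C: int,
    k: int,
    M: int,
    beta: float,
    n_causal_per_category: int = 40,
    seed=None,
    base: float = 0.45,
    jitter: tuple[float, float] = (0.85, 1.15),
):
    """Effect matrix with nested cross-category pleiotropy for module-recovery
    benchmarks.

    Each category owns a disjoint causal SNP set; a category's causal SNPs
    also load every other category, attenuated by ``base ** d`` where ``d``
    is the categories' join depth in a balanced binary hierarchy, with a
    per-pair multiplicative jitter.  This plants C genetically coherent
    modules whose between-module genetic correlations are distinct at every
    level — the irregular, nested structure real phenome data shows, and the
    regime the perturbation-stability selection of the module count is
    designed for.  (With perfectly exchangeable categories every coarse cut
    of the dendrogram is tied, and no stability criterion can prefer one.)

    Returns ``(B, causal)`` like :func:`effect_matrix`.
    """
    rng = np.random.default_rng(seed)
    load = np.eye(C)
    for a in range(C):
        for b in range(a + 1, C):
            d = _tree_join_depth(a, b)
            load[a, b] = load[b, a] = base**d * rng.uniform(*jitter)
    b_mat = np.zeros((M, C * k))
    causal = np.sort(rng.choice(M, size=n_causal_per_category * C, replace=False))
    order = rng.permutation(causal)
    for c, snps in enumerate(np.array_split(order, C)):
        for c2 in range(C):
            b_mat[np.ix_(snps, np.arange(c2 * k, (c2 + 1) * k))] += beta * load[c, c2]
    return b_mat, causal


def simulate_planted_modules(
    C: int,
    k: int,
    beta: float = 0.25,
    N: int = 2000,
    M: int = 2000,
    n_causal_per_category: int = 40,
    seed=None,
) -> SimulatedDataset:
    """Quantitative factor-model dataset with C planted genetic modules."""
    cfg = FactorModelConfig(N=N, M=M, K=C * k, C=C, beta=0.0, mode="quantitative")
    rng = np.random.default_rng(seed)
    geno, maf = gen_genotypes(N, M, seed=int(rng.integers(2**31 - 1)))
    b_mat, causal = hierarchical_effects(
        C, k, M, beta, n_causal_per_category, seed=int(rng.integers(2**31 - 1))
    )
    y = gen_quantitative(cfg, geno.counts, b_mat, int(rng.integers(2**31 - 1)))
    width = len(str(C * k))
    pheno = PhenotypeDataset(
        list(geno.sample_ids),
        [f"trait{j:0{width}d}" for j in range(C * k)],
        y,
        [QUANTITATIVE] * (C * k),
    )
    return SimulatedDataset(
        genotypes=geno,
        phenotypes=pheno,
        categories=np.repeat(np.arange(C), k),
        causal_snps=causal,
        effects=b_mat,
        liability=y,
        true_maf=maf,
    )


def dichotomize(y: np.ndarray, r: float) -> np.ndarray:
    """Liability thresholding: the top ``n_a = round(r N / (r+1))`` values are
    cases (ties broken by stable sample order)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    n_a = int(round(r * n / (r + 1.0)))
    if n_a == 0:
        raise ValueError(f"case-control ratio {r} yields zero cases at N={n}")
    if n_a >= n:
        raise ValueError(f"case-control ratio {r} yields zero controls at N={n}")
    order = np.argsort(-y, kind="stable")
    out = np.zeros(n)
    out[order[:n_a]] = 1.0
    return out


def sample_ratio(pool=DEFAULT_RATIO_POOL, seed=None) -> float:
    """Uniform draw of a case-control ratio from the configured pool."""
    rng = np.random.default_rng(seed)
    return float(rng.choice(np.asarray(pool, dtype=float)))


def simulate_dataset(config: FactorModelConfig, seed=None) -> SimulatedDataset:
    """Generate one dataset under the configured study conditions.

    'mixture' mode keeps the first half of each category quantitative and
    liability-thresholds the rest at the balanced ratio r = 1; 'binary' mode
    thresholds every trait at a ratio drawn from the unbalanced pool.
    """
    rng = np.random.default_rng(seed)
    geno_seed, b_seed, y_seed, r_seed = rng.integers(0, 2**31 - 1, size=4)
    geno, maf = gen_genotypes(config.N, config.M, config.maf_low, config.maf_high, geno_seed)
    if config.beta != 0.0:
        b, causal = effect_matrix(
            config.model_id, config.beta, config.C, config.k_per_category,
            config.M, b_seed, config.model_table,
        )
    else:
        b = np.zeros((config.M, config.K))
        causal = np.array([], dtype=int)
    liability = gen_quantitative(config, geno.counts, b, y_seed)
    values = liability.copy()
    kinds = [QUANTITATIVE] * config.K
    ratio_rng = np.random.default_rng(r_seed)
    k = config.k_per_category
    if config.mode == "mixture":
        for c in range(config.C):
            for j in range(c * k + (k + 1) // 2, (c + 1) * k):
                values[:, j] = dichotomize(liability[:, j], 1.0)
                kinds[j] = BINARY
    elif config.mode == "binary":
        pool = np.asarray(config.ratio_pool, dtype=float)
        for j in range(config.K):
            r = float(ratio_rng.choice(pool))
            values[:, j] = dichotomize(liability[:, j], r)
            kinds[j] = BINARY
    elif config.mode != "quantitative":
        raise ValueError(f"unknown simulation mode {config.mode!r}")
    width = len(str(config.K))
    pheno = PhenotypeDataset(
        list(geno.sample_ids),
        [f"trait{j:0{width}d}" for j in range(config.K)],
        values,
        kinds,
    )
    categories = np.repeat(np.arange(config.C), k)
    return SimulatedDataset(
        genotypes=geno,
        phenotypes=pheno,
        categories=categories,
        causal_snps=causal,
        effects=b,
        liability=liability,
        true_maf=maf,
    )
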