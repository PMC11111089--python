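"""Core in-memory containers for the GPN pipeline.

The pipeline moves through a fixed sequence of artifacts: individual-level
genotype/phenotype/covariate tables (or a summary-statistics table), the
signed bipartite phenotype-SNP association matrix ``T``, its one-mode
projection ``W`` onto phenotypes (a signed genetic-correlation network), a
partition of phenotypes into network modules, and per-SNP test reports.
Each container is a light dataclass around numpy arrays with identifier
bookkeeping; heavy computation lives in the sibling modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

QUANTITATIVE = "quantitative"
BINARY = "binary"


def _as_ids(ids: Sequence[str]) -> list[str]:
    out = [str(i) for i in ids]
    if len(set(out)) != len(out):
        raise ValueError("identifiers must be unique")
    return out


@dataclass
class GenotypeDataset:
    """Minor-allele count matrix for ``n`` samples at ``M`` SNPs.

    ``counts`` is ``n x M`` float with entries in {0, 1, 2} and NaN for
    missing calls.  Counts are oriented so that they count minor alleles
    (columns with allele frequency above 0.5 are flipped ``c -> 2 - c`` at
    read time).
    """

    sample_ids: list[str]
    snp_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _as_ids(self.sample_ids)
        self.snp_ids = _as_ids(self.snp_ids)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n, m = self.counts.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError("counts shape does not match identifiers")
        if n < 2 or m < 1:
            raise ValueError("need at least 2 samples and 1 SNP")
        finite = self.counts[~np.isnan(self.counts)]
        if not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype counts must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency from non-missing calls."""
        return np.nanmean(self.counts, axis=0) / 2.0

    def mean_imputed(self) -> np.ndarray:
        """Counts with missing calls replaced by the per-SNP mean."""
        x = self.counts.copy()
        col_mean = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x[idx] = col_mean[idx[1]]
        return x


@dataclass
class PhenotypeDataset:
    """``n x K`` phenotype matrix with per-trait kind flags.

    Binary traits are coded 0/1 before any residualization;
    ``case_control_ratio`` holds cases/controls per binary trait (NaN for
    quantitative traits).
    """

    sample_ids: list[str]
    trait_ids: list[str]
    values: np.ndarray
    trait_kind: list[str]
    case_control_ratio: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.sample_ids = _as_ids(self.sample_ids)
        self.trait_ids = _as_ids(self.trait_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("phenotype values must be a 2-D matrix")
        n, k = self.values.shape
        if n != len(self.sample_ids) or k != len(self.trait_ids):
            raise ValueError("values shape does not match identifiers")
        if k < 1:
            raise ValueError("need at least one trait")
        if len(self.trait_kind) != k:
            raise ValueError("trait_kind must have one entry per trait")
        for kind in self.trait_kind:
            if kind not in (QUANTITATIVE, BINARY):
                raise ValueError(f"unknown trait kind {kind!r}")
        ratios = np.full(k, np.nan)
        for j, kind in enumerate(self.trait_kind):
            col = self.values[:, j]
            col = col[~np.isnan(col)]
            if kind == BINARY:
                if not np.isin(col, (0.0, 1.0)).all():
                    raise ValueError(
                        f"binary trait {self.trait_ids[j]!r} has values outside {{0,1}}"
                    )
                n1 = float((col == 1).sum())
                n0 = float((col == 0).sum())
                ratios[j] = n1 / n0 if n0 > 0 else np.inf
        if self.case_control_ratio is None:
            self.case_control_ratio = ratios
        else:
            self.case_control_ratio = np.asarray(self.case_control_ratio, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def is_binary(self) -> np.ndarray:
        return np.array([k == BINARY for k in self.trait_kind])


@dataclass
class CovariateDataset:
    """``n x p`` covariate matrix (no intercept column; one is added by fits)."""

    sample_ids: list[str]
    covariate_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _as_ids(self.sample_ids)
        self.covariate_ids = _as_ids(self.covariate_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.covariate_ids)):
            raise ValueError("covariate shape does not match identifiers")


@dataclass
class AssociationStrengthMatrix:
    """Signed bipartite GPN adjacency.

    ``T[k, m] = sign(S_km) * Q_chi2_1(1 - p_km)`` links trait ``k`` to SNP
    ``m``; a positive weight means the minor allele is protective for the
    trait, a negative weight that it is a risk allele.
    """

    T: np.ndarray
    signs: np.ndarray
    pvals: np.ndarray
    trait_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.signs = np.asarray(self.signs)
        self.pvals = np.asarray(self.pvals, dtype=float)
        k, m = self.T.shape
        if self.signs.shape != (k, m) or self.pvals.shape != (k, m):
            raise ValueError("signs/pvals must match T's shape")
        if len(self.trait_ids) != k or len(self.snp_ids) != m:
            raise ValueError("identifier lengths must match T's shape")

    @property
    def n_traits(self) -> int:
        return self.T.shape[0]

    @property
    def n_snps(self) -> int:
        return self.T.shape[1]

    def zscores(self) -> np.ndarray:
        """Signed per-edge z-scores ``sign * Phi^-1(1 - p/2)``."""
        from scipy.stats import norm

        z = norm.isf(np.clip(self.pvals, 1e-320, 1.0) / 2.0)
        return self.signs * z


@dataclass
class GeneticCorrelationMatrix:
    """Signed phenotype-phenotype network: correlations of rows of ``T``."""

    W: np.ndarray
    trait_ids: list[str]

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        k = len(self.trait_ids)
        if self.W.shape != (k, k):
            raise ValueError("W must be K x K")

    @property
    def n_traits(self) -> int:
        return self.W.shape[0]


@dataclass
class ModulePartition:
    """Phenotype-to-module assignment with the stability (AF) curve."""

    labels: np.ndarray
    trait_ids: list[str]
    af: np.ndarray
    n_modules: int
    sigma2: float = np.nan
    n_perturb: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.af = np.asarray(self.af, dtype=float)
        if self.labels.shape != (len(self.trait_ids),):
            raise ValueError("labels must have one entry per trait")

    def module_members(self) -> dict[int, np.ndarray]:
        return {m: np.flatnonzero(self.labels == m) for m in np.unique(self.labels)}


@dataclass
class TestOutcome:
    """A single multi-phenotype test result."""

    statistic: float
    df: Optional[int]
    p: float
    test_name: str


@dataclass
class ModuleTestReport:
    """Per-module outcomes for one SNP plus the Bonferroni-combined p-value."""

    outcomes: list[TestOutcome]
    combined_p: float
    n_modules: int


@dataclass
class SimulatedDataset:
    """A factor-model simulation with its generating truth attached."""

    genotypes: GenotypeDataset
    phenotypes: PhenotypeDataset
    categories: np.ndarray
    causal_snps: np.ndarray
    effects: np.ndarray
    liability: np.ndarray = field(default=None, repr=False)
    true_maf: np.ndarray = field(default=None, repr=False)
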