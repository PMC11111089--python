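"""Construction of the signed bipartite genotype-phenotype network (GPN).

The edge weight between trait ``k`` and SNP ``m`` is

    T_km = sign(S_km) * Q_chi2_1(1 - p_km),

where ``S_km = sum_i (y_ik - ybar_k) g_im`` is the score statistic after
covariate residualization and ``p_km`` its two-sided p-value — from the
normal approximation ``S ~ N(0, sigma^2)`` with
``sigma^2 = sum(y - ybar)^2 * sum(g - gbar)^2 / n`` for quantitative (and
well-balanced binary) traits, or from the saddlepoint approximation for
binary traits with unbalanced case-control ratios.  ``Q_chi2_1`` is the
chi-square(1) quantile, evaluated via the upper-tail inverse so that
p-values down to 1e-300 map to finite weights.  A positive weight means the
minor allele is protective for the trait.

The same adjacency can be assembled from GWAS summary statistics (an effect
direction and a p-value per trait-SNP pair); individual-level data are not
required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator

from . import spa as _spa
from .datasets import (
    BINARY,
    AssociationStrengthMatrix,
    CovariateDataset,
    GenotypeDataset,
    PhenotypeDataset,
)
from .io import align_samples

logger = logging.getLogger(__name__)

P_FLOOR = 1e-320
#: hybrid saddlepoint rule: below this |z| the normal tail is kept (fast path)
SPA_Z_THRESHOLD = 2.0


@dataclass
class ScoreResult:
    S: float
    sigma2: float
    z: float
    p: float
    method: str


def residualize(values: np.ndarray, covariates: CovariateDataset | np.ndarray | None):
    """Replace each column by its residual from an OLS fit on the covariates.

    An intercept is always included, so an empty covariate set reduces to
    mean-centering.  Raises on rank-deficient designs, naming the collinear
    columns.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    n = values.shape[0]
    if covariates is None:
        x = np.ones((n, 1))
        names = ["intercept"]
    else:
        c = covariates.values if isinstance(covariates, CovariateDataset) else np.asarray(covariates, float)
        names = (
            ["intercept"] + list(covariates.covariate_ids)
            if isinstance(covariates, CovariateDataset)
            else ["intercept"] + [f"x{j}" for j in range(c.shape[1])]
        )
        x = np.column_stack([np.ones(n), c])
    if n <= x.shape[1]:
        raise ValueError("need more samples than covariates (plus intercept)")
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    if (diag < 1e-10 * max(diag.max(), 1.0)).any():
        bad = [names[j] for j in np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0))]
        raise ValueError(f"covariate design is rank deficient (collinear: {bad})")
    return values - q @ (q.T @ values)


def score_test(y: np.ndarray, g: np.ndarray) -> ScoreResult:
    """Score test for one trait-SNP pair with the normal null approximation.

    ``S = sum (y - ybar) g``; ``sigma^2 = sum(y-ybar)^2 sum(g-gbar)^2 / n``.
    A constant ``y`` or ``g`` is degenerate and returns S=0, z=0, p=1.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("score test needs n >= 3")
    yc = y - y.mean()
    gc = g - g.mean()
    s = float(yc @ g)
    sigma2 = float((yc @ yc) * (gc @ gc) / n)
    if sigma2 <= 0.0:
        logger.debug("degenerate score test (constant y or g)")
        return ScoreResult(0.0, 0.0, 0.0, 1.0, "normal")
    z = s / np.sqrt(sigma2)
    return ScoreResult(s, sigma2, z, float(2.0 * norm.sf(abs(z))), "normal")


def spa_pvalue(y: np.ndarray, g_resid: np.ndarray, mu: np.ndarray) -> ScoreResult:
    """Saddlepoint score test for a 0/1 trait given null case probabilities."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g_resid, dtype=float)
    mu = np.asarray(mu, dtype=float)
    s = float(g @ (y - mu))
    var = float((g * g * mu * (1.0 - mu)).sum())
    p = _spa.spa_two_sided(s, g, mu)
    z = s / np.sqrt(var) if var > 0 else 0.0
    return ScoreResult(s, var, float(z), float(p), "spa")


def strength_from_p(p: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Map (sign, p) to the signed chi-square(1) strength ``sign * Q(1-p)``.

    Uses the upper-tail inverse on ``p`` directly so tiny p-values keep full
    precision; p is clipped to [1e-320, 1].
    """
    p = np.clip(np.asarray(p, dtype=float), P_FLOOR, 1.0)
    return np.asarray(signs, dtype=float) * chi2.isf(p, df=1)


def null_case_probabilities(y: np.ndarray, covariates=None) -> np.ndarray:
    """Null P(y=1 | covariates) via logistic regression (intercept-only mean
    when there are no covariates)."""
    y = np.asarray(y, dtype=float)
    if covariates is None:
        return np.full(y.size, y.mean())
    import statsmodels.api as sm

    c = covariates.values if isinstance(covariates, CovariateDataset) else np.asarray(covariates, float)
    x = sm.add_constant(c)
    fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
    return np.clip(np.asarray(fit.mu), 1e-10, 1.0 - 1e-10)


def _score_matrix(y_resid: np.ndarray, g_resid: np.ndarray):
    """Vectorized score statistics for all trait-SNP pairs.

    Residualized inputs are orthogonal to the intercept, so the centered
    sums reduce to plain inner products.
    """
    n = y_resid.shape[0]
    s = y_resid.T @ g_resid
    ssy = (y_resid**2).sum(axis=0)
    ssg = (g_resid**2).sum(axis=0)
    sigma2 = np.outer(ssy, ssg) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sigma2 > 0, s / np.sqrt(sigma2), 0.0)
    return s, sigma2, z


class GPN(BaseEstimator):
    """Fit the signed genotype-phenotype network from individual-level data.

    Parameters
    ----------
    engine : {'auto', 'normal', 'spa'}
        'normal' uses the normal score approximation everywhere.  'auto' and
        'spa' use the saddlepoint tail for every binary trait, with the
        standard fast hybrid: entries with normal ``|z|`` below
        ``spa_threshold`` keep the (there indistinguishable) normal p-value.
        Set ``spa_threshold=0`` to force the saddlepoint everywhere.
    spa_threshold : float
        Hybrid switch point on the normal z scale.

    Attributes
    ----------
    T_ : AssociationStrengthMatrix
        The fitted K x M signed adjacency.
    """

    def __init__(self, engine: str = "auto", spa_threshold: float = SPA_Z_THRESHOLD):
        self.engine = engine
        self.spa_threshold = spa_threshold

    def fit(
        self,
        genotypes: GenotypeDataset,
        phenotypes: PhenotypeDataset,
        covariates: CovariateDataset | None = None,
        align: bool = True,
    ):
        if self.engine not in ("auto", "normal", "spa"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if align and genotypes.sample_ids != phenotypes.sample_ids:
            genotypes, phenotypes, covariates = align_samples(
                genotypes, phenotypes, covariates
            )
        g_raw = genotypes.mean_imputed()
        y_raw = phenotypes.values
        if np.isnan(y_raw).any():
            raise ValueError("phenotype matrix contains missing values")
        g_resid = residualize(g_raw, covariates)
        y_resid = residualize(y_raw, covariates)

        s, sigma2, z = _score_matrix(y_resid, g_resid)
        pvals = 2.0 * norm.sf(np.abs(z))
        pvals[sigma2 <= 0] = 1.0
        method = np.full(y_resid.shape[1], "normal", dtype=object)

        scale = max(1.0, float(np.abs(g_raw).max(initial=0.0)))
        dead_snps = (g_resid**2).sum(axis=0) <= (1e-9 * scale) ** 2 * g_resid.shape[0]
        if dead_snps.any():
            logger.warning("%d zero-variance SNP columns set to 0", dead_snps.sum())

        if self.engine in ("auto", "spa"):
            for k in np.flatnonzero(phenotypes.is_binary()):
                mu = null_case_probabilities(y_raw[:, k], covariates)
                if mu.min() <= 0.0 or mu.max() >= 1.0:
                    continue
                redo = np.flatnonzero(
                    (np.abs(z[k]) >= self.spa_threshold) & ~dead_snps
                )
                if not redo.size:
                    continue
                s_spa = g_resid[:, redo].T @ (y_raw[:, k] - mu)
                # chunk the vectorized saddlepoint to bound memory at n x 512
                for lo_i in range(0, redo.size, 512):
                    sl = slice(lo_i, lo_i + 512)
                    pvals[k, redo[sl]] = _spa.spa_two_sided_batch(
                        s_spa[sl], g_resid[:, redo[sl]], mu
                    )
                s[k, redo] = s_spa
                method[k] = "spa"

        signs = np.sign(s).astype(int)
        signs[sigma2 <= 0] = 0
        t = strength_from_p(pvals, signs)
        t[:, dead_snps] = 0.0
        self.T_ = AssociationStrengthMatrix(
            T=t,
            signs=signs,
            pvals=np.clip(pvals, P_FLOOR, 1.0),
            trait_ids=list(phenotypes.trait_ids),
            snp_ids=list(genotypes.snp_ids),
        )
        self.method_ = method
        return self

    def fit_from_summary(self, stats: pd.DataFrame, trait_ids=None, snp_ids=None):
        """Assemble the network from a (trait, SNP, direction, p_value) table."""
        self.T_ = build_gpn_from_summary(stats, trait_ids, snp_ids)
        return self


def build_gpn(
    genotypes: GenotypeDataset,
    phenotypes: PhenotypeDataset,
    covariates: CovariateDataset | None = None,
    engine: str = "auto",
    spa_threshold: float = SPA_Z_THRESHOLD,
) -> AssociationStrengthMatrix:
    """Functional wrapper over :class:`GPN`."""
    return GPN(engine=engine, spa_threshold=spa_threshold).fit(
        genotypes, phenotypes, covariates
    ).T_


def build_gpn_from_summary(
    stats: pd.DataFrame, trait_ids=None, snp_ids=None
) -> AssociationStrengthMatrix:
    """Build the adjacency from summary statistics.

    ``T_km = direction_km * Q_chi2_1(1 - p_km)``; pairs absent from the
    table are set to 0 with a logged count.
    """
    if (stats["p_value"] <= 0).any():
        raise ValueError("summary p_value entries must be positive")
    if trait_ids is None:
        trait_ids = list(pd.unique(stats["trait_id"].astype(str)))
    if snp_ids is None:
        snp_ids = list(pd.unique(stats["snp_id"].astype(str)))
    k, m = len(trait_ids), len(snp_ids)
    tmap = {t: i for i, t in enumerate(trait_ids)}
    smap = {s: i for i, s in enumerate(snp_ids)}
    pvals = np.ones((k, m))
    signs = np.zeros((k, m), dtype=int)
    seen = 0
    for row in stats.itertuples(index=False):
        ti = tmap.get(str(row.trait_id))
        si = smap.get(str(row.snp_id))
        if ti is None or si is None:
            continue
        pvals[ti, si] = row.p_value
        signs[ti, si] = int(row.direction)
        seen += 1
    missing = k * m - seen
    if missing:
        logger.info("%d (trait, SNP) pairs absent from summary table set to 0", missing)
    t = strength_from_p(pvals, signs)
    t[pvals >= 1.0] = 0.0
    return AssociationStrengthMatrix(t, signs, np.clip(pvals, P_FLOOR, 1.0), list(trait_ids), list(snp_ids))
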