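"""Multiple-phenotype association tests, per SNP.

All tests except MultiPhen operate on the vector ``z`` of per-phenotype
signed z-scores for one SNP and the null correlation matrix ``R`` of the
phenotype residuals (under no association, ``z ~ N(0, R)``):

- O'Brien:  ``1' R^-1 z / sqrt(1' R^-1 1)``, standard normal.
- Omnibus:  ``z' R^-1 z``, chi-square with K' df.
- CLC:      ``(U' R^-1 z)' (U' R^-1 U)^-1 (U' R^-1 z)`` for a cluster
            indicator ``U`` (K' x L), chi-square with L df.  ``U = I``
            recovers Omnibus; a single cluster recovers O'Brien squared.
- ceCLC:    CLC at every level L = 1..K' of a Ward dendrogram built on R,
            combined across levels by the Cauchy combination (ACAT).
- HCLC:     ACAT of CLC over the levels generated by the dendrogram's
            merges (L = K'-1 down to 1), i.e. excluding the all-singletons
            level.  Both ceCLC and HCLC are named strategies; the CLC family
            admits several published variants and these defaults are chosen
            for their null calibration.
- MultiPhen: reverse regression — proportional-odds ordinal regression of
            the genotype categories {0,1,2} on all phenotypes jointly,
            likelihood-ratio tested against the intercept-only model.

Tests run either on all K phenotypes at once ("N.O.") or within each
detected network module with a Bonferroni combination across the C modules
("NET"): ``combined_p = min(1, C * min_module_p)``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.cluster import hierarchy
from scipy.stats import chi2, norm

from .community import cut_clusters, ward_dendrogram
from .datasets import ModulePartition, ModuleTestReport, TestOutcome

logger = logging.getLogger(__name__)

JOINT_TESTS = ("obrien", "omnibus", "clc", "ceclc", "hclc")
ALL_TESTS = JOINT_TESTS + ("multiphen",)

_ACAT_CLIP = 1e-15


def univariate_z(y: np.ndarray, g: np.ndarray, trait_kind: str = "quantitative",
                 mu: np.ndarray | None = None) -> float:
    """Signed per-phenotype z-score for one SNP.

    Quantitative traits use the plain score z = S/sigma; binary traits use
    the saddlepoint-calibrated magnitude ``sign(S) * Phi^-1(1 - p/2)`` so
    that extreme case-control imbalance does not inflate the joint tests.
    """
    from .network import score_test, spa_pvalue

    if trait_kind == "binary":
        if mu is None:
            mu = np.full(len(y), float(np.mean(y)))
        res = spa_pvalue(y, np.asarray(g, float) - np.mean(g), mu)
        if res.p >= 1.0 or res.S == 0.0:
            return 0.0
        return float(np.sign(res.S) * norm.isf(res.p / 2.0))
    res = score_test(y, g)
    return res.z


def estimate_R(y_resid: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Null correlation of the phenotype residual columns, eigenvalue-floored.

    The joint tests need ``R^-1``; flooring the spectrum at ``floor`` keeps
    duplicated or near-collinear traits from making it singular.
    """
    y = np.asarray(y_resid, dtype=float)
    if y.shape[0] <= y.shape[1]:
        raise ValueError("need more samples than traits to estimate R")
    sd = y.std(axis=0)
    if (sd <= 0).any():
        bad = np.flatnonzero(sd <= 0)
        raise ValueError(f"constant phenotype columns at indices {bad.tolist()}")
    r = np.corrcoef(y, rowvar=False)
    r = np.atleast_2d(r)
    vals, vecs = np.linalg.eigh(r)
    if vals.min() < floor:
        r = (vecs * np.maximum(vals, floor)) @ vecs.T
        r = (r + r.T) / 2.0
    return r


def _validate_U(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.ndim != 2:
        raise ValueError("U must be a 2-D indicator matrix")
    if not ((u == 0) | (u == 1)).all() or not (u.sum(axis=1) == 1).all():
        raise ValueError("rows of U must one-hot assign each phenotype to a cluster")
    if (u.sum(axis=0) == 0).any():
        raise ValueError("U contains an empty cluster")
    return u


def labels_to_indicator(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    return (labels[:, None] == uniq[None, :]).astype(float)


def obrien(z: np.ndarray, R: np.ndarray) -> TestOutcome:
    """O'Brien's linear combination of correlated z-scores."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    ri_z = np.linalg.solve(R, z)
    ri_1 = np.linalg.solve(R, np.ones_like(z))
    stat = float(ri_z.sum() / np.sqrt(ri_1.sum()))
    return TestOutcome(stat, None, float(2.0 * norm.sf(abs(stat))), "obrien")


def omnibus(z: np.ndarray, R: np.ndarray) -> TestOutcome:
    """Quadratic-form chi-square test on the full z vector."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    stat = float(z @ np.linalg.solve(R, z))
    k = z.size
    return TestOutcome(stat, k, float(chi2.sf(stat, df=k)), "omnibus")


def clc(z: np.ndarray, R: np.ndarray, U: np.ndarray) -> TestOutcome:
    """Clustering linear combination test for a given cluster indicator U."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    u = _validate_U(U)
    ri_z = np.linalg.solve(R, z)
    ri_u = np.linalg.solve(R, u)
    a = u.T @ ri_z
    m = u.T @ ri_u
    stat = float(a @ np.linalg.solve(m, a))
    L = u.shape[1]
    return TestOutcome(stat, L, float(chi2.sf(stat, df=L)), "clc")


def acat(p_values: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Cauchy combination (ACAT) of possibly dependent p-values."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn("p-values at 0 or 1 clipped for the Cauchy combination")
        p = np.clip(p, _ACAT_CLIP, 1.0 - _ACAT_CLIP)
    if weights is None:
        weights = np.ones_like(p)
    w = np.asarray(weights, dtype=float)
    stat = float((w * np.tan((0.5 - p) * np.pi)).sum() / w.sum())
    return float(0.5 - np.arctan(stat) / np.pi)


def _dendrogram_on_R(R: np.ndarray) -> np.ndarray:
    return ward_dendrogram(np.asarray(R, dtype=float))


def clc_auto_levels(linkage: np.ndarray, k: int) -> int:
    """Cluster count for plain CLC: cut at the largest relative gap in
    Ward merge heights (deterministic; documented default)."""
    if k <= 2:
        return 1
    h = linkage[:, 2]
    gaps = (h[1:] - h[:-1]) / np.maximum(h[:-1], 1e-12)
    j = int(np.argmax(gaps))  # gap between merge j and j+1
    return k - (j + 1)


def ceclc(z: np.ndarray, R: np.ndarray, linkage: np.ndarray | None = None) -> TestOutcome:
    """Cauchy-combined CLC over every dendrogram level L = 1..K'."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    k = z.size
    if k == 1:
        stat = float(z[0] ** 2 / R[0, 0])
        return TestOutcome(stat, 1, float(chi2.sf(stat, df=1)), "ceclc")
    if linkage is None:
        linkage = _dendrogram_on_R(R)
    labels = cut_clusters(linkage, np.arange(1, k + 1))
    ps = [clc(z, R, labels_to_indicator(labels[:, j])).p for j in range(k)]
    p = acat(np.array(ps))
    return TestOutcome(float(np.tan((0.5 - np.array(ps)) * np.pi).mean()), None, p, "ceclc")


def hclc(z: np.ndarray, R: np.ndarray, linkage: np.ndarray | None = None) -> TestOutcome:
    """Cauchy-combined CLC over the dendrogram's merge levels (L = 1..K'-1)."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    k = z.size
    if k == 1:
        stat = float(z[0] ** 2 / R[0, 0])
        return TestOutcome(stat, 1, float(chi2.sf(stat, df=1)), "hclc")
    if linkage is None:
        linkage = _dendrogram_on_R(R)
    labels = cut_clusters(linkage, np.arange(1, k))
    ps = [clc(z, R, labels_to_indicator(labels[:, j])).p for j in range(k - 1)]
    p = acat(np.array(ps))
    return TestOutcome(float(np.tan((0.5 - np.array(ps)) * np.pi).mean()), None, p, "hclc")


def clc_default(z: np.ndarray, R: np.ndarray, linkage: np.ndarray | None = None) -> TestOutcome:
    """Plain CLC with the automatic cluster count from the Ward dendrogram."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    k = z.size
    if k == 1:
        stat = float(z[0] ** 2 / R[0, 0])
        return TestOutcome(stat, 1, float(chi2.sf(stat, df=1)), "clc")
    if linkage is None:
        linkage = _dendrogram_on_R(R)
    L = clc_auto_levels(linkage, k)
    u = labels_to_indicator(cut_clusters(linkage, L))
    out = clc(z, R, u)
    return TestOutcome(out.statistic, out.df, out.p, "clc")


def multiphen(g: np.ndarray, y_block: np.ndarray) -> TestOutcome:
    """Reverse (proportional-odds) regression of genotype on phenotypes.

    Likelihood-ratio test of the joint phenotype effect, df = K'.  Known to
    have inflated type I error with extremely unbalanced binary phenotypes;
    included for comparison, not recommended for biobank-style traits.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    g = np.asarray(g, dtype=float)
    y = np.atleast_2d(np.asarray(y_block, dtype=float))
    if y.shape[0] == 1:
        y = y.T
    k = y.shape[1]
    cats, counts = np.unique(g, return_counts=True)
    if cats.size < 2:
        logger.warning("genotype vector is constant; MultiPhen undefined")
        return TestOutcome(np.nan, k, np.nan, "multiphen")
    # intercept-only proportional-odds loglik is the multinomial MLE
    n = g.size
    ll0 = float((counts * np.log(counts / n)).sum())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(g, y, distr="logit")
            fit = model.fit(method="lbfgs", maxiter=200, disp=False)
        lr = 2.0 * (fit.llf - ll0)
        if not np.isfinite(lr):
            raise ValueError("non-finite likelihood")
        lr = max(lr, 0.0)
        return TestOutcome(float(lr), k, float(chi2.sf(lr, df=k)), "multiphen")
    except Exception as exc:
        logger.warning("MultiPhen fit failed: %s", exc)
        return TestOutcome(np.nan, k, np.nan, "multiphen")


_DISPATCH = {
    "obrien": lambda z, R: obrien(z, R),
    "omnibus": lambda z, R: omnibus(z, R),
    "clc": lambda z, R: clc_default(z, R),
    "ceclc": lambda z, R: ceclc(z, R),
    "hclc": lambda z, R: hclc(z, R),
}


def test_snp_no(z_full: np.ndarray, R_full: np.ndarray, test_name: str) -> TestOutcome:
    """Run one joint test on all K phenotypes (N.O. mode)."""
    if test_name not in _DISPATCH:
        raise ValueError(f"unknown joint test {test_name!r}")
    return _DISPATCH[test_name](np.asarray(z_full, float), np.asarray(R_full, float))


def test_snp_net(
    z_full: np.ndarray,
    R_full: np.ndarray,
    partition: ModulePartition | np.ndarray,
    test_name: str,
) -> ModuleTestReport:
    """Run one joint test within each module, Bonferroni-combined (NET mode)."""
    labels = partition.labels if isinstance(partition, ModulePartition) else np.asarray(partition)
    z = np.asarray(z_full, dtype=float)
    R = np.asarray(R_full, dtype=float)
    outcomes = []
    for mod in np.unique(labels):
        idx = np.flatnonzero(labels == mod)
        outcomes.append(test_snp_no(z[idx], R[np.ix_(idx, idx)], test_name))
    c = len(outcomes)
    combined = min(1.0, c * min(o.p for o in outcomes))
    return ModuleTestReport(outcomes, combined, c)


# ---------------------------------------------------------------------------
# Vectorized batch engine (all SNPs at once) used by the evaluation harness.


def _level_label_sets(R: np.ndarray):
    k = R.shape[0]
    if k == 1:
        return None, [np.zeros((1, 1))]
    link = _dendrogram_on_R(R)
    labels = cut_clusters(link, np.arange(1, k + 1))
    return link, [labels_to_indicator(labels[:, j]) for j in range(k)]


def _quadform_batch(zr: np.ndarray, zb: np.ndarray, R_inv: np.ndarray, u: np.ndarray):
    """CLC statistics for all rows of the z matrix for one indicator U."""
    a = zr @ u  # (M, L)
    m = u.T @ R_inv @ u
    sol = np.linalg.solve(m, a.T).T
    return (a * sol).sum(axis=1), u.shape[1]


def batch_test(
    Z: np.ndarray,
    R: np.ndarray,
    labels: np.ndarray | None = None,
    tests=JOINT_TESTS,
) -> dict[str, np.ndarray]:
    """Vectorized joint tests for an (M, K) matrix of z-score rows.

    With ``labels`` given, runs the NET mode (per-module tests combined by
    Bonferroni over the modules); otherwise the N.O. mode on all phenotypes.
    Returns a dict mapping test name to a length-M array of p-values.
    """
    Z = np.asarray(Z, dtype=float)
    R = np.asarray(R, dtype=float)
    m_snps, k = Z.shape
    if labels is None:
        labels = np.zeros(k, dtype=int)
    labels = np.asarray(labels)
    modules = np.unique(labels)
    per_mod: dict[str, list[np.ndarray]] = {t: [] for t in tests}
    for mod in modules:
        idx = np.flatnonzero(labels == mod)
        rb = R[np.ix_(idx, idx)]
        zb = Z[:, idx]
        rb_inv = np.linalg.inv(rb)
        zr = zb @ rb_inv
        kb = idx.size
        link, u_levels = _level_label_sets(rb)
        for t in tests:
            if t == "obrien":
                num = zr.sum(axis=1)
                den = np.sqrt(rb_inv.sum())
                per_mod[t].append(2.0 * norm.sf(np.abs(num / den)))
            elif t == "omnibus":
                stat = (zr * zb).sum(axis=1)
                per_mod[t].append(chi2.sf(stat, df=kb))
            elif t in ("clc", "ceclc", "hclc"):
                if kb == 1:
                    stat = zb[:, 0] ** 2 / rb[0, 0]
                    per_mod[t].append(chi2.sf(stat, df=1))
                    continue
                if t == "clc":
                    L = clc_auto_levels(link, kb)
                    stat, dfL = _quadform_batch(zr, zb, rb_inv, u_levels[L - 1])
                    per_mod[t].append(chi2.sf(stat, df=dfL))
                else:
                    levels = range(kb) if t == "ceclc" else range(kb - 1)
                    ps = []
                    for j in levels:
                        stat, dfL = _quadform_batch(zr, zb, rb_inv, u_levels[j])
                        ps.append(chi2.sf(stat, df=dfL))
                    pmat = np.clip(np.stack(ps), _ACAT_CLIP, 1.0 - _ACAT_CLIP)
                    cstat = np.tan((0.5 - pmat) * np.pi).mean(axis=0)
                    per_mod[t].append(0.5 - np.arctan(cstat) / np.pi)
            else:
                raise ValueError(f"unknown batch test {t!r}")
    c = modules.size
    return {
        t: np.minimum(1.0, c * np.minimum.reduce(per_mod[t])) for t in tests
    }
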