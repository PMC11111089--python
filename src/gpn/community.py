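"""Perturbation-calibrated Ward clustering of phenotypes into network modules.

Phenotypes are clustered by Ward's method on the dissimilarity
``d_kl = 1 - W_kl`` (anti-correlated phenotypes are maximally distant in
the signed network).  The number of modules is chosen by a perturbation
stability procedure: ``B`` perturbed copies ``T(b) = T + eps``,
``eps ~ N(0, sigma^2)`` with ``sigma^2`` the median of the per-SNP-column
variances of ``T``, are re-projected and re-clustered; for each candidate
cluster count ``k0`` the average perturbed connectivity matrix ``A_k0`` is
compared with the unperturbed one ``C_k0`` through ``D_k0 = |A_k0 - C_k0|``,
and the stability score ``AF_k0`` is the area under the empirical CDF of the
entries of ``D_k0`` — equal to ``1 - mean(D_k0)``.  The chosen module count
is the (smallest) ``k`` maximizing ``|AF_{k+1} - AF_k|``: the biggest drop
in stability marks the finest partition that perturbation cannot break.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .datasets import AssociationStrengthMatrix, GeneticCorrelationMatrix, ModulePartition
from .projection import _row_correlation

logger = logging.getLogger(__name__)


def ward_dendrogram(W: GeneticCorrelationMatrix | np.ndarray) -> np.ndarray:
    """Ward linkage on ``d = 1 - W``; returns a scipy linkage matrix.

    This is the proper Ward objective on the supplied dissimilarities (the
    "ward.D2"-style update).  Ties are broken deterministically by scipy's
    leaf-index ordering.
    """
    w = W.W if isinstance(W, GeneticCorrelationMatrix) else np.asarray(W, dtype=float)
    k = w.shape[0]
    if k < 2:
        raise ValueError("need at least 2 phenotypes to cluster")
    d = 1.0 - w
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    return hierarchy.linkage(squareform((d + d.T) / 2.0, checks=False), method="ward")


def cut_clusters(linkage: np.ndarray, n_clusters) -> np.ndarray:
    """Cut a dendrogram into exactly ``n_clusters`` groups (vector allowed)."""
    labels = hierarchy.cut_tree(linkage, n_clusters=n_clusters)
    return labels.squeeze() if np.isscalar(n_clusters) else labels


def connectivity(labels: np.ndarray) -> np.ndarray:
    """Binary co-membership matrix: C[k, l] = 1 iff labels_k == labels_l."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    return (labels[:, None] == labels[None, :]).astype(float)


def perturbation_sigma2(t: np.ndarray) -> float:
    """Noise variance: median over SNP columns of var(T_m) across the K traits."""
    if t.shape[0] < 2:
        raise ValueError("need K >= 2 traits for column variances")
    return float(np.median(np.var(t, axis=0, ddof=1)))


def perturb(T: AssociationStrengthMatrix | np.ndarray, seed=None) -> np.ndarray:
    """One perturbed copy ``T + N(0, sigma^2)`` with the stated sigma^2."""
    t = T.T if isinstance(T, AssociationStrengthMatrix) else np.asarray(T, dtype=float)
    sigma2 = perturbation_sigma2(t)
    if sigma2 <= 0.0:
        logger.warning("all SNP columns of T are constant; perturbation is degenerate")
        return t.copy()
    rng = np.random.default_rng(seed)
    return t + rng.normal(0.0, np.sqrt(sigma2), size=t.shape)


def select_modules(af: np.ndarray) -> int:
    """Smallest k in 1..K-1 maximizing ``|AF_{k+1} - AF_k|``."""
    af = np.asarray(af, dtype=float)
    if af.size < 2:
        raise ValueError("AF curve needs at least 2 entries")
    jumps = np.abs(np.diff(af))
    return int(np.argmax(jumps)) + 1


class ModuleDetector(BaseEstimator, ClusterMixin):
    """Partition phenotypes into network modules from the adjacency ``T``.

    Parameters
    ----------
    n_perturb : int
        Number of perturbed datasets ``B`` (>= 2).
    random_state : int or None
        Seed for the perturbation noise.
    perturb_mode : {'reproject', 'rows'}
        'reproject' (default) re-projects each perturbed ``T`` to its
        genetic-correlation matrix and clusters that, keeping the pipeline
        identical to the unperturbed path; 'rows' Ward-clusters the
        perturbed rows of ``T`` directly (Euclidean).

    Attributes
    ----------
    labels_ : (K,) int module assignment at the chosen count.
    af_ : (K,) stability curve AF_1..AF_K (AF_1 is always 1).
    n_modules_ : chosen module count C.
    sigma2_ : perturbation noise variance used.
    linkage_ : unperturbed Ward linkage.
    """

    def __init__(self, n_perturb: int = 1000, random_state=None, perturb_mode: str = "reproject"):
        self.n_perturb = n_perturb
        self.random_state = random_state
        self.perturb_mode = perturb_mode

    def _linkage_of(self, t: np.ndarray) -> np.ndarray:
        if self.perturb_mode == "reproject":
            return ward_dendrogram(_row_correlation(t))
        if self.perturb_mode == "rows":
            return hierarchy.linkage(t, method="ward")
        raise ValueError(f"unknown perturb_mode {self.perturb_mode!r}")

    def fit(self, T: AssociationStrengthMatrix | np.ndarray, y=None):
        if self.n_perturb < 2:
            raise ValueError("need at least B = 2 perturbed datasets")
        if isinstance(T, AssociationStrengthMatrix):
            t, trait_ids = T.T, list(T.trait_ids)
        else:
            t = np.asarray(T, dtype=float)
            trait_ids = [f"trait{i}" for i in range(t.shape[0])]
        k = t.shape[0]
        if k < 2:
            raise ValueError("need at least 2 phenotypes")
        counts = np.arange(1, k + 1)
        link0 = self._linkage_of(t)
        labels0 = hierarchy.cut_tree(link0, n_clusters=counts)  # K x K
        conn0 = np.stack([connectivity(labels0[:, j]) for j in range(k)])

        sigma2 = perturbation_sigma2(t)
        rng = np.random.default_rng(self.random_state)
        acc = np.zeros_like(conn0)
        if sigma2 <= 0.0:
            logger.warning("degenerate perturbation (sigma^2 = 0); AF curve is flat 1")
            acc = conn0 * self.n_perturb
        else:
            sd = np.sqrt(sigma2)
            for _ in range(self.n_perturb):
                tb = t + rng.normal(0.0, sd, size=t.shape)
                lb = hierarchy.cut_tree(self._linkage_of(tb), n_clusters=counts)
                for j in range(k):
                    acc[j] += connectivity(lb[:, j])
        a = acc / self.n_perturb
        d = np.abs(a - conn0)
        af = 1.0 - d.reshape(k, -1).mean(axis=1)
        self.d_ = d  # per-count |A - C| discrepancy matrices (K x K x K)

        c = select_modules(af)
        self.af_ = af
        self.sigma2_ = sigma2
        self.n_modules_ = c
        self.linkage_ = link0
        self.labels_ = labels0[:, c - 1].astype(int)
        self.partition_ = ModulePartition(
            labels=self.labels_,
            trait_ids=trait_ids,
            af=af,
            n_modules=c,
            sigma2=sigma2,
            n_perturb=self.n_perturb,
        )
        return self

    def fit_predict(self, T, y=None):
        return self.fit(T).labels_


def af_curve(T, n_perturb: int = 1000, seed=None, perturb_mode: str = "reproject") -> np.ndarray:
    """Stability curve AF_1..AF_K for the perturbation procedure."""
    det = ModuleDetector(n_perturb=n_perturb, random_state=seed, perturb_mode=perturb_mode)
    return det.fit(T).af_


def detect_modules(
    T, n_perturb: int = 1000, seed=None, perturb_mode: str = "reproject"
) -> ModulePartition:
    """Functional wrapper over :class:`ModuleDetector`."""
    det = ModuleDetector(n_perturb=n_perturb, random_state=seed, perturb_mode=perturb_mode)
    return det.fit(T).partition_
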