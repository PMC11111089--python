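"""One-mode projection of the GPN onto phenotypes.

The phenotype-phenotype network (PPN) has adjacency

    W_kl = sum_m (T_km - Tbar_k)(T_lm - Tbar_l)
           / sqrt( sum_m (T_km - Tbar_k)^2 * sum_m (T_lm - Tbar_l)^2 ),

the Pearson correlation between rows ``k`` and ``l`` of the association
strength matrix ``T`` over the M SNPs: the genetic correlation between two
phenotypes as seen through their shared association profile.  It is a
signed network with entries in [-1, 1] and unit diagonal.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import AssociationStrengthMatrix, GeneticCorrelationMatrix

logger = logging.getLogger(__name__)


def _row_correlation(t: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of rows; constant rows get 0 off-diagonal."""
    k, m = t.shape
    if m < 2:
        raise ValueError("projection needs at least 2 SNP columns")
    centered = t - t.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    scale = max(1.0, float(np.abs(t).max(initial=0.0)))
    dead = norms <= 1e-9 * scale * np.sqrt(m)
    if dead.any():
        logger.warning(
            "%d constant rows of T; their projection entries are set to 0",
            int(dead.sum()),
        )
    safe = np.where(dead, 1.0, norms)
    unit = centered / safe[:, None]
    w = unit @ unit.T
    w[dead, :] = 0.0
    w[:, dead] = 0.0
    np.fill_diagonal(w, 1.0)
    return np.clip(w, -1.0, 1.0)


class PhenotypeProjection(BaseEstimator, TransformerMixin):
    """Project the bipartite network to the phenotype layer.

    ``fit`` stores the genetic-correlation matrix as ``W_``; ``transform``
    returns the raw K x K array for pipeline composition.
    """

    def fit(self, T: AssociationStrengthMatrix | np.ndarray, y=None):
        if isinstance(T, AssociationStrengthMatrix):
            mat, ids = T.T, list(T.trait_ids)
        else:
            mat = np.asarray(T, dtype=float)
            ids = [f"trait{i}" for i in range(mat.shape[0])]
        self.W_ = GeneticCorrelationMatrix(_row_correlation(mat), ids)
        return self

    def transform(self, T) -> np.ndarray:
        if isinstance(T, AssociationStrengthMatrix):
            T = T.T
        return _row_correlation(np.asarray(T, dtype=float))


def project_ppn(T: AssociationStrengthMatrix | np.ndarray) -> GeneticCorrelationMatrix:
    """Functional wrapper over :class:`PhenotypeProjection`."""
    return PhenotypeProjection().fit(T).W_
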