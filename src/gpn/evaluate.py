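"""Monte-Carlo type-I-error and power harness for the module-wise tests.

Bookkeeping follows the study design this package simulates: a type-I run
simulates a null dataset (beta = 0) with M SNPs and contributes M null
replicates, so e.g. 500 MC runs x 2,000 SNPs = 10^6 replicates; a power run
contributes its causal SNPs, so 10 MC runs x 100 causal SNPs = 1,000
replicates.  Empirical type-I rates are reported as ratios to the nominal
level together with the binomial 95% band

    1 +/- 1.959964 * sqrt((1 - alpha) / (alpha * n)),

and power is the rejection rate of causal SNPs at the Bonferroni level
0.05 / (causal SNPs per MC run).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import assoc
from .community import ModuleDetector
from .datasets import BINARY
from .network import GPN
from .simulate import MODEL_TABLE, FactorModelConfig, simulate_dataset

logger = logging.getLogger(__name__)

_Z975 = 1.959964


@dataclass
class CalibrationReport:
    test_name: str
    mode: str  # 'NO' or 'NET'
    nominal: float
    n_replicates: int
    ratio: float
    ci: tuple[float, float]

    @property
    def within_ci(self) -> bool:
        return self.ci[0] <= self.ratio <= self.ci[1]


@dataclass
class PowerReport:
    test_name: str
    mode: str
    beta: float
    model_id: int
    power: float
    alpha_used: float
    n_replicates: int


def binomial_ci_ratio(alpha: float, n_replicates: int) -> tuple[float, float]:
    """95% band for (empirical type-I rate) / alpha, to 3 decimals."""
    if alpha * n_replicates < 5:
        warnings.warn(
            "fewer than 5 expected rejections; the normal-approximation CI is unreliable"
        )
    half = _Z975 * np.sqrt((1.0 - alpha) / (alpha * n_replicates))
    return (round(1.0 - half, 3), round(1.0 + half, 3))


def type_i_replicates(n_mc: int, m_null: int) -> int:
    """Null replicates contributed by ``n_mc`` runs of ``m_null`` SNPs each."""
    return n_mc * m_null


def power_replicates(n_mc: int, n_causal: int) -> int:
    """Power replicates contributed by ``n_mc`` runs with ``n_causal`` causal SNPs."""
    return n_mc * n_causal


def _prepare_run(config: FactorModelConfig, seed, engine, n_perturb, forced_labels=None):
    """Simulate one dataset and produce (Z, R, labels, dataset)."""
    rng = np.random.default_rng(seed)
    sim_seed, det_seed = rng.integers(0, 2**31 - 1, size=2)
    data = simulate_dataset(config, sim_seed)
    net = GPN(engine=engine).fit(data.genotypes, data.phenotypes, align=False)
    T = net.T_
    z = T.zscores().T  # (M, K)
    y_resid = data.phenotypes.values - data.phenotypes.values.mean(axis=0)
    r = assoc.estimate_R(y_resid)
    if forced_labels is not None:
        labels = np.asarray(forced_labels)
    else:
        labels = ModuleDetector(n_perturb=n_perturb, random_state=int(det_seed)).fit(T).labels_
    return z, r, labels, data


def run_type_i(
    config: FactorModelConfig,
    tests=assoc.JOINT_TESTS,
    modes=("NO", "NET"),
    n_mc: int = 50,
    nominal: float = 0.001,
    seed=None,
    engine: str = "auto",
    n_perturb: int = 100,
    forced_labels=None,
) -> list[CalibrationReport]:
    """Estimate type-I-error ratios for the joint tests under the null.

    ``config.beta`` must be 0.  MultiPhen (if requested) is fitted per SNP
    and is much slower than the vectorized joint tests.
    """
    if config.beta != 0.0:
        raise ValueError("type-I runs require beta = 0")
    joint = [t for t in tests if t in assoc.JOINT_TESTS]
    with_mp = "multiphen" in tests
    rng = np.random.default_rng(seed)
    hits = {(t, m): 0 for t in tests for m in modes}
    n_rep = 0
    for run in range(n_mc):
        z, r, labels, data = _prepare_run(
            config, rng.integers(0, 2**31 - 1), engine, n_perturb, forced_labels
        )
        n_rep += config.M
        for mode in modes:
            lab = None if mode == "NO" else labels
            if joint:
                pvals = assoc.batch_test(z, r, labels=lab, tests=joint)
                for t in joint:
                    hits[(t, mode)] += int((pvals[t] <= nominal).sum())
            if with_mp:
                hits[("multiphen", mode)] += _multiphen_hits(data, lab, nominal)
    out = []
    ci_cache = binomial_ci_ratio(nominal, n_rep)
    for t in tests:
        for m in modes:
            ratio = hits[(t, m)] / (n_rep * nominal)
            out.append(CalibrationReport(t, m, nominal, n_rep, ratio, ci_cache))
    return out


def _multiphen_hits(data, labels, nominal) -> int:
    y = data.phenotypes.values
    yc = y - y.mean(axis=0)
    g = data.genotypes.counts
    if labels is None:
        groups = [np.arange(y.shape[1])]
    else:
        groups = [np.flatnonzero(labels == m) for m in np.unique(labels)]
    c = len(groups)
    count = 0
    for m in range(g.shape[1]):
        best = np.inf
        for idx in groups:
            p = assoc.multiphen(g[:, m], yc[:, idx]).p
            if np.isfinite(p):
                best = min(best, p)
        if np.isfinite(best) and min(1.0, c * best) <= nominal:
            count += 1
    return count


def run_power(
    config: FactorModelConfig,
    tests=("ceclc",),
    modes=("NO", "NET"),
    n_mc: int = 10,
    seed=None,
    engine: str = "auto",
    n_perturb: int = 100,
    alpha: float = 0.05,
) -> list[PowerReport]:
    """Power at the Bonferroni level ``alpha / n_causal`` over the causal SNPs."""
    if config.beta == 0.0:
        logger.info("beta = 0: measured 'power' is the null rejection rate")
    n_causal = (
        config.model_table[config.model_id].n_causal if config.beta != 0.0 else config.M
    )
    alpha_used = alpha / n_causal
    rng = np.random.default_rng(seed)
    hits = {(t, m): 0 for t in tests for m in modes}
    total = 0
    for run in range(n_mc):
        z, r, labels, data = _prepare_run(
            config, rng.integers(0, 2**31 - 1), engine, n_perturb
        )
        causal = data.causal_snps if data.causal_snps.size else np.arange(config.M)
        total += causal.size
        zc = z[causal]
        for mode in modes:
            lab = None if mode == "NO" else labels
            pvals = assoc.batch_test(zc, r, labels=lab, tests=tests)
            for t in tests:
                hits[(t, mode)] += int((pvals[t] <= alpha_used).sum())
    return [
        PowerReport(t, m, config.beta, config.model_id, hits[(t, m)] / total, alpha_used, total)
        for t in tests
        for m in modes
    ]
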