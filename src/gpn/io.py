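"""Readers and writers for the standard table dialects used by the pipeline.

Genotypes come in either as a PLINK additive-recoded ``.raw`` export or as a
plain TSV matrix; phenotypes, covariates and summary statistics as TSV.  All
TSV dialects are tab-separated, '.' decimal, 'NA' for missing, UTF-8, with a
mandatory header row.  Network artifacts are written as edge-list TSV,
labeled dense matrix TSV, or GraphML (via networkx).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datasets import (
    BINARY,
    QUANTITATIVE,
    AssociationStrengthMatrix,
    CovariateDataset,
    GenotypeDataset,
    GeneticCorrelationMatrix,
    ModulePartition,
    PhenotypeDataset,
)

logger = logging.getLogger(__name__)

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
#: 17 significant digits round-trips IEEE doubles exactly.
_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """Raised when a file does not follow the expected dialect."""


def _orient_minor(counts: np.ndarray, snp_ids: list[str]) -> np.ndarray:
    """Flip columns with allele frequency > 0.5 so counts are minor-allele counts."""
    freq = np.nanmean(counts, axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        counts = counts.copy()
        counts[:, flip] = 2.0 - counts[:, flip]
        logger.info("flipped %d SNP columns to minor-allele orientation", flip.sum())
    return counts


def _validate_counts(counts: np.ndarray, sample_ids, snp_ids) -> None:
    bad = ~(np.isnan(counts) | np.isin(counts, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"genotype cell for sample {sample_ids[i]!r}, SNP {snp_ids[j]!r} "
            f"is {counts[i, j]!r}; expected 0, 1, 2 or NA"
        )


def read_genotypes(path, dialect: str = "plink_raw") -> GenotypeDataset:
    """Read a genotype matrix and orient it to minor-allele counts.

    Parameters
    ----------
    path : str or Path
        Input file.
    dialect : {'plink_raw', 'tsv'}
        ``plink_raw`` expects the PLINK ``--recode A`` layout
        (``FID IID PAT MAT SEX PHENOTYPE`` then one allele-count column per
        SNP, whitespace separated).  ``tsv`` expects a header row with a
        leading sample-id column followed by SNP columns.
    """
    if dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        if list(df.columns[:6]) != _PLINK_META:
            raise FormatError(
                f"malformed .raw header: expected {' '.join(_PLINK_META)}, "
                f"got {' '.join(map(str, df.columns[:6]))}"
            )
        sample_ids = df["IID"].astype(str).tolist()
        snp_ids = list(df.columns[6:])
        counts = df.iloc[:, 6:].to_numpy(dtype=float)
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        sample_ids = df.iloc[:, 0].astype(str).tolist()
        snp_ids = list(df.columns[1:])
        counts = df.iloc[:, 1:].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    _validate_counts(counts, sample_ids, snp_ids)
    counts = _orient_minor(counts, snp_ids)
    return GenotypeDataset(sample_ids, snp_ids, counts)


def write_genotypes(ds: GenotypeDataset, path) -> None:
    df = pd.DataFrame(ds.counts, columns=ds.snp_ids)
    df.insert(0, "sample_id", ds.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%g")


def read_phenotypes(path, trait_kinds: dict[str, str] | None = None) -> PhenotypeDataset:
    """Read a phenotype TSV; traits with value set within {0,1} auto-flag binary.

    ``trait_kinds`` maps trait id to 'quantitative' or 'binary' to override
    the auto-detection.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    trait_ids = list(df.columns[1:])
    try:
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric phenotype cell in {path}: {exc}") from exc
    kinds = []
    for j, tid in enumerate(trait_ids):
        col = values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(f"trait {tid!r} has no observed values")
        if trait_kinds and tid in trait_kinds:
            kinds.append(trait_kinds[tid])
        elif np.isin(obs, (0.0, 1.0)).all():
            kinds.append(BINARY)
        else:
            kinds.append(QUANTITATIVE)
    return PhenotypeDataset(sample_ids, trait_ids, values, kinds)


def write_phenotypes(ds: PhenotypeDataset, path) -> None:
    df = pd.DataFrame(ds.values, columns=ds.trait_ids)
    df.insert(0, "sample_id", ds.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_covariates(path) -> CovariateDataset:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return CovariateDataset(
        df.iloc[:, 0].astype(str).tolist(),
        list(df.columns[1:]),
        df.iloc[:, 1:].to_numpy(dtype=float),
    )


def read_summary_stats(path) -> pd.DataFrame:
    """Read a per-(trait, SNP) summary table: trait_id, snp_id, direction, p_value."""
    df = pd.read_csv(path, sep="\t")
    required = {"trait_id", "snp_id", "direction", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"summary table missing columns: {sorted(missing)}")
    if (df["p_value"] <= 0).any() or (df["p_value"] > 1).any():
        raise ValueError("summary p_value entries must lie in (0, 1]")
    if not df["direction"].isin([-1, 1]).all():
        raise ValueError("summary direction entries must be -1 or +1")
    if df.duplicated(["trait_id", "snp_id"]).any():
        raise ValueError("duplicate (trait_id, snp_id) rows in summary table")
    return df


def align_samples(
    geno: GenotypeDataset,
    pheno: PhenotypeDataset,
    covar: CovariateDataset | None = None,
):
    """Subset all datasets to shared sample ids, in genotype-file order.

    Mismatched ids are dropped with a logged count; biobank extracts rarely
    align row-for-row.
    """
    shared = set(geno.sample_ids) & set(pheno.sample_ids)
    if covar is not None:
        shared &= set(covar.sample_ids)
    order = [s for s in geno.sample_ids if s in shared]
    dropped = len(geno.sample_ids) - len(order)
    if dropped:
        logger.info("dropped %d samples not present in all datasets", dropped)
    if len(order) < 2:
        raise ValueError("fewer than 2 samples shared across datasets")

    def _take(ids, values, idx):
        return [ids[i] for i in idx], values[idx]

    gidx = np.array([geno.sample_ids.index(s) for s in order])
    pmap = {s: i for i, s in enumerate(pheno.sample_ids)}
    pidx = np.array([pmap[s] for s in order])
    g_ids, g_vals = _take(geno.sample_ids, geno.counts, gidx)
    p_ids, p_vals = _take(pheno.sample_ids, pheno.values, pidx)
    geno2 = GenotypeDataset(g_ids, geno.snp_ids, g_vals)
    pheno2 = PhenotypeDataset(p_ids, pheno.trait_ids, p_vals, list(pheno.trait_kind))
    if covar is None:
        return geno2, pheno2, None
    cmap = {s: i for i, s in enumerate(covar.sample_ids)}
    cidx = np.array([cmap[s] for s in order])
    c_ids, c_vals = _take(covar.sample_ids, covar.values, cidx)
    return geno2, pheno2, CovariateDataset(c_ids, covar.covariate_ids, c_vals)


def _network_parts(network):
    if isinstance(network, AssociationStrengthMatrix):
        return network.T, network.trait_ids, network.snp_ids, True
    if isinstance(network, GeneticCorrelationMatrix):
        return network.W, network.trait_ids, network.trait_ids, False
    raise TypeError("expected an AssociationStrengthMatrix or GeneticCorrelationMatrix")


def write_network(network, path, format: str = "matrix_tsv") -> None:
    """Write a network artifact.

    ``edge_tsv`` emits (source_id, target_id, weight) rows — every
    phenotype-SNP pair for the bipartite matrix, off-diagonal upper-triangle
    pairs for the symmetric projection (self-edges suppressed).  No
    thresholding is applied at write time.  ``matrix_tsv`` is a labeled dense
    matrix at 17 significant digits.  ``graphml`` nodes carry a ``layer``
    attribute ('phenotype' or 'snp') for the bipartite network.
    """
    mat, rows, cols, bipartite = _network_parts(network)
    if not np.isfinite(mat).all():
        raise ValueError("network matrix contains non-finite entries")
    if format == "matrix_tsv":
        df = pd.DataFrame(mat, index=rows, columns=cols)
        df.to_csv(path, sep="\t", index_label="id", float_format=_FLOAT_FMT)
    elif format == "edge_tsv":
        recs = []
        if bipartite:
            for i, r in enumerate(rows):
                for j, c in enumerate(cols):
                    recs.append((r, c, mat[i, j]))
        else:
            for i in range(len(rows)):
                for j in range(i + 1, len(cols)):
                    recs.append((rows[i], cols[j], mat[i, j]))
        pd.DataFrame(recs, columns=["source_id", "target_id", "weight"]).to_csv(
            path, sep="\t", index=False, float_format=_FLOAT_FMT
        )
    elif format == "graphml":
        import networkx as nx

        g = nx.Graph()
        if bipartite:
            for r in rows:
                g.add_node(f"pheno:{r}", layer="phenotype")
            for c in cols:
                g.add_node(f"snp:{c}", layer="snp")
            for i, r in enumerate(rows):
                for j, c in enumerate(cols):
                    g.add_edge(f"pheno:{r}", f"snp:{c}", weight=float(mat[i, j]))
        else:
            for r in rows:
                g.add_node(r, layer="phenotype")
            for i in range(len(rows)):
                for j in range(i + 1, len(cols)):
                    g.add_edge(rows[i], cols[j], weight=float(mat[i, j]))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_matrix(path) -> pd.DataFrame:
    """Read a labeled matrix TSV back into a DataFrame (ids as index)."""
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def read_association_matrix(path) -> AssociationStrengthMatrix:
    """Rebuild an association-strength matrix from its matrix TSV.

    Per-edge p-values are recovered from ``|T|`` through the chi-square(1)
    upper tail; signs from the sign of ``T``.
    """
    from scipy.stats import chi2

    df = read_network_matrix(path)
    t = df.to_numpy(dtype=float)
    return AssociationStrengthMatrix(
        T=t,
        signs=np.sign(t).astype(int),
        pvals=chi2.sf(np.abs(t), df=1),
        trait_ids=list(df.index.astype(str)),
        snp_ids=list(df.columns.astype(str)),
    )


def write_modules(partition: ModulePartition, path, af_path=None) -> None:
    pd.DataFrame(
        {"trait_id": partition.trait_ids, "module": partition.labels}
    ).to_csv(path, sep="\t", index=False)
    if af_path is not None:
        pd.DataFrame(
            {"n_clusters": np.arange(1, len(partition.af) + 1), "af": partition.af}
        ).to_csv(af_path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_modules(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"trait_id": str})


def write_results(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
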