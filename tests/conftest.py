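import numpy as np
import pytest

from gpn.datasets import GenotypeDataset, PhenotypeDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240510)


@pytest.fixture
def tiny_raw(tmp_path):
    """3-sample, 2-SNP PLINK .raw fixture with counts (0,1,2) and (1,1,0)."""
    path = tmp_path / "tiny.raw"
    path.write_text(
        "FID IID PAT MAT SEX PHENOTYPE rs1_A rs2_C\n"
        "f1 s1 0 0 1 -9 0 1\n"
        "f2 s2 0 0 2 -9 1 1\n"
        "f3 s3 0 0 1 -9 2 0\n"
    )
    return path


@pytest.fixture
def small_dataset(rng):
    """Aligned genotype/phenotype pair: 200 samples, 30 SNPs, 4 quantitative traits."""
    n, m, k = 200, 30, 4
    counts = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    geno = GenotypeDataset([f"s{i}" for i in range(n)], [f"snp{j}" for j in range(m)], counts)
    y = rng.standard_normal((n, k))
    pheno = PhenotypeDataset(
        [f"s{i}" for i in range(n)], [f"t{j}" for j in range(k)], y, ["quantitative"] * k
    )
    return geno, pheno
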