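import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_cohort(rng, tmp_path):
    """A 10-host, 5-taxon, 20-SNP cohort written as tab-delimited files."""
    hosts = [f"H{i}" for i in range(10)]
    taxa = [f"genus{j}" for j in range(5)]
    snps = [f"rs{j}" for j in range(20)]
    abundance = pd.DataFrame(
        rng.lognormal(2, 1, (10, 5)), index=hosts, columns=taxa
    )
    freq = rng.uniform(0.2, 0.5, 20)
    geno = pd.DataFrame(
        (rng.random((10, 20)) < freq).astype(int)
        + (rng.random((10, 20)) < freq).astype(int) - 1,
        index=hosts, columns=snps,
    )
    cov = pd.DataFrame(
        {"age": rng.integers(20, 70, 10), "sex": rng.integers(0, 2, 10)}, index=hosts
    )
    pheno = pd.DataFrame({"bmi": rng.normal(26, 4, 10)}, index=hosts)
    paths = {}
    for name, df in [("abundance", abundance), ("genotypes", geno),
                     ("covariates", cov), ("phenotypes", pheno)]:
        p = tmp_path / f"{name}.tsv"
        df.to_csv(p, sep="\t", index_label="host")
        paths[name] = p
    return paths
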