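"""Readers and writers for cohort tables, genotypes, networks and config.

Conventions: abundance/covariate/phenotype tables are tab-delimited with
a header row and host IDs in the first column; genotype input is either a
VCF (GT dosage 2/1/0 mapped to codes 1/0/-1 for AA/Aa/aa) or a
tab-delimited coded matrix; networks round-trip through an edge-list TSV
and GraphML; configuration is YAML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .network import MicrobialNetwork, DIRECTED_TYPES

logger = logging.getLogger("mnqtl")

__all__ = [
    "CohortBundle",
    "read_abundance",
    "read_table",
    "read_genotypes",
    "read_culture_series",
    "load_cohort",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
    "load_config",
]


def read_abundance(path) -> pd.DataFrame:
    """Host x taxon abundance matrix; validates nonnegativity and host IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate host IDs in {path}: {dupes}")
    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric abundance at host {df.index[r]!r}, taxon {df.columns[c]!r} in {path}"
        )
    neg = values.to_numpy() < 0
    if neg.any():
        r, c = np.argwhere(neg)[0]
        raise ValueError(
            f"negative abundance at host {df.index[r]!r}, taxon {df.columns[c]!r} in {path}"
        )
    return values


def read_table(path) -> pd.DataFrame:
    """Generic tab-delimited table with host IDs in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate host IDs in {path}")
    return df


def read_culture_series(path) -> pd.DataFrame:
    """Long-format co/monoculture time series.

    Columns: pair_id, time_h, strain_role (u/v), co_abundance,
    mono_abundance.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"pair_id", "time_h", "strain_role", "co_abundance", "mono_abundance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"culture table {path} lacks columns {sorted(missing)}")
    return df


def _genotypes_from_vcf(path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    hosts = list(vcf.samples)
    snp_ids, rows = [], []
    for variant in vcf:
        sid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        snp_ids.append(sid)
        # gt_types: 0=hom-ref, 1=het, 3=hom-alt, 2=unknown
        codes = np.full(len(hosts), np.nan)
        gt = variant.gt_types
        codes[gt == 3] = 1.0   # AA (alt/alt)
        codes[gt == 1] = 0.0   # Aa
        codes[gt == 0] = -1.0  # aa (ref/ref)
        rows.append(codes)
    return pd.DataFrame(np.array(rows).T, index=hosts, columns=snp_ids)


def read_genotypes(path) -> pd.DataFrame:
    """Host x SNP coded genotype matrix from VCF or TSV.

    VCF alt-allele dosage 2/1/0 maps to codes 1/0/-1 (AA/Aa/aa); missing
    calls become NaN.  A TSV must already contain codes in {1, 0, -1} or
    blanks.
    """
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return _genotypes_from_vcf(p)
    df = read_table(p).apply(pd.to_numeric, errors="coerce")
    vals = df.to_numpy()
    bad = np.isfinite(vals) & ~np.isin(vals, (1.0, 0.0, -1.0))
    if bad.any():
        raise ValueError(f"genotype matrix {path} contains codes outside {{1, 0, -1}}")
    return df


@dataclass
class CohortBundle:
    """Host-aligned abundance, genotype, covariate and phenotype tables."""

    abundance: pd.DataFrame
    genotypes: pd.DataFrame = None
    covariates: pd.DataFrame = None
    phenotypes: pd.DataFrame = None
    seasons: pd.Series = None
    taxon_labels: dict = field(default_factory=dict)

    @property
    def hosts(self) -> list:
        return list(self.abundance.index)


def load_cohort(
    abundance_path,
    genotype_path=None,
    covariate_path=None,
    phenotype_path=None,
    season_column: str = "season",
) -> CohortBundle:
    """Load and align all cohort components on shared host IDs.

    Hosts missing from any supplied component are dropped, with the count
    logged.  Season labels, if present as a covariate column, must be
    'winter' or 'summer'.
    """
    abundance = read_abundance(abundance_path)
    genotypes = read_genotypes(genotype_path) if genotype_path else None
    covariates = read_table(covariate_path) if covariate_path else None
    phenotypes = read_table(phenotype_path) if phenotype_path else None
    hosts = set(abundance.index)
    for part in (genotypes, covariates, phenotypes):
        if part is not None:
            hosts &= set(part.index)
    dropped = len(abundance.index) - len(hosts)
    if dropped:
        logger.warning("dropped %d hosts missing from one or more components", dropped)
    hosts = [h for h in abundance.index if h in hosts]
    seasons = None
    if covariates is not None and season_column in covariates.columns:
        seasons = covariates.loc[hosts, season_column]
        bad = set(seasons.dropna().unique()) - {"winter", "summer"}
        if bad:
            raise ValueError(f"unknown season labels {sorted(bad)}")
        covariates = covariates.drop(columns=[season_column])
    # taxon numeric labels, mirroring the numbered-genus convention
    taxon_labels = {name: i + 1 for i, name in enumerate(abundance.columns)}
    return CohortBundle(
        abundance=abundance.loc[hosts],
        genotypes=genotypes.loc[hosts] if genotypes is not None else None,
        covariates=covariates.loc[hosts] if covariates is not None else None,
        phenotypes=phenotypes.loc[hosts] if phenotypes is not None else None,
        seasons=seasons,
        taxon_labels=taxon_labels,
    )


def write_edge_list(net: MicrobialNetwork, path) -> None:
    net.edge_list().to_csv(path, sep="\t", index=False)


def read_edge_list(path, nodes=None) -> MicrobialNetwork:
    """Rebuild a network from an edge-list TSV written by write_edge_list."""
    df = pd.read_csv(path, sep="\t")
    if df.empty and nodes is None:
        raise ValueError(f"empty edge list {path} requires an explicit node list")
    itype = df["type"].iloc[0] if len(df) else "mutualism"
    directed = itype in DIRECTED_TYPES
    if nodes is None:
        nodes = sorted(set(df["u"]) | set(df["v"]))
    index = {nm: i for i, nm in enumerate(nodes)}
    n = len(nodes)
    adjacency = np.zeros((n, n), dtype=int)
    weights = np.full((n, n), np.nan)
    for _, row in df.iterrows():
        i, j = index[row["u"]], index[row["v"]]
        adjacency[i, j] = 1
        weights[i, j] = row["weight"]
        if not directed:
            adjacency[j, i] = 1
            weights[j, i] = row["weight"]
    return MicrobialNetwork(itype, list(nodes), adjacency, weights, directed)


def write_graphml(net: MicrobialNetwork, path) -> None:
    import networkx as nx

    nx.write_graphml(net.to_networkx(), path)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg
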