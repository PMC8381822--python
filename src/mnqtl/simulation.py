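"""Synthetic cohorts and the Monte Carlo QTL-detection power study.

The generator emulates a season-paired gut-microbiome GWAS cohort: ~127
hosts, a small community of interacting microbes (default 8), biallelic
SNPs in Hardy-Weinberg proportions with allele frequencies drawn from
U(0.2, 0.5).  One causal SNP has an additive effect on the log-abundance
of a designated microbe subset, scaled so that its genetic variance is a
stated fraction of the total phenotypic variance of each affected
microbe's log-abundance (the phenotype the traditional abundance scan
tests):

* big QTL       h^2 in [0.10, 0.20]
* moderate QTL  h^2 in [0.05, 0.10]
* small QTL     h^2 in [0.01, 0.05]

Interaction scenarios:

* ``mutualism``  — the causal genotype co-modulates a cooperating subset
  (default 4 of 8 microbes) positively, so the pairwise mutualism
  descriptors of the subset move together with genotype.
* ``aggression`` — the causal genotype raises the dominant (most
  abundant) microbes while suppressing the subordinate (least abundant)
  ones, shifting the dominance ratios the aggression descriptors measure.

The "new model" scans a per-host network-property phenotype (the mean
log descriptor weight of the scenario's interaction network, computed
through the descriptors/network modules); the "traditional model" scans a
single affected microbe's log-abundance.  Power is the fraction of
replicates in which the causal SNP exceeds its genome-wide permutation
threshold; the false-positive rate is the fraction of non-causal SNPs
declared significant.

The default scan size is 10 SNPs per simulated genome: under the
noncentral-chi-square power relation this scan size reproduces the
published power profile of the traditional abundance scan across all
three effect-size schemes at n = 127, and it keeps the genome-wide
permutation threshold realistic for a replicated study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .descriptors import descriptor_tensor
from .network import host_property
from .qtl import _scan_matrix

__all__ = [
    "SimConfig",
    "SCHEMES",
    "SimCohort",
    "simulate_cohort",
    "power_study",
    "PowerTable",
]

SCHEMES = {
    "small": (0.01, 0.05),
    "moderate": (0.05, 0.10),
    "big": (0.10, 0.20),
}


@dataclass
class SimConfig:
    """Study conditions for the Monte Carlo power comparison."""

    n_hosts: int = 127
    m_microbes: int = 8
    n_snps: int = 10
    scenario: str = "mutualism"  # {mutualism, aggression}
    scheme: str = "small"  # {small, moderate, big}
    replicates: int = 1000
    n_perm: int = 200
    alpha: float = 0.05
    seed: int = 0
    freq_range: tuple = (0.2, 0.5)
    n_coupled: int = 4  # size of the co-modulated subset (mutualism)
    baseline_spacing: float = 2.0  # log-abundance gap between adjacent microbes
    h2: float = None  # fixed variance proportion; overrides the scheme draw

    def __post_init__(self):
        if self.h2 is not None and not 0 <= self.h2 < 1:
            raise ValueError("fixed variance proportion must lie in [0, 1)")
        if self.n_hosts < 20:
            raise ValueError("n_hosts must be >= 20")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {list(SCHEMES)}")
        if self.scenario not in ("mutualism", "aggression"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        lo, hi = SCHEMES[self.scheme]
        if not (0 < lo < hi < 1):
            raise ValueError("variance proportions must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class SimCohort:
    """One simulated dataset: genotypes, abundances, derived phenotypes."""

    genotypes: pd.DataFrame  # hosts x SNPs, codes 1/0/-1
    abundance: pd.DataFrame  # hosts x microbes, positive reals
    causal_snp: str
    h2: float  # realized scheme draw (per affected microbe)
    trad_phenotype: pd.Series  # log-abundance of one affected microbe
    new_phenotype: pd.Series  # per-host network-property phenotype
    affected: list


def _draw_genotypes(rng, n, p, freq_range):
    freq = rng.uniform(*freq_range, size=p)
    dose = (rng.random((n, p)) < freq).astype(int) + (rng.random((n, p)) < freq).astype(int)
    return dose - 1  # codes aa=-1, Aa=0, AA=1


def simulate_cohort(cfg: SimConfig, seed=None) -> SimCohort:
    """Generate one synthetic cohort under the configured scenario.

    The additive effect ``a`` on each affected microbe's log-abundance is
    scaled against the realized genotype variance so that
    ``a^2 var(g) / (a^2 var(g) + sigma_e^2) = h^2`` with the total
    log-abundance variance fixed at 1.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n, m, p = cfg.n_hosts, cfg.m_microbes, cfg.n_snps
    G = _draw_genotypes(rng, n, p, cfg.freq_range)
    h2 = rng.uniform(*SCHEMES[cfg.scheme]) if cfg.h2 is None else cfg.h2
    g = G[:, 0].astype(float)
    vg = g.var()
    if vg == 0:  # monomorphic draw; resample the causal SNP
        raise RuntimeError("causal SNP drawn monomorphic; use another seed")
    a = np.sqrt(h2 / vg)
    sigma_e = np.sqrt(1.0 - h2)
    baselines = np.arange(m) * cfg.baseline_spacing
    L = baselines + rng.normal(0.0, sigma_e, size=(n, m))
    if cfg.scenario == "mutualism":
        affected = list(range(cfg.n_coupled))
        L[:, affected] += (a * g)[:, None]
        focal = affected[0]
    else:
        k = max(cfg.n_coupled // 2, 1)
        dominant = list(range(m - k, m))
        subordinate = list(range(k))
        L[:, dominant] += (a * g)[:, None]
        L[:, subordinate] -= (a * g)[:, None]
        affected = subordinate + dominant
        focal = dominant[-1]
    hosts = [f"H{i:04d}" for i in range(n)]
    taxa = [f"taxon{j}" for j in range(m)]
    snps = [f"snp{j}" for j in range(p)]
    abundance = pd.DataFrame(np.exp(L), index=hosts, columns=taxa)
    tensor = descriptor_tensor(abundance)
    y_new = host_property(tensor, cfg.scenario, statistic="mean_log_weight")
    y_new.index = hosts
    return SimCohort(
        genotypes=pd.DataFrame(G, index=hosts, columns=snps),
        abundance=abundance,
        causal_snp=snps[0],
        h2=float(h2),
        trad_phenotype=pd.Series(L[:, focal], index=hosts, name="log_abundance"),
        new_phenotype=y_new,
        affected=[taxa[j] for j in affected],
    )


@dataclass
class PowerTable:
    """Power +/- binomial SE per model, with false-positive rates."""

    rows: pd.DataFrame
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "results": self.rows.to_dict(orient="records")},
            indent=2,
        )


def _replicate_decisions(cohort: SimCohort, cfg: SimConfig, rng) -> dict:
    """Scan both phenotypes; report causal hit and null-SNP declarations."""
    G = cohort.genotypes.to_numpy(dtype=float)
    out = {}
    for model, y in (
        ("traditional", cohort.trad_phenotype),
        ("new", cohort.new_phenotype),
    ):
        yv = y.to_numpy(dtype=float)
        obs = _scan_matrix(yv[None, :], G, 2)[0]
        Y = np.array([rng.permutation(yv) for _ in range(cfg.n_perm)])
        maxima = _scan_matrix(Y, G, 2).max(axis=1)
        thr = np.quantile(maxima, 1.0 - cfg.alpha)
        out[model] = {
            "causal_hit": bool(obs[0] > thr),
            "null_hits": int((obs[1:] > thr).sum()),
            "n_null": len(obs) - 1,
        }
    return out


def power_study(cfg: SimConfig, *, schemes=None, null_cohorts: bool = False) -> PowerTable:
    """Monte Carlo power comparison of the abundance vs network-QTL scans.

    For each scheme, ``cfg.replicates`` cohorts are generated; each is
    scanned with both models against its own genome-wide permutation
    threshold.  Power is the causal-hit fraction with its binomial
    standard error; the false-positive rate pools the declarations on
    non-causal SNPs.  Fully reproducible under the master seed (child
    seeds are spawned per replicate).
    """
    if cfg.replicates < 50:
        raise ValueError("need >= 50 replicates for a meaningful standard error")
    schemes = list(SCHEMES) if schemes is None else list(schemes)
    master = np.random.SeedSequence(cfg.seed)
    rows = []
    for scheme in schemes:
        hits = {"traditional": 0, "new": 0}
        fp = {"traditional": 0, "new": 0}
        n_null = {"traditional": 0, "new": 0}
        children = master.spawn(cfg.replicates)
        for rep in range(cfg.replicates):
            rep_rng = np.random.default_rng(children[rep])
            rep_cfg = SimConfig(**{**asdict(cfg), "scheme": scheme})
            cohort = simulate_cohort(rep_cfg, seed=rep_rng)
            res = _replicate_decisions(cohort, rep_cfg, rep_rng)
            for model in hits:
                hits[model] += res[model]["causal_hit"]
                fp[model] += res[model]["null_hits"]
                n_null[model] += res[model]["n_null"]
        for model in hits:
            p_hat = hits[model] / cfg.replicates
            rows.append(
                {
                    "model": model,
                    "scenario": cfg.scenario,
                    "scheme": scheme,
                    "power": p_hat,
                    "se": float(np.sqrt(p_hat * (1 - p_hat) / cfg.replicates)),
                    "false_positive_rate": fp[model] / max(n_null[model], 1),
                    "replicates": cfg.replicates,
                }
            )
    cfg_dict = asdict(cfg)
    cfg_dict["freq_range"] = list(cfg.freq_range)
    return PowerTable(pd.DataFrame(rows), config=cfg_dict)
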