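"""Likelihood-ratio QTL mapping of network-property phenotypes.

For a biallelic SNP with genotypes AA/Aa/aa coded 1/0/-1 and a corrected
phenotype ``y``, the alternative model gives each genotype class its own
normal mean with a shared variance; the null model has a single mean.
With maximum-likelihood (divide-by-n) variances the log-likelihood-ratio
statistic reduces to

    LRT = n * ln(sigma0^2 / sigma1^2)

which is asymptotically chi-square with (classes - 1) degrees of freedom
under the null.  Genome-wide significance uses the permutation
distribution of the maximum LRT across SNPs under phenotype shuffling.

The scan machinery is fully vectorized across SNPs and across permuted
phenotype copies, which keeps genome-wide permutation thresholds cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeVector",
    "correct_phenotype",
    "fit_snp",
    "scan",
    "permutation_threshold",
    "ScanResult",
    "seasonal_difference",
]

GENOTYPE_CODES = (1, 0, -1)  # AA, Aa, aa
_VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class GenotypeVector:
    """Per-host genotype codes for one SNP (1/0/-1 = AA/Aa/aa, NaN missing)."""

    codes: np.ndarray
    snp_id: str = ""
    position: int = -1

    def __post_init__(self):
        c = np.asarray(self.codes, dtype=float)
        object.__setattr__(self, "codes", c)
        valid = np.isin(c[~np.isnan(c)], GENOTYPE_CODES)
        if not valid.all():
            raise ValueError(f"genotype codes must be in {GENOTYPE_CODES} or NaN")

    def class_counts(self) -> dict:
        return {g: int(np.sum(self.codes == g)) for g in GENOTYPE_CODES}


def correct_phenotype(
    raw, covariates: pd.DataFrame = None, *, kinship: np.ndarray = None
) -> pd.Series:
    """Residualize a phenotype on fixed-effect covariates.

    Returns the residuals of an intercept-including least-squares fit of
    ``raw`` on the covariate columns (age, sex, ...).  With no covariates
    the phenotype is simply centered.  If ``kinship`` (a full residual
    covariance matrix, e.g. from a relatedness model) is supplied, the fit
    is generalized least squares: both sides are whitened by the inverse
    Cholesky factor before the regression.  Rank-deficient covariates
    raise an error naming the collinear columns.
    """
    y = pd.Series(raw).astype(float)
    if covariates is None or covariates.shape[1] == 0:
        return y - y.mean()
    C = covariates.loc[y.index] if covariates.index.equals(y.index) or set(
        y.index
    ).issubset(covariates.index) else covariates
    X = np.column_stack([np.ones(len(y)), C.to_numpy(dtype=float)])
    names = ["intercept"] + list(C.columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = []
        rank = 1
        for j in range(1, X.shape[1]):
            r = np.linalg.matrix_rank(X[:, : j + 1])
            if r == rank:
                bad.append(names[j])
            rank = r
        raise ValueError(f"collinear covariate columns: {bad}")
    yv = y.to_numpy()
    if kinship is not None:
        L = np.linalg.cholesky(np.asarray(kinship, dtype=float))
        X = np.linalg.solve(L, X)
        yv = np.linalg.solve(L, yv)
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    return pd.Series(resid, index=y.index, name=getattr(raw, "name", "residual"))


@dataclass
class SnpFit:
    """Per-SNP MLEs and likelihood-ratio test."""

    means: dict  # genotype code -> class mean (NaN if class absent/dropped)
    sigma2: float
    sigma2_null: float
    loglik_alt: float
    loglik_null: float
    lrt: float
    n: int
    n_classes: int
    degenerate: bool = False


def fit_snp(y, genotypes, *, min_class_size: int = 2) -> SnpFit:
    """Fit the genotype-dependent normal model for one SNP.

    Classes with fewer than ``min_class_size`` members are dropped with a
    warning (their hosts excluded from both models).  Missing genotypes
    are dropped per-SNP.  A constant phenotype yields LRT = 0 by
    convention; a zero within-class variance is floored and flagged
    degenerate.
    """
    g = genotypes.codes if isinstance(genotypes, GenotypeVector) else np.asarray(
        genotypes, dtype=float
    )
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(g) & ~np.isnan(y)
    small = []
    for c in GENOTYPE_CODES:
        idx = keep & (g == c)
        if 0 < idx.sum() < min_class_size:
            small.append(c)
            keep &= g != c
    if small:
        warnings.warn(
            f"dropped genotype classes {small} below minimum size {min_class_size}",
            stacklevel=2,
        )
    yk, gk = y[keep], g[keep]
    n = len(yk)
    classes = [c for c in GENOTYPE_CODES if np.sum(gk == c) > 0]
    if len(classes) < 2:
        raise ValueError("fewer than 2 usable genotype classes; SNP skipped")
    means = {c: np.nan for c in GENOTYPE_CODES}
    ss_within = 0.0
    for c in classes:
        yc = yk[gk == c]
        means[c] = float(yc.mean())
        ss_within += float(((yc - yc.mean()) ** 2).sum())
    mu0 = yk.mean()
    ss_total = float(((yk - mu0) ** 2).sum())
    sigma2_null = ss_total / n
    sigma2 = ss_within / n
    degenerate = False
    if sigma2_null <= _VARIANCE_FLOOR:  # constant phenotype
        return SnpFit(means, max(sigma2, _VARIANCE_FLOOR), max(sigma2_null, _VARIANCE_FLOOR),
                      np.nan, np.nan, 0.0, n, len(classes), degenerate=True)
    if sigma2 <= _VARIANCE_FLOOR:
        warnings.warn("zero within-class variance; floored and flagged degenerate",
                      stacklevel=2)
        sigma2 = _VARIANCE_FLOOR
        degenerate = True
    ll_alt = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    ll_null = -0.5 * n * (np.log(2 * np.pi * sigma2_null) + 1.0)
    lrt = max(float(n * np.log(sigma2_null / sigma2)), 0.0)
    return SnpFit(means, sigma2, sigma2_null, ll_alt, ll_null, lrt, n, len(classes),
                  degenerate)


def _scan_matrix(Y: np.ndarray, G: np.ndarray, min_class_size: int) -> np.ndarray:
    """LRT for every (phenotype row of Y) x (SNP column of G).

    Y: (B, n) phenotype copies; G: (n, p) codes with NaN missing.
    Host-inclusion masks depend only on G, so permuted copies share them.
    Returns (B, p) LRT values.
    """
    B, n = Y.shape
    include = ~np.isnan(G)
    class_masks = {}
    for c in GENOTYPE_CODES:
        m = (G == c)
        counts = m.sum(axis=0)
        drop = (counts > 0) & (counts < min_class_size)
        if drop.any():
            include &= ~(m & drop[None, :])
            m = m & ~drop[None, :]
        class_masks[c] = m
    W = include.astype(float)  # (n, p)
    n_j = W.sum(axis=0)
    Y2 = Y**2
    Sw = Y @ W
    Qw = Y2 @ W
    with np.errstate(invalid="ignore", divide="ignore"):
        ss_total = Qw - Sw**2 / np.maximum(n_j, 1)
        ss_within = np.zeros_like(ss_total)
        for c in GENOTYPE_CODES:
            Mc = class_masks[c].astype(float)
            nc = Mc.sum(axis=0)
            Sc = Y @ Mc
            Qc = Y2 @ Mc
            ss_within += np.where(nc > 0, Qc - Sc**2 / np.maximum(nc, 1), 0.0)
        s0 = ss_total / np.maximum(n_j, 1)
        s1 = np.maximum(ss_within / np.maximum(n_j, 1), _VARIANCE_FLOOR)
        lrt = np.where(
            (n_j >= 4) & (s0 > _VARIANCE_FLOOR),
            n_j * np.log(np.maximum(s0, _VARIANCE_FLOOR) / s1),
            0.0,
        )
    return np.maximum(lrt, 0.0)


@dataclass
class ScanResult:
    """Genome scan of one phenotype: per-SNP table plus the threshold."""

    table: pd.DataFrame
    threshold: float
    alpha: float
    n_perm: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["lrt"] > self.threshold]


def scan(
    y,
    genotype_matrix: pd.DataFrame,
    *,
    min_class_size: int = 2,
) -> pd.DataFrame:
    """Per-SNP MLEs and LRT for every SNP column of a coded genotype matrix."""
    G = genotype_matrix.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    lrt = _scan_matrix(yv[None, :], G, min_class_size)[0]
    rows = []
    for j, snp in enumerate(genotype_matrix.columns):
        g = G[:, j]
        keep = ~np.isnan(g) & ~np.isnan(yv)
        means = {}
        for c in GENOTYPE_CODES:
            idx = keep & (g == c)
            means[c] = float(yv[idx].mean()) if idx.sum() >= min_class_size else np.nan
        rows.append(
            {
                "snp": snp,
                "mu_AA": means[1],
                "mu_Aa": means[0],
                "mu_aa": means[-1],
                "n": int(keep.sum()),
                "lrt": lrt[j],
            }
        )
    return pd.DataFrame(rows)


def permutation_threshold(
    y,
    genotype_matrix: pd.DataFrame,
    *,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    min_class_size: int = 2,
) -> float:
    """Genome-wide LRT threshold from the max-statistic permutation law.

    The phenotype is shuffled across hosts ``n_perm`` times; each round
    records the maximum LRT over all SNPs; the threshold is the
    (1 - alpha) empirical quantile of those maxima.  Bit-reproducible for
    a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable tail quantile")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    G = genotype_matrix.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    Y = np.array([rng.permutation(yv) for _ in range(n_perm)])
    maxima = _scan_matrix(Y, G, min_class_size).max(axis=1)
    return float(np.quantile(maxima, 1.0 - alpha))


def scan_with_threshold(
    y, genotype_matrix, *, n_perm=1000, alpha=0.05, seed=0, min_class_size=2
) -> ScanResult:
    """Convenience wrapper: per-SNP scan plus its permutation threshold."""
    table = scan(y, genotype_matrix, min_class_size=min_class_size)
    thr = permutation_threshold(
        y, genotype_matrix, n_perm=n_perm, alpha=alpha, seed=seed,
        min_class_size=min_class_size,
    )
    table["significant"] = table["lrt"] > thr
    return ScanResult(table, thr, alpha, n_perm)


def seasonal_difference(values: pd.DataFrame, *, minuend: str = "winter",
                        subtrahend: str = "summer") -> pd.Series:
    """Within-host seasonal perturbation of a property (winter - summer).

    ``values`` has hosts as rows and season labels as columns; only hosts
    measured in both seasons are kept.
    """
    both = values[[minuend, subtrahend]].dropna()
    return both[minuend] - both[subtrahend]
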