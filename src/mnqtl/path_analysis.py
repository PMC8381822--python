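"""Path-analysis decomposition of SNP -> phenotype correlations.

A QTL's correlation with an end-point phenotype ``z`` (e.g. BMI) is
dissected into a direct path and indirect paths routed through network
perturbation endophenotypes ``y_j`` (winter - summer differences of
network properties):

    r_gz = P_{z<-g} + sum_j P_{z<-y_j} r_{gy_j}

Path coefficients are standardized multiple-regression weights of ``z``
on ``(g, y_1, ..., y_k)``, so the decomposition identity above holds
exactly by the normal equations, as does the coefficient of determination

    R^2 = beta' R_xx beta       (the quadratic form in the predictor
                                 correlation matrix)

and the residual path ``P_{z<-e} = sqrt(1 - R^2)``.  Mediators enter only
when their genotype correlation is significant at the 10% level.
Genotype-phenotype correlations can be estimated either by dose-coded
Pearson correlation or by a mutual-information estimator mapped to the
correlation scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PathSystem",
    "PathModel",
    "mi_correlation",
    "select_mediators",
    "decompose",
]

_VAR_FLOOR = 1e-12


def mi_correlation(g, y, *, estimator: str = "gaussian") -> float:
    """Correlation between a discrete genotype and a continuous variable.

    ``estimator='gaussian'`` estimates the mutual information I(g; y)
    with class-conditional Gaussian entropies,

        I = 0.5 [ ln sigma_total^2 - sum_c pi_c ln sigma_c^2 ],

    and maps it to the correlation scale via |r| = sqrt(1 - exp(-2 I))
    (exact for a bivariate Gaussian); the sign is taken from the
    dose-coded covariance.  ``estimator='pearson'`` returns the plain
    dose-coded Pearson correlation.  A single observed genotype class
    leaves r undefined (NaN with a warning).
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(g) & ~np.isnan(y)
    g, y = g[keep], y[keep]
    classes = np.unique(g)
    if len(classes) < 2:
        warnings.warn("single genotype class; correlation undefined", stacklevel=2)
        return np.nan
    if estimator == "pearson":
        return float(stats.pearsonr(g, y)[0])
    if estimator != "gaussian":
        raise ValueError(f"unknown estimator {estimator!r}")
    n = len(y)
    total_var = max(y.var(), _VAR_FLOOR)
    cond = 0.0
    for c in classes:
        yc = y[g == c]
        cond += (len(yc) / n) * np.log(max(yc.var(), _VAR_FLOOR))
    mi = 0.5 * (np.log(total_var) - cond)
    # under independence 2n*I_hat is ~chi-square with 2(C-1) df (per-class
    # mean and variance estimates), so subtract its expectation (C-1)/n
    mi = max(mi - (len(classes) - 1) / n, 0.0)
    r = np.sqrt(1.0 - np.exp(-2.0 * mi))
    sign = np.sign(np.cov(g, y)[0, 1])
    return float(r * (sign if sign != 0 else 1.0))


@dataclass
class PathSystem:
    """Aligned genotype, mediator(s) and end-point phenotype for one QTL."""

    g: np.ndarray
    mediators: pd.DataFrame  # hosts x mediator properties (y_j)
    z: np.ndarray
    genotype_correlation: str = "gaussian"  # estimator for reported r_gy / r_gz

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if len(self.g) != len(self.z) or len(self.g) != len(self.mediators):
            raise ValueError("g, mediators and z must be host-aligned")

    def correlations(self) -> dict:
        """Reported correlations: r_gy_j, r_gz (MI-based by default), r_y_jz."""
        out = {"r_gz": mi_correlation(self.g, self.z, estimator=self.genotype_correlation)}
        for name in self.mediators.columns:
            yj = self.mediators[name].to_numpy()
            out[f"r_g,{name}"] = mi_correlation(
                self.g, yj, estimator=self.genotype_correlation
            )
            out[f"r_{name},z"] = float(stats.pearsonr(yj, self.z)[0])
        return out


def select_mediators(system: PathSystem, *, alpha: float = 0.10) -> list:
    """Mediators whose genotype correlation is significant at level alpha.

    Two-sided dose-coded Pearson test of each g-y_j link; mediators with
    p <= alpha are retained.
    """
    kept = []
    for name in system.mediators.columns:
        yj = system.mediators[name].to_numpy(dtype=float)
        keep = ~np.isnan(yj)
        if keep.sum() < 3 or np.std(yj[keep]) == 0:
            continue
        _, p = stats.pearsonr(system.g[keep], yj[keep])
        if p <= alpha:
            kept.append(name)
    return kept


@dataclass
class PathModel:
    """Fitted path decomposition for one QTL-network-phenotype system."""

    direct: float  # P_{z<-g}
    mediator_coefficients: dict  # name -> P_{z<-y_j}
    indirect: dict  # name -> P_{z<-y_j} * r_{gy_j}
    r_gz: float
    r_gy: dict
    r_yz: dict
    r_squared: float
    residual_path: float  # P_{z<-e}
    included: list
    n: int
    reported_correlations: dict = field(default_factory=dict)

    @property
    def total_indirect(self) -> float:
        return float(sum(self.indirect.values()))

    def to_json(self, **kwargs) -> str:
        payload = {
            "direct": self.direct,
            "mediator_coefficients": self.mediator_coefficients,
            "indirect": self.indirect,
            "r_gz": self.r_gz,
            "r_gy": self.r_gy,
            "r_yz": self.r_yz,
            "r_squared": self.r_squared,
            "residual_path": self.residual_path,
            "included_mediators": self.included,
            "n": self.n,
            "reported_correlations": self.reported_correlations,
        }
        return json.dumps(payload, indent=2, **kwargs)

    def edge_table(self) -> pd.DataFrame:
        """Source/target/coefficient rows mirroring a path diagram."""
        rows = [{"source": "g", "target": "z", "coefficient": self.direct,
                 "sign": "+" if self.direct >= 0 else "-"}]
        for name, coef in self.mediator_coefficients.items():
            rows.append({"source": name, "target": "z", "coefficient": coef,
                         "sign": "+" if coef >= 0 else "-"})
            rows.append({"source": "g", "target": name,
                         "coefficient": self.r_gy[name],
                         "sign": "+" if self.r_gy[name] >= 0 else "-"})
        rows.append({"source": "e", "target": "z", "coefficient": self.residual_path,
                     "sign": "+"})
        return pd.DataFrame(rows)


def _standardize(x):
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd <= 0:
        raise ValueError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


def decompose(
    system: PathSystem,
    *,
    mediators: list = None,
    single_path: bool = False,
    max_condition: float = 1e8,
) -> PathModel:
    """Fit the path model for a QTL-mediator-phenotype system.

    Coefficients are standardized multiple-regression weights of z on
    (g, selected mediators), obtained from the normal equations in
    correlation form, so ``r_gz = direct + sum indirect`` holds to
    numerical precision.  ``single_path=True`` applies the constrained
    single-mediator variant in which the mediator keeps its marginal
    correlation as its path coefficient (P_{z<-y} = r_yz) and the direct
    path absorbs the remainder of the decomposition identity.

    Collinear mediator sets are rejected with the condition number
    reported; drop mediators and refit.
    """
    if mediators is None:
        mediators = select_mediators(system)
    names = list(mediators)
    n = len(system.g)
    if n <= len(names) + 2:
        raise ValueError("need n > number of predictors + 1 hosts")
    gs = _standardize(system.g)
    zs = _standardize(system.z)
    Y = np.column_stack([_standardize(system.mediators[m]) for m in names]) if names else None

    r_gz = float(gs @ zs / n)
    r_gy = {m: float(gs @ Y[:, j] / n) for j, m in enumerate(names)}
    r_yz = {m: float(Y[:, j] @ zs / n) for j, m in enumerate(names)}

    if not names:
        direct, coefs, indirect = r_gz, {}, {}
        r2 = r_gz**2
    elif single_path and len(names) == 1:
        m = names[0]
        coefs = {m: r_yz[m]}
        direct = r_gz - r_yz[m] * r_gy[m]
        indirect = {m: coefs[m] * r_gy[m]}
        r2 = direct**2 + coefs[m] ** 2 + 2 * r_gy[m] * direct * coefs[m]
    else:
        X = np.column_stack([gs, Y])
        Rxx = (X.T @ X) / n
        cond = np.linalg.cond(Rxx)
        if cond > max_condition:
            raise ValueError(
                f"collinear predictors (condition number {cond:.3g}); drop mediators"
            )
        rxz = X.T @ zs / n
        beta = np.linalg.solve(Rxx, rxz)
        direct = float(beta[0])
        coefs = {m: float(beta[1 + j]) for j, m in enumerate(names)}
        indirect = {m: coefs[m] * r_gy[m] for m in names}
        r2 = float(beta @ Rxx @ beta)
    r2 = min(max(r2, 0.0), 1.0)
    return PathModel(
        direct=direct,
        mediator_coefficients=coefs,
        indirect=indirect,
        r_gz=r_gz,
        r_gy=r_gy,
        r_yz=r_yz,
        r_squared=r2,
        residual_path=float(np.sqrt(1.0 - r2)),
        included=names,
        n=n,
        reported_correlations=system.correlations(),
    )
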