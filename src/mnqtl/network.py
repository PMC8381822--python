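"""Interaction-network reconstruction and emergent-property indices.

From a cohort :class:`~mnqtl.descriptors.InteractionTensor`, one network
per interaction type is built: an edge between two taxa is retained when
its descriptor values across hosts are significantly elevated relative to
a within-host permutation null (taxon labels reshuffled inside each host),
with Benjamini–Hochberg FDR control.  Mutualism/antagonism networks are
undirected; aggression/altruism edges point from the more to the less
abundant taxon (majority vote across hosts).

Six emergent-property indices summarize a network and serve as mapping
phenotypes:

* connectivity   Con      — mean number of links per microbe
* closeness      C(u) = 1 / sum_v D(u, v)
* betweenness    B(u) = sum_{v<w} g_vw(u) / g_vw  (fractional counting)
* eccentricity   E(u) = 1 / max_v D(u, v)
* eigenvector    G: A G = lambda G, leading eigenpair
* PageRank       P(u) = (1 - d) + d sum_v a_vu P(v) / K_v, damping d = 0.85

All node-level indices are implemented directly from these definitions
(BFS distance/path-count machinery, dense eigensolves, linear-system
PageRank) so that an external graph library can serve as an independent
cross-check rather than the implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .descriptors import InteractionTensor, _pair_descriptor_arrays, _winsorize_rows

__all__ = [
    "MicrobialNetwork",
    "DistanceMatrix",
    "CentralityProfile",
    "HubReport",
    "build_network",
    "per_host_network",
    "host_property",
    "shortest_paths",
    "centralities",
    "detect_hubs",
    "powerlaw_test",
]

DIRECTED_TYPES = frozenset({"aggression", "altruism"})


@dataclass
class MicrobialNetwork:
    """A significance-filtered interaction network for one interaction type."""

    interaction_type: str
    nodes: list
    adjacency: np.ndarray  # binary, (n, n); row u -> col v for directed types
    weights: np.ndarray  # same shape; NaN where no edge
    directed: bool
    provenance: str = "cohort"
    season: str = ""
    edge_pvalues: pd.DataFrame = field(default=None, repr=False)
    indeterminate: bool = False

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.shape[0] != a.shape[1] or a.shape[0] != len(self.nodes):
            raise ValueError("adjacency must be square and match the node list")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-edges are not allowed")
        if not self.directed and not np.array_equal(a, a.T):
            raise ValueError("undirected network must have symmetric adjacency")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        e = int(self.adjacency.sum())
        return e if self.directed else e // 2

    def degrees(self) -> np.ndarray:
        """Number of incident links per node (in + out for directed)."""
        if self.directed:
            return self.adjacency.sum(axis=1) + self.adjacency.sum(axis=0)
        return self.adjacency.sum(axis=1)

    def edge_list(self) -> pd.DataFrame:
        rows = []
        n = self.n_nodes
        for i in range(n):
            for j in range(n):
                if self.adjacency[i, j] and (self.directed or i < j):
                    rows.append(
                        {
                            "u": self.nodes[i],
                            "v": self.nodes[j],
                            "type": self.interaction_type,
                            "weight": self.weights[i, j],
                            "directed": self.directed,
                        }
                    )
        return pd.DataFrame(rows, columns=["u", "v", "type", "weight", "directed"])

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edge_list().iterrows():
            g.add_edge(row["u"], row["v"], weight=row["weight"])
        return g


def _null_mean_distribution(tensor, interaction_type, n_perm, rng):
    """Cross-host mean descriptor per pair under within-host label shuffles.

    Null tensors receive the same per-host winsorization as the observed
    one (if any), so observed and null means are compared on one footing.
    """
    X = tensor.abundance.to_numpy(dtype=float)
    n_hosts, m = X.shape
    iu, iv = np.triu_indices(m, k=1)
    null = np.empty((n_perm, len(iu)))
    winsorized = (
        tensor.winsor_quantile is not None
        and interaction_type in ("mutualism", "antagonism")
    )
    for b in range(n_perm):
        # independent within-host shuffles via row-wise random-key argsort
        order = rng.random((n_hosts, m)).argsort(axis=1)
        perm = np.take_along_axis(X, order, axis=1)
        vals, _ = _pair_descriptor_arrays(perm, iu, iv, tensor.antagonism_form)
        v = vals[interaction_type]
        if winsorized:
            v = _winsorize_rows(v, tensor.winsor_quantile)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            null[b] = np.nanmean(v, axis=0)
    return null


def build_network(
    tensor: InteractionTensor,
    interaction_type: str,
    *,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    season: str = "",
) -> MicrobialNetwork:
    """Build the cohort-average network for one interaction type.

    The test statistic for a pair is its cross-host mean descriptor; the
    null distribution comes from reshuffling taxon labels independently
    within each host and recomputing (``n_perm`` rounds, fixed seed).
    Per-pair permutation p-values are BH-FDR adjusted and edges with
    q <= ``alpha`` are retained, weighted by the observed mean.  If every
    edge is filtered out an empty network is returned with a warning.
    """
    if interaction_type not in tensor.values:
        raise ValueError(f"unknown interaction type {interaction_type!r}")
    if tensor.n_hosts < 2:
        raise ValueError("need >= 2 hosts for the edge significance test")
    if tensor.abundance is None:
        raise ValueError("tensor must carry its source abundance matrix")
    directed = interaction_type in DIRECTED_TYPES
    vals = tensor.values[interaction_type]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        obs = np.nanmean(vals, axis=0)
    indeterminate = False
    if tensor.n_pairs < 3:
        # shuffling <=2 labels cannot rearrange an unordered pair: null degenerate
        warnings.warn(
            "permutation null degenerate for < 3 pairs; edge decisions indeterminate",
            stacklevel=2,
        )
        indeterminate = True
        keep = np.zeros(tensor.n_pairs, dtype=bool)
        pvals = np.full(tensor.n_pairs, np.nan)
    else:
        rng = np.random.default_rng(seed)
        null = _null_mean_distribution(tensor, interaction_type, n_perm, rng)
        ge = np.nansum(null >= obs[None, :], axis=0)
        pvals = (1.0 + ge) / (1.0 + n_perm)
        pvals = np.where(np.isfinite(obs), pvals, np.nan)
        finite = np.isfinite(pvals)
        keep = np.zeros(tensor.n_pairs, dtype=bool)
        if finite.any():
            q = stats.false_discovery_control(pvals[finite], method="bh")
            keep[np.nonzero(finite)[0][q <= alpha]] = True
    if not keep.any() and not indeterminate:
        warnings.warn(
            f"no {interaction_type} edge survived FDR at alpha={alpha}; empty network",
            stacklevel=2,
        )
    m = len(tensor.taxa)
    adjacency = np.zeros((m, m), dtype=int)
    weights = np.full((m, m), np.nan)
    iu, iv = np.triu_indices(m, k=1)
    for p in np.nonzero(keep)[0]:
        i, j = iu[p], iv[p]
        w = obs[p]
        if directed:
            # orient from the more abundant taxon by majority vote across hosts
            votes_i_u = int(tensor.orientation[:, p].sum())
            if votes_i_u * 2 >= tensor.n_hosts:
                adjacency[i, j] = 1
                weights[i, j] = w
            else:
                adjacency[j, i] = 1
                weights[j, i] = w
        else:
            adjacency[i, j] = adjacency[j, i] = 1
            weights[i, j] = weights[j, i] = w
    pv = pd.DataFrame(
        {
            "u": [tensor.pairs[p][0] for p in range(tensor.n_pairs)],
            "v": [tensor.pairs[p][1] for p in range(tensor.n_pairs)],
            "mean": obs,
            "p_value": pvals,
            "retained": keep,
        }
    )
    return MicrobialNetwork(
        interaction_type, list(tensor.taxa), adjacency, weights, directed,
        provenance="cohort", season=season, edge_pvalues=pv,
        indeterminate=indeterminate,
    )


def per_host_network(
    tensor: InteractionTensor,
    host,
    interaction_type: str,
    *,
    quantile: float = 0.9,
) -> MicrobialNetwork:
    """Build one host's network: finite descriptors above a per-host quantile.

    Per-host networks carry no cross-host significance test; by convention
    an edge exists where the host's descriptor is finite and at or above
    the given quantile of that host's finite values (``quantile=0`` keeps
    every finite pair).
    """
    h = tensor.hosts.index(host)
    vals = tensor.values[interaction_type][h]
    finite = np.isfinite(vals)
    keep = np.zeros_like(finite)
    if finite.any():
        cut = np.quantile(vals[finite], quantile) if quantile > 0 else -np.inf
        keep = finite & (vals >= cut)
    directed = interaction_type in DIRECTED_TYPES
    m = len(tensor.taxa)
    adjacency = np.zeros((m, m), dtype=int)
    weights = np.full((m, m), np.nan)
    iu, iv = np.triu_indices(m, k=1)
    for p in np.nonzero(keep)[0]:
        i, j = iu[p], iv[p]
        if directed and not tensor.orientation[h, p]:
            i, j = j, i
        adjacency[i, j] = 1
        weights[i, j] = vals[p]
        if not directed:
            adjacency[j, i] = 1
            weights[j, i] = vals[p]
    return MicrobialNetwork(
        interaction_type, list(tensor.taxa), adjacency, weights, directed,
        provenance=f"host:{host}",
    )


def host_property(
    tensor: InteractionTensor,
    interaction_type: str,
    *,
    statistic: str = "mean_log_weight",
) -> pd.Series:
    """Scalar per-host network-property phenotype from the descriptor tensor.

    ``mean_log_weight`` (default) averages the log descriptor over the
    host's finite pairs — a connectivity-weighted mean interaction
    strength on the scale on which abundance effects are additive.
    ``mean_weight`` averages the raw descriptor.
    """
    vals = tensor.values[interaction_type]
    with np.errstate(divide="ignore", invalid="ignore"):
        if statistic == "mean_log_weight":
            x = np.where(vals > 0, np.log(np.where(vals > 0, vals, 1.0)), np.nan)
        elif statistic == "mean_weight":
            x = vals
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(x, axis=1)
    return pd.Series(out, index=pd.Index(tensor.hosts, name="host"), name=statistic)


# ---------------------------------------------------------------------------
# distances, path counts, centralities
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Hop distances and shortest-path counts for a network."""

    nodes: list
    D: np.ndarray  # (n, n) float, np.inf where unreachable
    sigma: np.ndarray  # (n, n) shortest-path counts g_vw

    def path_count_through(self, u: int) -> np.ndarray:
        """g_vw(u): number of v->w shortest paths passing through u."""
        D, sigma = self.D, self.sigma
        n = len(self.nodes)
        out = np.zeros((n, n))
        with np.errstate(invalid="ignore"):
            on_path = D[:, u][:, None] + D[u, :][None, :] == D
        on_path[u, :] = on_path[:, u] = False
        np.fill_diagonal(on_path, False)
        out[on_path] = (sigma[:, u][:, None] * sigma[u, :][None, :])[on_path]
        return out


def shortest_paths(net: MicrobialNetwork) -> DistanceMatrix:
    """BFS hop distances and path counts, respecting edge direction."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    n = net.n_nodes
    succ = [np.nonzero(net.adjacency[i])[0] for i in range(n)]
    D = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        D[s, s] = 0.0
        sigma[s, s] = 1.0
        frontier = [s]
        dist = 0
        while frontier:
            dist += 1
            nxt = []
            for v in frontier:
                for w in succ[v]:
                    if not np.isfinite(D[s, w]):
                        D[s, w] = dist
                        sigma[s, w] = sigma[s, v]
                        nxt.append(w)
                    elif D[s, w] == dist:
                        sigma[s, w] += sigma[s, v]
            frontier = nxt
    return DistanceMatrix(list(net.nodes), D, sigma)


@dataclass
class CentralityProfile:
    """Node-level indices plus the network-level connectivity."""

    table: pd.DataFrame  # node x {closeness, betweenness, eccentricity, eigenvector, pagerank}
    connectivity: float
    eigenvalue: float
    damping: float
    reachable_fraction: pd.Series

    def aggregate(self) -> pd.Series:
        """Per-network scalar summary: mean over microbes of each index."""
        agg = self.table.mean()
        agg["connectivity"] = self.connectivity
        return agg


def _eigenvector_centrality(A: np.ndarray, tol: float = 1e-14, max_iter: int = 10000):
    """Leading eigenpair of the (binary) adjacency by power iteration.

    Solves A G = lambda G as printed; the Perron vector is nonnegative and
    returned with unit Euclidean norm.
    """
    n = A.shape[0]
    x = np.full(n, 1.0 / np.sqrt(n))
    # iterate with A + I: same eigenvectors, but the Perron eigenvalue
    # becomes strictly dominant, so bipartite graphs cannot oscillate
    for _ in range(max_iter):
        y = A @ x + x
        norm = np.linalg.norm(y)
        if norm <= tol:
            return np.full(n, np.nan), np.nan
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    lam = float(x @ (A @ x))
    if abs(lam) <= 1e-12:
        return np.full(n, np.nan), np.nan
    x = np.abs(x)
    x /= np.linalg.norm(x)
    return x, lam


def _pagerank(A: np.ndarray, d: float, variant: str):
    """Solve the damped ranking recursion as a linear system.

    ``as_printed``: P = (1 - d) 1 + d M P;  ``normalized``: the standard
    (1 - d)/m teleport.  M spreads each node's score along its out-links
    (column u of M holds a_uv / K_u); dangling nodes spread uniformly.
    The two variants differ by the constant factor m, so rankings coincide.
    """
    n = A.shape[0]
    K = A.sum(axis=1).astype(float)
    M = np.zeros((n, n))
    nz = K > 0
    M[:, nz] = (A[nz].T / K[nz])
    M[:, ~nz] = 1.0 / n
    teleport = (1.0 - d) * (np.ones(n) if variant == "as_printed" else np.full(n, 1.0 / n))
    if variant not in ("as_printed", "normalized"):
        raise ValueError(f"unknown pagerank variant {variant!r}")
    return np.linalg.solve(np.eye(n) - d * M, teleport)


def centralities(
    net: MicrobialNetwork,
    *,
    damping: float = 0.85,
    pagerank_variant: str = "as_printed",
) -> CentralityProfile:
    """Compute the five node-level indices and network connectivity.

    Closeness and eccentricity are computed within each node's reachable
    set (unreachable pairs excluded) and the reachable fraction is
    reported, so disconnected graphs yield finite values.  Betweenness
    uses fractional counting over (unordered for undirected, ordered for
    directed) node pairs.  Isolated nodes receive NaN closeness and
    eccentricity.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network: indices undefined")
    n = net.n_nodes
    dm = shortest_paths(net)
    D = dm.D
    finiteD = np.isfinite(D)
    np.fill_diagonal(finiteD, False)
    reach = finiteD.sum(axis=1)
    close = np.full(n, np.nan)
    ecc = np.full(n, np.nan)
    for u in range(n):
        if reach[u] > 0:
            close[u] = 1.0 / D[u, finiteD[u]].sum()
            ecc[u] = 1.0 / D[u, finiteD[u]].max()
    btw = np.zeros(n)
    for u in range(n):
        thr = dm.path_count_through(u)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(dm.sigma > 0, thr / np.where(dm.sigma > 0, dm.sigma, 1.0), 0.0)
        if net.directed:
            btw[u] = frac.sum()
        else:
            btw[u] = np.triu(frac, k=1).sum()
    eig, lam = _eigenvector_centrality(net.adjacency.astype(float))
    pr = _pagerank(net.adjacency.astype(float), damping, pagerank_variant)
    table = pd.DataFrame(
        {
            "closeness": close,
            "betweenness": btw,
            "eccentricity": ecc,
            "eigenvector": eig,
            "pagerank": pr,
        },
        index=pd.Index(net.nodes, name="node"),
    )
    con = float(net.degrees().mean())
    return CentralityProfile(
        table=table,
        connectivity=con,
        eigenvalue=lam,
        damping=damping,
        reachable_fraction=pd.Series(reach / max(n - 1, 1), index=table.index),
    )


# ---------------------------------------------------------------------------
# hubs and roles
# ---------------------------------------------------------------------------

_ROLES = {
    "mutualism": ("leader", "follower"),
    "antagonism": ("antagonist", "agonist"),
}


@dataclass
class HubReport:
    hubs: list
    degree_threshold: float
    t_statistic: float
    p_value: float
    roles: pd.Series


def detect_hubs(net: MicrobialNetwork, abundances: pd.Series) -> HubReport:
    """Flag hub (keystone) microbes and compare their abundance to the rest.

    Hubs are nodes whose degree exceeds ``median + 1 MAD`` of the degree
    distribution (a convention; the threshold is reported).  A two-sample
    t-test contrasts hub vs non-hub abundance.  Role labels: undirected
    networks label hubs leader/antagonist and the rest follower/agonist;
    the aggression network partitions nodes into hawk (out-edges only),
    dove (in-edges only) and hawk-dove (both); altruism analogously into
    altruist/beneficiary/altruist-beneficiary.  Isolated nodes are labeled
    'isolated'.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    deg = net.degrees().astype(float)
    med = np.median(deg)
    mad = np.median(np.abs(deg - med))
    thr = med + mad
    hub_mask = deg > thr
    if mad == 0 and len(set(deg)) == 1:
        warnings.warn("all degrees equal; empty hub set", stacklevel=2)
        hub_mask[:] = False
    hubs = [net.nodes[i] for i in np.nonzero(hub_mask)[0]]
    ab = abundances.reindex(net.nodes).to_numpy(dtype=float)
    if 0 < hub_mask.sum() < net.n_nodes:
        t, p = stats.ttest_ind(ab[hub_mask], ab[~hub_mask], equal_var=False)
    else:
        t, p = np.nan, np.nan
    if net.directed:
        out_deg = net.adjacency.sum(axis=1)
        in_deg = net.adjacency.sum(axis=0)
        if net.interaction_type == "aggression":
            names = ("hawk", "dove", "hawk-dove")
        else:
            names = ("altruist", "beneficiary", "altruist-beneficiary")
        roles = np.where(
            (out_deg > 0) & (in_deg > 0), names[2],
            np.where(out_deg > 0, names[0], np.where(in_deg > 0, names[1], "isolated")),
        )
    else:
        lead, follow = _ROLES.get(net.interaction_type, ("hub", "non-hub"))
        roles = np.where(hub_mask, lead, follow)
        roles = np.where(deg == 0, "isolated", roles)
    return HubReport(
        hubs=hubs,
        degree_threshold=float(thr),
        t_statistic=float(t) if np.isfinite(t) else np.nan,
        p_value=float(p) if np.isfinite(p) else np.nan,
        roles=pd.Series(roles, index=pd.Index(net.nodes, name="node")),
    )


# ---------------------------------------------------------------------------
# scale-free test
# ---------------------------------------------------------------------------


def _zeta_pmf(k: np.ndarray, alpha: float, kmin: int) -> np.ndarray:
    return k ** (-alpha) / special.zeta(alpha, kmin)


def _fit_discrete_powerlaw(degrees: np.ndarray, kmin: int) -> float:
    logs = np.log(degrees).sum()
    n = len(degrees)

    def nll(alpha):
        return n * np.log(special.zeta(alpha, kmin)) + alpha * logs

    res = optimize.minimize_scalar(nll, bounds=(1.01, 10.0), method="bounded")
    return float(res.x)


def _ks_discrete(degrees: np.ndarray, alpha: float, kmin: int) -> float:
    ks = np.arange(kmin, degrees.max() + 1)
    cdf = np.cumsum(_zeta_pmf(ks.astype(float), alpha, kmin))
    emp = np.searchsorted(np.sort(degrees), ks, side="right") / len(degrees)
    return float(np.max(np.abs(emp - cdf)))


def _sample_zeta(n: int, alpha: float, kmin: int, rng) -> np.ndarray:
    # inverse-CDF sampling with a tail cutoff at cumulative mass 1 - 1e-9
    kmax = kmin + 10
    while True:
        ks = np.arange(kmin, kmax + 1, dtype=float)
        pmf = _zeta_pmf(ks, alpha, kmin)
        if pmf.sum() > 1 - 1e-9 or kmax > 10**7:
            break
        kmax *= 4
    cdf = np.cumsum(pmf) / pmf.sum()
    u = rng.random(n)
    return ks[np.searchsorted(cdf, u)].astype(int)


@dataclass
class PowerlawResult:
    exponent: float
    p_value: float
    kmin: int
    n: int
    defined: bool = True


def powerlaw_test(
    net_or_degrees, *, n_boot: int = 100, seed: int = 0, kmin: int = None
) -> PowerlawResult:
    """Scale-freeness test: discrete power-law fit to the degree sequence.

    The exponent is the maximum-likelihood estimate under the Hurwitz-zeta
    (discrete power-law) model with fixed ``kmin`` (default: the smallest
    positive degree).  The goodness-of-fit p-value is the parametric
    bootstrap probability of a Kolmogorov–Smirnov distance at least as
    large as observed; small p rejects scale-freeness.  Fewer than 10
    positive-degree nodes yields an undefined (flagged) result.
    """
    if isinstance(net_or_degrees, MicrobialNetwork):
        degrees = net_or_degrees.degrees()
    else:
        degrees = np.asarray(net_or_degrees)
    degrees = degrees[degrees >= 1].astype(int)
    if len(degrees) < 10:
        warnings.warn("fewer than 10 positive-degree nodes; power-law fit undefined",
                      stacklevel=2)
        return PowerlawResult(np.nan, np.nan, 0, len(degrees), defined=False)
    if kmin is None:
        kmin = int(degrees.min())
    degrees = degrees[degrees >= kmin]
    alpha = _fit_discrete_powerlaw(degrees, kmin)
    obs_ks = _ks_discrete(degrees, alpha, kmin)
    rng = np.random.default_rng(seed)
    n = len(degrees)
    exceed = 0
    for _ in range(n_boot):
        sim = _sample_zeta(n, alpha, kmin, rng)
        a_sim = _fit_discrete_powerlaw(sim, kmin)
        if _ks_discrete(sim, a_sim, kmin) >= obs_ks:
            exceed += 1
    return PowerlawResult(alpha, (exceed + 1) / (n_boot + 1), kmin, n)
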