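"""Behavioral-ecology descriptors of pairwise microbial interactions.

Given a snapshot of the abundances of two microbes ``u`` and ``v`` with
``x_u > x_v > 0``, four closed-form descriptors quantify the ecological
relationship of the pair:

* mutualism      ``Z_mu = x_u * x_v / (x_u - x_v)``  (symmetric)
* antagonism     ``Z_an``, a reciprocal form of the same quantities
  (symmetric; see :data:`ANTAGONISM_FORMS`)
* aggression     ``Z_ag = x_u / x_v``                (directed u -> v)
* altruism       ``Z_al = 1 - x_v / x_u``            (directed u -> v)

The descriptors serve as single-snapshot proxies for the *observed*
interaction strengths obtainable only from paired co-culture/monoculture
experiments (:func:`observed_strengths`), against which they can be
validated (:func:`validate_descriptors`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundancePair",
    "InteractionDescriptors",
    "CulturePair",
    "ObservedStrengths",
    "InteractionTensor",
    "INTERACTION_TYPES",
    "ANTAGONISM_FORMS",
    "compute_descriptors",
    "descriptor_tensor",
    "observed_strengths",
    "validate_descriptors",
]

INTERACTION_TYPES = ("mutualism", "antagonism", "aggression", "altruism")

#: The antagonism descriptor is published in a typographically ambiguous
#: form; both defensible readings are provided.  ``reciprocal_product`` is
#: the default: 1 / (x_u * x_v * (x_u - x_v)).  ``inverse_mutualism`` is
#: the alternative (x_u - x_v) / (x_u * x_v) = 1 / Z_mu.  Analyses based on
#: Z_an depend on this choice.
ANTAGONISM_FORMS = ("reciprocal_product", "inverse_mutualism")


class DegenerateTieError(ValueError):
    """Raised in strict mode when x_u == x_v makes Z_mu/Z_an undefined."""


class UndefinedPairError(ValueError):
    """Raised in strict mode when a zero abundance makes a pair undefined."""


@dataclass(frozen=True)
class AbundancePair:
    """An ordered abundance pair with ``x_u >= x_v >= 0``.

    Use :meth:`from_unordered` to build from raw (taxon, abundance) data;
    the more abundant microbe is relabeled ``u``.
    """

    u_id: str
    v_id: str
    x_u: float
    x_v: float

    def __post_init__(self):
        if self.u_id == self.v_id:
            raise ValueError(f"pair requires two distinct taxa, got {self.u_id!r} twice")
        if self.x_v < 0 or self.x_u < self.x_v:
            raise ValueError(
                f"abundances must satisfy x_u >= x_v >= 0, got x_u={self.x_u}, x_v={self.x_v}"
            )

    @classmethod
    def from_unordered(cls, id_a, x_a, id_b, x_b) -> "AbundancePair":
        if x_a >= x_b:
            return cls(id_a, id_b, float(x_a), float(x_b))
        return cls(id_b, id_a, float(x_b), float(x_a))


@dataclass(frozen=True)
class InteractionDescriptors:
    """The four descriptors for one pair; Z_ag/Z_al are directed u -> v."""

    u_id: str
    v_id: str
    z_mu: float
    z_an: float
    z_ag: float
    z_al: float

    def as_dict(self) -> dict:
        return {
            "mutualism": self.z_mu,
            "antagonism": self.z_an,
            "aggression": self.z_ag,
            "altruism": self.z_al,
        }


def _antagonism(x_u: float, x_v: float, form: str) -> float:
    if form == "reciprocal_product":
        return 1.0 / (x_u * x_v * (x_u - x_v))
    if form == "inverse_mutualism":
        return (x_u - x_v) / (x_u * x_v)
    raise ValueError(f"unknown antagonism form {form!r}; choose from {ANTAGONISM_FORMS}")


def compute_descriptors(
    pair: AbundancePair,
    *,
    antagonism_form: str = "reciprocal_product",
    strict: bool = False,
) -> InteractionDescriptors:
    """Evaluate the four interaction descriptors for one abundance pair.

    Ties (``x_u == x_v``) leave Z_mu/Z_an undefined: they are returned as
    NaN with a warning (Z_ag = 1 and Z_al = 0 remain well defined); with
    ``strict=True`` a :class:`DegenerateTieError` is raised instead.  A zero
    abundance leaves every descriptor undefined (all NaN, or
    :class:`UndefinedPairError` in strict mode).
    """
    x_u, x_v = pair.x_u, pair.x_v
    if x_v == 0.0:
        if strict:
            raise UndefinedPairError(
                f"pair ({pair.u_id}, {pair.v_id}) has a zero abundance; descriptors undefined"
            )
        warnings.warn(
            f"zero abundance in pair ({pair.u_id}, {pair.v_id}); descriptors set to NaN",
            stacklevel=2,
        )
        return InteractionDescriptors(pair.u_id, pair.v_id, np.nan, np.nan, np.nan, np.nan)
    z_ag = x_u / x_v
    z_al = 1.0 - x_v / x_u
    if x_u == x_v:
        if strict:
            raise DegenerateTieError(
                f"tied abundances in pair ({pair.u_id}, {pair.v_id}); Z_mu/Z_an undefined"
            )
        warnings.warn(
            f"tied abundances in pair ({pair.u_id}, {pair.v_id}); Z_mu/Z_an set to NaN",
            stacklevel=2,
        )
        return InteractionDescriptors(pair.u_id, pair.v_id, np.nan, np.nan, z_ag, z_al)
    z_mu = x_u * x_v / (x_u - x_v)
    z_an = _antagonism(x_u, x_v, antagonism_form)
    return InteractionDescriptors(pair.u_id, pair.v_id, z_mu, z_an, z_ag, z_al)


@dataclass
class InteractionTensor:
    """Per-host, per-pair descriptor values for a whole cohort.

    ``values[t]`` is an ``(n_hosts, n_pairs)`` array for interaction type
    ``t``; pairs are indexed in canonical (i < j) taxon order and
    ``orientation[h, p]`` is True when taxon ``i`` is the more abundant
    member (the ``u`` role) in host ``h``.  Pairs failing preconditions
    (zero abundance, ties for Z_mu/Z_an) hold NaN — flagged missing, never
    dropped.
    """

    hosts: list
    taxa: list
    pairs: list  # list of (taxon_i, taxon_j), i < j in column order
    values: dict  # interaction type -> (n_hosts, n_pairs) float array
    orientation: np.ndarray  # (n_hosts, n_pairs) bool
    abundance: pd.DataFrame = field(repr=False, default=None)
    antagonism_form: str = "reciprocal_product"
    winsor_quantile: float = None  # set when winsorize() has been applied

    @property
    def n_hosts(self) -> int:
        return len(self.hosts)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def winsorize(self, quantile: float = 0.99) -> "InteractionTensor":
        """Cap Z_mu/Z_an per host at the given quantile of finite values.

        Z_mu and Z_an diverge as x_u -> x_v; capping stabilizes downstream
        network construction.  Returns a new tensor; the action is logged.
        """
        values = {
            t: (_winsorize_rows(v, quantile) if t in ("mutualism", "antagonism")
                else v.copy())
            for t, v in self.values.items()
        }
        warnings.warn(
            f"winsorized Z_mu/Z_an per host at quantile {quantile}", stacklevel=2
        )
        return InteractionTensor(
            self.hosts, self.taxa, self.pairs, values, self.orientation,
            self.abundance, self.antagonism_form, winsor_quantile=quantile,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per host x pair with the four values."""
        rows = []
        for h, host in enumerate(self.hosts):
            for p, (ti, tj) in enumerate(self.pairs):
                u, v = (ti, tj) if self.orientation[h, p] else (tj, ti)
                rows.append(
                    {
                        "host": host,
                        "u": u,
                        "v": v,
                        **{t: self.values[t][h, p] for t in INTERACTION_TYPES},
                    }
                )
        return pd.DataFrame(rows)


def _winsorize_rows(v: np.ndarray, quantile: float) -> np.ndarray:
    """Cap each row's finite values at that row's given quantile."""
    out = v.copy()
    finite = np.isfinite(out)
    rows = finite.sum(axis=1) >= 2
    if rows.any():
        masked = np.where(finite[rows], out[rows], np.nan)
        srt = np.sort(masked, axis=1)  # NaNs sort to the end
        cnt = finite[rows].sum(axis=1)
        pos = quantile * (cnt - 1)
        lo = np.floor(pos).astype(int)
        hi = np.ceil(pos).astype(int)
        frac = pos - lo
        idx = np.arange(len(cnt))
        caps = (srt[idx, lo] * (1 - frac) + srt[idx, hi] * frac)[:, None]
        out[rows] = np.where(finite[rows] & (out[rows] > caps), caps, out[rows])
    return out


def _pair_descriptor_arrays(X: np.ndarray, iu, iv, antagonism_form: str):
    """Vectorized descriptor evaluation for all hosts x pairs.

    X is (n_hosts, n_taxa) nonnegative; iu/iv index the canonical pair
    columns.  Returns dict of arrays plus the orientation mask.
    """
    a = X[:, iu]
    b = X[:, iv]
    orient = a >= b  # ties: orientation arbitrary, descriptors NaN anyway
    hi = np.where(orient, a, b)
    lo = np.where(orient, b, a)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_ag = np.where(lo > 0, hi / lo, np.nan)
        z_al = np.where(hi > 0, 1.0 - lo / hi, np.nan)
        diff = hi - lo
        ok = (lo > 0) & (diff > 0)
        z_mu = np.where(ok, hi * lo / np.where(diff > 0, diff, 1.0), np.nan)
        if antagonism_form == "reciprocal_product":
            z_an = np.where(ok, 1.0 / np.where(ok, hi * lo * diff, 1.0), np.nan)
        elif antagonism_form == "inverse_mutualism":
            z_an = np.where(ok, diff / np.where(lo > 0, hi * lo, 1.0), np.nan)
        else:
            raise ValueError(
                f"unknown antagonism form {antagonism_form!r}; choose from {ANTAGONISM_FORMS}"
            )
        # a zero abundance invalidates the whole pair
        valid = lo > 0
        z_ag = np.where(valid, z_ag, np.nan)
        z_al = np.where(valid, z_al, np.nan)
    return (
        {"mutualism": z_mu, "antagonism": z_an, "aggression": z_ag, "altruism": z_al},
        orient,
    )


def descriptor_tensor(
    abundance: pd.DataFrame,
    *,
    antagonism_form: str = "reciprocal_product",
    pseudocount: float = 0.0,
    normalize: bool = False,
) -> InteractionTensor:
    """Compute all four descriptors for every host and unordered taxon pair.

    Parameters
    ----------
    abundance
        Host x taxon table of nonnegative abundances (hosts as rows).
    antagonism_form
        Which rendering of the antagonism descriptor to use.
    pseudocount
        Added to every abundance before computation (default 0: off); a
        small pseudocount rescues zero-abundance pairs.
    normalize
        If True, convert each host's abundances to relative abundances
        first.  Z_ag and Z_al are scale-invariant; Z_mu/Z_an are not, so
        this switch matters for them.
    """
    if abundance.shape[1] < 2:
        raise ValueError("need at least 2 taxa to form pairs")
    X = abundance.to_numpy(dtype=float)
    if np.any(X < 0):
        r, c = np.argwhere(X < 0)[0]
        raise ValueError(
            f"negative abundance at host {abundance.index[r]!r}, taxon {abundance.columns[c]!r}"
        )
    if pseudocount:
        X = X + pseudocount
    if normalize:
        totals = X.sum(axis=1, keepdims=True)
        X = np.divide(X, totals, out=np.zeros_like(X), where=totals > 0)
    taxa = list(abundance.columns)
    iu, iv = np.triu_indices(len(taxa), k=1)
    values, orient = _pair_descriptor_arrays(X, iu, iv, antagonism_form)
    pairs = [(taxa[i], taxa[j]) for i, j in zip(iu, iv)]
    return InteractionTensor(
        hosts=list(abundance.index),
        taxa=taxa,
        pairs=pairs,
        values=values,
        orientation=orient,
        abundance=abundance,
        antagonism_form=antagonism_form,
    )


@dataclass(frozen=True)
class CulturePair:
    """Co-culture vs monoculture abundances for one strain pair.

    ``u`` is the strain more abundant in co-culture; ``x`` are co-culture
    and ``w`` monoculture abundances.  ``phase`` is the growth phase at the
    sampling time (lag/log/stationary).
    """

    x_u: float
    x_v: float
    w_u: float
    w_v: float
    time: float = np.nan
    phase: str = ""

    def __post_init__(self):
        for name in ("x_u", "x_v", "w_u", "w_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.x_u < self.x_v:
            raise ValueError("u must be the strain more abundant in co-culture (x_u >= x_v)")

    @classmethod
    def from_unordered(cls, x_a, w_a, x_b, w_b, time=np.nan, phase="") -> "CulturePair":
        if x_a >= x_b:
            return cls(x_a, x_b, w_a, w_b, time, phase)
        return cls(x_b, x_a, w_b, w_a, time, phase)


@dataclass(frozen=True)
class ObservedStrengths:
    """Observed interaction strengths from a co/mono-culture contrast.

    ``m_u`` (mutualism) is meaningful only when both strains grow better
    in co-culture (both co/mono ratios > 1); ``a_n`` (antagonism) only when
    both grow worse (both ratios < 1); the applicability flags record this.
    ``a_g``/``a_l`` are the directed aggression/altruism strengths u -> v
    and satisfy a_g * a_l = 1 identically.
    """

    m_u: float
    a_n: float
    a_g: float
    a_l: float
    mutualism_applicable: bool
    antagonism_applicable: bool
    phase: str = ""


def observed_strengths(culture: CulturePair, *, strict: bool = False) -> ObservedStrengths:
    """Quantify actual interaction strengths from paired culture abundances."""
    ru = culture.x_u / culture.w_u  # co/mono ratio, strain u
    rv = culture.x_v / culture.w_v
    a_g = (culture.x_u / culture.x_v) / (culture.w_u / culture.w_v)
    a_l = rv / ru
    if ru == rv:
        if strict:
            raise DegenerateTieError("equal co/mono ratios: M_u and A_n undefined")
        warnings.warn("equal co/mono ratios: M_u and A_n set to NaN", stacklevel=2)
        m_u = a_n = np.nan
    else:
        m_u = ru * rv / abs(ru - rv)
        a_n = (1.0 / ru) * (1.0 / rv) / abs(1.0 / ru - 1.0 / rv)
    return ObservedStrengths(
        m_u=m_u,
        a_n=a_n,
        a_g=a_g,
        a_l=a_l,
        mutualism_applicable=bool(ru > 1 and rv > 1),
        antagonism_applicable=bool(ru < 1 and rv < 1),
        phase=culture.phase,
    )


_CHANNEL = {
    # interaction -> (descriptor attr, strength attr, applicability attr or None)
    "mutualism": ("z_mu", "m_u", "mutualism_applicable"),
    "antagonism": ("z_an", "a_n", "antagonism_applicable"),
    "aggression": ("z_ag", "a_g", None),
    "altruism": ("z_al", "a_l", None),
}


def validate_descriptors(records, *, min_pairs: int = 3) -> pd.DataFrame:
    """Correlate each descriptor with its observed strength, per growth phase.

    ``records`` is an iterable of ``(InteractionDescriptors,
    ObservedStrengths, phase)`` tuples.  For each phase and interaction
    type, the Pearson correlation is computed over the applicable pairs
    (mutualism/antagonism restrict to their applicability flags).  Strata
    with fewer than ``min_pairs`` valid pairs are reported as NaN rather
    than raising.

    Returns a table indexed by (phase, interaction) with columns
    ``r``, ``p_value``, ``n``.
    """
    rows = []
    records = list(records)
    phases = sorted({rec[2] for rec in records})
    for phase in phases:
        in_phase = [rec for rec in records if rec[2] == phase]
        for interaction, (zattr, sattr, flag) in _CHANNEL.items():
            zs, ss = [], []
            for desc, strength, _ in in_phase:
                if flag is not None and not getattr(strength, flag):
                    continue
                z = getattr(desc, zattr)
                s = getattr(strength, sattr)
                if np.isfinite(z) and np.isfinite(s):
                    zs.append(z)
                    ss.append(s)
            if len(zs) >= min_pairs and np.std(zs) > 0 and np.std(ss) > 0:
                r, p = stats.pearsonr(zs, ss)
            else:
                r, p = np.nan, np.nan
            rows.append(
                {"phase": phase, "interaction": interaction, "r": r, "p_value": p, "n": len(zs)}
            )
    return pd.DataFrame(rows).set_index(["phase", "interaction"])
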