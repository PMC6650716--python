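"""Association indices and matrix-correlation (Mantel) stability tests.

Two complementary indices quantify pairwise affiliation from covisit data:

* **Simple ratio (SR)** — the day-level Jaccard index: days both units
  visited divided by days at least one visited.  The classic gambit-of-the-
  group index, but inflated for rarely seen units.
* **Binomial probability (BP)** — the upper-tail probability of the observed
  covisit count k_ij under independent visiting, X ~ Binomial(T, (v_i/T)(v_j/T)).
  A small tail means the pair covisits far more than chance; the association
  value is 1 - tail so both indices read "bigger = closer".  A rate-adjusted
  mode replaces the constant per-day covisit probability with one modulated by
  overall daily attendance (Poisson-binomial tail), correcting for seasonal
  fluctuation in visitation.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import PresenceMatrix

log = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "MantelResult",
    "simple_ratio",
    "binomial_probability",
    "poisson_binomial_sf",
    "mantel",
]


@dataclass
class AssociationMatrix:
    """Symmetric pairwise association values tagged with their index type.

    For BP matrices ``tails`` holds the raw upper-tail probabilities p_ij
    (the hierarchy stage consumes those as distances); ``values`` is 1 - p_ij.
    """

    units: list[str]
    values: np.ndarray
    index_type: str  # "SR" or "BP"
    tails: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.units)
        if self.values.shape != (n, n):
            raise ValueError("association matrix shape does not match units")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("association matrix must be symmetric")
        if np.diagonal(self.values).any():
            raise ValueError("association matrix diagonal must be zero")
        if self.index_type not in ("SR", "BP"):
            raise ValueError("index_type must be 'SR' or 'BP'")

    @property
    def n_units(self) -> int:
        return len(self.units)

    def upper(self) -> np.ndarray:
        """Off-diagonal upper-triangle values as a flat vector."""
        iu = np.triu_indices(self.n_units, k=1)
        return self.values[iu]

    def subset(self, units: list[str]) -> "AssociationMatrix":
        idx = [self.units.index(u) for u in units]
        tails = self.tails[np.ix_(idx, idx)] if self.tails is not None else None
        return AssociationMatrix(list(units), self.values[np.ix_(idx, idx)],
                                 self.index_type, tails)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.units, columns=self.units).to_csv(
            path, index_label="unit_id"
        )

    @classmethod
    def from_csv(cls, path: str | Path, index_type: str) -> "AssociationMatrix":
        df = pd.read_csv(path, index_col=0)
        df.columns = [str(c) for c in df.columns]
        return cls([str(u) for u in df.index], df.to_numpy(dtype=float), index_type)

    @classmethod
    def from_edge_list(cls, path: str | Path, index_type: str) -> "AssociationMatrix":
        """Read a long-format edge list ``unit_a,unit_b,value``."""
        df = pd.read_csv(path, dtype={"unit_a": str, "unit_b": str})
        units = sorted(set(df["unit_a"]) | set(df["unit_b"]))
        idx = {u: i for i, u in enumerate(units)}
        vals = np.zeros((len(units), len(units)))
        for row in df.itertuples(index=False):
            i, j = idx[row.unit_a], idx[row.unit_b]
            vals[i, j] = vals[j, i] = float(row.value)
        np.fill_diagonal(vals, 0.0)
        return cls(units, vals, index_type)


@dataclass(frozen=True)
class MantelResult:
    Z: float
    p: float
    n_perm: int


def simple_ratio(pm: PresenceMatrix) -> AssociationMatrix:
    """Simple-ratio association: SR_ij = x / (x + y_i + y_j).

    x is the number of days both units visited, y_i / y_j days only one did.
    The denominator equals the size of the union of the two visit-day sets,
    so SR is the Jaccard index of visit days.  Pairs never seen at all get 0.
    """
    if pm.n_units < 2:
        raise ValueError("need at least 2 units")
    x = pm.covisits().astype(float)
    v = pm.visit_counts().astype(float)
    union = v[:, None] + v[None, :] - x
    with np.errstate(invalid="ignore", divide="ignore"):
        sr = np.where(union > 0, x / union, 0.0)
    np.fill_diagonal(sr, 0.0)
    return AssociationMatrix(list(pm.units), sr, "SR")


def poisson_binomial_sf(k: int, probs: np.ndarray) -> float:
    """P(X >= k) for X a sum of independent Bernoulli(probs).

    Exact dynamic-programming convolution of the per-trial success
    probabilities; O(len(probs)^2) but the pmf vector is truncated to what
    the tail sum needs.
    """
    probs = np.asarray(probs, dtype=float)
    if k <= 0:
        return 1.0
    if k > len(probs):
        return 0.0
    # pmf[m] = P(X = m) over trials processed so far, truncated to m < k;
    # mass promoted past k-1 simply drops out, so 1 - sum(pmf) is the tail.
    pmf = np.zeros(k)
    pmf[0] = 1.0
    for p in probs:
        upper = pmf[1:] * (1 - p) + pmf[:-1] * p
        pmf[0] *= 1 - p
        pmf[1:] = upper
    return float(np.clip(1.0 - pmf.sum(), 0.0, 1.0))


def binomial_probability(
    pm: PresenceMatrix, rate_adjust: bool = False
) -> AssociationMatrix:
    """Binomial-probability association index.

    Plain mode: tail p_ij = P(X >= k_ij) with X ~ Binomial(T, (v_i/T)(v_j/T)).
    Rate-adjusted mode: the per-day covisit probability is modulated by the
    squared relative daily attendance s_t (busy days make chance covisits more
    likely for both members of the pair), normalised so the mean per-day
    probability matches plain mode, and the tail comes from the exact
    Poisson-binomial distribution.  Association value a_ij = 1 - p_ij.
    """
    if pm.T < 1:
        raise ValueError("presence matrix has no days")
    v = pm.visit_counts()
    if (v == 0).any():
        bad = [u for u, c in zip(pm.units, v) if c == 0]
        raise ValueError(f"units with zero visits (filter first): {bad}")
    T = pm.T
    k = pm.covisits()
    p0 = np.outer(v, v) / (T * T)
    n = pm.n_units
    tails = np.ones((n, n))
    if not rate_adjust:
        tails = stats.binom.sf(k - 1, T, p0)
    else:
        att = pm.attendance().astype(float)
        s = att / att.mean()
        w = s * s
        w = w / w.mean()  # mean per-day probability stays p0
        n_clamped = 0
        for i in range(n):
            for j in range(i + 1, n):
                q = p0[i, j] * w
                if (q > 1).any():
                    n_clamped += int((q > 1).sum())
                    q = np.minimum(q, 1.0)
                tails[i, j] = tails[j, i] = poisson_binomial_sf(int(k[i, j]), q)
        if n_clamped:
            log.warning(
                "binomial_probability: clamped %d per-day probabilities to 1", n_clamped
            )
    np.fill_diagonal(tails, 1.0)
    values = 1.0 - tails
    np.fill_diagonal(values, 0.0)
    return AssociationMatrix(list(pm.units), values, "BP", tails=tails)


def _mantel_stat(a: np.ndarray, b: np.ndarray, iu) -> float:
    return float(np.corrcoef(a[iu], b[iu])[0, 1])


def mantel(
    A: AssociationMatrix,
    B: AssociationMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    exact: bool = False,
) -> MantelResult:
    """Mantel matrix-correlation test between two association matrices.

    Restricted to the shared unit set.  Z is the Pearson correlation of the
    off-diagonal upper triangles; the null relabels units of B (simultaneous
    row/column permutation).  One-sided (Z' >= Z), add-one convention.  With
    ``exact=True`` all n! relabelings are enumerated (small n only) and the
    p-value is the exact proportion, identity included.
    """
    shared = [u for u in A.units if u in set(B.units)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared units for a Mantel test")
    a = A.subset(shared).values
    b = B.subset(shared).values
    n = len(shared)
    iu = np.triu_indices(n, k=1)
    if np.std(a[iu]) == 0 or np.std(b[iu]) == 0:
        raise ValueError("Mantel Z undefined: a matrix has constant off-diagonal values")
    z_obs = _mantel_stat(a, b, iu)
    if exact:
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8 units")
        perms = list(itertools.permutations(range(n)))
        hits = sum(
            _mantel_stat(a, b[np.ix_(p, p)], iu) >= z_obs - 1e-12 for p in perms
        )
        return MantelResult(z_obs, hits / len(perms), len(perms))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if _mantel_stat(a, b[np.ix_(p, p)], iu) >= z_obs - 1e-12:
            hits += 1
    return MantelResult(z_obs, (1 + hits) / (1 + n_perm), n_perm)
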