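"""Louvain modularity, resolution sweeps, and tier-consistency regression.

The second social tier is detected as the module structure of the weighted
association network.  Modularity with resolution parameter gamma,

    Q(gamma) = sum_c [ w_c / W - gamma * (s_c / 2W)^2 ],

(w_c intra-module weight, s_c module strength, W total weight) is optimised
by the Louvain multi-level algorithm; significance comes from re-optimising
each matrix of a null ensemble at the same gamma.  Sweeping gamma from 0 to 2
traces module size from one giant module down to singletons; troughs in the
p-value curve mark scales at which the data are more modular than chance —
multiple troughs indicate multiple nested tiers.
"""
from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import AssociationMatrix
from .data_model import UnitInfo
from .hierarchy import TierPartition
from .null_models import NullEnsemble, empirical_p

log = logging.getLogger(__name__)

__all__ = [
    "ModularityResult",
    "ComembershipResult",
    "louvain",
    "modularity_p",
    "resolution_sweep",
    "find_troughs",
    "comembership_glm",
]


@dataclass
class ModularityResult:
    partition: TierPartition
    Q: float
    gamma: float
    p: float | None = None
    null_Q: np.ndarray | None = None


@dataclass(frozen=True)
class ComembershipResult:
    """Wald test of tier-1 co-membership predicting tier-2 co-membership."""

    z: float
    p: float
    separated: bool
    table: tuple[int, int, int, int]  # (n00, n01, n10, n11) by (x, y)


def _as_graph(A: AssociationMatrix) -> ig.Graph:
    n = A.n_units
    iu, ju = np.triu_indices(n, k=1)
    w = A.values[iu, ju]
    keep = w > 0
    g = ig.Graph(n, list(zip(iu[keep].tolist(), ju[keep].tolist())))
    g.es["weight"] = w[keep].tolist()
    return g


def _louvain_once(
    g: ig.Graph, gamma: float, order: np.ndarray, py_seed: int = 0
) -> tuple[np.ndarray, float]:
    """One Louvain run with the given vertex ordering.

    igraph draws its randomness from Python's ``random`` module, which is
    re-seeded here so runs are reproducible given (order, py_seed).
    """
    _pyrandom.seed(py_seed)
    perm = order.tolist()
    h = g.permute_vertices(perm)  # vertex i of g becomes perm[i] of h
    memb = h.community_multilevel(weights="weight", resolution=gamma).membership
    labels = np.empty(g.vcount(), dtype=int)
    for i in range(g.vcount()):
        labels[i] = memb[perm[i]]
    Q = g.modularity(labels.tolist(), weights="weight", resolution=gamma)
    return labels, float(Q)


def louvain(
    A: AssociationMatrix,
    gamma: float = 1.0,
    seed: int | None = 0,
    restarts: int = 10,
    unit_info: dict[str, UnitInfo] | None = None,
) -> ModularityResult:
    """Best-of-restarts Louvain optimisation at resolution ``gamma``.

    Each restart shuffles the vertex order (the only stochastic element);
    the partition with the highest recomputed Q is kept.
    """
    if A.n_units < 2:
        raise ValueError("need at least 2 units")
    if (A.values < 0).any():
        raise ValueError("association weights must be non-negative")
    if not A.values.any():
        raise ValueError("all association weights are zero")
    g = _as_graph(A)
    rng = np.random.default_rng(seed)
    best_labels, best_Q = None, -np.inf
    for r in range(max(1, restarts)):
        order = np.arange(g.vcount()) if r == 0 else rng.permutation(g.vcount())
        labels, Q = _louvain_once(g, gamma, order, py_seed=r)
        if Q > best_Q:
            best_labels, best_Q = labels, Q
    part = TierPartition.from_labels(2, list(A.units), best_labels, unit_info)
    return ModularityResult(part, best_Q, gamma)


def modularity_p(
    A: AssociationMatrix,
    ensemble: NullEnsemble,
    gamma: float = 1.0,
    seed: int | None = 0,
    restarts: int = 10,
    null_restarts: int = 1,
    unit_info: dict[str, UnitInfo] | None = None,
) -> ModularityResult:
    """Louvain modularity with an empirical p-value against a null ensemble."""
    if ensemble.n == 0:
        raise ValueError("empty null ensemble")
    if ensemble.index_type != A.index_type:
        raise ValueError(
            f"ensemble index {ensemble.index_type} does not match matrix {A.index_type}"
        )
    obs = louvain(A, gamma=gamma, seed=seed, restarts=restarts, unit_info=unit_info)
    null_Q = np.array(
        [
            louvain(M, gamma=gamma, seed=seed, restarts=null_restarts).Q
            for M in ensemble.matrices
        ]
    )
    obs.p = empirical_p(obs.Q, null_Q, "ge")
    obs.null_Q = null_Q
    return obs


def resolution_sweep(
    A: AssociationMatrix,
    ensemble: NullEnsemble,
    gammas=None,
    seed: int | None = 0,
    restarts: int = 1,
    unit_info: dict[str, UnitInfo] | None = None,
) -> pd.DataFrame:
    """Louvain over a grid of resolutions with per-gamma empirical p-values.

    One null ensemble is reused across the whole grid.  Returns a table with
    columns gamma, Q, p, n_modules, mean_units, mean_individuals.
    """
    if gammas is None:
        gammas = np.round(np.arange(0.0, 2.0 + 1e-9, 0.01), 2)
    gammas = np.asarray(gammas, dtype=float)
    if len(gammas) < 3:
        raise ValueError("sweep needs at least 3 resolution values")
    g_obs = _as_graph(A)
    g_nulls = [_as_graph(M) for M in ensemble.matrices]
    rng = np.random.default_rng(seed)
    rows = []
    n = A.n_units
    ident = np.arange(n)
    for gamma in gammas:
        best_labels, best_Q = None, -np.inf
        for r in range(max(1, restarts)):
            order = ident if r == 0 else rng.permutation(n)
            labels, Q = _louvain_once(g_obs, gamma, order, py_seed=r)
            if Q > best_Q:
                best_labels, best_Q = labels, Q
        null_Q = [_louvain_once(gn, gamma, ident)[1] for gn in g_nulls]
        part = TierPartition.from_labels(2, list(A.units), best_labels, unit_info)
        rows.append(
            {
                "gamma": float(gamma),
                "Q": best_Q,
                "p": empirical_p(best_Q, null_Q, "ge"),
                "n_modules": part.n_clusters,
                "mean_units": part.mean_units,
                "mean_individuals": part.mean_individuals,
            }
        )
    return pd.DataFrame(rows)


def find_troughs(sweep: pd.DataFrame, alpha: float = 0.05) -> list[pd.Series]:
    """Local minima of the p-value curve over gamma, retained if p < alpha.

    Plateaus of equal p collapse to a single candidate; each retained trough
    is reported at the most significant gamma of its plateau (the midpoint
    when tied).  Returns the corresponding sweep rows, in gamma order.
    """
    if len(sweep) < 3:
        raise ValueError("sweep must cover at least 3 resolution values")
    p = sweep["p"].to_numpy()
    # run-length encode plateaus
    segs = []  # (value, start, end)
    start = 0
    for i in range(1, len(p) + 1):
        if i == len(p) or p[i] != p[start]:
            segs.append((p[start], start, i - 1))
            start = i
    troughs = []
    for s, (val, a, b) in enumerate(segs):
        left_ok = s == 0 or segs[s - 1][0] > val
        right_ok = s == len(segs) - 1 or segs[s + 1][0] > val
        if left_ok and right_ok and val < alpha:
            troughs.append(sweep.iloc[(a + b) // 2])
    return troughs


def _pair_indicators(
    tier1: TierPartition, tier2: TierPartition
) -> tuple[np.ndarray, np.ndarray]:
    units = sorted(set(tier1.assignment) & set(tier2.assignment))
    if len(units) < 3:
        raise ValueError("partitions share fewer than 3 units")
    l1 = np.array([tier1.assignment[u] for u in units])
    l2 = np.array([tier2.assignment[u] for u in units])
    iu, ju = np.triu_indices(len(units), k=1)
    x = (l1[iu] == l1[ju]).astype(int)
    y = (l2[iu] == l2[ju]).astype(int)
    return x, y


def _binary_logit_wald(x: np.ndarray, y: np.ndarray) -> ComembershipResult:
    """Wald z for the slope of a logistic regression of y on binary x."""
    n00 = int(((x == 0) & (y == 0)).sum())
    n01 = int(((x == 0) & (y == 1)).sum())
    n10 = int(((x == 1) & (y == 0)).sum())
    n11 = int(((x == 1) & (y == 1)).sum())
    table = (n00, n01, n10, n11)
    if min(table) == 0:
        # infinite-slope (separation) condition: the Wald z is undefined
        return ComembershipResult(np.nan, np.nan, True, table)
    model = sm.GLM(y, sm.add_constant(x.astype(float)), family=sm.families.Binomial())
    fit = model.fit()
    z = float(fit.params[1] / fit.bse[1])
    return ComembershipResult(z, float(fit.pvalues[1]), False, table)


def comembership_glm(tier1: TierPartition, tier2: TierPartition) -> ComembershipResult:
    """Does sharing a tier-1 cluster predict sharing a tier-2 module?

    Binomial logistic regression over all unordered unit pairs of the shared
    unit set: same-tier-2 (0/1) on same-tier-1 (0/1).  A significant positive
    slope indicates the two detection methods agree and the structure is
    hierarchically inclusive.  Dyadic observations are not independent, so
    the p-value is anti-conservative; treat it as descriptive.
    """
    x, y = _pair_indicators(tier1, tier2)
    return _binary_logit_wald(x, y)
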