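"""Hierarchical clustering of BP associations and social-tier detection.

The BP tail probability, raised to the 2/3 power, serves as the clustering
distance: pairs that covisit far beyond chance have tails near zero and sit
close together.  Under a null model the power transform makes the cumulative
count of dendrogram joins approximately linear in distance, so a change of
gradient in the observed curve — a *knot*, located by a two-sample Wilcoxon
rank-sum scan over the local gradient series — marks the transition from one
social tier to the next.  Cutting the dendrogram at the knot height yields
the first-tier partition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform

from .association import AssociationMatrix
from .data_model import UnitInfo

log = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "BifurcationCurve",
    "KnotResult",
    "TierPartition",
    "bp_distance",
    "upgma",
    "bifurcation_curve",
    "detect_knot",
    "linearity_r2",
    "cut_tier1",
]


@dataclass
class Dendrogram:
    """UPGMA merge tree: a scipy linkage matrix plus leaf labels."""

    Z: np.ndarray  # (n-1, 4) scipy linkage encoding
    leaves: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def cophenetic(self) -> np.ndarray:
        """Square matrix of cophenetic (merge-height) distances."""
        return squareform(cophenet(self.Z))

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}

        def render(node: int) -> str:
            if node < n:
                return self.leaves[node]
            l, r, h, _ = self.Z[node - n]
            l, r = int(l), int(r)
            return (
                f"({render(l)}:{h - heights[l]:.6g},"
                f"{render(r)}:{h - heights[r]:.6g})"
            )

        for m, (l, r, h, _) in enumerate(self.Z):
            heights[n + m] = h
        return render(2 * n - 2) + ";"


@dataclass
class BifurcationCurve:
    """Cumulative count of dendrogram joins as a function of merge height."""

    heights: np.ndarray  # sorted ascending, one entry per merge (ties repeat)
    cumulative: np.ndarray  # 1..n_merges

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=int)
        if len(self.heights) != len(self.cumulative):
            raise ValueError("heights and cumulative lengths differ")


@dataclass(frozen=True)
class KnotResult:
    """A detected gradient change point in the bifurcation curve."""

    d_knot: float
    w: float  # rank-sum statistic of the below-knot gradient sample
    p: float
    significant: bool


@dataclass
class TierPartition:
    """Assignment of social units to clusters/modules at one tier."""

    tier: int
    assignment: dict[str, int]
    mean_units: float
    mean_individuals: float | None = None

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def labels_for(self, units: list[str]) -> list[int]:
        return [self.assignment[u] for u in units]

    @classmethod
    def from_labels(
        cls,
        tier: int,
        units: list[str],
        labels,
        unit_info: dict[str, UnitInfo] | None = None,
    ) -> "TierPartition":
        assignment = {u: int(l) for u, l in zip(units, labels)}
        clusters: dict[int, list[str]] = {}
        for u, l in assignment.items():
            clusters.setdefault(l, []).append(u)
        mean_units = len(units) / len(clusters)
        mean_ind = None
        if unit_info is not None:
            missing = [u for u in units if u not in unit_info]
            if missing:
                log.warning(
                    "TierPartition: %d units missing size info; "
                    "mean_individuals omitted",
                    len(missing),
                )
            else:
                sizes = [
                    sum(unit_info[u].n_individuals for u in members)
                    for members in clusters.values()
                ]
                mean_ind = float(np.mean(sizes))
        return cls(tier, assignment, mean_units, mean_ind)


def bp_distance(A: AssociationMatrix) -> np.ndarray:
    """Clustering distance d_ij = p_ij^(2/3) from BP tail probabilities."""
    if A.index_type != "BP" or A.tails is None:
        raise TypeError("dendrogram distance is defined for BP matrices with tails")
    D = np.asarray(A.tails, dtype=float) ** (2.0 / 3.0)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def upgma(D: np.ndarray, labels: list[str]) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a square distance matrix."""
    D = np.asarray(D, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if D.shape[0] < 2:
        raise ValueError("need at least 2 leaves")
    Z = linkage(squareform(D, checks=False), method="average")
    return Dendrogram(Z, list(labels))


def bifurcation_curve(dend: Dendrogram) -> BifurcationCurve:
    """Extract the cumulative bifurcation curve from a dendrogram."""
    h = np.sort(dend.heights)
    return BifurcationCurve(h, np.arange(1, len(h) + 1))


def _gradients(curve: BifurcationCurve) -> tuple[np.ndarray, np.ndarray]:
    """Local gradients between consecutive *distinct* heights.

    Ties (several merges at one height) contribute a single step whose rise is
    the number of tied merges.  Returns (boundary heights, gradients); the
    gradient g[r] spans heights (h[r], h[r+1]).
    """
    h, counts = np.unique(curve.heights, return_counts=True)
    cum = np.cumsum(counts)
    if len(h) < 2:
        raise ValueError("all merges at a single height; no gradients defined")
    g = np.diff(cum) / np.diff(h)
    return h, g


def detect_knot(
    curve: BifurcationCurve, min_side: int = 5, alpha: float = 0.05
) -> KnotResult:
    """Locate the tier-transition knot in the bifurcation curve.

    Scans every split of the local-gradient series with at least ``min_side``
    gradients on each side; each split is scored by a two-sided two-sample
    Wilcoxon rank-sum test (exact for <= 25 gradients per side, normal
    approximation with tie correction otherwise).  The knot is the most
    significant split; ``w`` is the rank-sum of the below-knot sample.
    """
    h, g = _gradients(curve)
    n_g = len(g)
    if n_g < 2 * min_side:
        raise ValueError(
            f"need at least {2 * min_side} gradients for a knot scan, have {n_g}"
        )
    best = None
    for m in range(min_side, n_g - min_side + 1):
        below, above = g[:m], g[m:]
        method = "exact" if max(len(below), len(above)) <= 25 else "asymptotic"
        try:
            res = stats.mannwhitneyu(below, above, alternative="two-sided", method=method)
        except ValueError:  # exact method refuses ties; fall back
            res = stats.mannwhitneyu(
                below, above, alternative="two-sided", method="asymptotic"
            )
        # rank-sum W of the below sample from the Mann-Whitney U statistic
        w = float(res.statistic) + len(below) * (len(below) + 1) / 2.0
        # knot height = boundary between the two gradient regimes
        cand = (float(h[m]), w, float(res.pvalue))
        if best is None or cand[2] < best[2]:
            best = cand
    d_knot, w, p = best
    return KnotResult(d_knot, w, p, significant=p < alpha)


def linearity_r2(curve: BifurcationCurve) -> float:
    """R-squared of the OLS fit cumulative ~ height."""
    if len(curve.heights) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(curve.heights) == 0:
        raise ValueError("constant heights: linear fit undefined")
    res = stats.linregress(curve.heights, curve.cumulative)
    return float(res.rvalue**2)


def cut_tier1(
    dend: Dendrogram,
    d_knot: float,
    unit_info: dict[str, UnitInfo] | None = None,
) -> TierPartition:
    """First-tier partition: subtrees whose internal merges all lie below the knot.

    Units whose first merge is at or above ``d_knot`` become singletons.
    """
    # strict inequality: merges exactly at the knot height are cut
    thresh = np.nextafter(float(d_knot), -np.inf)
    labels = fcluster(dend.Z, t=thresh, criterion="distance")
    return TierPartition.from_labels(1, dend.leaves, labels, unit_info)
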