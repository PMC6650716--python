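"""Tier-size scaling fits and kinship prediction of module co-membership.

Hierarchically modular societies show a roughly constant multiplier between
the mean sizes of adjacent social tiers.  Fitting ln(size) ~ level by OLS
and exponentiating the slope gives that scaling ratio.  Levels covered:

  1 individuals; 2 mother-offspring units; 3 family units (groups/solitaries);
  4 first-tier associations; 5 second-tier associations; 6 sub-population;
  7 population.

Levels 1 and 3-5 are computed from the covisit pipeline; 2, 6 and 7 cannot be
derived from covisit streams and enter as explicit configuration, never as
silent defaults.  Kin structure of modules is tested by logistic regression
of pairwise module co-membership on binary silverback relatedness.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import UnitInfo
from .hierarchy import TierPartition
from .modularity import ComembershipResult, _binary_logit_wald

log = logging.getLogger(__name__)

__all__ = [
    "TierSizeTable",
    "ScalingFit",
    "KinshipResult",
    "tier_sizes",
    "scaling_fit",
    "kinship_glm",
]


@dataclass
class TierSizeTable:
    """Mean individuals per social unit at each available social level."""

    population: str
    levels: list[int]
    sizes: list[float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sizes):
            raise ValueError("tier sizes must be strictly positive")
        if len(self.levels) != len(self.sizes):
            raise ValueError("levels and sizes lengths differ")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"population": self.population, "level": self.levels, "size": self.sizes}
        )


@dataclass(frozen=True)
class ScalingFit:
    ratio: float  # multiplier between adjacent tiers, exp(slope)
    r_squared: float
    p: float
    n_points: int


@dataclass(frozen=True)
class KinshipResult:
    z: float
    p: float
    related_fraction: float  # related / all same-module pairs with known kinship
    n_pairs: int
    separated: bool = False


def tier_sizes(
    tier1: TierPartition,
    tier2: TierPartition,
    unit_info: dict[str, UnitInfo],
    extra_levels: dict[int, float] | None = None,
    population: str = "synthetic",
) -> TierSizeTable:
    """Assemble the per-level mean unit sizes for a population.

    Level 1 is 1 by definition; level 3 averages UnitInfo.n_individuals over
    groups and solitaries; levels 4 and 5 come from the tier partitions'
    mean_individuals.  Levels 2, 6 and 7 are taken from ``extra_levels`` when
    provided and omitted with a warning otherwise.
    """
    extra_levels = extra_levels or {}
    levels: dict[int, float] = {1: 1.0}
    units = sorted(set(tier1.assignment) | set(tier2.assignment))
    sizes = [unit_info[u].n_individuals for u in units if u in unit_info]
    if not sizes:
        raise ValueError("no unit sizes available")
    levels[3] = float(np.mean(sizes))
    for lvl, part in ((4, tier1), (5, tier2)):
        if part.mean_individuals is None:
            log.warning("tier_sizes: level %d missing mean_individuals; omitted", lvl)
        else:
            levels[lvl] = float(part.mean_individuals)
    for lvl in (2, 6, 7):
        if lvl in extra_levels:
            levels[lvl] = float(extra_levels[lvl])
        else:
            log.warning("tier_sizes: level %d not configured; omitted", lvl)
    ordered = sorted(levels)
    return TierSizeTable(population, ordered, [levels[k] for k in ordered])


def scaling_fit(
    tables: TierSizeTable | list[TierSizeTable], mode: str = "mean"
) -> ScalingFit:
    """OLS of ln(size) on social level; the scaling ratio is exp(slope).

    A single table is fitted directly.  For several populations,
    ``mode="mean"`` first averages sizes at each level across populations and
    fits the means; ``mode="pooled"`` fits all points jointly with a separate
    intercept per population (the slope stays shared).
    """
    if isinstance(tables, TierSizeTable):
        tables = [tables]
    if not tables:
        raise ValueError("no tier-size tables supplied")
    df = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    if (df["size"] <= 0).any():
        raise ValueError("tier sizes must be positive for a log fit")
    if len(tables) > 1 and mode == "mean":
        df = (
            df.groupby("level", as_index=False)["size"]
            .mean()
            .assign(population="mean")
        )
    if df["level"].nunique() < 3:
        raise ValueError("need at least 3 distinct levels")
    y = np.log(df["size"].to_numpy(dtype=float))
    X = pd.DataFrame({"level": df["level"].to_numpy(dtype=float)})
    if len(tables) > 1 and mode == "pooled":
        X = pd.concat(
            [X, pd.get_dummies(df["population"], drop_first=True, dtype=float)], axis=1
        )
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return ScalingFit(
        ratio=float(np.exp(fit.params["level"])),
        r_squared=float(fit.rsquared),
        p=float(fit.pvalues["level"]),
        n_points=int(len(df)),
    )


def kinship_glm(
    kinship: pd.DataFrame,
    partition: TierPartition,
    unit_info: dict[str, UnitInfo],
) -> KinshipResult:
    """Does silverback relatedness predict module co-membership?

    ``kinship`` has columns silverback_a, silverback_b, related (0/1).  Each
    silverback maps to the module of its unit; pairs whose silverbacks both
    belong to partitioned units enter a logistic regression of co-membership
    on relatedness.  Complete separation is flagged rather than fitted.
    """
    sb_to_module: dict[str, int] = {}
    for u, mod in partition.assignment.items():
        info = unit_info.get(u)
        if info is not None and info.silverback_id is not None:
            sb_to_module[info.silverback_id] = mod
    x_rel, y_same = [], []
    for row in kinship.itertuples(index=False):
        ma = sb_to_module.get(str(row.silverback_a))
        mb = sb_to_module.get(str(row.silverback_b))
        if ma is None or mb is None:
            continue
        x_rel.append(int(row.related))
        y_same.append(int(ma == mb))
    if len(x_rel) < 3:
        raise ValueError("fewer than 3 kinship pairs map onto the partition")
    x = np.array(x_rel)
    y = np.array(y_same)
    n_same = int(y.sum())
    if n_same == 0:
        raise ValueError("no same-module pairs with known kinship")
    related_fraction = float(x[y == 1].mean())
    res: ComembershipResult = _binary_logit_wald(x, y)
    return KinshipResult(res.z, res.p, related_fraction, len(x), res.separated)
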