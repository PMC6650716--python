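"""Null association ensembles.

Two null constructions, one per index:

* **Data-stream permutation (SR)** — checkerboard swaps of the presence
  matrix.  A swap picks two units and two days forming a [[1,0],[0,1]] (or
  flipped) pattern and exchanges the ones, preserving every unit's visit
  count and every day's attendance.  Chained swaps with thinning give a
  sequence of null matrices conditioned on both margins.
* **Parametric visit resampling (BP)** — each unit's visit days are redrawn
  as a uniform random subset of its observed size, matching the BP index's
  own null hypothesis (which conditions on unit visit counts only).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .association import AssociationMatrix, binomial_probability, simple_ratio
from .data_model import PresenceMatrix

log = logging.getLogger(__name__)

__all__ = ["NullEnsemble", "datastream_permute", "null_ensemble", "empirical_p"]


@dataclass
class NullEnsemble:
    """A set of association matrices drawn under a null model."""

    index_type: str
    matrices: list[AssociationMatrix]
    seed: int | None
    method: str  # "datastream" or "parametric"

    @property
    def n(self) -> int:
        return len(self.matrices)


def _swap_chain(X: np.ndarray, n_steps: int, rng: np.random.Generator) -> int:
    """Run ``n_steps`` trial checkerboard swaps in place; return successes.

    Each step draws two occupied cells (i,t1), (j,t2) and flips the 2x2
    checkerboard when cells (i,t2), (j,t1) are empty, otherwise leaves the
    matrix unchanged.  Rejected proposals count as chain steps: the proposal
    is symmetric over ordered pairs of ones and self-loops carry the rest of
    the mass, so the stationary distribution is uniform over the fixed-margin
    matrix class (a success-only chain would oversample matrices with many
    available checkerboards).
    """
    ones = np.argwhere(X)
    rows = ones[:, 0].tolist()
    cols = ones[:, 1].tolist()
    m = len(rows)
    if m < 2:
        return 0
    done = 0
    remaining = n_steps
    while remaining > 0:
        batch = min(remaining, 8192)
        remaining -= batch
        draws = rng.integers(0, m, size=(batch, 2))
        for a, b in draws:
            i, t1 = rows[a], cols[a]
            j, t2 = rows[b], cols[b]
            if i == j or t1 == t2 or X[i, t2] or X[j, t1]:
                continue
            X[i, t1] = 0
            X[j, t2] = 0
            X[i, t2] = 1
            X[j, t1] = 1
            cols[a] = t2
            cols[b] = t1
            done += 1
    return done


def datastream_permute(
    pm: PresenceMatrix, n_swaps: int, seed: int | None = None
) -> PresenceMatrix:
    """Return a margin-preserving permutation of the presence matrix.

    ``n_swaps`` counts trial-swap chain steps (rejected proposals included,
    which keeps the sampling uniform over the fixed-margin class).  If the
    margins admit no checkerboard at all (degenerate matrix), the input comes
    back unchanged with a warning.
    """
    if pm.n_units < 2 or pm.T < 2:
        raise ValueError("need at least a 2x2 presence matrix")
    rng = np.random.default_rng(seed)
    X = pm.X.copy()
    done = _swap_chain(X, n_swaps, rng)
    if done == 0:
        log.warning(
            "datastream_permute: no swap succeeded in %d trials "
            "(degenerate margins?)", n_swaps,
        )
    return PresenceMatrix(list(pm.units), pm.days.copy(), X)


def null_ensemble(
    pm: PresenceMatrix,
    index_type: str,
    n: int = 1000,
    swaps_per_sample: int = 500,
    burn_in: int | None = None,
    seed: int | None = None,
    bp_rate_adjust: bool = False,
) -> NullEnsemble:
    """Draw ``n`` null association matrices.

    SR uses one sequential trial-swap chain, sampling every
    ``swaps_per_sample`` chain steps after ``burn_in`` steps (default: 2x the
    thinning interval).  BP redraws each unit's visit days uniformly at its
    observed count and recomputes the index.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if index_type not in ("SR", "BP"):
        raise ValueError("index_type must be 'SR' or 'BP'")
    rng = np.random.default_rng(seed)
    mats: list[AssociationMatrix] = []
    if index_type == "SR":
        if burn_in is None:
            burn_in = 2 * swaps_per_sample
        X = pm.X.copy()
        _swap_chain(X, burn_in, rng)
        for _ in range(n):
            _swap_chain(X, swaps_per_sample, rng)
            mats.append(simple_ratio(PresenceMatrix(list(pm.units), pm.days, X.copy())))
        return NullEnsemble("SR", mats, seed, "datastream")
    v = pm.visit_counts()
    T = pm.T
    for _ in range(n):
        X = np.zeros_like(pm.X)
        for i, vi in enumerate(v):
            X[i, rng.choice(T, size=vi, replace=False)] = 1
        mats.append(
            binomial_probability(
                PresenceMatrix(list(pm.units), pm.days, X), rate_adjust=bp_rate_adjust
            )
        )
    return NullEnsemble("BP", mats, seed, "parametric")


def empirical_p(observed: float, null_values, direction: str = "ge") -> float:
    """Add-one empirical p-value of ``observed`` against a null sample.

    ``direction='ge'`` counts nulls >= observed (is the observed value
    unusually large?); ``'le'`` the reverse.  Ties count against the observed
    value, and the add-one convention keeps p in (0, 1].
    """
    nulls = np.asarray(list(null_values), dtype=float)
    if nulls.size == 0:
        raise ValueError("need at least one null value")
    if direction == "ge":
        hits = int((nulls >= observed).sum())
    elif direction == "le":
        hits = int((nulls <= observed).sum())
    else:
        raise ValueError("direction must be 'ge' or 'le'")
    return (1 + hits) / (1 + nulls.size)
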