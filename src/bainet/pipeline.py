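"""End-to-end orchestration of the covisit inference chain.

Stages: read + filter visits -> association matrices (SR, BP) -> null
ensembles -> UPGMA/knot/tier-1 -> Louvain modularity + p -> resolution sweep
and troughs -> tier-consistency GLM -> scaling fit -> kinship GLM -> JSON
summary.  Every stochastic stage derives its seed from the run seed, so a
rerun with the same config is byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .association import AssociationMatrix, binomial_probability, mantel, simple_ratio
from .data_model import (
    PresenceMatrix,
    StudyPeriod,
    build_presence,
    filter_min_visits,
    read_kinship,
    read_units,
    read_visits,
    split_periods,
)
from .hierarchy import (
    bifurcation_curve,
    bp_distance,
    cut_tier1,
    detect_knot,
    linearity_r2,
    upgma,
)
from .modularity import comembership_glm, find_troughs, modularity_p, resolution_sweep
from .null_models import null_ensemble
from .scaling_kinship import kinship_glm, scaling_fit, tier_sizes

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Defaults follow the published analysis plan: minimum 8 visits per unit,
    1000 permutations, resolution grid 0..2 in steps of 0.01, alpha 0.05.
    """

    visits: str = ""
    units: str | None = None
    kinship: str | None = None
    outdir: str = "bainet_out"
    periods: list[tuple[str, int, int]] | None = None  # (label, start, end)
    min_visits: int = 8
    bp_rate_adjust: bool = False
    n_permutations: int = 1000
    swaps_per_sample: int = 500
    burn_in: int | None = None
    gamma_min: float = 0.0
    gamma_max: float = 2.0
    gamma_step: float = 0.01
    alpha: float = 0.05
    restarts: int = 10
    do_sweep: bool = True
    extra_levels: dict[int, float] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "periods" in raw and raw["periods"] is not None:
            raw["periods"] = [tuple(p) for p in raw["periods"]]
        if "extra_levels" in raw and raw["extra_levels"] is not None:
            raw["extra_levels"] = {int(k): float(v) for k, v in raw["extra_levels"].items()}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["periods"] is not None:
            d["periods"] = [list(p) for p in d["periods"]]
        return d

    def gammas(self) -> np.ndarray:
        return np.round(
            np.arange(self.gamma_min, self.gamma_max + 1e-9, self.gamma_step),
            6,
        )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write artifacts plus a JSON summary to outdir.

    Returns the summary dict.  With several periods, hierarchy and modularity
    are run on the period with the most retained units, and Mantel stability
    is computed between every pair of periods.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": cfg.to_dict(), "version": __version__}
    rng = np.random.default_rng(cfg.seed)
    seeds = {k: int(rng.integers(2**31)) for k in
             ("null_sr", "null_bp", "mantel", "louvain", "sweep")}
    summary["stage_seeds"] = seeds

    records = _stage("read_visits")(read_visits)(cfg.visits)
    unit_info = _stage("read_units")(read_units)(cfg.units) if cfg.units else None
    if not records:
        raise StageError("stage 'read_visits' failed: no visit records")
    if cfg.periods:
        periods = [StudyPeriod(l, s, e) for l, s, e in cfg.periods]
    else:
        days = [r.day for r in records]
        periods = [StudyPeriod("all", min(days), max(days))]
    split = _stage("split_periods")(split_periods)(records, periods)

    filtered: list[tuple[StudyPeriod, PresenceMatrix]] = []
    for p, pm in split:
        pmf = _stage("filter_min_visits")(filter_min_visits)(pm, cfg.min_visits)
        filtered.append((p, pmf))
        pmf.to_csv(out / f"presence_{p.label}.csv")
    summary["periods"] = {
        p.label: {"n_units": pm.n_units, "T": pm.T} for p, pm in filtered
    }

    # association matrices per period
    sr_by_period: dict[str, AssociationMatrix] = {}
    bp_by_period: dict[str, AssociationMatrix] = {}
    for p, pm in filtered:
        sr = _stage("simple_ratio")(simple_ratio)(pm)
        bp = _stage("binomial_probability")(binomial_probability)(
            pm, rate_adjust=cfg.bp_rate_adjust
        )
        sr.to_csv(out / f"sr_{p.label}.csv")
        bp.to_csv(out / f"bp_{p.label}.csv")
        sr_by_period[p.label] = sr
        bp_by_period[p.label] = bp

    # Mantel stability between periods (SR)
    if len(filtered) > 1:
        stability = {}
        labels = [p.label for p, _ in filtered]
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                try:
                    res = mantel(
                        sr_by_period[labels[i]],
                        sr_by_period[labels[j]],
                        n_perm=cfg.n_permutations,
                        seed=seeds["mantel"] + i * 100 + j,
                    )
                    stability[f"{labels[i]}~{labels[j]}"] = {
                        "Z": res.Z, "p": res.p, "n_perm": res.n_perm
                    }
                except ValueError as exc:
                    stability[f"{labels[i]}~{labels[j]}"] = {"error": str(exc)}
        summary["mantel_stability"] = stability

    # analysis period: most retained units
    p_main, pm_main = max(filtered, key=lambda t: t[1].n_units)
    summary["analysis_period"] = p_main.label
    sr, bp = sr_by_period[p_main.label], bp_by_period[p_main.label]

    # hierarchy (BP)
    dend = _stage("upgma")(lambda: upgma(bp_distance(bp), bp.units))()
    (out / "dendrogram.nwk").write_text(dend.to_newick())
    curve = bifurcation_curve(dend)
    knot = _stage("detect_knot")(detect_knot)(curve, alpha=cfg.alpha)
    r2 = linearity_r2(curve)
    tier1 = cut_tier1(dend, knot.d_knot, unit_info)
    summary["hierarchy"] = {
        "knot": dataclasses.asdict(knot),
        "curve_r2": r2,
        "tier1_n_clusters": tier1.n_clusters,
        "tier1_mean_units": tier1.mean_units,
        "tier1_mean_individuals": tier1.mean_individuals,
    }
    _write_partition(tier1, out / "tier1_partition.csv")

    # null ensembles + modularity
    ens_sr = _stage("null_ensemble")(null_ensemble)(
        pm_main, "SR", n=cfg.n_permutations,
        swaps_per_sample=cfg.swaps_per_sample, burn_in=cfg.burn_in,
        seed=seeds["null_sr"],
    )
    ens_bp = _stage("null_ensemble")(null_ensemble)(
        pm_main, "BP", n=cfg.n_permutations, seed=seeds["null_bp"],
        bp_rate_adjust=cfg.bp_rate_adjust,
    )
    summary["modularity"] = {}
    tier2 = None
    for name, A, ens in (("SR", sr, ens_sr), ("BP", bp, ens_bp)):
        res = _stage("modularity_p")(modularity_p)(
            A, ens, gamma=1.0, seed=seeds["louvain"], restarts=cfg.restarts,
            unit_info=unit_info,
        )
        summary["modularity"][name] = {
            "Q": res.Q,
            "p": res.p,
            "n_modules": res.partition.n_clusters,
            "mean_units": res.partition.mean_units,
            "mean_individuals": res.partition.mean_individuals,
        }
        _write_partition(res.partition, out / f"tier2_{name.lower()}_partition.csv")
        if name == "SR":
            tier2 = res.partition
            tier2_bp = None
        else:
            tier2_bp = res.partition

    # consistency between the two detection routes
    cons = _stage("comembership_glm")(comembership_glm)(tier1, tier2)
    summary["consistency"] = dataclasses.asdict(cons)

    # resolution sweep (SR only)
    if cfg.do_sweep:
        sweep = _stage("resolution_sweep")(resolution_sweep)(
            sr, ens_sr, gammas=cfg.gammas(), seed=seeds["sweep"],
            unit_info=unit_info,
        )
        sweep.to_csv(out / "sweep.csv", index=False)
        troughs = find_troughs(sweep, alpha=cfg.alpha)
        summary["sweep"] = {
            "n_gammas": len(sweep),
            "troughs": [_jsonable(t.to_dict()) for t in troughs],
        }

    # scaling
    if unit_info is not None:
        try:
            table = tier_sizes(tier1, tier2, unit_info, cfg.extra_levels)
            fit = scaling_fit(table)
            summary["scaling"] = {
                "levels": table.levels,
                "sizes": table.sizes,
                **dataclasses.asdict(fit),
            }
        except ValueError as exc:
            summary["scaling"] = {"error": str(exc)}

    # kinship
    if cfg.kinship and unit_info is not None:
        kin = _stage("read_kinship")(read_kinship)(cfg.kinship)
        summary["kinship"] = {}
        for name, part in (("SR", tier2), ("BP", tier2_bp)):
            try:
                kres = kinship_glm(kin, part, unit_info)
                summary["kinship"][name] = dataclasses.asdict(kres)
            except ValueError as exc:
                summary["kinship"][name] = {"error": str(exc)}

    summary = _jsonable(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _write_partition(part, path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        sorted(part.assignment.items()), columns=["unit_id", "cluster"]
    ).to_csv(path, index=False)
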