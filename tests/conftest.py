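import numpy as np
import pytest

import bainet as bn


def presence_from_day_sets(day_sets: dict[str, set[int]], T: int) -> bn.PresenceMatrix:
    """Build a PresenceMatrix from explicit per-unit visit-day sets."""
    units = sorted(day_sets)
    X = np.zeros((len(units), T), dtype=np.uint8)
    for i, u in enumerate(units):
        for d in day_sets[u]:
            X[i, d] = 1
    return bn.PresenceMatrix(units, np.arange(T), X)


@pytest.fixture
def random_presence():
    """Factory for random presence matrices with a seeded generator."""

    def make(n_units=6, T=30, density=0.3, seed=0):
        rng = np.random.default_rng(seed)
        X = (rng.random((n_units, T)) < density).astype(np.uint8)
        # guarantee every unit has at least one visit
        for i in range(n_units):
            if X[i].sum() == 0:
                X[i, rng.integers(T)] = 1
        return bn.PresenceMatrix([f"u{i}" for i in range(n_units)], np.arange(T), X)

    return make


@pytest.fixture(scope="session")
def strong_signal_run():
    """One synthetic dataset with planted structure, run through the core chain.

    Session-scoped: several test modules inspect different aspects of the
    same run.
    """
    cfg = bn.GeneratorConfig(seed=7)
    truth = bn.generate_population(cfg)
    records = bn.simulate_visits(truth, seed=1007)
    pm = bn.build_presence(records, bn.StudyPeriod("all", 0, cfg.T - 1))
    pm = bn.filter_min_visits(pm, 8)
    sr = bn.simple_ratio(pm)
    bp = bn.binomial_probability(pm)
    dend = bn.upgma(bn.bp_distance(bp), bp.units)
    curve = bn.bifurcation_curve(dend)
    knot = bn.detect_knot(curve)
    tier1 = bn.cut_tier1(dend, knot.d_knot, truth.unit_info)
    tier2 = bn.louvain(sr, seed=0, unit_info=truth.unit_info).partition
    return {
        "cfg": cfg,
        "truth": truth,
        "pm": pm,
        "sr": sr,
        "bp": bp,
        "dend": dend,
        "curve": curve,
        "knot": knot,
        "tier1": tier1,
        "tier2": tier2,
    }
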