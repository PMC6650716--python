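import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

import bainet as bn
from bainet.hierarchy import TierPartition


def naive_upgma(D):
    """Brute-force average-linkage agglomeration; returns merge heights and
    the cophenetic matrix.  Independent of scipy's linkage implementation."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights), coph


def random_distance(n, seed):
    rng = np.random.default_rng(seed)
    D = rng.random((n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    return D


class TestBpDistance:
    def test_tail_one_maps_to_distance_one(self):
        units = ["a", "b"]
        tails = np.array([[1.0, 1.0], [1.0, 1.0]])
        A = bn.AssociationMatrix(units, 1 - tails + np.eye(2) * 0, "BP", tails=tails)
        D = bn.bp_distance(A)
        assert D[0, 1] == pytest.approx(1.0)
        assert D[0, 0] == 0.0

    def test_transform_inverts_at_knot_scale(self):
        p = 0.29 ** 1.5
        tails = np.array([[1.0, p], [p, 1.0]])
        A = bn.AssociationMatrix(["a", "b"], 1 - tails - np.diag([0.0, 0.0]), "BP",
                                 tails=tails)
        # fix diagonal to zero for validity
        A.values[np.diag_indices(2)] = 0
        assert bn.bp_distance(A)[0, 1] == pytest.approx(0.29, abs=1e-12)

    def test_sr_input_rejected(self):
        A = bn.AssociationMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0]]), "SR")
        with pytest.raises(TypeError):
            bn.bp_distance(A)

    def test_monotone_in_tail(self):
        ps = np.linspace(0.01, 1, 50)
        ds = ps ** (2 / 3)
        assert (np.diff(ds) > 0).all()


class TestUpgma:
    def test_three_leaf_hand_agglomeration(self):
        D = np.array([[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]])
        dend = bn.upgma(D, ["A", "B", "C"])
        assert dend.heights.tolist() == pytest.approx([0.1, 0.5])
        # first merge joins the two leaves at distance 0.1
        assert sorted(dend.Z[0, :2].astype(int).tolist()) == [0, 1]

    def test_equidistant_triple(self):
        D = np.full((3, 3), 0.4)
        np.fill_diagonal(D, 0)
        dend = bn.upgma(D, ["A", "B", "C"])
        assert dend.heights.tolist() == pytest.approx([0.4, 0.4])

    @pytest.mark.parametrize("n", [4, 5, 6])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_naive_oracle(self, n, seed):
        D = random_distance(n, seed)
        dend = bn.upgma(D, [f"u{i}" for i in range(n)])
        heights, coph_oracle = naive_upgma(D)
        assert np.allclose(np.sort(dend.heights), heights)
        assert np.allclose(dend.cophenetic(), coph_oracle)

    def test_ultrametric_input_is_fixed_point(self):
        base = bn.upgma(random_distance(7, 9), [f"u{i}" for i in range(7)])
        U = base.cophenetic()
        again = bn.upgma(U, base.leaves)
        assert np.allclose(again.cophenetic(), U)

    def test_nan_distance_rejected(self):
        D = random_distance(4, 0)
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            bn.upgma(D, list("abcd"))

    def test_newick_export_parses(self):
        dend = bn.upgma(random_distance(5, 2), [f"u{i}" for i in range(5)])
        nwk = dend.to_newick()
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == dend.leaves


class TestBifurcationCurve:
    def test_three_leaves_give_two_points(self):
        dend = bn.upgma(random_distance(3, 0), list("abc"))
        curve = bn.bifurcation_curve(dend)
        assert len(curve.heights) == 2
        assert curve.cumulative.tolist() == [1, 2]

    def test_tied_heights_share_height_with_distinct_counts(self):
        D = np.full((4, 4), 0.4)
        np.fill_diagonal(D, 0)
        curve = bn.bifurcation_curve(bn.upgma(D, list("abcd")))
        assert np.allclose(curve.heights, 0.4)
        assert curve.cumulative.tolist() == [1, 2, 3]


def two_regime_curve(n_low=41, n_high=41, g_low=200.0, g_high=20.0, seed=0):
    """Cumulative curve with a sharp gradient drop at the regime boundary."""
    rng = np.random.default_rng(seed)
    steps = np.concatenate([
        1 / (g_low * (1 + 0.1 * rng.random(n_low))),
        1 / (g_high * (1 + 0.1 * rng.random(n_high))),
    ])
    heights = np.cumsum(steps)
    return bn.BifurcationCurve(heights, np.arange(1, len(heights) + 1)), heights[n_low - 1]


class TestDetectKnot:
    def test_finds_planted_change_point(self):
        curve, boundary = two_regime_curve()
        knot = bn.detect_knot(curve)
        assert knot.significant
        assert knot.p < 1e-3
        assert knot.d_knot == pytest.approx(boundary, rel=0.15)

    def test_homogeneous_gradients_not_significant(self):
        heights = np.linspace(0.01, 0.8, 40)
        curve = bn.BifurcationCurve(heights, np.arange(1, 41))
        knot = bn.detect_knot(curve)
        assert not knot.significant

    def test_exactly_constant_gradients_give_p_one(self):
        heights = np.arange(1, 41, dtype=float)  # exact ties in every gradient
        curve = bn.BifurcationCurve(heights, np.arange(1, 41))
        knot = bn.detect_knot(curve)
        assert knot.p == pytest.approx(1.0)
        assert not knot.significant

    def test_w_is_rank_sum_of_below_sample(self):
        # two clearly separated regimes: below-gradients all larger, so the
        # below sample takes the top m ranks
        curve, _ = two_regime_curve(n_low=10, n_high=10)
        knot = bn.detect_knot(curve, min_side=5)
        h, g = bn.hierarchy._gradients(curve)
        m = int(np.searchsorted(h, knot.d_knot))
        below = g[:m]
        ranks = np.argsort(np.argsort(g)) + 1
        assert knot.w == pytest.approx(ranks[:m].sum())

    def test_too_few_merges_raise(self):
        curve = bn.BifurcationCurve(np.linspace(0, 1, 5), np.arange(1, 6))
        with pytest.raises(ValueError, match="gradients"):
            bn.detect_knot(curve)


class TestLinearity:
    def test_perfect_line_gives_one(self):
        curve = bn.BifurcationCurve(np.linspace(0.1, 1, 20), np.arange(1, 21))
        assert bn.linearity_r2(curve) == pytest.approx(1.0)

    def test_two_regime_curve_fits_worse_than_line(self):
        curve, _ = two_regime_curve()
        assert bn.linearity_r2(curve) < 0.95

    def test_constant_heights_raise(self):
        curve = bn.BifurcationCurve(np.full(5, 0.3), np.arange(1, 6))
        with pytest.raises(ValueError):
            bn.linearity_r2(curve)

    def test_null_bp_curve_is_approximately_linear(self):
        """The x^(2/3) transform linearises the null bifurcation curve."""
        r2s = []
        for seed in range(5):
            cfg = bn.GeneratorConfig(
                n_units=30, T=365, within_tier1_boost=1, within_tier2_boost=1,
                tier1_excursion_prob=0, tier2_excursion_prob=0,
                base_visit_rate=0.1, seasonal_amplitude=0, seed=seed,
            )
            truth = bn.generate_population(cfg)
            pm = bn.filter_min_visits(
                bn.build_presence(
                    bn.simulate_visits(truth, seed=seed + 100),
                    bn.StudyPeriod("all", 0, cfg.T - 1),
                ),
                8,
            )
            bp = bn.binomial_probability(pm)
            curve = bn.bifurcation_curve(bn.upgma(bn.bp_distance(bp), bp.units))
            r2s.append(bn.linearity_r2(curve))
        assert np.median(r2s) > 0.9


class TestCutTier1:
    @pytest.fixture
    def dend(self):
        return bn.upgma(random_distance(8, 4), [f"u{i}" for i in range(8)])

    def test_knot_below_all_heights_gives_singletons(self, dend):
        part = bn.cut_tier1(dend, dend.heights.min() / 2)
        assert part.n_clusters == 8
        assert part.mean_units == 1.0

    def test_knot_above_all_heights_gives_one_cluster(self, dend):
        part = bn.cut_tier1(dend, dend.heights.max() * 2)
        assert part.n_clusters == 1
        assert part.mean_units == 8.0

    def test_merge_exactly_at_knot_is_cut(self, dend):
        h0 = np.sort(dend.heights)[0]
        part = bn.cut_tier1(dend, h0)
        assert part.n_clusters == 8  # the first merge is excluded

    def test_matches_cophenetic_threshold_partition(self, dend):
        """Cutting the tree at h equals thresholding cophenetic distance at h."""
        coph = dend.cophenetic()
        for h in np.quantile(dend.heights, [0.3, 0.6, 0.9]):
            part = bn.cut_tier1(dend, h)
            # connected components of the graph cophenetic < h
            import networkx as nx

            G = nx.from_numpy_array((coph < h) & ~np.eye(8, dtype=bool))
            comps = list(nx.connected_components(G))
            labels_ref = {}
            for c, comp in enumerate(comps):
                for i in comp:
                    labels_ref[dend.leaves[i]] = c
            # same partition up to relabeling
            from sklearn.metrics import adjusted_rand_score

            units = dend.leaves
            ari = adjusted_rand_score(
                [labels_ref[u] for u in units], [part.assignment[u] for u in units]
            )
            assert ari == pytest.approx(1.0)

    def test_mean_individuals_weighting(self, dend):
        info = {u: bn.UnitInfo(u, "group", 3) for u in dend.leaves}
        part = bn.cut_tier1(dend, dend.heights.max() * 2, info)
        assert part.mean_individuals == pytest.approx(24.0)

    def test_missing_sizes_omit_mean_individuals(self, dend, caplog):
        info = {dend.leaves[0]: bn.UnitInfo(dend.leaves[0], "group", 3)}
        part = bn.cut_tier1(dend, dend.heights.max() * 2, info)
        assert part.mean_individuals is None


def test_tier1_recovery_on_planted_pairs():
    """Knot + cut recovers planted first-tier clusters at strong signal."""
    from sklearn.metrics import adjusted_rand_score

    aris = []
    for seed in range(20):
        cfg = bn.GeneratorConfig(seed=seed)
        truth = bn.generate_population(cfg)
        pm = bn.filter_min_visits(
            bn.build_presence(
                bn.simulate_visits(truth, seed=seed + 2000),
                bn.StudyPeriod("all", 0, cfg.T - 1),
            ),
            8,
        )
        bp = bn.binomial_probability(pm)
        dend = bn.upgma(bn.bp_distance(bp), bp.units)
        knot = bn.detect_knot(bn.bifurcation_curve(dend))
        part = bn.cut_tier1(dend, knot.d_knot)
        shared = [u for u in truth.units if u in part.assignment]
        aris.append(
            adjusted_rand_score(
                [truth.tier1_labels[u] for u in shared],
                [part.assignment[u] for u in shared],
            )
        )
    assert np.median(aris) >= 0.9
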