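"""UPGMA, ultrametric trees, and the mixed Yule-coalescent engine."""

import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from eurydelim import distances, gmyc, synthdata
from eurydelim.gmyc import Node, UltrametricTree


def dm_from(values, ids=None):
    v = np.asarray(values, dtype=float)
    ids = tuple(ids or (f"s{i}" for i in range(len(v))))
    return distances.DistanceMatrix(ids, v)


def cophenetic(tree):
    """Tip-pair distances implied by the tree (2 x MRCA height)."""
    tips = {}

    def collect(node):
        if node.is_tip:
            return {node.label}
        out = set()
        for c in node.children:
            sub = collect(c)
            for other in out:
                for a in sub:
                    tips[frozenset((a, other))] = 2 * node.height
            out |= sub
        return out

    leaves = collect(tree.root)
    return tips, sorted(leaves)


class TestUPGMA:
    def test_two_taxa_cherry(self):
        tree = gmyc.upgma(dm_from([[0, 0.2], [0.2, 0]], ids=["a", "b"]))
        assert tree.root.height == pytest.approx(0.1)
        assert sorted(tree.tip_labels) == ["a", "b"]

    def test_ultrametric_input_reproduced_exactly(self):
        # distances already ultrametric: cophenetic output == input
        v = np.array(
            [[0, 0.1, 0.4, 0.4], [0.1, 0, 0.4, 0.4], [0.4, 0.4, 0, 0.2], [0.4, 0.4, 0.2, 0]]
        )
        dm = dm_from(v)
        tree = gmyc.upgma(dm)
        coph, _ = cophenetic(tree)
        for i, a in enumerate(dm.ids):
            for j, b in enumerate(dm.ids):
                if i < j:
                    assert coph[frozenset((a, b))] == pytest.approx(v[i, j])

    def test_matches_scipy_average_linkage(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            m = rng.random((n, n)) * 0.5 + 0.01
            v = np.triu(m, 1)
            v = v + v.T
            dm = dm_from(v)
            tree = gmyc.upgma(dm)
            coph, _ = cophenetic(tree)
            z = average(squareform(v, checks=False))
            sq = squareform(cophenet(z))
            for i in range(n):
                for j in range(i + 1, n):
                    assert coph[frozenset((dm.ids[i], dm.ids[j]))] == pytest.approx(
                        sq[i, j], rel=1e-9
                    )

    def test_single_id_rejected(self):
        with pytest.raises(ValueError):
            gmyc.upgma(dm_from([[0.0]]))


class TestTreeIO:
    def test_newick_roundtrip(self):
        nwk = "((a:1.0,b:1.0):2.0,(c:2.5,d:2.5):0.5);"
        tree = UltrametricTree.from_newick(nwk)
        assert tree.n_tips == 4
        assert tree.root.height == pytest.approx(3.0)
        back = UltrametricTree.from_newick(tree.to_newick())
        assert sorted(back.tip_labels) == ["a", "b", "c", "d"]
        assert back.root.height == pytest.approx(3.0)

    def test_non_ultrametric_rejected(self):
        with pytest.raises(ValueError, match="ultrametric"):
            UltrametricTree.from_newick("((a:1.0,b:3.0):2.0,c:3.0);")

    def test_polytomy_resolved_to_binary(self):
        tree = UltrametricTree.from_newick("(a:1.0,b:1.0,c:1.0,d:1.0);")
        for node in tree.preorder():
            if not node.is_tip:
                assert len(node.children) == 2
        assert tree.n_tips == 4


def toy_tree():
    """Four tips: cherry (a,b) at height 0.1, cherry (c,d) at 0.2, root 1.0."""
    return UltrametricTree(
        Node(
            1.0,
            (
                Node(0.1, (Node(0, label="a"), Node(0, label="b"))),
                Node(0.2, (Node(0, label="c"), Node(0, label="d"))),
            ),
        )
    )


class TestBranchingSchedule:
    def test_threshold_above_root_single_entity(self):
        s = gmyc.branching_schedule(toy_tree(), 2.0)
        assert s.n_entities == 1 and s.n_clusters == 1

    def test_threshold_zero_all_tips(self):
        s = gmyc.branching_schedule(toy_tree(), 0.0)
        assert s.n_entities == 4 and s.n_clusters == 0
        assert [iv.event_process for iv in s.intervals] == ["div", "div"]

    def test_interior_threshold_clusters_and_counts(self):
        s = gmyc.branching_schedule(toy_tree(), 0.5)
        assert s.n_entities == 2 and s.n_clusters == 2
        # lineages through time: 2 at the root, then 3, ending at 4 tips
        assert s.lineages_through_time == [2, 3, 4]
        assert sorted(m for m, _ in s.clusters) == [2, 2]

    def test_entities_non_increasing_in_threshold(self, preset_dataset):
        tree = preset_dataset.true_tree
        heights = np.unique(tree.internal_heights())
        prev = tree.n_tips + 1
        ents = [
            gmyc.branching_schedule(tree, t).n_entities
            for t in np.linspace(0, tree.root.height, 25)
        ]
        assert ents == sorted(ents, reverse=True)


class TestLikelihoodEngine:
    def test_hand_computed_interior_threshold(self):
        """Interval-product engine vs direct per-interval arithmetic on the
        4-tip toy tree at T = 0.5 with fixed parameters."""
        tree = toy_tree()
        lam1, p1, lam2, p2 = 2.0, 1.0, 30.0, 1.5
        # intervals: (1.0 -> 0.2): 2 lineages, event at 0.2 (coal);
        #            (0.2 -> 0.1): 3 lineages, event at 0.1 (coal)
        # T = 0.5 splits the first interval: 0.5 above / 0.3 below.
        # entities: 2 cherries; below T their counts are 1 until each splits.
        b_above = lam1 * 2 ** p1
        E = 2  # entities -> frozen diversification count below T
        # interval 1 below part: both clusters single lineages -> coal rate 0
        b1_below = lam1 * E ** p1
        # interval 2: cherry (c,d) has split at 0.2 -> its count is 2, f = 2
        b2 = lam1 * E ** p1 + lam2 * (2 * 1) ** p2
        expected = (
            math.log(b1_below) - (b_above * 0.5 + b1_below * 0.3)
            + math.log(b2) - b2 * 0.1
        )
        s = gmyc.branching_schedule(tree, 0.5)
        assert gmyc.mixed_loglik(s, lam1, p1, lam2, p2) == pytest.approx(expected, rel=1e-9)

    def test_hand_computed_null_form(self):
        """At T = 0 the engine reduces to the single-process pure-birth form."""
        tree = toy_tree()
        lam, p = 3.0, 1.2
        b1, b2 = lam * 2 ** p, lam * 3 ** p
        expected = math.log(b1) - b1 * 0.8 + math.log(b2) - b2 * 0.1
        s = gmyc.branching_schedule(tree, 0.0)
        assert gmyc.mixed_loglik(s, lam, p, 123.0, 0.7) == pytest.approx(expected, rel=1e-9)


class TestNullFit:
    def test_closed_form_rate_at_optimum(self, preset_dataset):
        """At the fitted exponent, the rate satisfies lambda = E / sum(n^p x)."""
        tree = preset_dataset.true_tree
        fit = gmyc.fit_null(tree)
        heights = tree.internal_heights()
        E = len(heights) - 1
        S = sum(
            (i + 2) ** fit.p * (heights[i] - heights[i + 1])
            for i in range(len(heights) - 1)
        )
        assert fit.lam == pytest.approx(E / S, rel=1e-6)

    def test_scale_equivariance(self):
        tree = toy_tree()
        fit1 = gmyc.fit_null(tree)

        def scale(node):
            return Node(node.height * 2, tuple(scale(c) for c in node.children), node.label)

        fit2 = gmyc.fit_null(UltrametricTree(scale(toy_tree().root)))
        assert fit2.lam == pytest.approx(fit1.lam / 2, rel=1e-4)
        n_events = 2
        assert fit2.lnL == pytest.approx(fit1.lnL - n_events * math.log(2), rel=1e-6)

    def test_yule_exponent_recovery(self):
        """On pure Yule trees the fitted exponent should average near 1."""
        ps = []
        for s in range(100):
            cfg = synthdata.SimConfig(
                n_species=25, samples_per_species=1, min_split_height=0.0,
                birth_rate=10.0, theta=0.0, seed=40_000 + s,
            )
            tree, _ = synthdata.simulate_tree(cfg)
            ps.append(gmyc.fit_null(tree).p)
        mean_p = float(np.mean(ps))
        se = float(np.std(ps) / np.sqrt(len(ps)))
        assert abs(mean_p - 1.0) < max(3 * se, 0.25)

    def test_too_few_tips_rejected(self):
        tree = UltrametricTree(
            Node(1.0, (Node(0, label="a"), Node(0, label="b")))
        )
        with pytest.raises(ValueError):
            gmyc.fit_null(tree)


class TestGMYCFit:
    def test_alternative_never_below_null(self, preset_dataset, rng):
        trees = [preset_dataset.true_tree]
        for s in range(3):
            cfg = synthdata.SimConfig(
                n_species=12, samples_per_species=1, min_split_height=0.0,
                birth_rate=10.0, theta=0.0, seed=50_000 + s,
            )
            trees.append(synthdata.simulate_tree(cfg)[0])
        for tree in trees:
            null = gmyc.fit_null(tree)
            fit = gmyc.fit_gmyc_single(tree)
            assert fit.lnL >= null.lnL - 1e-6

    def test_boundary_threshold_reproduces_null(self, preset_dataset):
        tree = preset_dataset.true_tree
        null = gmyc.fit_null(tree)
        s = gmyc.branching_schedule(tree, 0.0)
        lnL, _ = gmyc._fit_schedule(s)
        assert lnL == pytest.approx(null.lnL, rel=1e-9)

    def test_recovers_species_count_on_separated_trees(self):
        """Most strongly separated replicates should delimit exactly the
        simulated number of species."""
        hits = 0
        for s in range(10):
            tree, _ = synthdata.simulate_tree(
                synthdata.paper_like_config(seed=300 + s)
            )
            hits += gmyc.fit_gmyc_single(tree).n_entities == 9
        assert hits >= 7

    def test_small_tree_rejected(self):
        tree = UltrametricTree(
            Node(1.0, (Node(0, label="a"), Node(0, label="b")))
        )
        with pytest.raises(ValueError):
            gmyc.fit_gmyc_single(tree)


class TestLRT:
    def test_published_table_arithmetic(self):
        res = gmyc.lrt_from_likelihoods(31.9843, 38.171)
        assert res.statistic == pytest.approx(12.3734, abs=5e-5)
        assert res.p_value < 0.01

    def test_identical_fits_give_zero(self):
        null = gmyc.NullFit(1.0, 1.0, 10.0, 5)
        res = gmyc.lrt(null, 10.0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_negative_statistic_rejected(self):
        null = gmyc.NullFit(1.0, 1.0, 10.0, 5)
        with pytest.raises(ValueError):
            gmyc.lrt(null, 9.0)

    def test_statistic_is_twice_delta(self, rng):
        for _ in range(20):
            a, b = sorted(rng.random(2) * 50)
            res = gmyc.lrt_from_likelihoods(a, b)
            assert res.statistic == pytest.approx(2 * (b - a))
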