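"""Module-network learning: trees, likelihoods, the refit/reassign loop."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from seqmine.errors import NoTFError, ValidationError
from seqmine.gnet import (
    GnetConfig,
    RegulatoryModule,
    RegulatoryTree,
    TreeNode,
    export_network,
    fit,
    gene_log_likelihood,
    kmeans_init,
    learn_tree,
    module_correlation,
    reassign,
    require_tfs,
)
from seqmine.simulate import FixtureSpec, gen_regulatory


def _tf_frame(rows: dict, conds=None):
    df = pd.DataFrame(rows).T
    if conds is not None:
        df.columns = conds
    return df


class TestRequireTfs:
    def test_intersection(self):
        assert require_tfs({"a", "t1"}, ["t1", "t2"]) == {"t1"}

    def test_empty_intersection_raises(self):
        with pytest.raises(NoTFError):
            require_tfs({"a"}, ["t1"])

    def test_all_de_are_tfs(self):
        assert require_tfs({"a", "b"}, ["a", "b"]) == {"a", "b"}


class TestKmeansInit:
    def test_single_cluster(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)))
        assert set(kmeans_init(expr, 1, seed=0)) == {0}

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, size=(10, 6)) + np.array([5, 5, -5, -5, 5, -5])
        b = rng.normal(0, 0.1, size=(10, 6)) + np.array([-5, 5, 5, -5, -5, 5])
        expr = pd.DataFrame(np.vstack([a, b]))
        labels = kmeans_init(expr, 2, seed=0)
        assert adjusted_rand_score([0] * 10 + [1] * 10, labels) == 1.0

    def test_seed_determinism(self):
        expr = pd.DataFrame(np.random.default_rng(2).normal(size=(30, 8)))
        assert (kmeans_init(expr, 3, 7) == kmeans_init(expr, 3, 7)).all()


class TestLearnTree:
    def test_no_tfs_gives_single_leaf_at_grand_mean(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        tree = learn_tree(x, pd.DataFrame(columns=[0, 1]), GnetConfig())
        assert tree.root.is_leaf
        assert tree.root.mean == pytest.approx(2.5)
        assert tree.used_tfs == []

    def test_perfectly_bisecting_tf_is_chosen(self):
        conds = list(range(8))
        x = np.vstack([[0.0] * 4 + [5.0] * 4] * 3)  # 3 member genes
        tf = _tf_frame({"tf1": [0, 0, 0, 0, 1, 1, 1, 1],
                        "noise": [0, 1, 0, 1, 0, 1, 0, 1]}, conds)
        tree = learn_tree(x, tf, GnetConfig(max_depth=2))
        assert tree.root.tf == "tf1"
        assert tree.root.left.mean == pytest.approx(0.0)
        assert tree.root.right.mean == pytest.approx(5.0)

    def test_constant_expression_yields_floored_leaf(self):
        x = np.full((2, 6), 3.0)
        tf = _tf_frame({"tf1": np.arange(6.0)}, list(range(6)))
        cfg = GnetConfig()
        tree = learn_tree(x, tf, cfg)
        assert tree.root.is_leaf
        assert tree.root.variance == cfg.variance_floor

    def test_depth_cap_respected(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(4, 16))
        tf = _tf_frame({f"tf{i}": rng.normal(size=16) for i in range(3)},
                       list(range(16)))
        tree = learn_tree(x, tf, GnetConfig(max_depth=2))
        assert tree.depth() <= 2


class TestGeneLogLikelihood:
    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(4)
        conds = list(range(6))
        tf = _tf_frame({"t": rng.normal(size=6)}, conds)
        thr = float(tf.loc["t"].median())
        tree = RegulatoryTree(
            TreeNode(tf="t", threshold=thr,
                     left=TreeNode(mean=-1.0, variance=0.5),
                     right=TreeNode(mean=2.0, variance=1.5)),
            used_tfs=["t"],
        )
        profile = rng.normal(size=6)
        expected = 0.0
        for c in conds:
            leaf = tree.root.left if tf.loc["t", c] < thr else tree.root.right
            expected += (
                -0.5 * math.log(2 * math.pi * leaf.variance)
                - (profile[c] - leaf.mean) ** 2 / (2 * leaf.variance)
            )
        assert gene_log_likelihood(profile, tree, tf) == pytest.approx(expected)

    def test_profile_at_leaf_means_is_maximal(self):
        tf = _tf_frame({"t": [0.0, 1.0]}, [0, 1])
        tree = RegulatoryTree(
            TreeNode(tf="t", threshold=0.5,
                     left=TreeNode(mean=-2.0, variance=1.0),
                     right=TreeNode(mean=3.0, variance=1.0)),
            used_tfs=["t"],
        )
        best = gene_log_likelihood(np.array([-2.0, 3.0]), tree, tf)
        rng = np.random.default_rng(5)
        for _ in range(20):
            other = np.array([-2.0, 3.0]) + rng.normal(size=2)
            assert gene_log_likelihood(other, tree, tf) <= best + 1e-12

    def test_shape_mismatch_raises(self):
        tf = _tf_frame({"t": [0.0, 1.0]}, [0, 1])
        tree = RegulatoryTree(TreeNode(mean=0.0, variance=1.0), used_tfs=[])
        with pytest.raises(ValidationError):
            gene_log_likelihood(np.zeros(3), tree, tf)


class TestReassign:
    def _two_trees(self, tf):
        low = RegulatoryTree(TreeNode(mean=0.0, variance=0.5), used_tfs=[])
        high = RegulatoryTree(TreeNode(mean=5.0, variance=0.5), used_tfs=[])
        return [low, high]

    def test_gene_goes_to_generating_module(self):
        tf = _tf_frame({"t": np.zeros(4)}, list(range(4)))
        trees = self._two_trees(tf)
        expr = np.vstack([np.full(4, 0.1), np.full(4, 4.9), np.full(4, 5.2)])
        labels, active = reassign(expr, trees, tf, min_module_size=1)
        assert list(labels) == [0, 1, 1]

    def test_identical_trees_tie_break_to_lowest_id(self):
        tf = _tf_frame({"t": np.zeros(3)}, list(range(3)))
        t = RegulatoryTree(TreeNode(mean=0.0, variance=1.0), used_tfs=[])
        labels, _ = reassign(np.zeros((4, 3)), [t, t], tf, min_module_size=1)
        assert set(labels) == {0}

    def test_single_tree_takes_all(self):
        tf = _tf_frame({"t": np.zeros(3)}, list(range(3)))
        t = RegulatoryTree(TreeNode(mean=0.0, variance=1.0), used_tfs=[])
        labels, active = reassign(np.zeros((5, 3)), [t], tf)
        assert set(labels) == {0} and active == [0]

    def test_undersized_module_dissolved(self):
        tf = _tf_frame({"t": np.zeros(4)}, list(range(4)))
        trees = self._two_trees(tf)
        # only one gene prefers the high module
        expr = np.vstack([np.zeros(4)] * 5 + [np.full(4, 5.0)])
        labels, active = reassign(expr, trees, tf, min_module_size=2)
        assert active == [0] and set(labels) == {0}


class TestFit:
    def test_planted_modules_recovered_at_low_noise(self):
        spec = FixtureSpec(seed=0, n_genes=40, n_modules=2, replicates=6,
                           noise_sd=0.1, leaf_separation=3.0)
        expr, tfs, truth, _ = gen_regulatory(spec)
        res = fit(expr.drop(index=tfs), expr.loc[tfs],
                  GnetConfig(n_clusters=2, seed=0))
        ari = adjusted_rand_score(truth[res.assignment.index], res.assignment)
        assert ari == 1.0

    def test_max_iter_zero_returns_kmeans_partition(self):
        spec = FixtureSpec(seed=1, n_genes=20, n_modules=2, replicates=6)
        expr, tfs, _, _ = gen_regulatory(spec)
        members = expr.drop(index=tfs)
        res = fit(members, expr.loc[tfs], GnetConfig(n_clusters=2, seed=3, max_iter=0))
        km = kmeans_init(members, 2, seed=3)
        assert adjusted_rand_score(km, res.assignment) == 1.0
        assert len(res.trace) == 1

    def test_trace_is_monotone_nondecreasing(self):
        for seed in range(5):
            spec = FixtureSpec(seed=seed, n_genes=30, n_modules=2,
                               replicates=6, noise_sd=1.0)
            expr, tfs, _, _ = gen_regulatory(spec)
            res = fit(expr.drop(index=tfs), expr.loc[tfs],
                      GnetConfig(n_clusters=3, seed=seed))
            diffs = np.diff(res.trace)
            assert (diffs >= -1e-8).all(), f"seed {seed}: {res.trace}"

    def test_fit_is_deterministic(self):
        spec = FixtureSpec(seed=2, n_genes=24, n_modules=2, replicates=6)
        expr, tfs, _, _ = gen_regulatory(spec)
        cfg = GnetConfig(n_clusters=2, seed=5)
        r1 = fit(expr.drop(index=tfs), expr.loc[tfs], cfg)
        r2 = fit(expr.drop(index=tfs), expr.loc[tfs], cfg)
        assert (r1.assignment == r2.assignment).all()
        assert r1.trace == r2.trace

    def test_tree_routing_partitions_conditions(self):
        spec = FixtureSpec(seed=3, n_genes=30, n_modules=3, replicates=6,
                           tf_per_module=2)
        expr, tfs, _, _ = gen_regulatory(spec)
        res = fit(expr.drop(index=tfs), expr.loc[tfs],
                  GnetConfig(n_clusters=3, seed=0))
        for module in res.modules:
            mu, var = module.tree.leaf_params(expr.loc[tfs])
            assert np.isfinite(mu).all() and (var > 0).all()


class TestModuleCorrelation:
    def test_identical_profiles(self):
        x = np.tile(np.arange(5.0), (3, 1))
        score, _ = module_correlation(x)
        assert score == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        base = np.arange(5.0)
        score, _ = module_correlation(np.vstack([base, -base]))
        assert score == pytest.approx(-1.0)

    def test_independent_profiles_near_zero(self):
        rng = np.random.default_rng(6)
        score, _ = module_correlation(rng.normal(size=(10, 50)))
        assert abs(score) < 0.3

    def test_single_member_flagged(self):
        score, flagged = module_correlation(np.ones((1, 4)))
        assert score == 1.0 and flagged

    def test_zero_variance_profile_contributes_zero(self):
        x = np.vstack([np.arange(4.0), np.ones(4)])
        score, flagged = module_correlation(x)
        assert score == 0.0 and flagged


def _module(mid, tfs, genes, score=0.5):
    root = TreeNode(mean=0.0, variance=1.0)
    for t in tfs:  # chain the TFs into a nominal tree
        root = TreeNode(tf=t, threshold=0.0, left=TreeNode(mean=0, variance=1),
                        right=root)
    tree = RegulatoryTree(root=root, used_tfs=list(tfs))
    return RegulatoryModule(mid, list(genes), tree, score, 0.0)


class TestExportNetwork:
    def test_three_tf_twentyone_gene_module_gives_63_edges(self):
        m = _module(0, [f"tf{i}" for i in range(3)], [f"g{i}" for i in range(21)])
        net = export_network([m], top_n=10)
        assert net.n_edges == 63
        assert len(net.tf_nodes) == 3 and len(net.gene_nodes) == 21

    def test_single_leaf_module_contributes_no_edges(self):
        m = _module(0, [], ["g1", "g2"])
        assert export_network([m]).n_edges == 0

    def test_edge_count_matches_brute_force(self):
        rng = np.random.default_rng(7)
        modules = []
        for mid in range(5):
            tfs = [f"tf{mid}_{i}" for i in range(int(rng.integers(0, 4)))]
            genes = [f"g{mid}_{i}" for i in range(int(rng.integers(2, 9)))]
            modules.append(_module(mid, tfs, genes, score=float(rng.random())))
        net = export_network(modules, top_n=5)
        brute = set()
        for m in modules:
            for t in m.tree.used_tfs:
                for g in m.members:
                    if t != g:
                        brute.add((t, g, m.module_id))
        assert net.edges == brute

    def test_self_edges_dropped(self):
        m = _module(0, ["x"], ["x", "y"])
        assert export_network([m]).edges == {("x", "y", 0)}

    def test_top_n_selects_by_correlation(self):
        low = _module(0, ["t"], ["a", "b"], score=0.1)
        high = _module(1, ["t"], ["c", "d"], score=0.9)
        net = export_network([low, high], top_n=1)
        assert {e[2] for e in net.edges} == {1}
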