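"""Brownian-motion ancestral estimation against closed forms and a numeric oracle."""

import numpy as np
import pytest
from scipy.optimize import minimize

from cnepairs.ancestral import (AncestorNotReconstructible, PhyloModel,
                                reconstruct_pair_ancestors,
                                reconstruct_transposon_ancestors)
from cnepairs.io import parse_newick_string


def numeric_ml_root(tree, tip_values, check_with_bfgs=False):
    """Oracle: maximize the joint BM likelihood over ALL internal states.

    With sigma = 1 the negative log-likelihood is sum (x_child - x_parent)^2
    / (2 L) over edges — a quadratic in the internal states, minimized
    exactly by its normal equations (assembled edge by edge, independent of
    the GLS code path).  Optionally cross-checked against scipy BFGS.
    """
    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    idx = {n: i for i, n in enumerate(internal)}
    k = len(internal)
    A = np.zeros((k, k))
    b = np.zeros(k)
    for n in nodes:
        if n.parent_node is None:
            continue
        w = 1.0 / n.edge.length
        p = n.parent_node
        if n in idx and p in idx:
            A[idx[n], idx[n]] += w
            A[idx[p], idx[p]] += w
            A[idx[n], idx[p]] -= w
            A[idx[p], idx[n]] -= w
        elif p in idx:  # n is a tip
            A[idx[p], idx[p]] += w
            b[idx[p]] += w * tip_values[n.taxon.label]
    x = np.linalg.solve(A, b)
    if check_with_bfgs:
        def nll(z):
            s = 0.0
            for n in nodes:
                if n.parent_node is None:
                    continue
                def val(m):
                    return z[idx[m]] if m in idx else tip_values[m.taxon.label]
                s += (val(n) - val(n.parent_node)) ** 2 / (2 * n.edge.length)
            return s
        res = minimize(nll, np.zeros(k), method="BFGS", options={"gtol": 1e-10})
        assert np.allclose(res.x, x, atol=1e-4)
    return x[idx[tree.seed_node]]


def random_tree_newick(rng, n_tips):
    """Random binary topology with branch lengths in [0.2, 2]."""
    labels = [f"T{i}" for i in range(n_tips)]
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        la, lb = rng.uniform(0.2, 2.0, size=2)
        nodes[i] = f"({a}:{la:.4f},{b}:{lb:.4f})"
        del nodes[j]
    return nodes[0] + ";", labels


class TestClosedForms:
    def test_constant_tips_are_invariant(self):
        model = PhyloModel(parse_newick_string("((A:1,B:1):1,C:2);"))
        est, n = model.ml_ancestral_state({"A": 7, "B": 7, "C": 7},
                                          ancestor_of={"A", "B", "C"})
        assert est == pytest.approx(7.0)
        est2, _ = model.ml_ancestral_state({"A": 7, "B": 7, "C": 7},
                                           ancestor_of={"A", "B"})
        assert est2 == pytest.approx(7.0)

    def test_two_tip_star_weighted_mean(self):
        model = PhyloModel(parse_newick_string("(A:1,B:1);"))
        est, _ = model.ml_ancestral_state({"A": 10, "B": 20}, ancestor_of={"A", "B"})
        assert est == pytest.approx(15.0)
        # unequal branch lengths weight by inverse branch length
        model2 = PhyloModel(parse_newick_string("(A:1,B:3);"))
        est2, _ = model2.ml_ancestral_state({"A": 10, "B": 20}, ancestor_of={"A", "B"})
        assert est2 == pytest.approx((10 / 1 + 20 / 3) / (1 / 1 + 1 / 3))

    def test_three_tip_gls_closed_form(self):
        model = PhyloModel(parse_newick_string("((A:1,B:1):1,C:2);"))
        root, _ = model.ml_ancestral_state({"A": 0, "B": 0, "C": 6},
                                           ancestor_of={"A", "B", "C"})
        assert root == pytest.approx(18 / 7, rel=1e-12)
        inner, _ = model.ml_ancestral_state({"A": 0, "B": 0, "C": 6},
                                            ancestor_of={"A", "B"})
        assert inner == pytest.approx(6 / 7, rel=1e-12)


class TestOracleEquivalence:
    def test_matches_numeric_likelihood_maximization(self, rng):
        for rep in range(25):
            n_tips = int(rng.integers(3, 6))
            newick, labels = random_tree_newick(rng, n_tips)
            tree = parse_newick_string(newick)
            tips = {l: float(v) for l, v in
                    zip(labels, rng.uniform(0, 100, size=n_tips))}
            model = PhyloModel(tree)
            est, _ = model.ml_ancestral_state(tips, ancestor_of=set(labels))
            oracle = numeric_ml_root(parse_newick_string(newick), tips,
                                     check_with_bfgs=(rep == 0))
            assert est == pytest.approx(oracle, abs=1e-6)


class TestProperties:
    def test_affine_equivariance(self, rng):
        newick, labels = random_tree_newick(rng, 5)
        model = PhyloModel(parse_newick_string(newick))
        tips = {l: float(v) for l, v in zip(labels, rng.uniform(0, 50, 5))}
        base, _ = model.ml_ancestral_state(tips, ancestor_of=set(labels))
        scaled = {l: 3.0 * v + 11.0 for l, v in tips.items()}
        est, _ = model.ml_ancestral_state(scaled, ancestor_of=set(labels))
        assert est == pytest.approx(3.0 * base + 11.0, rel=1e-9)

    def test_estimate_within_tip_range(self, rng):
        for _ in range(10):
            newick, labels = random_tree_newick(rng, int(rng.integers(2, 6)))
            model = PhyloModel(parse_newick_string(newick))
            tips = {l: float(v) for l, v in
                    zip(labels, rng.uniform(-10, 10, len(labels)))}
            est, _ = model.ml_ancestral_state(tips, ancestor_of=set(labels))
            assert min(tips.values()) - 1e-9 <= est <= max(tips.values()) + 1e-9

    def test_unbiased_on_bm_simulations(self, rng):
        """Across replicates the root estimate centers on the true root state."""
        newick = "((A:1,B:1):1,(C:1.5,D:0.5):0.5);"
        tree = parse_newick_string(newick)
        model = PhyloModel(tree)
        true_root = 40.0
        errs = []
        for _ in range(500):
            vals = {}
            state = {tree.seed_node: true_root}
            for node in tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                state[node] = state[node.parent_node] + rng.normal(
                    0, np.sqrt(2.0 * node.edge.length))
                if node.is_leaf():
                    vals[node.taxon.label] = state[node]
            est, _ = model.ml_ancestral_state(vals, ancestor_of={"A", "B", "C", "D"})
            errs.append(est - true_root)
        se = np.std(errs) / np.sqrt(len(errs))
        assert abs(np.mean(errs)) < 3 * se + 0.01

    def test_polytomy_resolution_preserves_estimate(self):
        poly = PhyloModel(parse_newick_string("(A:1,B:1,C:1);"), seed=1)
        est, _ = poly.ml_ancestral_state({"A": 0, "B": 3, "C": 9},
                                         ancestor_of={"A", "B", "C"})
        # zero-length resolution: equal pendant branches -> plain mean
        assert est == pytest.approx(4.0)

    def test_duplicated_zero_length_tips_error(self):
        model = PhyloModel(parse_newick_string("((A:0,B:0):1,C:2);"))
        with pytest.raises(AncestorNotReconstructible):
            model.ml_ancestral_state({"A": 1, "B": 2, "C": 3},
                                     ancestor_of={"A", "B", "C"})


TREE = "(((human:6,chimp:6):174,platypus:180):140,chicken:320);"
MAMMALS3 = ["human", "chimp", "platypus"]


class TestPairReconstruction:
    def test_platypus_required(self):
        tree = parse_newick_string(TREE)
        res = reconstruct_pair_ancestors(
            {"p1": {"human": 5000, "chimp": 5100}}, tree, MAMMALS3)
        assert np.isnan(res[0].estimate)
        assert "no_platypus" in res[0].flags

    def test_two_tip_pair_equals_gls(self):
        tree = parse_newick_string(TREE)
        res = reconstruct_pair_ancestors(
            {"p1": {"human": 1000, "platypus": 2000}}, tree, MAMMALS3)
        model = PhyloModel(tree)
        exp, _ = model.ml_ancestral_state({"human": 1000, "platypus": 2000},
                                          ancestor_of=set(MAMMALS3))
        assert res[0].estimate == pytest.approx(exp)
        assert res[0].n_tips == 2

    def test_transposon_clamping_and_zero(self):
        tree = parse_newick_string(TREE)
        out = reconstruct_transposon_ancestors(
            {("p1", "SINE"): {"human": 0.0, "chimp": 0.0, "platypus": 0.0},
             ("p1", "LINE"): {"human": 0.0, "chimp": 0.0, "platypus": 500.0}},
            tree, MAMMALS3)
        assert out[("p1", "SINE")].estimate == 0.0
        est = out[("p1", "LINE")].estimate
        assert 0.0 <= est < 500.0
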