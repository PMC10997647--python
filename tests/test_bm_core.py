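"""Brownian-motion machinery against closed forms and independent oracles."""
import json
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bergmann import bm_core, phylo_data as pdm, synthetic_data as sd
from bergmann.bm_core import (ModelSpec, ancestral_states, covariance,
                              design_matrix, gls_fit, independent_contrasts,
                              percent_change_per_unit, pic_slope, r_squared,
                              vif)

from conftest import brute_force_covariance, make_dataset, random_tree


class TestCovariance:
    def test_two_tip_no_shared_path(self, two_tip_tree):
        V = covariance(two_tip_tree, lam=1.0).matrix
        assert np.allclose(V, np.eye(2))

    def test_three_tip_read_off_paths(self, three_tip_tree):
        V = covariance(three_tip_tree, lam=1.0).matrix
        labels = three_tip_tree.tip_labels
        expected = {"A": 0, "B": 1, "C": 2}
        order = [expected[l] for l in labels]
        want = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        assert np.allclose(V, want[np.ix_(order, order)])

    def test_lambda_halves_offdiagonals_only(self, three_tip_tree):
        V1 = covariance(three_tip_tree, lam=1.0).matrix
        Vh = covariance(three_tip_tree, lam=0.5).matrix
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(Vh[off], 0.5 * V1[off])
        assert np.allclose(np.diag(Vh), np.diag(V1))

    def test_lambda_out_of_range_rejected(self, two_tip_tree):
        with pytest.raises(ValueError):
            covariance(two_tip_tree, lam=1.2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999),
           lam=st.floats(0.0, 1.0))
    def test_symmetric_positive_semidefinite(self, seed, lam):
        tree = sd.yule_tree(7, seed=seed, root_height=20.0)
        V = covariance(tree, lam=lam).matrix
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > -1e-9

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999))
    def test_matches_ancestor_chain_oracle(self, seed):
        tree = sd.yule_tree(6, seed=seed, root_height=15.0)
        V = covariance(tree, lam=0.7).matrix
        Vb, labels = brute_force_covariance(tree, lam=0.7)
        assert labels == tree.tip_labels
        assert np.allclose(V, Vb, atol=1e-10)


class TestGls:
    def test_star_tree_reduces_to_ols(self):
        n = 12
        newick = "(" + ",".join(f"s{i}:1" for i in range(n)) + ");"
        tree = pdm.Phylogeny.from_newick(newick)
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        fit = gls_fit(y, X, covariance(tree).matrix)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.coefficients, ols, atol=1e-10)

    def test_noiseless_identity(self):
        tree = random_tree(seed=4, n_tips=9)
        V = covariance(tree).matrix
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(9), rng.normal(size=9)])
        b = np.array([0.5, -1.25])
        fit = gls_fit(X @ b, X, V)
        assert np.allclose(fit.coefficients, b, atol=1e-9)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-18)

    def test_rank_deficient_design_names_columns(self):
        tree = random_tree(seed=6, n_tips=6)
        V = covariance(tree).matrix
        x = np.arange(6.0)
        X = np.column_stack([np.ones(6), x, 2 * x])
        with pytest.raises(ValueError, match="dup"):
            gls_fit(np.ones(6), X, V, names=["intercept", "x", "dup"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_explicit_inverse_oracle(self, seed):
        tree = sd.yule_tree(6, seed=100 + seed, root_height=30.0)
        rng = np.random.default_rng(seed)
        V = covariance(tree).matrix
        X = np.column_stack([np.ones(6), rng.normal(size=6)])
        y = rng.normal(size=6)
        fit = gls_fit(y, X, V)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        s2 = r @ Vi @ r / 6
        logl = -0.5 * (6 * np.log(2 * np.pi * s2)
                       + np.linalg.slogdet(V)[1] + 6)
        assert np.allclose(fit.coefficients, beta, atol=1e-8)
        assert fit.sigma2 == pytest.approx(s2, abs=1e-10)
        assert fit.loglik == pytest.approx(logl, abs=1e-8)


class TestContrasts:
    def test_constant_trait_all_zero(self):
        tree = random_tree(seed=1, n_tips=7)
        c = independent_contrasts(tree, {l: 3.14 for l in tree.tip_labels})
        assert np.allclose(c, 0.0)

    def test_two_tip_formula(self, two_tip_tree):
        c = independent_contrasts(two_tip_tree, {"A": 0.0, "B": 2.0})
        assert abs(abs(c[0]) - 2.0 / np.sqrt(2.0)) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_pic_slope_equals_gls_slope(self, seed):
        tree = sd.yule_tree(10, seed=200 + seed, root_height=40.0)
        rng = np.random.default_rng(seed)
        labels = tree.tip_labels
        x = dict(zip(labels, rng.normal(size=10)))
        y = dict(zip(labels, rng.normal(size=10)))
        V = covariance(tree, lam=1.0).matrix
        X = np.column_stack([np.ones(10), [x[l] for l in labels]])
        fit = gls_fit(np.array([y[l] for l in labels]), X, V)
        assert pic_slope(tree, x, y) == pytest.approx(
            fit.coefficients[1], abs=1e-8)


class TestAncestralStates:
    def test_two_tip_symmetry(self, two_tip_tree):
        states = ancestral_states(two_tip_tree, {"A": 1.0, "B": 3.0})
        assert states[two_tip_tree.root] == pytest.approx(2.0)

    def test_constant_trait_everywhere(self):
        tree = random_tree(seed=2, n_tips=6)
        states = ancestral_states(tree, {l: 7.0 for l in tree.tip_labels})
        assert all(abs(v - 7.0) < 1e-10 for v in states.values())

    def test_root_equals_gls_phylogenetic_mean(self):
        tree = random_tree(seed=8, n_tips=9)
        rng = np.random.default_rng(5)
        x = rng.normal(size=9)
        states = ancestral_states(tree, dict(zip(tree.tip_labels, x)))
        V = covariance(tree).matrix
        Vi = np.linalg.inv(V)
        one = np.ones(9)
        mu = one @ Vi @ x / (one @ Vi @ one)
        assert states[tree.root] == pytest.approx(mu, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_joint_gls_oracle(self, seed):
        tree = sd.yule_tree(5, seed=300 + seed, root_height=25.0)
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        states = ancestral_states(tree, dict(zip(tree.tip_labels, x)))
        oracle = _joint_gls_ancestral(tree, dict(zip(tree.tip_labels, x)))
        for node, want in oracle.items():
            assert states[node] == pytest.approx(want, abs=1e-8)

    def test_root_state_invariant_to_zero_length_root_edge(self):
        tree = random_tree(seed=11, n_tips=6)
        rng = np.random.default_rng(2)
        vals = dict(zip(tree.tip_labels, rng.normal(size=6)))
        base_root = ancestral_states(tree, vals)[tree.root]
        rerooted = tree.copy()
        new_root = pdm.PhyloNode()
        old = rerooted.root
        old.length = 0.0
        new_root.add_child(old)
        rerooted = pdm.Phylogeny(new_root)
        assert ancestral_states(rerooted, vals)[new_root] == pytest.approx(
            base_root, abs=1e-9)


def _joint_gls_ancestral(tree, values):
    """Conditional-expectation oracle over the full tip+node covariance."""
    nodes = list(tree.postorder())
    depths = tree.depths()
    idx = {id(n): i for i, n in enumerate(nodes)}

    def mrca_depth(a, b):
        anc = set()
        node = a
        while node is not None:
            anc.add(id(node))
            node = node.parent
        node = b
        while id(node) not in anc:
            node = node.parent
        return depths[node]

    n = len(nodes)
    C = np.zeros((n, n))
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            C[i, j] = depths[a] if a is b else mrca_depth(a, b)
    tips = [n_ for n_ in nodes if n_.is_tip]
    internals = [n_ for n_ in nodes if not n_.is_tip]
    ti = [idx[id(t)] for t in tips]
    x = np.array([values[t.label] for t in tips])
    Ctt = C[np.ix_(ti, ti)]
    Cti = np.linalg.inv(Ctt)
    one = np.ones(len(tips))
    mu = one @ Cti @ x / (one @ Cti @ one)
    out = {}
    for node in internals:
        ci = C[idx[id(node)], ti]
        out[node] = mu + ci @ Cti @ (x - mu * one)
    return out


def test_pic_and_ancestral_states_match_r_reference(tmp_path):
    """Cross-validation against ape::pic and phytools::fastAnc."""
    tree = sd.yule_tree(8, seed=77, root_height=50.0)
    rng = np.random.default_rng(1)
    vals = dict(zip(tree.tip_labels, rng.normal(size=8)))
    tree.write(tmp_path / "tree.nwk")
    with open(tmp_path / "vals.csv", "w") as fh:
        fh.write("species,value\n")
        for k, v in vals.items():
            fh.write(f"{k},{float(v)!r}\n")
    script = tmp_path / "oracle.R"
    script.write_text(
        "suppressMessages({library(ape); library(phytools)})\n"
        f"setwd('{tmp_path}')\n"
        "t <- read.tree('tree.nwk'); d <- read.csv('vals.csv')\n"
        "v <- setNames(d$value, d$species)\n"
        "cat(jsonlite::toJSON(list(pic=as.numeric(pic(v, t)),"
        " anc=as.numeric(fastAnc(t, v))), digits=12))\n")
    proc = subprocess.run(["Rscript", str(script)], capture_output=True,
                          text=True)
    assert proc.returncode == 0, proc.stderr
    ref = json.loads(proc.stdout)
    mine_pic = np.sort(np.abs(independent_contrasts(tree, vals)))
    assert np.allclose(mine_pic, np.sort(np.abs(ref["pic"])), atol=1e-6)
    states = ancestral_states(tree, vals)
    mine_anc = np.sort([v for n, v in states.items() if not n.is_tip])
    assert np.allclose(mine_anc, np.sort(ref["anc"]), atol=1e-6)


class TestRSquared:
    def test_noiseless_fit_is_one(self):
        tree = random_tree(seed=3, n_tips=8)
        V = covariance(tree).matrix
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(8), rng.normal(size=8)])
        b = np.array([1.0, 0.3])
        assert r_squared(X @ b, X, V, b) == pytest.approx(1.0)

    def test_zero_slope_at_ml_intercept_is_zero(self):
        tree = random_tree(seed=7, n_tips=10)
        V = covariance(tree).matrix
        rng = np.random.default_rng(2)
        y = rng.normal(size=10)
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        mu_fit = gls_fit(y, np.ones((10, 1)), V)
        coef = np.array([mu_fit.coefficients[0], 0.0])
        assert r_squared(y, X, V, coef) == pytest.approx(0.0, abs=1e-10)

    def test_bad_coefficients_go_negative(self):
        tree = random_tree(seed=9, n_tips=8)
        V = covariance(tree).matrix
        rng = np.random.default_rng(3)
        y = rng.normal(size=8)
        X = np.column_stack([np.ones(8), rng.normal(size=8)])
        assert r_squared(y, X, V, np.array([50.0, -40.0])) < 0

    def test_constant_whitened_response_flagged(self, two_tip_tree):
        V = covariance(two_tip_tree).matrix
        X = np.ones((2, 1))
        assert np.isnan(r_squared(np.array([1.0, 1.0]), X, V,
                                  np.array([1.0])))


class TestVif:
    def test_orthogonal_columns_are_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        a -= a.mean()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # centred and orthogonal to a
        X = np.column_stack([np.ones(40), a, b])
        out = vif(X, np.eye(40), names=["intercept", "a", "b"])
        assert out["a"] == pytest.approx(1.0, abs=1e-10)
        assert out["b"] == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_column_infinite(self):
        x = np.arange(10.0)
        X = np.column_stack([np.ones(10), x, x])
        out = vif(X, np.eye(10))
        assert np.isinf(out["x1"]) and np.isinf(out["x2"])

    def test_known_bivariate_correlation(self):
        rng = np.random.default_rng(12)
        n = 4000
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        X = np.column_stack([np.ones(n), a, b])
        out = vif(X, np.eye(n), names=["intercept", "a", "b"])
        assert out["a"] == pytest.approx(1.0 / (1.0 - 0.81), rel=0.1)

    def test_invariant_to_column_rescaling(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(30), rng.normal(size=30),
                             rng.normal(size=30)])
        base = vif(X, np.eye(30))
        X2 = X.copy()
        X2[:, 2] *= 37.5
        scaled = vif(X2, np.eye(30))
        assert base["x1"] == pytest.approx(scaled["x1"], rel=1e-9)
        assert base["x2"] == pytest.approx(scaled["x2"], rel=1e-9)


class TestPercentChange:
    def test_zero_slope_is_zero(self):
        assert percent_change_per_unit(0.0) == 0.0

    def test_inverse_changes_compose_to_unity(self):
        for beta in (0.0036, 0.0097, -0.02, 0.5):
            p = percent_change_per_unit(beta)
            q = percent_change_per_unit(-beta)
            assert (1 + p / 100) * (1 + q / 100) == pytest.approx(1.0,
                                                                  abs=1e-12)


class TestDesignMatrix:
    def test_absolute_latitude_taken_at_design_time(self, three_tip_tree):
        data = make_dataset(three_tip_tree, {"A": 1, "B": 2, "C": 3},
                            latitudes={"A": -40, "B": 10, "C": -5})
        # stored signed
        lats = [o[0].palaeolatitude for o in data.occurrences]
        assert min(lats) < 0
        X, names = design_matrix(data, ModelSpec(predictor="abs_latitude"))
        assert np.all(X[:, names.index("abs_latitude")] >= 0)

    def test_dummy_baselines(self, three_tip_tree):
        data = make_dataset(three_tip_tree, {"A": 1, "B": 2, "C": 3},
                            latitudes={"A": 40, "B": -10, "C": 5},
                            period=["Triassic", "Jurassic", "Cretaceous"],
                            clade=["Ornithischia", "Theropoda",
                                   "Sauropodomorpha"])
        X, names = design_matrix(
            data, ModelSpec(predictor="abs_latitude", hemisphere=True,
                            period=True, clade=True))
        # baselines northern / Triassic / Ornithischia are all-zero coded
        labels = three_tip_tree.tip_labels
        a = labels.index("A")
        assert "hemisphere:S" in names and "period:Jurassic" in names
        assert "clade:Theropoda" in names
        assert X[a, names.index("hemisphere:S")] == 0.0  # A is northern
        assert X[a, names.index("period:Jurassic")] == 0.0  # A is Triassic

    def test_missing_required_column_errors(self, three_tip_tree):
        data = make_dataset(three_tip_tree, {"A": 1, "B": 2, "C": 3})
        with pytest.raises(ValueError, match="period"):
            design_matrix(data, ModelSpec(predictor="abs_latitude",
                                          period=True))
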