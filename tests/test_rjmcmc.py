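"""Sampler behaviour: summaries, reproducibility, prior recovery, and the
conjugate-normal reduction."""
import numpy as np
import pytest
from scipy import stats

from bergmann import bm_core, phylo_data as pdm, rjmcmc, synthetic_data as sd
from bergmann.bm_core import ModelSpec, TreeArrays
from bergmann.rjmcmc import (ChainConfig, Placement, PosteriorSample,
                             effective_scalars, p_mcmc, run_chain, summarise)

from conftest import make_dataset


class TestPMcmc:
    def test_all_positive_is_zero(self):
        assert p_mcmc(np.array([0.1, 0.2, 3.0])) == 0.0

    def test_symmetric_near_half(self):
        rng = np.random.default_rng(0)
        assert p_mcmc(rng.normal(0, 1, 20_001)) == pytest.approx(0.5,
                                                                 abs=0.02)

    def test_direct_count(self):
        assert p_mcmc(np.array([-1.0, 2.0, 3.0, 4.0])) == 0.25

    def test_zero_median_is_half(self):
        assert p_mcmc(np.array([-1.0, 0.0, 1.0])) == 0.5

    def test_zero_samples_count_as_crossing(self):
        assert p_mcmc(np.array([0.0, 2.0, 3.0, 4.0])) == 0.25


def _fake_samples(values):
    return [PosteriorSample(iteration=i, coefficients=np.array([v]),
                            sigma2=1.0, lam=1.0, placements=(),
                            assignment=(), loglik=0.0, r2=0.5)
            for i, v in enumerate(values)]


class TestSummarise:
    def _result(self, values):
        tree = pdm.Phylogeny.from_newick("(A:1,B:1);")
        return rjmcmc.ChainResult(
            samples=_fake_samples(values), acceptance={},
            coef_names=["intercept"], arrays=TreeArrays(tree),
            config=ChainConfig(), final_state={})

    def test_constant_stream_point_interval(self):
        s = summarise(self._result([2.5] * 10))
        assert s.ci95["intercept"] == (2.5, 2.5)

    def test_quantile_arithmetic_1_to_100(self):
        s = summarise(self._result(list(range(1, 101))))
        assert s.medians["intercept"] == pytest.approx(50.5)
        assert s.ci95["intercept"][0] == pytest.approx(3.475)
        assert s.ci95["intercept"][1] == pytest.approx(97.525)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            summarise(self._result([1.0]))


@pytest.fixture(scope="module")
def small_scenario():
    spec = sd.SimulationSpec(model="regression", n_tips=16, seed=21,
                             beta=0.01, sigma2=1e-3, root_height=80.0,
                             extra_occ_mean=1.0)
    return sd.simulate(spec)


class TestChainContracts:
    def test_same_seed_bit_identical(self, small_scenario):
        tree, ds, _ = small_scenario
        cfg = ChainConfig.test_preset(iterations=3000, burn_in=500,
                                      thinning=5)
        spec = ModelSpec(predictor="abs_latitude", variable_rates=True)
        a = run_chain(ds, tree, spec, cfg, seed=99)
        b = run_chain(ds, tree, spec, cfg, seed=99)
        assert len(a.samples) == len(b.samples)
        for sa, sb in zip(a.samples, b.samples):
            assert np.array_equal(sa.coefficients, sb.coefficients)
            assert sa.sigma2 == sb.sigma2 and sa.lam == sb.lam
            assert sa.placements == sb.placements

    def test_thinning_subsets_the_same_trajectory(self, small_scenario):
        tree, ds, _ = small_scenario
        spec = ModelSpec(predictor="abs_latitude", variable_rates=True)
        fine = run_chain(ds, tree, spec,
                         ChainConfig.test_preset(iterations=3000,
                                                 burn_in=500, thinning=5),
                         seed=7)
        coarse = run_chain(ds, tree, spec,
                           ChainConfig.test_preset(iterations=3000,
                                                   burn_in=500, thinning=10),
                           seed=7)
        fine_by_iter = {s.iteration: s for s in fine.samples}
        assert coarse.samples  # non-empty
        for s in coarse.samples:
            assert np.array_equal(
                s.coefficients, fine_by_iter[s.iteration].coefficients)

    def test_effective_scalars_respect_bounds(self, small_scenario):
        tree, ds, _ = small_scenario
        spec = ModelSpec(predictor="abs_latitude", variable_rates=True)
        res = run_chain(ds, tree, spec,
                        ChainConfig.test_preset(iterations=20_000,
                                                burn_in=1000, thinning=20),
                        seed=13, power=0.0)
        lo, hi = rjmcmc.SCALAR_BOUNDS
        for s in res.samples:
            eff = effective_scalars(s.placements, res.arrays)
            branch = eff[res.arrays.branch_indices]
            assert branch.min() >= lo and branch.max() <= hi

    def test_occurrence_move_reassigns_multi_locality_species(
            self, small_scenario):
        tree, ds, _ = small_scenario
        assert ds.multi_occurrence_species  # generator produced some
        spec = ModelSpec(predictor="abs_latitude")
        res = run_chain(ds, tree, spec,
                        ChainConfig.test_preset(iterations=8000,
                                                burn_in=500, thinning=5),
                        seed=3, power=0.0)
        i = res.arrays.tip_labels.index(
            ds.species[ds.multi_occurrence_species[0]])
        seen = {s.assignment[i] for s in res.samples}
        assert len(seen) > 1


def test_constant_likelihood_recovers_constrained_placement_prior():
    """With the likelihood switched off (power 0) the chain must sample the
    placement prior: truncated Poisson(1) placements with log-uniform
    scalars, conditioned on every branch product staying inside the scalar
    bounds.  The reference distribution comes from an independent rejection
    sampler."""
    tree, ds, _ = sd.simulate(sd.SimulationSpec(model="regression", n_tips=8,
                                                seed=3))
    arrays = TreeArrays(tree)
    rng = np.random.default_rng(123)
    kmax = 2 * 8 - 2
    pk = stats.poisson.pmf(np.arange(kmax + 1), 1.0)
    pk /= pk.sum()
    branch_t = arrays.branch_indices
    clade_t = np.array([i for i in arrays.branch_indices
                        if not arrays.nodes[i].is_tip])
    lo, hi = np.log(rjmcmc.SCALAR_BOUNDS[0]), np.log(rjmcmc.SCALAR_BOUNDS[1])

    def draw_prior_k():
        while True:
            k = rng.choice(np.arange(kmax + 1), p=pk)
            placements = []
            for _ in range(k):
                if rng.random() < 0.5:
                    target = branch_t[rng.integers(len(branch_t))]
                    kind = "branch"
                else:
                    target = clade_t[rng.integers(len(clade_t))]
                    kind = "clade"
                placements.append(Placement(kind, int(target),
                                            float(np.exp(rng.uniform(lo,
                                                                     hi)))))
            eff = effective_scalars(placements, arrays)[arrays.branch_indices]
            if np.all((eff >= rjmcmc.SCALAR_BOUNDS[0])
                      & (eff <= rjmcmc.SCALAR_BOUNDS[1])):
                return k

    oracle = np.array([draw_prior_k() for _ in range(40_000)])
    probs = np.zeros(6)
    for k in oracle:
        probs[min(k, 5)] += 1
    probs /= oracle.size

    cfg = ChainConfig.test_preset(iterations=120_000, burn_in=10_000,
                                  thinning=50)
    res = run_chain(ds, tree,
                    ModelSpec(predictor="abs_latitude", variable_rates=True),
                    cfg, seed=9, power=0.0)
    ks = np.array([len(s.placements) for s in res.samples])
    obs = np.zeros(6)
    for k in ks:
        obs[min(k, 5)] += 1
    exp = probs * ks.size
    while exp[-1] < 5:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        exp, obs = exp[:-1], obs[:-1]
    p = stats.chisquare(obs, exp * obs.sum() / exp.sum()).pvalue
    assert p > 0.01


def test_conjugate_normal_reduction_ks():
    """sigma^2 fixed, slope fixed, V = I: the intercept posterior must match
    the analytic conjugate-normal posterior (KS test)."""
    n = 40
    rng = np.random.default_rng(5)
    y = rng.normal(0.7, 1.0, n)
    newick = "(" + ",".join(f"s{i}:1" for i in range(n)) + ");"
    tree = pdm.Phylogeny.from_newick(newick)
    ds = make_dataset(tree, dict(zip(tree.tip_labels, y)),
                      latitudes={l: float(i % 30)
                                 for i, l in enumerate(tree.tip_labels)})
    s0 = 2.0
    cfg = ChainConfig.test_preset(iterations=80_000, burn_in=10_000,
                                  thinning=20, fix_sigma2=1.0,
                                  fix_lambda=1.0, coef_prior_sd=s0,
                                  fixed_coef={1: 0.0})
    res = run_chain(ds, tree, ModelSpec(predictor="abs_latitude"), cfg,
                    seed=11)
    alphas = res.coef_samples("intercept")
    post_var = 1.0 / (n + 1.0 / s0 ** 2)
    post_mean = post_var * y.sum()
    ks = stats.kstest(alphas, "norm", args=(post_mean, np.sqrt(post_var)))
    assert ks.pvalue > 0.01
    # fixed coordinates never move
    assert np.all(res.coef_samples("abs_latitude") == 0.0)


def test_initial_state_pathology_reported():
    tree = pdm.Phylogeny.from_newick("(A:1,B:1);")
    ds = make_dataset(tree, {"A": 1.0, "B": 2.0})
    bad = ChainConfig.test_preset(iterations=10, burn_in=1, thinning=1,
                                  fix_sigma2=0.0)
    with pytest.raises((ValueError, ZeroDivisionError)):
        run_chain(ds, tree, ModelSpec(predictor=None), bad, seed=1)
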