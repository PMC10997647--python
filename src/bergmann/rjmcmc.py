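"""Reversible-jump MCMC for the variable-rates phylogenetic regression.

The posterior is over (coefficients, sigma^2, lambda, a set of rate-scalar
placements on branches or clades, and the occurrence assignment of
multi-locality species).  Moves:

* coefficients — Gaussian random walk, one coefficient at a time, with an
  adaptive step targeting ~0.3 acceptance (frozen at the end of burn-in);
* sigma^2 — random walk on the log scale;
* lambda — reflected random walk on [0, 1];
* rate scalars — reversible-jump birth/death of branch- or clade-level
  placements plus a log-normal "modify" of an existing scalar;
* occurrence — one multi-occurrence species is re-assigned a uniformly
  random linked record (latitude, MAT, CMMT swapped jointly).

Priors (the upstream software leaves these unpublished; fixed here once):
coefficients N(0, 10^2); log sigma^2 uniform on [log 1e-8, log 1e8]; lambda
uniform on [0, 1]; placement count truncated Poisson(1) on [0, 2n-2]; scalar
log-uniform on [1e-3, 1e3].  The likelihood may be raised to a power
``power`` (priors untempered), which both drives stepping-stone estimation
and, at power 0, turns the chain into an exact prior sampler.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg

from .bm_core import ModelSpec, TreeArrays, design_matrix, gls_fit
from .phylo_data import Phylogeny, TraitDataset

__all__ = [
    "Placement",
    "ChainConfig",
    "PosteriorSample",
    "ChainResult",
    "PosteriorSummary",
    "run_chain",
    "p_mcmc",
    "summarise",
    "effective_scalars",
    "write_trace",
]

SCALAR_BOUNDS = (1e-3, 1e3)


@dataclass(frozen=True)
class Placement:
    """One rate-scalar placement: a branch or a clade stem, and a multiplier."""

    kind: str   # "branch" or "clade"
    node: int   # node index in the chain's TreeArrays
    r: float


@dataclass
class ChainConfig:
    """Chain lengths, move mixture and priors.

    The presets mirror the published run lengths (Mesozoic
    12.5M/2.5M/thin 1000, extant 150M/100M/thin 1000); tests use
    :meth:`test_preset` scaled down.
    """

    iterations: int = 12_500_000
    burn_in: int = 2_500_000
    thinning: int = 1000
    move_weights: dict = field(default_factory=lambda: {
        "coef": 0.30, "sigma2": 0.15, "lambda": 0.15,
        "rj": 0.30, "occurrence": 0.10})
    coef_prior_sd: float = 10.0
    placement_rate: float = 1.0          # Poisson mean for placement count
    modify_sd: float = 0.3
    fix_sigma2: float | None = None
    fix_lambda: float | None = None
    fixed_coef: dict = field(default_factory=dict)   # index -> value
    adapt: bool = True
    target_acceptance: float = 0.3

    @classmethod
    def mesozoic(cls, **kw) -> "ChainConfig":
        return cls(**kw)

    @classmethod
    def extant(cls, **kw) -> "ChainConfig":
        return cls(iterations=150_000_000, burn_in=100_000_000,
                   thinning=1000, **kw)

    @classmethod
    def test_preset(cls, iterations=20_000, burn_in=5_000, thinning=10,
                    **kw) -> "ChainConfig":
        return cls(iterations=iterations, burn_in=burn_in,
                   thinning=thinning, **kw)


@dataclass(frozen=True)
class PosteriorSample:
    iteration: int
    coefficients: np.ndarray
    sigma2: float
    lam: float
    placements: tuple[Placement, ...]
    assignment: tuple[int, ...]
    loglik: float
    r2: float


@dataclass
class ChainResult:
    samples: list[PosteriorSample]
    acceptance: dict[str, float]
    coef_names: list[str]
    arrays: TreeArrays
    config: ChainConfig
    final_state: dict

    def coef_samples(self, name: str) -> np.ndarray:
        j = self.coef_names.index(name)
        return np.array([s.coefficients[j] for s in self.samples])


def effective_scalars(placements, arrays: TreeArrays) -> np.ndarray:
    """Per-node effective branch multiplier: product of covering placements."""
    eff = np.ones(arrays.n_nodes)
    for p in placements:
        if p.kind == "branch":
            eff[p.node] *= p.r
        else:
            eff[arrays.descendant_branches(p.node)] *= p.r
    return eff


class _Engine:
    """Cached likelihood for one (dataset, tree, model) triple.

    Keeps the Cholesky factor of V and the whitened response/design so that
    coefficient and sigma^2 moves cost O(n p) and only lambda / scalar moves
    pay for a refactorisation.
    """

    def __init__(self, dataset: TraitDataset, tree: Phylogeny,
                 spec: ModelSpec, config: ChainConfig):
        self.arrays = TreeArrays(tree)
        order = self.arrays.tip_labels
        if set(order) != set(dataset.species):
            raise ValueError("dataset and tree must be aligned first")
        self.dataset = dataset.subset(order)
        self.spec = spec
        self.config = config
        self.y = np.asarray(self.dataset.response, dtype=float)
        self.n = len(self.y)
        self.multi = self.dataset.multi_occurrence_species
        self.ones = np.ones(self.n)
        # filled by refresh calls
        self.X = None
        self.names: list[str] = []
        self.S = None
        self.L = None
        self.logdet = 0.0
        self.yw = None
        self.Xw = None
        self.onew = None

    def set_scalars(self, eff: np.ndarray) -> None:
        self.S = self.arrays.shared_path_matrix(eff)

    def set_lambda(self, lam: float) -> None:
        V = lam * self.S
        np.fill_diagonal(V, np.diag(self.S))
        self.L = linalg.cholesky(V, lower=True)
        self.logdet = 2.0 * float(np.sum(np.log(np.diag(self.L))))
        self._whiten()

    def set_design(self, assignment: np.ndarray) -> None:
        self.X, self.names = design_matrix(self.dataset, self.spec, assignment)
        if self.L is not None:
            self.Xw = linalg.solve_triangular(self.L, self.X, lower=True)

    def _whiten(self) -> None:
        self.yw = linalg.solve_triangular(self.L, self.y, lower=True)
        self.onew = linalg.solve_triangular(self.L, self.ones, lower=True)
        if self.X is not None:
            self.Xw = linalg.solve_triangular(self.L, self.X, lower=True)

    def loglik(self, coef: np.ndarray, sigma2: float) -> float:
        resid = self.yw - self.Xw @ coef
        sse = float(resid @ resid)
        return -0.5 * (self.n * math.log(2 * math.pi * sigma2)
                       + self.logdet + sse / sigma2)

    def r2(self, coef: np.ndarray) -> float:
        mu = float(self.onew @ self.yw / (self.onew @ self.onew))
        sst = float(np.sum((self.yw - mu * self.onew) ** 2))
        if sst <= 0:
            return float("nan")
        sse = float(np.sum((self.yw - self.Xw @ coef) ** 2))
        return 1.0 - sse / sst


LOG_S2_BOUNDS = (math.log(1e-8), math.log(1e8))


def run_chain(dataset: TraitDataset, tree: Phylogeny, model_spec: ModelSpec,
              chain_config: ChainConfig, seed: int, power: float = 1.0,
              init_state: dict | None = None) -> ChainResult:
    """Sample the variable-rates PGLS posterior.

    ``power`` tempers the likelihood only (``power=0`` samples the prior).
    The same seed and configuration reproduce the sample stream exactly.
    """
    rng = np.random.default_rng(seed)
    cfg = chain_config
    eng = _Engine(dataset, tree, model_spec, cfg)
    arrays = eng.arrays
    kmax = 2 * arrays.n_tips - 2

    branch_targets = arrays.branch_indices
    clade_targets = np.array(
        [i for i in arrays.branch_indices if not arrays.nodes[i].is_tip],
        dtype=np.int64)
    kinds = ["branch"] + (["clade"] if len(clade_targets) else [])
    kind_prior_p = 1.0 / len(kinds)
    log_lo, log_hi = math.log(SCALAR_BOUNDS[0]), math.log(SCALAR_BOUNDS[1])

    # ---- initial state ----------------------------------------------------
    if init_state is None:
        assignment = np.zeros(len(eng.dataset), dtype=int)
        placements: list[Placement] = []
        lam = cfg.fix_lambda if cfg.fix_lambda is not None else 0.5
        eng.set_design(assignment)
        eng.set_scalars(np.ones(arrays.n_nodes))
        eng.set_lambda(lam)
        fit = gls_fit(eng.y, eng.X, lam * eng.S
                      + np.diag(np.diag(eng.S)) * (1 - lam), eng.names)
        coef = fit.coefficients.copy()
        for j, v in cfg.fixed_coef.items():
            coef[j] = v
        sigma2 = cfg.fix_sigma2 if cfg.fix_sigma2 is not None else \
            float(np.clip(fit.sigma2, 1e-6, 1e6))
    else:
        assignment = np.array(init_state["assignment"], dtype=int)
        placements = list(init_state["placements"])
        lam = init_state["lam"]
        coef = np.array(init_state["coef"], dtype=float)
        sigma2 = init_state["sigma2"]
        eng.set_design(assignment)
        eng.set_scalars(effective_scalars(placements, arrays))
        eng.set_lambda(lam)

    eff = effective_scalars(placements, arrays)
    ll = eng.loglik(coef, sigma2)
    if not np.isfinite(ll):
        raise ValueError("non-finite likelihood at the initial state; "
                         "check the data for pathologies")

    p = len(coef)
    free_coef = [j for j in range(p) if j not in cfg.fixed_coef]

    # move mixture; impossible moves get weight zero
    weights = dict(cfg.move_weights)
    if cfg.fix_sigma2 is not None:
        weights["sigma2"] = 0.0
    if cfg.fix_lambda is not None:
        weights["lambda"] = 0.0
    if not eng.multi:
        weights["occurrence"] = 0.0
    if not model_spec.variable_rates:
        weights["rj"] = 0.0
    if not free_coef:
        weights["coef"] = 0.0
    move_names = [m for m in ("coef", "sigma2", "lambda", "rj", "occurrence")
                  if weights.get(m, 0) > 0]
    wvec = np.array([weights[m] for m in move_names], dtype=float)
    wvec /= wvec.sum()

    # adaptive proposal scales
    coef_scale = np.full(p, 0.1)
    s2_scale, lam_scale = 0.5, 0.15

    prior_sd = cfg.coef_prior_sd
    mu_k = cfg.placement_rate

    proposed = {m: 0 for m in
                ("coef", "sigma2", "lambda", "birth", "death", "modify",
                 "occurrence")}
    accepted = dict(proposed)

    def coef_logprior(c):
        return -0.5 * float(np.sum((c / prior_sd) ** 2))

    samples: list[PosteriorSample] = []
    adapting = cfg.adapt

    for it in range(1, cfg.iterations + 1):
        if it > cfg.burn_in:
            adapting = False
        move = move_names[rng.choice(len(move_names), p=wvec)] \
            if len(move_names) > 1 else move_names[0]

        if move == "coef":
            j = free_coef[rng.integers(len(free_coef))]
            prop = coef.copy()
            prop[j] += rng.normal(0.0, coef_scale[j])
            ll_new = eng.loglik(prop, sigma2)
            loga = power * (ll_new - ll) + coef_logprior(prop) \
                - coef_logprior(coef)
            proposed["coef"] += 1
            ok = math.log(rng.random()) < loga
            if ok:
                coef, ll = prop, ll_new
                accepted["coef"] += 1
            if adapting:
                coef_scale[j] *= math.exp(
                    ((1.0 if ok else 0.0) - cfg.target_acceptance)
                    / math.sqrt(1.0 + it / 100.0))

        elif move == "sigma2":
            step = rng.normal(0.0, s2_scale)
            ls_new = math.log(sigma2) + step
            proposed["sigma2"] += 1
            ok = False
            if LOG_S2_BOUNDS[0] <= ls_new <= LOG_S2_BOUNDS[1]:
                s2_new = math.exp(ls_new)
                ll_new = eng.loglik(coef, s2_new)
                ok = math.log(rng.random()) < power * (ll_new - ll)
                if ok:
                    sigma2, ll = s2_new, ll_new
                    accepted["sigma2"] += 1
            if adapting:
                s2_scale *= math.exp(
                    ((1.0 if ok else 0.0) - cfg.target_acceptance)
                    / math.sqrt(1.0 + it / 100.0))

        elif move == "lambda":
            lam_new = lam + rng.normal(0.0, lam_scale)
            # reflect into [0, 1]
            while not 0.0 <= lam_new <= 1.0:
                lam_new = -lam_new if lam_new < 0 else 2.0 - lam_new
            proposed["lambda"] += 1
            old = (eng.L, eng.logdet, eng.yw, eng.Xw, eng.onew, lam)
            eng.set_lambda(lam_new)
            ll_new = eng.loglik(coef, sigma2)
            ok = math.log(rng.random()) < power * (ll_new - ll)
            if ok:
                lam, ll = lam_new, ll_new
                accepted["lambda"] += 1
            else:
                eng.L, eng.logdet, eng.yw, eng.Xw, eng.onew, lam = old
            if adapting:
                lam_scale *= math.exp(
                    ((1.0 if ok else 0.0) - cfg.target_acceptance)
                    / math.sqrt(1.0 + it / 100.0))
            lam_scale = min(lam_scale, 1.0)

        elif move == "rj":
            sub = ("add_branch", "add_clade", "delete", "modify")[
                rng.integers(4)]
            k = len(placements)
            new_places = None
            log_hastings = 0.0
            if sub in ("add_branch", "add_clade"):
                kind = "branch" if sub == "add_branch" else "clade"
                targets = branch_targets if kind == "branch" else clade_targets
                if k < kmax and kind in kinds and len(targets):
                    node = int(targets[rng.integers(len(targets))])
                    r = math.exp(rng.uniform(log_lo, log_hi))
                    new_places = placements + [Placement(kind, node, r)]
                    log_hastings = math.log(mu_k / (k + 1)) \
                        + math.log(kind_prior_p)
                proposed["birth"] += 1
                tag = "birth"
            elif sub == "delete":
                proposed["death"] += 1
                tag = "death"
                if k > 0:
                    idx = int(rng.integers(k))
                    new_places = placements[:idx] + placements[idx + 1:]
                    log_hastings = math.log(k / mu_k) \
                        - math.log(kind_prior_p)
            else:
                proposed["modify"] += 1
                tag = "modify"
                if k > 0:
                    idx = int(rng.integers(k))
                    old_p = placements[idx]
                    r_new = old_p.r * math.exp(rng.normal(0.0, cfg.modify_sd))
                    if SCALAR_BOUNDS[0] <= r_new <= SCALAR_BOUNDS[1]:
                        new_places = placements.copy()
                        new_places[idx] = replace(old_p, r=r_new)
                        log_hastings = 0.0
            if new_places is not None:
                eff_new = effective_scalars(new_places, arrays)
                branch_eff = eff_new[arrays.branch_indices]
                if np.all((branch_eff >= SCALAR_BOUNDS[0])
                          & (branch_eff <= SCALAR_BOUNDS[1])):
                    old = (eng.S, eng.L, eng.logdet, eng.yw, eng.Xw, eng.onew)
                    eng.set_scalars(eff_new)
                    eng.set_lambda(lam)
                    ll_new = eng.loglik(coef, sigma2)
                    if math.log(rng.random()) < power * (ll_new - ll) \
                            + log_hastings:
                        placements, eff, ll = new_places, eff_new, ll_new
                        accepted[tag] += 1
                    else:
                        (eng.S, eng.L, eng.logdet, eng.yw, eng.Xw,
                         eng.onew) = old

        elif move == "occurrence":
            i = eng.multi[rng.integers(len(eng.multi))]
            j_new = int(rng.integers(len(eng.dataset.occurrences[i])))
            proposed["occurrence"] += 1
            if j_new == assignment[i]:
                accepted["occurrence"] += 1
            else:
                old_X, old_Xw, old_j = eng.X, eng.Xw, assignment[i]
                assignment[i] = j_new
                eng.set_design(assignment)
                ll_new = eng.loglik(coef, sigma2)
                if math.log(rng.random()) < power * (ll_new - ll):
                    ll = ll_new
                    accepted["occurrence"] += 1
                else:
                    assignment[i] = old_j
                    eng.X, eng.Xw = old_X, old_Xw

        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0:
            samples.append(PosteriorSample(
                iteration=it, coefficients=coef.copy(), sigma2=sigma2,
                lam=lam, placements=tuple(placements),
                assignment=tuple(int(a) for a in assignment),
                loglik=ll, r2=eng.r2(coef)))

    rates = {m: (accepted[m] / proposed[m] if proposed[m] else float("nan"))
             for m in proposed}
    final = {"coef": coef.copy(), "sigma2": sigma2, "lam": lam,
             "placements": list(placements),
             "assignment": assignment.copy()}
    return ChainResult(samples=samples, acceptance=rates,
                       coef_names=eng.names, arrays=arrays, config=cfg,
                       final_state=final)


# ---------------------------------------------------------------------------
# posterior summaries


def p_mcmc(beta_samples: np.ndarray) -> float:
    """Proportion of slope samples crossing zero relative to the posterior
    median's sign (a sample exactly at zero counts as crossing); a median of
    exactly zero returns 0.5."""
    b = np.asarray(beta_samples, dtype=float)
    if b.size == 0:
        raise ValueError("need at least one sample")
    med = float(np.median(b))
    if med == 0.0:
        return 0.5
    if med > 0:
        return float(np.mean(b <= 0))
    return float(np.mean(b >= 0))


@dataclass
class PosteriorSummary:
    medians: dict
    ci95: dict
    p_mcmc: dict
    median_r2: float
    r2_ci95: tuple
    mean_branch_scalars: np.ndarray
    acceptance: dict
    ess: dict
    n_samples: int


def _ess(x: np.ndarray) -> float:
    import arviz as az
    if np.allclose(x, x[0]):
        return float(len(x))
    return float(az.ess(x[None, :]))


def summarise(result: ChainResult) -> PosteriorSummary:
    """Medians, equal-tailed 95% CIs, p_MCMC per slope, median R^2, mean
    per-branch effective scalars, acceptance rates and ESS."""
    samples = result.samples
    if len(samples) < 2:
        raise ValueError("need at least two posterior samples")
    names = result.coef_names
    coefs = np.array([s.coefficients for s in samples])
    params = {name: coefs[:, j] for j, name in enumerate(names)}
    params["sigma2"] = np.array([s.sigma2 for s in samples])
    params["lambda"] = np.array([s.lam for s in samples])
    params["n_scalars"] = np.array([len(s.placements) for s in samples],
                                   dtype=float)

    medians = {k: float(np.median(v)) for k, v in params.items()}
    ci95 = {k: tuple(np.quantile(v, [0.025, 0.975]))
            for k, v in params.items()}
    pvals = {name: p_mcmc(params[name]) for name in names
             if name != "intercept"}

    r2s = np.array([s.r2 for s in samples])
    r2s_ok = r2s[np.isfinite(r2s)]
    median_r2 = float(np.median(r2s_ok)) if r2s_ok.size else float("nan")
    r2_ci = tuple(np.quantile(r2s_ok, [0.025, 0.975])) if r2s_ok.size \
        else (float("nan"), float("nan"))

    eff = np.mean([effective_scalars(s.placements, result.arrays)
                   for s in samples], axis=0)

    ess = {k: _ess(v) for k, v in params.items()
           if k in names or k in ("sigma2", "lambda")}
    return PosteriorSummary(
        medians=medians, ci95=ci95, p_mcmc=pvals, median_r2=median_r2,
        r2_ci95=r2_ci, mean_branch_scalars=eff,
        acceptance=result.acceptance, ess=ess, n_samples=len(samples))


def write_trace(result: ChainResult, path) -> None:
    """Tab-separated chain log: iteration, logL, coefficients, sigma2,
    lambda, number of scalar placements."""
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["iteration", "logL", *result.coef_names,
                    "sigma2", "lambda", "n_scalars"])
        for s in result.samples:
            w.writerow([s.iteration, f"{s.loglik:.6f}",
                        *(f"{c:.8g}" for c in s.coefficients),
                        f"{s.sigma2:.8g}", f"{s.lam:.6f}",
                        len(s.placements)])
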