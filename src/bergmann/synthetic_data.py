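"""Simulators for every statistical structure the analyses assume.

Includes Brownian trait evolution on a tree, correlated bivariate Brownian
evolution (the positive control), independent evolution (the negative
control), clade-specific rate multipliers, a Bergmann-type latitude-size
dependence, multi-occurrence tip records with linked local temperatures, and
a deterministic latitude-temperature profile standing in for the
GCM-derived temperature columns.

All generators are reproducible from a seed; trees are Yule (pure birth,
unit rate) rescaled to a stated root height, a deliberately plain choice
since tree shape is not what the estimators under test are sensitive to.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phylo_data import (OccurrenceRecord, Phylogeny, PhyloNode,
                         TraitDataset)

__all__ = [
    "SimulationSpec",
    "yule_tree",
    "simulate_bm",
    "simulate_correlated_bm",
    "temperature_from_latitude",
    "TEMPERATURE_PRESETS",
    "simulate",
    "make_fixture",
    "FIXTURES",
    "pick_clade",
]


# ---------------------------------------------------------------------------
# trees


def yule_tree(n_tips: int, seed: int | None = None,
              root_height: float = 100.0,
              rng: np.random.Generator | None = None) -> Phylogeny:
    """Pure-birth tree with ``n_tips``, rescaled so the root-to-tip height is
    ``root_height`` Myr.  Tip labels are t1..tn in traversal order."""
    if n_tips < 2:
        raise ValueError("need at least two tips")
    rng = rng if rng is not None else np.random.default_rng(seed)
    root = PhyloNode()
    t = 0.0
    born: dict[int, float] = {}
    active: list[PhyloNode] = []
    for _ in range(2):
        c = root.add_child(PhyloNode())
        born[id(c)] = 0.0
        active.append(c)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        node.length = t - born[id(node)]
        for _ in range(2):
            c = node.add_child(PhyloNode())
            born[id(c)] = t
            active.append(c)
    t_end = t + rng.exponential(1.0 / len(active))
    for node in active:
        node.length = t_end - born[id(node)]
    scale = root_height / t_end
    counter = 0
    tree = Phylogeny.__new__(Phylogeny)
    tree.root = root
    for node in tree.preorder():
        node.length *= scale
        if node.is_tip:
            counter += 1
            node.label = f"t{counter}"
    return Phylogeny(root)


def pick_clade(tree: Phylogeny, min_frac: float = 0.2,
               max_frac: float = 0.5) -> PhyloNode:
    """Deterministically pick an internal node whose clade holds between
    ``min_frac`` and ``max_frac`` of the tips (largest such clade)."""
    n = tree.n_tips
    best, best_size = None, -1
    for node in tree.preorder():
        if node.is_tip or node.parent is None:
            continue
        size = sum(1 for _ in _tips_below(node))
        if min_frac * n <= size <= max_frac * n and size > best_size:
            best, best_size = node, size
    if best is None:
        raise ValueError("no clade in the requested size range")
    return best


def _tips_below(node: PhyloNode):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_tip:
            yield n
        stack.extend(n.children)


# ---------------------------------------------------------------------------
# trait simulation


def simulate_bm(tree: Phylogeny, rate: float, root_state: float,
                rng: np.random.Generator,
                branch_scalars: dict[int, float] | None = None
                ) -> tuple[dict[str, float], dict[int, float]]:
    """Brownian motion along the tree: tip values and all node values.

    ``branch_scalars`` optionally multiplies the variance accumulated on
    individual branches (keyed by id(node)).
    """
    node_vals: dict[int, float] = {}
    tip_vals: dict[str, float] = {}
    for node in _preorder_stable(tree):
        if node.parent is None:
            node_vals[id(node)] = root_state
        else:
            mult = 1.0 if branch_scalars is None else \
                branch_scalars.get(id(node), 1.0)
            var = rate * node.length * mult
            node_vals[id(node)] = node_vals[id(node.parent)] \
                + rng.normal(0.0, np.sqrt(var)) if var > 0 \
                else node_vals[id(node.parent)]
        if node.is_tip:
            tip_vals[node.label] = node_vals[id(node)]
    return tip_vals, node_vals


def _preorder_stable(tree: Phylogeny):
    # plain preorder; kept separate so simulation order is an explicit contract
    return tree.preorder()


def simulate_correlated_bm(tree: Phylogeny, Sigma: np.ndarray,
                           roots: tuple[float, float],
                           rng: np.random.Generator
                           ) -> dict[str, tuple[float, float]]:
    """Bivariate Brownian motion with per-Myr rate matrix ``Sigma``."""
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.shape != (2, 2) or not np.allclose(Sigma, Sigma.T):
        raise ValueError("Sigma must be symmetric 2x2")
    if np.any(np.linalg.eigvalsh(Sigma) < -1e-12):
        raise ValueError("Sigma must be positive semi-definite")
    chol = np.linalg.cholesky(Sigma + 1e-15 * np.eye(2))
    vals: dict[int, np.ndarray] = {}
    out: dict[str, tuple[float, float]] = {}
    for node in tree.preorder():
        if node.parent is None:
            vals[id(node)] = np.array(roots, dtype=float)
        else:
            step = chol @ rng.normal(size=2) * np.sqrt(node.length)
            vals[id(node)] = vals[id(node.parent)] + step
        if node.is_tip:
            out[node.label] = tuple(vals[id(node)])
    return out


# ---------------------------------------------------------------------------
# the latitude -> temperature profile (GCM columns are consumed, not built;
# this deterministic profile only emulates their gross latitudinal structure)

# preset: (equatorial MAT, polar MAT, seasonality amplitude), deg C
TEMPERATURE_PRESETS = {
    "triassic": (30.0, 3.0, 15.0),
    "cretaceous": (30.0, -11.0, 20.0),
    "modern": (27.0, -25.0, 25.0),
}


def temperature_from_latitude(lat: float, preset: str = "triassic",
                              noise_sd: float = 0.0,
                              rng: np.random.Generator | None = None
                              ) -> tuple[float, float]:
    """(MAT, CMMT) at a latitude: linear decline in |lat| from the
    equatorial anchor to the polar value, with a seasonality offset growing
    towards the poles (CMMT <= MAT always)."""
    if abs(lat) > 90:
        raise ValueError("latitude outside [-90, 90]")
    eq, pole, season = TEMPERATURE_PRESETS[preset]
    frac = abs(lat) / 90.0
    mat = eq + (pole - eq) * frac
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise requires an rng")
        mat += rng.normal(0.0, noise_sd)
    cmmt = mat - season * frac
    return float(mat), float(cmmt)


# ---------------------------------------------------------------------------
# full scenario simulation


@dataclass
class SimulationSpec:
    """One synthetic scenario.

    ``model`` selects the generating process: ``independent_bm`` and
    ``correlated_bm`` evolve two abstract traits (negative / positive
    controls); ``regression`` and ``bergmann`` generate a latitude history by
    Brownian motion and a response alpha + beta*|lat| + phylogenetic noise
    (``regression`` is the same machinery with any beta, ``bergmann`` names
    the rule's direction); ``variable_rates`` evolves a single trait with
    clade-specific rate multipliers.
    """

    model: str = "bergmann"
    n_tips: int = 128
    root_height: float = 100.0
    seed: int = 0
    tree: Phylogeny | None = None
    # correlated/independent BM
    Sigma: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.0], [0.0, 1.0]]))
    # regression-type models
    beta: float = 0.01
    alpha: float = 2.0
    sigma2: float = 1e-3          # residual rate, per Myr
    target_r2: float | None = None  # derive sigma2 from the realised
    # latitude spread so the scenario's variance explained is as stated
    lam: float = 1.0
    root_latitude: float = 30.0
    latitude_rate: float = 25.0   # deg^2 per Myr
    # variable rates
    rate: float = 1e-3
    clade_multiplier: float = 10.0
    # occurrence structure
    extra_occ_mean: float = 0.0   # Poisson mean for records beyond the first
    jitter_sd: float = 2.0        # deg of latitude
    temperature_preset: str | None = "triassic"


def _reflect_latitude(x: float) -> float:
    # reflect a Brownian path value into [-90, 90]
    period = 360.0
    x = (x + 90.0) % period
    if x < 0:
        x += period
    return x - 90.0 if x <= 180.0 else 270.0 - x


def _occurrences_for(lat: float, spec: SimulationSpec,
                     rng: np.random.Generator,
                     age: float | None = None) -> list[OccurrenceRecord]:
    k = 1 + (rng.poisson(spec.extra_occ_mean) if spec.extra_occ_mean > 0
             else 0)
    recs = []
    for _ in range(k):
        jl = float(np.clip(lat + rng.normal(0.0, spec.jitter_sd),
                           -90.0, 90.0))
        mat = cmmt = None
        if spec.temperature_preset:
            mat, cmmt = temperature_from_latitude(
                jl, spec.temperature_preset)
        recs.append(OccurrenceRecord(palaeolatitude=jl, mat=mat, cmmt=cmmt,
                                     age=age))
    return recs


def simulate(spec: SimulationSpec) -> tuple[Phylogeny, TraitDataset, dict]:
    """Draw one dataset under ``spec``; the truth record holds every
    generating quantity needed by recovery tests."""
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree if spec.tree is not None else yule_tree(
        spec.n_tips, rng=rng, root_height=spec.root_height)
    labels = tree.tip_labels
    depths = tree.depths()
    tip_depth = {t.label: depths[t] for t in tree.tips}
    truth: dict = {"model": spec.model, "seed": spec.seed,
                   "n_tips": tree.n_tips}

    if spec.model in ("independent_bm", "correlated_bm"):
        Sigma = np.asarray(spec.Sigma, dtype=float)
        if spec.model == "independent_bm":
            Sigma = np.diag(np.diag(Sigma))
        vals = simulate_correlated_bm(tree, Sigma, (0.0, 0.0), rng)
        x = np.array([vals[l][0] for l in labels])
        y = np.array([vals[l][1] for l in labels])
        truth.update(Sigma=Sigma, trait1={l: vals[l][0] for l in labels},
                     trait2={l: vals[l][1] for l in labels})
        # plumbing dataset: trait1 as the response, trait2 mapped to a
        # latitude-like column (clipped); analyses of the controls use the
        # raw truth values
        lat = np.clip(y * 15.0, -89.9, 89.9)
        dataset = TraitDataset(
            species=list(labels), response=x,
            occurrences=[[OccurrenceRecord(palaeolatitude=float(v))]
                         for v in lat])
        return tree, dataset, truth

    if spec.model == "variable_rates":
        clade = pick_clade(tree)
        mult: dict[int, float] = {}
        stack = [clade]
        while stack:
            n = stack.pop()
            mult[id(n)] = spec.clade_multiplier
            stack.extend(n.children)
        tips, _ = simulate_bm(tree, spec.rate, 0.0, rng,
                              branch_scalars=mult)
        fast_tips = sorted(t.label for t in _tips_below(clade))
        truth.update(rate=spec.rate, clade_multiplier=spec.clade_multiplier,
                     fast_clade_tips=fast_tips)
        x = np.array([tips[l] for l in labels])
        dataset = TraitDataset(
            species=list(labels), response=x,
            occurrences=[[OccurrenceRecord(palaeolatitude=0.0)]
                         for _ in labels])
        return tree, dataset, truth

    if spec.model in ("regression", "bergmann"):
        lat_tips, _ = simulate_bm(tree, spec.latitude_rate,
                                  spec.root_latitude, rng)
        lat = {l: _reflect_latitude(v) for l, v in lat_tips.items()}
        sigma2 = spec.sigma2
        if spec.target_r2 is not None:
            # pick the residual rate so the stated fraction of the response
            # variance is explained by |latitude| at this realised spread
            explained = spec.beta ** 2 * float(
                np.var([abs(v) for v in lat.values()]))
            noise_total = explained * (1.0 - spec.target_r2) / spec.target_r2
            mean_depth = float(np.mean([tip_depth[l] for l in labels]))
            sigma2 = noise_total / mean_depth
        # phylogenetic noise: BM share lam, independent share (1 - lam)
        noise_bm, _ = simulate_bm(tree, spec.lam * sigma2, 0.0, rng)
        response = {}
        for l in labels:
            indep_sd = np.sqrt(max((1.0 - spec.lam) * sigma2
                                   * tip_depth[l], 0.0))
            response[l] = (spec.alpha + spec.beta * abs(lat[l])
                           + noise_bm[l] + rng.normal(0.0, indep_sd))
        occurrences = [_occurrences_for(lat[l], spec, rng) for l in labels]
        truth.update(beta=spec.beta, alpha=spec.alpha, sigma2=sigma2,
                     lam=spec.lam, latitude={l: lat[l] for l in labels})
        dataset = TraitDataset(
            species=list(labels),
            response=np.array([response[l] for l in labels]),
            occurrences=occurrences)
        return tree, dataset, truth

    raise ValueError(f"unknown generating model {spec.model!r}")


# ---------------------------------------------------------------------------
# named fixtures


def _write_dataset(tree: Phylogeny, dataset: TraitDataset,
                   outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tree.write(outdir / "tree.nwk")
    dataset.to_frame().to_csv(outdir / "traits.csv", index=False)


def _fixture_ursid8(outdir: Path) -> dict:
    """8-tip bear-like worked example, synthetic: the generating slope is
    the published ursid value (0.0097 log10 g per degree of latitude) and
    the noise level is chosen so latitude explains about three quarters of
    the variance."""
    spec = SimulationSpec(model="bergmann", n_tips=8, root_height=20.0,
                          seed=8801, beta=0.0097, alpha=4.6, target_r2=0.75,
                          lam=1.0, root_latitude=35.0, latitude_rate=25.0,
                          extra_occ_mean=0.0, temperature_preset="modern")
    tree, dataset, truth = simulate(spec)
    _write_dataset(tree, dataset, outdir)
    return truth


def _fixture_dino_small(outdir: Path) -> dict:
    spec = SimulationSpec(model="regression", n_tips=64, root_height=150.0,
                          seed=6401, beta=0.0, alpha=2.2, sigma2=1e-3,
                          lam=0.9, extra_occ_mean=1.0,
                          temperature_preset="cretaceous")
    tree, dataset, truth = simulate(spec)
    rng = np.random.default_rng(spec.seed + 1)
    frame = dataset.to_frame()
    ages = {sp: float(rng.uniform(70.0, 245.0)) for sp in dataset.species}
    frame["age"] = frame["species"].map(ages)
    frame["tip_age"] = frame["species"].map(ages)
    from .bias_covariates import period_from_age
    frame["period"] = frame["age"].map(period_from_age)
    clades = ("Theropoda", "Sauropodomorpha", "Ornithischia")
    frame["clade"] = frame["species"].map(
        {sp: clades[i % 3] for i, sp in enumerate(dataset.species)})
    outdir.mkdir(parents=True, exist_ok=True)
    tree.write(outdir / "tree.nwk")
    frame.to_csv(outdir / "traits.csv", index=False)
    return truth


def _fixture_control(outdir: Path, rho: float, n: int, seed: int) -> dict:
    Sigma = np.array([[1.0, rho], [rho, 1.0]])
    spec = SimulationSpec(
        model="correlated_bm" if rho else "independent_bm",
        n_tips=n, root_height=100.0, seed=seed, Sigma=Sigma)
    tree, dataset, truth = simulate(spec)
    _write_dataset(tree, dataset, outdir)
    return truth


def _fixture_biastable_toy(outdir: Path) -> dict:
    """Ten occurrence rows in one (zone, period) cell: three rows share
    formation F1, the rest are unique formations; two rows are flagged
    unidentifiable and one is not a body fossil, so the retained occurrence
    count is 7."""
    rows = []
    formations = ["F1", "F1", "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8"]
    for i, f in enumerate(formations):
        rows.append({
            "taxon": f"taxon_{i + 1}",
            "formation": f,
            "period": "Jurassic",
            "age": 170.0,
            "palaeolatitude": 5.0,
            "identifiable": i not in (1, 4),
            "body_fossil": i != 7,
        })
    df = pd.DataFrame(rows)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / "occurrences.csv", index=False)
    return {"n_rows": 10, "expected_occurrences": 7,
            "expected_formations": 8, "zone": 4, "period": "Jurassic"}


FIXTURES = {
    "ursid8": _fixture_ursid8,
    "dino_small": _fixture_dino_small,
    "control_pos": lambda d: _fixture_control(d, rho=0.8, n=500, seed=501),
    "control_neg": lambda d: _fixture_control(d, rho=0.0, n=2500, seed=502),
    "biastable_toy": _fixture_biastable_toy,
}


def make_fixture(name: str, outdir: str | Path) -> dict:
    """Write the named fixture's files under ``outdir``; deterministic for a
    given registry entry.  Returns the truth record."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; "
                         f"known: {sorted(FIXTURES)}")
    return FIXTURES[name](Path(outdir))
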