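"""Closed-form Brownian-motion machinery.

Phylogenetic covariance under Pagel's lambda and branch-rate scalars, GLS
estimation and likelihood, Felsenstein independent contrasts, ML ancestral
states, a whitened R-squared, variance inflation factors, and the
log10-slope-to-percent-change conversion.

Under Brownian motion with rate sigma^2 the covariance of two tips is
sigma^2 times the shared root-to-MRCA path length; Pagel's lambda multiplies
only the off-diagonal shared paths, and a variable-rates configuration
multiplies each branch length by a positive scalar before paths are summed.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .phylo_data import Phylogeny, PhyloNode, TraitDataset

logger = logging.getLogger(__name__)

__all__ = [
    "TreeArrays",
    "PhyloCovariance",
    "ModelSpec",
    "design_matrix",
    "covariance",
    "gls_fit",
    "GlsResult",
    "independent_contrasts",
    "pic_slope",
    "ancestral_states",
    "r_squared",
    "vif",
    "percent_change_per_unit",
    "RIDGE_FRACTION",
]

RIDGE_FRACTION = 1e-10  # of mean diagonal, added only when V is singular


class TreeArrays:
    """Array compilation of a (resolved) tree for covariance work.

    Nodes are indexed in postorder (root last).  Every non-root node ``i``
    owns the branch to its parent; ``tip_incidence[i, j]`` marks tip ``j``
    as a descendant of that branch, so the tip-tip shared-path matrix is
    ``B^T diag(w) B`` with ``w`` the scaled branch lengths.
    """

    def __init__(self, tree: Phylogeny):
        if not tree.is_bifurcating():
            tree = tree.resolve_polytomies()
        self.tree = tree
        self.nodes: list[PhyloNode] = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.n_nodes = len(self.nodes)
        self.root_index = self.index[id(tree.root)]
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        self.lengths = np.zeros(self.n_nodes)
        for i, node in enumerate(self.nodes):
            self.lengths[i] = node.length
            if node.parent is not None:
                self.parent[i] = self.index[id(node.parent)]
        self.tip_indices = np.array(
            [i for i, n in enumerate(self.nodes) if n.is_tip], dtype=np.int64)
        self.tip_labels = [self.nodes[i].label for i in self.tip_indices]
        self.n_tips = len(self.tip_indices)
        tip_col = {t: j for j, t in enumerate(self.tip_indices)}

        inc = np.zeros((self.n_nodes, self.n_tips), dtype=np.float64)
        for i, node in enumerate(self.nodes):  # postorder: children first
            if node.is_tip:
                inc[i, tip_col[i]] = 1.0
            else:
                for child in node.children:
                    inc[i] += inc[self.index[id(child)]]
        self.tip_incidence = inc
        self.branch_indices = np.array(
            [i for i in range(self.n_nodes) if i != self.root_index],
            dtype=np.int64)
        # descendant-tip sets per node (for clade scalars / clade summaries)
        self.clade_tip_mask = inc.astype(bool)
        self._children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if self.parent[i] >= 0:
                self._children[self.parent[i]].append(i)
        self._clade_cache: dict[int, np.ndarray] = {}

    def shared_path_matrix(self, scalars: np.ndarray | None = None
                           ) -> np.ndarray:
        """Tip-by-tip matrix of scaled shared path lengths (diagonal =
        scaled root-to-tip depth)."""
        w = self.lengths.copy()
        if scalars is not None:
            scalars = np.asarray(scalars, dtype=float)
            if scalars.shape != (self.n_nodes,):
                raise ValueError("scalars must align with the node array")
            if np.any(scalars <= 0):
                raise ValueError("rate scalars must be positive")
            w = w * scalars
        B = self.tip_incidence[self.branch_indices]
        wb = w[self.branch_indices]
        return (B * wb[:, None]).T @ B

    def descendant_branches(self, node_index: int) -> np.ndarray:
        """Branch indices inside the clade rooted at ``node_index``
        (including its own stem branch)."""
        cached = self._clade_cache.get(node_index)
        if cached is not None:
            return cached
        out: list[int] = []
        stack = [node_index]
        while stack:
            i = stack.pop()
            if i != self.root_index:
                out.append(i)
            stack.extend(self._children[i])
        result = np.array(sorted(out), dtype=np.int64)
        self._clade_cache[node_index] = result
        return result

    def node_heights(self) -> np.ndarray:
        """Height above the deepest tip, in Myr (tree height minus depth)."""
        depth = np.zeros(self.n_nodes)
        for i in reversed(range(self.n_nodes)):  # preorder over postorder list
            p = self.parent[i]
            if p >= 0:
                depth[i] = depth[p] + self.lengths[i]
        height = depth[self.tip_indices].max()
        return height - depth


@dataclass(frozen=True)
class PhyloCovariance:
    """A realised phylogenetic covariance matrix with its provenance."""

    matrix: np.ndarray
    tip_labels: tuple[str, ...]
    lam: float
    scalars_id: str = "homogeneous"


def covariance(tree: Phylogeny | TreeArrays, lam: float = 1.0,
               scalars: np.ndarray | None = None) -> PhyloCovariance:
    """Phylogenetic covariance V under Pagel's lambda and rate scalars.

    V_ij = lambda * shared scaled path for i != j; V_ii = scaled root-to-tip
    path.  ``scalars`` is a per-node array of effective branch multipliers
    (entry for the root ignored), defaulting to 1 everywhere.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    arrays = tree if isinstance(tree, TreeArrays) else TreeArrays(tree)
    S = arrays.shared_path_matrix(scalars)
    V = lam * S
    np.fill_diagonal(V, np.diag(S))
    return PhyloCovariance(matrix=V, tip_labels=tuple(arrays.tip_labels),
                           lam=lam,
                           scalars_id="homogeneous" if scalars is None
                           else "scaled")


# ---------------------------------------------------------------------------
# model specification / design matrices

# dummy-coding baselines: these levels are coded 0
BASELINES = {"hemisphere": "N", "period": "Triassic", "clade": "Ornithischia"}
PERIOD_LEVELS = ("Triassic", "Jurassic", "Cretaceous")


@dataclass(frozen=True)
class ModelSpec:
    """A regression design: which focal predictor and which extra terms.

    ``predictor`` is one of ``"abs_latitude"``, ``"mat"``, ``"cmmt"`` or
    ``None`` (intercept-only, the univariate tempo model).  Dummy covariates
    use k-1 indicators with northern hemisphere / Triassic / Ornithischia as
    the zero-coded baselines.
    """

    predictor: str | None = "abs_latitude"
    hemisphere: bool = False
    period: bool = False
    clade: bool = False
    interactions: bool = False
    tip_age: bool = False
    formation_count: bool = False
    occurrence_count: bool = False
    variable_rates: bool = False
    name: str = ""

    def label(self) -> str:
        if self.name:
            return self.name
        parts = [self.predictor or "intercept"]
        for flag in ("hemisphere", "period", "clade", "interactions",
                     "tip_age", "formation_count", "occurrence_count"):
            if getattr(self, flag):
                parts.append(flag)
        parts.append("VR" if self.variable_rates else "HR")
        return "+".join(parts)


def design_matrix(dataset: TraitDataset, spec: ModelSpec,
                  assignment: np.ndarray | None = None
                  ) -> tuple[np.ndarray, list[str]]:
    """Build the design matrix for ``spec``.

    ``assignment[i]`` picks which linked occurrence record represents species
    ``i`` (default: the first).  The absolute-value transform of latitude
    happens here and only here.
    """
    n = len(dataset)
    if assignment is None:
        assignment = np.zeros(n, dtype=int)
    recs = [dataset.occurrences[i][int(assignment[i])] for i in range(n)]

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    focal = None
    if spec.predictor is not None:
        if spec.predictor == "abs_latitude":
            focal = np.abs([r.palaeolatitude for r in recs])
        elif spec.predictor in ("mat", "cmmt"):
            vals = [getattr(r, spec.predictor) for r in recs]
            if any(v is None for v in vals):
                raise ValueError(f"{spec.predictor} missing for some species")
            focal = np.array(vals, dtype=float)
        else:
            raise ValueError(f"unknown predictor {spec.predictor!r}")
        cols.append(focal)
        names.append(spec.predictor)

    def dummy(level_values, levels, baseline, prefix):
        for level in levels:
            if level == baseline:
                continue
            cols.append(np.array([1.0 if v == level else 0.0
                                  for v in level_values]))
            names.append(f"{prefix}:{level}")

    if spec.hemisphere:
        hemis = [r.hemisphere for r in recs]
        dummy(hemis, ("N", "S"), BASELINES["hemisphere"], "hemisphere")
    if spec.period:
        if any(p is None for p in dataset.period):
            raise ValueError("period column required by this model")
        dummy(dataset.period, PERIOD_LEVELS, BASELINES["period"], "period")
    if spec.clade:
        if any(c is None for c in dataset.clade):
            raise ValueError("clade column required by this model")
        levels = tuple(sorted(set(dataset.clade)))
        base = BASELINES["clade"] if BASELINES["clade"] in levels else levels[0]
        dummy(dataset.clade, levels, base, "clade")
    if spec.interactions:
        if focal is None:
            raise ValueError("interactions need a focal predictor")
        base_cols = [(names[i], cols[i]) for i in range(len(cols))
                     if names[i].split(":")[0] in
                     ("hemisphere", "period", "clade")]
        for nm, c in base_cols:
            cols.append(c * focal)
            names.append(f"{spec.predictor}x{nm}")
    if spec.tip_age:
        if dataset.tip_age is None:
            raise ValueError("tip_age column required by this model")
        cols.append(np.asarray(dataset.tip_age, dtype=float))
        names.append("tip_age")
    if spec.formation_count:
        if dataset.formation_count is None:
            raise ValueError("formation_count required by this model")
        cols.append(np.asarray(dataset.formation_count, dtype=float))
        names.append("formation_count")
    if spec.occurrence_count:
        if dataset.occurrence_count is None:
            raise ValueError("occurrence_count required by this model")
        cols.append(np.asarray(dataset.occurrence_count, dtype=float))
        names.append("occurrence_count")

    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# GLS


@dataclass(frozen=True)
class GlsResult:
    coefficients: np.ndarray
    sigma2: float          # ML residual rate, trait variance per Myr
    loglik: float
    names: tuple[str, ...] = ()


def _safe_cholesky(V: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor; on singularity add a logged ridge."""
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        ridge = RIDGE_FRACTION * float(np.mean(np.diag(V)))
        logger.warning("covariance singular; adding ridge %.3e", ridge)
        warnings.warn("phylogenetic covariance singular; ridge added",
                      RuntimeWarning, stacklevel=3)
        return linalg.cholesky(V + ridge * np.eye(V.shape[0]), lower=True)


def _check_rank(X: np.ndarray, names) -> None:
    R = np.linalg.qr(X, mode="r")
    bad = np.abs(np.diag(R)) < 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    if bad.any():
        offending = [names[i] if names else str(i)
                     for i in np.nonzero(bad)[0]]
        raise ValueError(f"rank-deficient design; offending columns: "
                         f"{offending}")


def gls_fit(y: np.ndarray, X: np.ndarray, V: np.ndarray | PhyloCovariance,
            names: list[str] | None = None) -> GlsResult:
    """Maximum-likelihood GLS under residual covariance sigma^2 V.

    coefficients = (X' V^-1 X)^-1 X' V^-1 y; sigma2 = r' V^-1 r / n; loglik
    is the multivariate-normal log density at the ML values.
    """
    if isinstance(V, PhyloCovariance):
        V = V.matrix
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.shape[0]
    L = _safe_cholesky(np.asarray(V, dtype=float))
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    _check_rank(Xw, names)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    sigma2 = float(resid @ resid) / n
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2 <= 0:
        sigma2 = 0.0
        loglik = np.inf  # degenerate noiseless fit
    else:
        loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetV + n)
    return GlsResult(coefficients=beta, sigma2=sigma2, loglik=float(loglik),
                     names=tuple(names) if names else ())


# ---------------------------------------------------------------------------
# contrasts and ancestral states


def _tip_value_array(tree: Phylogeny, values) -> dict[str, float]:
    if isinstance(values, dict):
        return {k: float(v) for k, v in values.items()}
    vals = np.asarray(values, dtype=float)
    labels = tree.tip_labels
    if vals.shape != (len(labels),):
        raise ValueError("values must map tips or align with tip order")
    return dict(zip(labels, vals))


def independent_contrasts(tree: Phylogeny, values) -> np.ndarray:
    """Felsenstein's standardised independent contrasts (n-1 of them).

    The tree is resolved to bifurcations first (zero-length splits); zero
    contrast variance at a zero-length split is guarded with a small epsilon.
    """
    tree = tree if tree.is_bifurcating() else tree.resolve_polytomies()
    vmap = _tip_value_array(tree, values)
    contrasts = []
    state: dict[int, tuple[float, float]] = {}
    for node in tree.postorder():
        if node.is_tip:
            state[id(node)] = (vmap[node.label], node.length)
        else:
            (x1, v1), (x2, v2) = (state[id(c)] for c in node.children)
            var = v1 + v2
            contrasts.append((x1 - x2) / np.sqrt(max(var, 1e-300)))
            # precision-weighted mean; v=0 children carry infinite precision
            if var <= 0:
                xm, extra = 0.5 * (x1 + x2), 0.0
            elif v1 == 0:
                xm, extra = x1, 0.0
            elif v2 == 0:
                xm, extra = x2, 0.0
            else:
                xm = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
                extra = v1 * v2 / var
            state[id(node)] = (xm, node.length + extra)
    return np.asarray(contrasts)


def pic_slope(tree: Phylogeny, x, y) -> float:
    """Through-origin regression of y-contrasts on x-contrasts; equals the
    GLS slope at lambda = 1 for a simple regression."""
    cx = independent_contrasts(tree, x)
    cy = independent_contrasts(tree, y)
    return float(cx @ cy / (cx @ cx))


def ancestral_states(tree: Phylogeny, values) -> dict[PhyloNode, float]:
    """Maximum-likelihood (GLS) ancestral states under Brownian motion.

    Two-pass message passing: an upward (pruning) pass collects each
    subtree's conditional mean and variance, a downward pass folds in the
    information from the rest of the tree.  The root state equals the GLS
    phylogenetic mean.  Handles multifurcations natively; tips return their
    observed values.
    """
    vmap = _tip_value_array(tree, values)
    EPS = 1e-12

    up: dict[int, tuple[float, float]] = {}  # node -> (mean, var below node)
    post = list(tree.postorder())
    for node in post:
        if node.is_tip:
            up[id(node)] = (vmap[node.label], 0.0)
        else:
            prec = mean = 0.0
            for c in node.children:
                m, v = up[id(c)]
                p = 1.0 / max(v + c.length, EPS)
                prec += p
                mean += p * m
            up[id(node)] = (mean / prec, 1.0 / prec)

    states: dict[PhyloNode, float] = {}
    down: dict[int, tuple[float, float] | None] = {id(tree.root): None}
    for node in reversed(post):  # preorder
        if node.is_tip:
            states[node] = vmap[node.label]
            continue
        above = down[id(node)]
        prec = mean = 0.0
        if above is not None:
            am, av = above
            p = 1.0 / max(av, EPS)
            prec += p
            mean += p * am
        for c in node.children:
            m, v = up[id(c)]
            p = 1.0 / max(v + c.length, EPS)
            prec += p
            mean += p * m
        states[node] = mean / prec
        # push "above" messages to children
        for c in node.children:
            pr = mn = 0.0
            if above is not None:
                am, av = above
                p = 1.0 / max(av, EPS)
                pr += p
                mn += p * am
            for s in node.children:
                if s is c:
                    continue
                m, v = up[id(s)]
                p = 1.0 / max(v + s.length, EPS)
                pr += p
                mn += p * m
            # a unifurcation at the root carries no information from above
            down[id(c)] = None if pr == 0 else (mn / pr, 1.0 / pr + c.length)
    return states


# ---------------------------------------------------------------------------
# fit quality / diagnostics


def r_squared(y: np.ndarray, X: np.ndarray, V: np.ndarray | PhyloCovariance,
              coefficients: np.ndarray) -> float:
    """Whitened R^2 = 1 - SSE/SST.

    Data and design are whitened by the inverse Cholesky factor of V; SST is
    taken about the GLS phylogenetic mean.  Evaluated at arbitrary (sampled)
    coefficients this can be negative.  Returns nan when the whitened
    response is constant (SST = 0).
    """
    if isinstance(V, PhyloCovariance):
        V = V.matrix
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    L = _safe_cholesky(np.asarray(V, dtype=float))
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    onew = linalg.solve_triangular(L, np.ones_like(y), lower=True)
    mu = float(onew @ yw / (onew @ onew))
    sst = float(np.sum((yw - mu * onew) ** 2))
    if sst <= 0:
        return float("nan")
    sse = float(np.sum((yw - Xw @ np.asarray(coefficients)) ** 2))
    return 1.0 - sse / sst


def vif(X: np.ndarray, V: np.ndarray | PhyloCovariance | None = None,
        names: list[str] | None = None) -> dict[str, float]:
    """Variance inflation factors for the non-intercept columns of ``X``.

    Each column is GLS-regressed (whitened by V) on all the others;
    VIF_j = 1/(1-R^2_j).  Perfect collinearity yields ``inf``.  A leading
    all-ones column is treated as the intercept and not reported.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if V is None:
        Xw = X.copy()
    else:
        if isinstance(V, PhyloCovariance):
            V = V.matrix
        L = _safe_cholesky(np.asarray(V, dtype=float))
        Xw = linalg.solve_triangular(L, X, lower=True)
    has_intercept = np.allclose(X[:, 0], 1.0)
    start = 1 if has_intercept else 0
    if p - start < 2:
        raise ValueError("VIF needs at least two non-intercept columns")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    out: dict[str, float] = {}
    for j in range(start, p):
        others = [k for k in range(p) if k != j]
        target = Xw[:, j]
        Z = Xw[:, others]
        beta, *_ = np.linalg.lstsq(Z, target, rcond=None)
        resid = target - Z @ beta
        center = target - target.mean()
        sst = float(center @ center)
        sse = float(resid @ resid)
        if sst <= 0 or sse <= 1e-12 * max(sst, 1.0):
            out[names[j]] = float("inf")
            continue
        r2 = 1.0 - sse / sst
        out[names[j]] = float("inf") if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def percent_change_per_unit(beta_log10: float, delta: float = 1.0) -> float:
    """Percent change in the (log10-scale) response per ``delta`` units of
    the predictor: (10^(beta*delta) - 1) * 100."""
    if not np.isfinite(beta_log10):
        raise ValueError("slope must be finite")
    return (10.0 ** (beta_log10 * delta) - 1.0) * 100.0
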