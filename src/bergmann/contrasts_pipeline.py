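"""Branch-wise change analysis: rate-scaled trees, ancestral states, and
sister-branch change sets, plus the change-vs-change scatter.

The pipeline mirrors the figure protocol: a univariate variable-rates run
(intercept-only regression) per trait yields a posterior of branch scalars;
the consensus tree scales each branch by its posterior-mean effective
scalar; ML ancestral states on that tree give a per-branch change
(descendant state minus ancestor state); and the scatter of change pairs
across traits, anchored at the origin, visualises co-directional evolution
(a Bergmann-consistent signal runs upper-left to lower-right for size
against temperature).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bm_core import TreeArrays, ancestral_states
from .phylo_data import Phylogeny, PhyloNode
from .rjmcmc import PosteriorSample, effective_scalars

__all__ = [
    "RateScaledTree",
    "rate_scaled_tree",
    "branch_changes",
    "combine_changes",
    "change_scatter",
    "contrast_trend",
    "fit_origin_trend",
    "TrendFit",
]


@dataclass
class RateScaledTree:
    """A base tree plus per-branch mean posterior scalars; the scaled tree
    has branch lengths multiplied by those scalars."""

    base: Phylogeny
    scaled: Phylogeny
    scalars: np.ndarray      # per node of the resolved base tree, postorder
    arrays: TreeArrays       # of the resolved base tree


def rate_scaled_tree(tree: Phylogeny, samples: list[PosteriorSample],
                     statistic: str = "mean") -> RateScaledTree:
    """Scale each branch by the across-sample consensus effective scalar.

    With a fixed topology the maximum-clade-credibility summary reduces to a
    per-branch statistic; the default is the arithmetic mean (``"median"``
    is available).
    """
    if not samples:
        raise ValueError("empty posterior")
    arrays = TreeArrays(tree)
    eff = np.array([effective_scalars(s.placements, arrays)
                    for s in samples])
    scal = np.mean(eff, axis=0) if statistic == "mean" \
        else np.median(eff, axis=0)
    scaled = arrays.tree.copy()
    for node, s in zip(scaled.postorder(), scal):
        node.length *= float(s)
    return RateScaledTree(base=arrays.tree, scaled=scaled, scalars=scal,
                          arrays=arrays)


def branch_changes(scaled_tree: RateScaledTree | Phylogeny, tip_values,
                   trait: str = "trait") -> pd.DataFrame:
    """Per-branch ancestral change in one trait on the (rate-scaled) tree.

    Ancestral states come from the ML Brownian reconstruction on the scaled
    tree; tips contribute their observed values, so the changes along any
    root-to-tip path telescope to (tip value - root state).  Multi-occurrence
    species should be reduced to a single value (their across-record mean)
    before calling.  Returns a table with parent/child identifiers, the
    ancestor height (Ma above the youngest tip), branch length and the
    change.
    """
    tree = scaled_tree.scaled if isinstance(scaled_tree, RateScaledTree) \
        else scaled_tree
    states = ancestral_states(tree, tip_values)
    depths = tree.depths()
    height = max(depths[t] for t in tree.tips)

    def ident(node: PhyloNode, idx: int) -> str:
        return node.label if node.label else f"node{idx}"

    order = {id(n): i for i, n in enumerate(tree.postorder())}
    rows = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        rows.append({
            "parent": ident(node.parent, order[id(node.parent)]),
            "child": ident(node, order[id(node)]),
            "branch": order[id(node)],
            "ancestor_height_ma": height - depths[node.parent],
            "branch_length": node.length,
            f"delta_{trait}": states[node] - states[node.parent],
        })
    return pd.DataFrame(rows)


def combine_changes(change_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-trait change tables computed on the same topology."""
    out = None
    for name, df in change_tables.items():
        cols = ["parent", "child", "branch", "ancestor_height_ma",
                f"delta_{name}"]
        part = df[[c for c in cols if c in df.columns]]
        out = part if out is None else out.merge(
            part[["branch", f"delta_{name}"]], on="branch")
    return out


@dataclass(frozen=True)
class TrendFit:
    """Origin-anchored least-squares trend through the change scatter."""

    slope: float
    se: float
    n: int

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.slope - 1.96 * self.se, self.slope + 1.96 * self.se)


def contrast_trend(tree: Phylogeny, x_values, y_values) -> TrendFit:
    """Through-origin trend of standardised independent contrasts.

    Branch-change pairs share ancestral reconstructions, so the naive
    least-squares error of the change scatter understates uncertainty;
    standardised contrasts are independent under Brownian motion and give a
    valid interval.  The contrast correlation is the inferential counterpart
    of the change scatter's visual trend.
    """
    from .bm_core import independent_contrasts

    cx = independent_contrasts(tree, x_values)
    cy = independent_contrasts(tree, y_values)
    return fit_origin_trend(cx, cy)


def fit_origin_trend(dx: np.ndarray, dy: np.ndarray) -> TrendFit:
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    sxx = float(dx @ dx)
    if sxx <= 0:
        return TrendFit(slope=0.0, se=float("inf"), n=len(dx))
    slope = float(dx @ dy) / sxx
    resid = dy - slope * dx
    s2 = float(resid @ resid) / max(len(dx) - 1, 1)
    return TrendFit(slope=slope, se=float(np.sqrt(s2 / sxx)), n=len(dx))


def change_scatter(changes: pd.DataFrame, trait_x: str, trait_y: str,
                   color_by: str = "delta_x", ax=None):
    """Scatter of per-branch changes in two traits with origin crosshairs.

    ``color_by`` selects the point colouring: ``"delta_x"`` (changes in the
    x trait) or ``"delta_y"``.  Returns ``(ax, TrendFit)``; the trend is the
    origin-anchored least-squares line (no evolution in either trait sits at
    the crosshair intersection).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    dx = changes[f"delta_{trait_x}"].to_numpy()
    dy = changes[f"delta_{trait_y}"].to_numpy()
    trend = fit_origin_trend(dx, dy)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    colors = dx if color_by == "delta_x" else dy
    sc = ax.scatter(dx, dy, c=colors, cmap="coolwarm", s=12, alpha=0.8)
    ax.axhline(0.0, ls=":", c="grey", lw=0.8)
    ax.axvline(0.0, ls=":", c="grey", lw=0.8)
    if np.isfinite(trend.se):
        xs = np.linspace(dx.min(), dx.max(), 50)
        ax.plot(xs, trend.slope * xs, c="black", lw=1.2)
    ax.set_xlabel(f"change in {trait_x}")
    ax.set_ylabel(f"change in {trait_y}")
    ax.figure.colorbar(sc, ax=ax, label=f"change in "
                       f"{trait_x if color_by == 'delta_x' else trait_y}")
    return ax, trend
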