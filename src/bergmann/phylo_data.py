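"""Data model and I/O for phylogenies, trait tables and occurrence tables.

The in-memory tree is a minimal rooted structure (parents, children, branch
lengths in Myr) compiled elsewhere into arrays for covariance work.  Parsing
and serialisation of Newick/Nexus go through dendropy; trait and occurrence
tables are delimited text read with pandas against a small column schema.

Latitudes are stored *signed*; the absolute-value transform used as the focal
regression predictor is applied only when a design matrix is built, never at
read time.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloNode",
    "Phylogeny",
    "OccurrenceRecord",
    "TraitDataset",
    "TraitSchema",
    "read_tree",
    "read_traits",
    "align",
    "normalise_name",
]


def normalise_name(name: str) -> str:
    """Canonical taxon name: trimmed, internal whitespace collapsed, spaces
    unified to underscores.  Exact matching after this; no fuzzy matching."""
    return re.sub(r"\s+", "_", name.strip())


class PhyloNode:
    """One node of a rooted tree; ``length`` is the branch to the parent."""

    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: str | None = None, length: float = 0.0,
                 parent: "PhyloNode | None" = None):
        self.label = label
        self.length = float(length)
        self.parent = parent
        self.children: list[PhyloNode] = []

    def add_child(self, child: "PhyloNode") -> "PhyloNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<PhyloNode {self.label or '?'} {kind} len={self.length:g}>"


class Phylogeny:
    """A rooted, time-calibrated tree with branch lengths in Myr.

    Invariants enforced at construction: branch lengths non-negative, tip
    labels unique and non-empty, every non-root node has exactly one parent.
    Polytomies are permitted and preserved; numeric code resolves them
    deterministically via :meth:`resolve_polytomies`.
    """

    def __init__(self, root: PhyloNode):
        self.root = root
        self.root.parent = None
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        def convert(dnode) -> PhyloNode:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            if length < 0:
                raise ValueError(f"negative branch length {length} at {label!r}")
            node = PhyloNode(label=normalise_name(label) if label else None,
                             length=length)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    # -- validation / traversal -------------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.preorder():
            if node.length < 0:
                raise ValueError("negative branch length in tree")
            if node.is_tip:
                if not node.label:
                    raise ValueError("tip without a label")
                if node.label in seen:
                    raise ValueError(f"duplicate tip label {node.label!r}")
                seen.add(node.label)
            for child in node.children:
                if child.parent is not node:
                    raise ValueError("broken parent link")
        if len(seen) < 2:
            raise ValueError("tree must have at least two tips")

    def preorder(self) -> Iterator[PhyloNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[PhyloNode]:
        out: list[PhyloNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    @property
    def tips(self) -> list[PhyloNode]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def depths(self) -> dict[PhyloNode, float]:
        """Root-to-node path lengths (root depth 0)."""
        out: dict[PhyloNode, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            out[node] = out[node.parent] + node.length
        return out

    def height(self) -> float:
        """Maximum root-to-tip path length."""
        d = self.depths()
        return max(d[t] for t in self.tips)

    # -- serialisation -----------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: PhyloNode) -> str:
            if node.is_tip:
                core = node.label
            else:
                inner = ",".join(fmt(c) for c in node.children)
                core = f"({inner})" + (node.label or "")
            return f"{core}:{node.length:.12g}"

        return fmt(self.root) + ";"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # -- manipulation ------------------------------------------------------

    def copy(self) -> "Phylogeny":
        def clone(node: PhyloNode) -> PhyloNode:
            new = PhyloNode(label=node.label, length=node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Phylogeny(clone(self.root))

    def prune_to(self, keep: Iterable[str]) -> "Phylogeny":
        """Prune to the given tip labels, suppressing unifurcations so that
        patristic distances among retained tips are unchanged."""
        keep_set = {normalise_name(k) for k in keep}
        missing = keep_set - set(self.tip_labels)
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)}")
        if not keep_set:
            raise ValueError("cannot prune to an empty tip set")

        tree = self.copy()
        # drop unwanted tips iteratively
        changed = True
        while changed:
            changed = False
            for node in list(tree.preorder()):
                if node.is_tip and node.label not in keep_set and node.parent:
                    node.parent.children.remove(node)
                    changed = True
        # suppress childless internals and unifurcations
        def tidy(node: PhyloNode) -> PhyloNode | None:
            node.children = [c for c in (tidy(ch) for ch in node.children) if c]
            for c in node.children:
                c.parent = node
            if not node.children and node.label not in keep_set:
                return None
            if len(node.children) == 1 and node.label not in keep_set:
                child = node.children[0]
                child.length += node.length
                return child
            return node

        new_root = tidy(tree.root)
        if new_root is None:
            raise ValueError("pruning removed the whole tree")
        new_root.length = 0.0
        return Phylogeny(new_root)

    def resolve_polytomies(self) -> "Phylogeny":
        """Return a fully bifurcating copy; polytomies are broken into
        zero-length bifurcations in sorted-child-label order (reproducible)."""

        def min_label(node: PhyloNode) -> str:
            return min(t.label for t in _subtree_tips(node))

        tree = self.copy()
        for node in list(tree.preorder()):
            while len(node.children) > 2:
                node.children.sort(key=min_label)
                a, b = node.children[0], node.children[1]
                joint = PhyloNode(length=0.0)
                node.children.remove(a)
                node.children.remove(b)
                joint.add_child(a)
                joint.add_child(b)
                node.add_child(joint)
                node.children.sort(key=min_label)
        return Phylogeny(tree.root)

    def is_bifurcating(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.preorder()
                   if not n.is_tip)


def _subtree_tips(node: PhyloNode) -> list[PhyloNode]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_tip:
            out.append(n)
        stack.extend(n.children)
    return out


# ---------------------------------------------------------------------------
# trees on disk


def read_tree(path: str | Path, format: str | None = None,
              tree_index: int | None = None) -> Phylogeny:
    """Read a rooted tree from Newick or Nexus.

    ``format`` is inferred from the file suffix when not given (.nex/.nexus
    -> nexus, else newick).  Files holding several trees require
    ``tree_index``; a single-tree file needs none.
    """
    path = Path(path)
    if format is None:
        format = "nexus" if path.suffix.lower() in {".nex", ".nexus", ".trees"} \
            else "newick"
    trees = dendropy.TreeList.get(path=str(path), schema=format)
    if len(trees) == 0:
        raise ValueError(f"no trees found in {path}")
    if len(trees) > 1 and tree_index is None:
        raise ValueError(
            f"{path} holds {len(trees)} trees; pass tree_index to pick one")
    dtree = trees[tree_index or 0]
    return Phylogeny.from_dendropy(dtree)


# ---------------------------------------------------------------------------
# occurrences and traits


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced occurrence of a species.

    Fields are linked: latitude and the local temperatures always refer to the
    same locality, so occurrence resampling swaps them jointly.
    """

    palaeolatitude: float
    mat: float | None = None        # mean annual temperature, deg C
    cmmt: float | None = None       # cold-month mean temperature, deg C
    age: float | None = None        # Ma

    def __post_init__(self):
        if not -90.0 <= self.palaeolatitude <= 90.0:
            raise ValueError(
                f"palaeolatitude {self.palaeolatitude} outside [-90, 90]")
        if self.mat is not None and self.cmmt is not None \
                and self.cmmt > self.mat + 1e-9:
            raise ValueError("CMMT exceeds MAT")

    @property
    def hemisphere(self) -> str:
        """'N' for latitude >= 0, else 'S' (recomputed per record)."""
        return "N" if self.palaeolatitude >= 0 else "S"


@dataclass
class TraitDataset:
    """Per-species response plus one or more linked occurrence records.

    ``response`` is on a log10 scale (mm of femoral circumference or grams of
    body mass).  Categorical covariates and the sampling-bias counts are
    optional; ``None`` entries mean "not provided".
    """

    species: list[str]
    response: np.ndarray
    occurrences: list[list[OccurrenceRecord]]
    period: list[str | None] = field(default_factory=list)
    clade: list[str | None] = field(default_factory=list)
    tip_age: np.ndarray | None = None
    formation_count: np.ndarray | None = None
    occurrence_count: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.species)
        self.response = np.asarray(self.response, dtype=float)
        if not self.period:
            self.period = [None] * n
        if not self.clade:
            self.clade = [None] * n
        if self.response.shape != (n,):
            raise ValueError("response length mismatch")
        if len(self.occurrences) != n:
            raise ValueError("occurrences length mismatch")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("non-finite response values")
        for sp, occ in zip(self.species, self.occurrences):
            if len(occ) < 1:
                raise ValueError(f"species {sp!r} has no occurrence records")

    def __len__(self) -> int:
        return len(self.species)

    @property
    def multi_occurrence_species(self) -> list[int]:
        """Indices of species carrying more than one linked record."""
        return [i for i, occ in enumerate(self.occurrences) if len(occ) > 1]

    def mean_latitude(self) -> np.ndarray:
        return np.array([np.mean([o.palaeolatitude for o in occ])
                         for occ in self.occurrences])

    def mean_age(self) -> np.ndarray:
        """Per-species mean occurrence age (falls back to tip_age, else nan)."""
        out = np.full(len(self), np.nan)
        for i, occ in enumerate(self.occurrences):
            ages = [o.age for o in occ if o.age is not None]
            if ages:
                out[i] = float(np.mean(ages))
            elif self.tip_age is not None and np.isfinite(self.tip_age[i]):
                out[i] = self.tip_age[i]
        return out

    def subset(self, labels: Sequence[str]) -> "TraitDataset":
        index = {sp: i for i, sp in enumerate(self.species)}
        missing = [l for l in labels if l not in index]
        if missing:
            raise ValueError(f"species not in dataset: {missing}")
        idx = [index[l] for l in labels]

        def take(arr):
            return None if arr is None else np.asarray(arr)[idx]

        return TraitDataset(
            species=[self.species[i] for i in idx],
            response=self.response[idx],
            occurrences=[self.occurrences[i] for i in idx],
            period=[self.period[i] for i in idx],
            clade=[self.clade[i] for i in idx],
            tip_age=take(self.tip_age),
            formation_count=take(self.formation_count),
            occurrence_count=take(self.occurrence_count),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per occurrence record."""
        rows = []
        for i, sp in enumerate(self.species):
            for occ in self.occurrences[i]:
                rows.append({
                    "species": sp,
                    "response": self.response[i],
                    "latitude": occ.palaeolatitude,
                    "mat": occ.mat,
                    "cmmt": occ.cmmt,
                    "age": occ.age,
                    "period": self.period[i],
                    "clade": self.clade[i],
                    "tip_age": None if self.tip_age is None else self.tip_age[i],
                })
        return pd.DataFrame(rows)


DEFAULT_SCHEMA = {
    "species": "species",
    "response": "response",
    "latitude": "latitude",
    "mat": "mat",
    "cmmt": "cmmt",
    "period": "period",
    "clade": "clade",
    "age": "age",
    "tip_age": "tip_age",
}


class TraitSchema(dict):
    """Column-name mapping for trait tables; YAML-loadable.

    Required keys: species, response, latitude.  Optional: mat, cmmt, period,
    clade, age, tip_age.
    """

    REQUIRED = ("species", "response", "latitude")

    @classmethod
    def load(cls, source: str | Path | Mapping | None) -> "TraitSchema":
        if source is None:
            mapping = dict(DEFAULT_SCHEMA)
        elif isinstance(source, Mapping):
            mapping = {**DEFAULT_SCHEMA, **source}
        else:
            with open(source) as fh:
                mapping = {**DEFAULT_SCHEMA, **(yaml.safe_load(fh) or {})}
        schema = cls(mapping)
        for key in cls.REQUIRED:
            if key not in schema:
                raise ValueError(f"schema missing required key {key!r}")
        return schema


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def read_traits(path: str | Path,
                schema: str | Path | Mapping | None = None,
                tree: Phylogeny | None = None,
                on_unmatched: str = "error") -> TraitDataset:
    """Read a trait/occurrence table into a :class:`TraitDataset`.

    A species appearing on several rows collapses into one entry holding one
    :class:`OccurrenceRecord` per row.  When a ``tree`` is supplied, taxa
    absent from it are handled per ``on_unmatched``: ``"error"`` raises,
    ``"drop"`` removes them with a logged warning.
    """
    if on_unmatched not in {"error", "drop"}:
        raise ValueError("on_unmatched must be 'error' or 'drop'")
    sch = TraitSchema.load(schema)
    df = _read_table(path)
    for key in TraitSchema.REQUIRED:
        if sch[key] not in df.columns:
            raise ValueError(f"required column {sch[key]!r} missing from {path}")

    df = df.copy()
    df["_species"] = df[sch["species"]].astype(str).map(normalise_name)

    if tree is not None:
        tree_tips = set(tree.tip_labels)
        unmatched = sorted(set(df["_species"]) - tree_tips)
        if unmatched:
            if on_unmatched == "error":
                raise ValueError(f"taxa absent from tree: {unmatched}")
            logger.warning("dropping %d taxa absent from tree: %s",
                           len(unmatched), ", ".join(unmatched))
            df = df[df["_species"].isin(tree_tips)]
        if df.empty:
            raise ValueError("no taxa shared between table and tree")

    def opt(row, key):
        col = sch.get(key)
        if col is None or col not in df.columns:
            return None
        val = row[col]
        return None if pd.isna(val) else float(val)

    species, response, occurrences, period, clade, tip_age = [], [], [], [], [], []
    for sp, group in df.groupby("_species", sort=True):
        species.append(sp)
        resp = pd.to_numeric(group[sch["response"]], errors="coerce")
        if resp.isna().any():
            raise ValueError(f"non-numeric response for species {sp!r}")
        if resp.nunique() > 1:
            # several size records: linked occurrences share the species mean
            logger.info("species %s has %d response values; using the mean",
                        sp, resp.nunique())
        response.append(float(resp.mean()))
        recs = []
        for _, row in group.iterrows():
            lat = pd.to_numeric(pd.Series([row[sch["latitude"]]]),
                                errors="coerce").iloc[0]
            if pd.isna(lat):
                raise ValueError(f"non-numeric latitude for species {sp!r}")
            recs.append(OccurrenceRecord(
                palaeolatitude=float(lat),
                mat=opt(row, "mat"), cmmt=opt(row, "cmmt"),
                age=opt(row, "age")))
        occurrences.append(recs)
        first = group.iloc[0]
        pcol, ccol = sch.get("period"), sch.get("clade")
        period.append(str(first[pcol]) if pcol in group.columns
                      and pd.notna(first[pcol]) else None)
        clade.append(str(first[ccol]) if ccol in group.columns
                     and pd.notna(first[ccol]) else None)
        tcol = sch.get("tip_age")
        tip_age.append(float(first[tcol]) if tcol in group.columns
                       and pd.notna(first[tcol]) else np.nan)

    ages = np.array(tip_age)
    return TraitDataset(
        species=species,
        response=np.array(response),
        occurrences=occurrences,
        period=period,
        clade=clade,
        tip_age=None if np.all(np.isnan(ages)) else ages,
    )


def align(dataset: TraitDataset, tree: Phylogeny
          ) -> tuple[TraitDataset, Phylogeny]:
    """Restrict dataset and tree to their shared taxa, in tree-tip order."""
    shared = [t for t in tree.tip_labels if t in set(dataset.species)]
    if not shared:
        raise ValueError("dataset and tree share no taxa")
    pruned = tree.prune_to(shared) if len(shared) < tree.n_tips else tree
    ordered = pruned.tip_labels
    return dataset.subset(ordered), pruned
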