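import warnings

import numpy as np
import pytest

from bergmann import phylo_data, synthetic_data as sd

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture
def three_tip_tree() -> phylo_data.Phylogeny:
    return phylo_data.Phylogeny.from_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def two_tip_tree() -> phylo_data.Phylogeny:
    return phylo_data.Phylogeny.from_newick("(A:1,B:1):0;")


def random_tree(seed: int, n_tips: int = 8, height: float = 50.0):
    return sd.yule_tree(n_tips, seed=seed, root_height=height)


def brute_force_covariance(tree, lam: float = 1.0) -> tuple:
    """Shared-path covariance via explicit ancestor-chain walking —
    independent of the incidence-matrix implementation."""
    tips = tree.tips
    depths = tree.depths()

    def ancestors(node):
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent
        return chain

    n = len(tips)
    V = np.zeros((n, n))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            if i == j:
                V[i, j] = depths[a]
                continue
            common = set(map(id, ancestors(a))) & set(map(id, ancestors(b)))
            mrca = next(nd for nd in ancestors(a) if id(nd) in common)
            V[i, j] = lam * depths[mrca]
    return V, [t.label for t in tips]


def make_dataset(tree, response, latitudes=None, **kw):
    """Minimal TraitDataset aligned with a tree's tip order."""
    labels = tree.tip_labels
    if latitudes is None:
        latitudes = {l: 0.0 for l in labels}
    occ = [[phylo_data.OccurrenceRecord(palaeolatitude=float(latitudes[l]))]
           for l in labels]
    return phylo_data.TraitDataset(
        species=list(labels),
        response=np.asarray([response[l] for l in labels], dtype=float),
        occurrences=occ, **kw)
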