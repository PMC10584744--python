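"""Tree congruence: Robinson-Foulds distance, species collapsing, SH test.

The normalized RF distance between two unrooted trees on the same n leaves
is the size of the symmetric difference of their nontrivial bipartition
sets, as a percentage of the maximum 2(n-3).  The Shimodaira-Hasegawa test
uses RELL resampling of site log-likelihoods with the original centering
convention (each tree's resampled likelihoods centered by its own replicate
mean) to ask which candidate topologies a dataset rejects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import SiteLikelihoodMatrix
from .trees import Node, Tree


@dataclass
class TreeComparisonResult:
    tree_a: str
    tree_b: str
    rf: int
    nrf_pct: float


@dataclass
class SHTestResult:
    dataset: str
    tree_labels: list[str]
    lnL: np.ndarray
    delta: np.ndarray          # lnL_best - lnL_t, >= 0
    p_values: np.ndarray
    n_rell: int
    seed: int


def rf_distance(a: Tree, b: Tree, label_a: str = "a", label_b: str = "b") -> TreeComparisonResult:
    """Robinson-Foulds distance and its normalized percentage."""
    la, lb = a.leaf_labels(), b.leaf_labels()
    if la != lb:
        raise ValueError(f"leaf sets differ: {sorted(la ^ lb)}")
    n = len(la)
    if n < 4:
        raise ValueError("RF distance needs at least 4 leaves")
    sa = set(a.bipartitions())
    sb = set(b.bipartitions())
    rf = len(sa ^ sb)
    return TreeComparisonResult(tree_a=label_a, tree_b=label_b, rf=rf,
                                nrf_pct=100.0 * rf / (2 * (n - 3)))


def collapse_same_species(tree: Tree, species_of: dict[str, str]):
    """Collapse maximal single-species clades to one leaf per species.

    Each maximal clade whose leaves all map to one species becomes a single
    leaf labeled with the species name, keeping the clade's stem length.
    Species whose sequences do not form such a single clade are left
    untouched and returned in the non-monophyletic list.  Operates on the
    tree's rooted representation (root with an outgroup first if orientation
    matters).
    """
    missing = {n.label for n in tree.leaves()} - set(species_of)
    if missing:
        raise ValueError(f"species map missing leaves: {sorted(missing)}")
    tree = tree.copy()
    species_below: dict[int, set[str]] = {}
    leaves_below: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            species_below[id(node)] = {species_of[node.label]}
            leaves_below[id(node)] = 1
        else:
            species_below[id(node)] = set().union(
                *(species_below[id(c)] for c in node.children))
            leaves_below[id(node)] = sum(leaves_below[id(c)] for c in node.children)

    # maximal single-species nodes
    maximal: dict[str, list[Node]] = {}
    total: dict[str, int] = {}
    for node in tree.postorder():
        sp_set = species_below[id(node)]
        if node.is_leaf:
            total[species_of[node.label]] = total.get(species_of[node.label], 0) + 1
        if len(sp_set) == 1:
            parent = node.parent
            if parent is None or len(species_below[id(parent)]) > 1:
                maximal.setdefault(next(iter(sp_set)), []).append(node)

    non_monophyletic = sorted(
        sp for sp, nodes in maximal.items()
        if len(nodes) > 1 or leaves_below[id(nodes[0])] != total[sp])
    for sp, nodes in maximal.items():
        if sp in non_monophyletic:
            continue
        node = nodes[0]
        if node.is_leaf:
            node.label = sp
        else:
            node.children = []
            node.label = sp
    return tree, non_monophyletic


def sh_test(site_lnls: dict[str, SiteLikelihoodMatrix], n_rell: int = 1000,
            seed: int = 0, dataset: str = "") -> SHTestResult:
    """Shimodaira-Hasegawa test over candidate trees on one dataset.

    ``site_lnls`` maps tree label -> per-pattern log-likelihoods computed on
    the *same* packed alignment (identical patterns, weights, partitions).
    RELL resamples sites with replacement within each partition; each tree's
    resampled totals are centered by their own replicate mean, the
    per-replicate test statistic is the centered maximum minus the tree's
    centered value, and p is the proportion of replicates at or above the
    observed delta.  Deterministic given the seed.
    """
    if n_rell < 1:
        raise ValueError("n_rell must be >= 1")
    labels = list(site_lnls)
    mats = [site_lnls[t] for t in labels]
    ref = mats[0]
    for m in mats[1:]:
        if m.pattern_lnl.shape != ref.pattern_lnl.shape or \
                not np.array_equal(m.weights, ref.weights):
            raise ValueError("site log-likelihood matrices have mismatched sites")
    L = np.stack([m.pattern_lnl for m in mats])          # (ntrees, npat)
    obs = L @ ref.weights
    delta = obs.max() - obs

    rng = np.random.default_rng(seed)
    npat = L.shape[1]
    counts = np.zeros((n_rell, npat))
    for pid in np.unique(ref.partition):
        sel = ref.partition == pid
        w = ref.weights[sel]
        n_sites = int(w.sum())
        counts[:, sel] = rng.multinomial(n_sites, w / n_sites, size=n_rell)
    Lstar = counts @ L.T                                  # (n_rell, ntrees)
    centered = Lstar - Lstar.mean(axis=0, keepdims=True)
    dstar = centered.max(axis=1, keepdims=True) - centered  # (n_rell, ntrees)
    p = (dstar >= delta[None, :] - 1e-9).mean(axis=0)
    return SHTestResult(dataset=dataset, tree_labels=labels, lnL=obs,
                        delta=delta, p_values=p, n_rell=n_rell, seed=seed)


def congruence_matrix(trees: dict[str, Tree],
                      site_lnls: dict[str, dict[str, SiteLikelihoodMatrix]],
                      alpha: float = 0.01, n_rell: int = 1000, seed: int = 0):
    """All-pairs nRF matrix and dataset x tree SH p-value matrix.

    ``trees`` maps tree label -> tree (shared leaf sets); ``site_lnls`` maps
    dataset label -> {tree label -> site lnL matrix on that dataset}.
    Returns ``(nrf_df, sh_df, flags_df)`` where flags mark p < alpha.
    """
    labels = list(trees)
    nrf = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            r = rf_distance(trees[a], trees[b], a, b)
            nrf.loc[a, b] = nrf.loc[b, a] = r.nrf_pct
    rows = {}
    for k, (ds, per_tree) in enumerate(site_lnls.items()):
        res = sh_test(per_tree, n_rell=n_rell, seed=seed + 104729 * k, dataset=ds)
        rows[ds] = pd.Series(res.p_values, index=res.tree_labels)
    sh = pd.DataFrame(rows).T if rows else pd.DataFrame()
    flags = sh < alpha if not sh.empty else sh
    return nrf, sh, flags
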