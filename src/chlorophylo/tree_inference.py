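"""Tree search and branch support.

Maximum-likelihood trees come from a neighbor-joining start tree refined by
nearest-neighbor-interchange (NNI) hill climbing with branch-length
re-optimization after every accepted move; the search contract is a local
optimum under NNI.  Branch support is the Felsenstein bootstrap proportion
(exact bipartition recovery) and the transfer bootstrap expectation, which
grants partial credit through the transfer index: the minimum number of
leaves that must switch sides for a reference bipartition to appear in a
replicate tree, normalized by its maximum p-1 for a light side of p leaves.
"""

from __future__ import annotations

import logging

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from . import marker_stats
from .alignment_ops import Alignment, Supermatrix
from .likelihood import (PackedAlignment, log_likelihood,
                         optimize_branch_lengths, pack_alignment)
from .trees import Tree, internal_edges, nni_neighbors, root_with_outgroup  # noqa: F401

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------- distances

def k2p_distance_matrix(aln: Alignment, saturation_cap: float = 5.0) -> tuple[list[str], np.ndarray]:
    """Pairwise K2P distances over alignment rows; saturated pairs capped."""
    labels = list(aln.rows)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ns, ts, tv, _, _ = marker_stats.count_site_patterns(
                aln.rows[labels[i]], aln.rows[labels[j]])
            if ns == 0:
                d = saturation_cap
            else:
                d, saturated = marker_stats.k2p_distance(ts / ns, tv / ns)
                if saturated:
                    d = saturation_cap
            D[i, j] = D[j, i] = d
    return labels, D


def nj_tree(labels: list[str], distances: np.ndarray) -> Tree:
    """Neighbor-joining tree; negative branch lengths clamped to zero."""
    distances = np.asarray(distances, dtype=float)
    if distances.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(distances, distances.T) or np.any(np.diag(distances) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if not np.all(np.isfinite(distances)):
        raise ValueError("distance matrix must be finite")
    distances = 0.5 * (distances + distances.T)   # exact symmetry for skbio
    np.fill_diagonal(distances, 0.0)
    dm = DistanceMatrix(distances, ids=labels)
    newick = str(_skbio_nj(dm))
    tree = Tree.from_newick(newick)
    for node in tree.postorder():
        if node.parent is not None and node.length < 0:
            node.length = 0.0
    return tree


# ------------------------------------------------------------------ ML search

def ml_search(start: Tree, packed: PackedAlignment, models,
              max_sweeps: int = 30, tol: float = 1e-4,
              bl_rounds: int = 2) -> tuple[Tree, float]:
    """NNI hill climbing from ``start``; returns (tree, lnL).

    Each sweep scores both NNI rearrangements of every internal edge (with a
    quick focal-branch-only optimization), accepts the best improving move,
    and re-optimizes all branch lengths; the search stops at a local optimum
    or the sweep cap.  The final lnL never falls below the start lnL.
    """
    tree = start.copy().unroot()
    best = optimize_branch_lengths(tree, packed, models, rounds=bl_rounds)
    for sweep in range(max_sweeps):
        best_candidate, best_score = None, best
        for edge in internal_edges(tree):
            for neigh in nni_neighbors(tree, edge):
                score = log_likelihood(neigh, packed, models)
                if score > best_score:
                    best_candidate, best_score = neigh, score
        if best_candidate is None or best_score <= best + tol:
            # no move clears the tolerance on raw scores, but a move can
            # still be uphill once its branch lengths adapt: re-score every
            # neighborhood with a branch-length pass before declaring a
            # local optimum
            best_candidate, best_score = None, best
            for edge in internal_edges(tree):
                for neigh in nni_neighbors(tree, edge):
                    cand = optimize_branch_lengths(neigh, packed, models,
                                                   rounds=1)
                    if cand > best_score + tol:
                        best_candidate, best_score = neigh, cand
        if best_candidate is None or best_score <= best + tol:
            break
        tree = best_candidate
        best = optimize_branch_lengths(tree, packed, models, rounds=bl_rounds)
        logger.debug("sweep %d: accepted NNI, lnL=%.4f", sweep, best)
    return tree, best


# ------------------------------------------------------------------ bootstrap

def bootstrap_replicates(source: Alignment | Supermatrix, n: int = 1000,
                         seed: int = 0):
    """Column bootstrap; supermatrices resample within each partition.

    Yields resampled objects of the same type as ``source``; partition
    lengths are preserved.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(source, Supermatrix):
        bounds = [(s, e) for _, s, e, _ in source.scheme.parts]
        aln = source.alignment
    else:
        bounds = [(0, source.n_columns)]
        aln = source
    labels = list(aln.rows)
    mat = np.array([list(aln.rows[t]) for t in labels])
    out = []
    for _ in range(n):
        cols = np.concatenate([rng.integers(s, e, size=e - s) for s, e in bounds])
        rows = {t: "".join(mat[i, cols]) for i, t in enumerate(labels)}
        res_aln = Alignment(rows=rows, marker=aln.marker)
        if isinstance(source, Supermatrix):
            out.append(Supermatrix(alignment=res_aln, scheme=source.scheme,
                                   arrangement=source.arrangement))
        else:
            out.append(res_aln)
    return out


def bootstrap_trees(source: Alignment | Supermatrix, models, n: int = 100,
                    seed: int = 0, method: str = "nj",
                    ml_sweeps: int = 2) -> list[Tree]:
    """Trees inferred from bootstrap replicates.

    ``method='nj'`` builds a K2P neighbor-joining tree per replicate (fast,
    the default for support estimation at desk scale); ``method='ml'`` runs
    a short NNI search from the NJ tree under ``models``.
    """
    out = []
    for i, rep in enumerate(bootstrap_replicates(source, n, seed)):
        aln = rep.alignment if isinstance(rep, Supermatrix) else rep
        labels, D = k2p_distance_matrix(aln)
        t = nj_tree(labels, D)
        if method == "ml":
            packed = pack_alignment(rep)
            t, _ = ml_search(t, packed, models, max_sweeps=ml_sweeps, bl_rounds=1)
        out.append(t)
    return out


# ------------------------------------------------------------------- support

def _check_leafsets(ref: Tree, boot_trees) -> list[str]:
    leaves = sorted(ref.leaf_labels())
    for t in boot_trees:
        if sorted(t.leaf_labels()) != leaves:
            raise ValueError("bootstrap tree leaf set differs from reference")
    return leaves


def fbp_support(ref: Tree, boot_trees) -> dict[frozenset, float]:
    """Felsenstein bootstrap proportion per internal reference branch.

    Returns split -> percentage and annotates the reference tree nodes'
    ``support['fbp']``.  Pendant branches carry no support entry.
    """
    _check_leafsets(ref, boot_trees)
    ref_splits = ref.bipartitions()
    counts = {s: 0 for s in ref_splits}
    for t in boot_trees:
        bs = t.bipartitions()
        for s in counts:
            if s in bs:
                counts[s] += 1
    out = {}
    for s, node in ref_splits.items():
        pct = 100.0 * counts[s] / len(boot_trees)
        out[s] = pct
        node.support = dict(node.support or {})
        node.support["fbp"] = pct
    return out


def _split_matrix(tree: Tree, index: dict[str, int]) -> np.ndarray:
    """Indicator matrix (one row per edge, incl. pendant) of leafsets below."""
    rows = []
    below = {}
    for node in tree.postorder():
        if node.is_leaf:
            v = np.zeros(len(index), dtype=bool)
            v[index[node.label]] = True
        else:
            v = np.zeros(len(index), dtype=bool)
            for ch in node.children:
                v |= below[id(ch)]
        below[id(node)] = v
        if node.parent is not None:
            rows.append(v)
    return np.array(rows)


def transfer_index(split: np.ndarray, boot_matrix: np.ndarray) -> int:
    """Minimum leaves to move so ``split`` matches some edge of the replicate.

    ``split`` is a boolean indicator over the common leaf order and
    ``boot_matrix`` the replicate's edge indicator matrix; the transfer
    index is the minimum Hamming distance to any edge bipartition, taking
    the better orientation of each.
    """
    h = (boot_matrix != split[None, :]).sum(axis=1)
    n = split.size
    return int(np.minimum(h, n - h).min())


def tbe_support(ref: Tree, boot_trees) -> dict[frozenset, float]:
    """Transfer bootstrap expectation per internal reference branch.

    support = 100 * (1 - mean over replicates of delta/(p-1)) where p is the
    light-side size of the branch's bipartition.  Equals FBP exactly on
    cherries (p = 2).  Annotates ``support['tbe']`` on the reference nodes.
    """
    leaves = _check_leafsets(ref, boot_trees)
    index = {t: i for i, t in enumerate(leaves)}
    n = len(leaves)
    ref_splits = ref.bipartitions()
    split_vecs = {}
    for s in ref_splits:
        v = np.zeros(n, dtype=bool)
        for leaf in s:
            v[index[leaf]] = True
        split_vecs[s] = v
    deficits = {s: 0.0 for s in ref_splits}
    for t in boot_trees:
        M = _split_matrix(t, index)
        for s, v in split_vecs.items():
            p = min(len(s), n - len(s))
            delta = transfer_index(v, M)
            deficits[s] += delta / (p - 1)
    out = {}
    for s, node in ref_splits.items():
        pct = 100.0 * (1.0 - deficits[s] / len(boot_trees))
        out[s] = pct
        node.support = dict(node.support or {})
        node.support["tbe"] = pct
    return out
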