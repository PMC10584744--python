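"""Felsenstein pruning likelihood, parameter optimization, model selection.

Alignments are packed into site patterns (identical columns deduplicated
with multiplicities) before any likelihood work; every log-likelihood here
is exact w.r.t. the unpacked alignment.  Rate variation enters as a mixture
over the +I spike and the discrete-Gamma categories, combined per pattern in
log space with per-category scaling to avoid underflow.  IUPAC ambiguity
codes become partial leaf likelihoods over the compatible bases; gaps are
fully missing (all-ones).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from .alignment_ops import Alignment, Supermatrix
from .models import FAMILIES, SubstitutionModel, aicc
from .trees import Tree

logger = logging.getLogger(__name__)

#: IUPAC nucleotide -> bitmask over (A, C, G, T)
_CODE = {"A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
         "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
         "B": 14, "D": 13, "H": 11, "V": 7, "N": 15, "-": 15, "?": 15}

_MASK_TO_PARTIAL = np.zeros((16, 4))
for _m in range(16):
    for _b in range(4):
        if _m >> _b & 1:
            _MASK_TO_PARTIAL[_m, _b] = 1.0
_MASK_TO_PARTIAL[0] = 1.0  # defensive: unknown char behaves as missing

MIN_BRANCH, MAX_BRANCH = 1e-8, 20.0


@dataclass
class PackedAlignment:
    """Pattern-compressed alignment shared by all trees being scored."""

    taxa: list[str]
    codes: np.ndarray            # (n_taxa, n_patterns) uint8 bitmasks
    weights: np.ndarray          # (n_patterns,) multiplicities
    partition: np.ndarray        # (n_patterns,) partition index
    partition_names: list[str]
    n_sites: int

    @property
    def n_patterns(self) -> int:
        return self.codes.shape[1]


@dataclass
class SiteLikelihoodMatrix:
    """Per-pattern log-likelihoods for one tree on one packed alignment."""

    pattern_lnl: np.ndarray
    weights: np.ndarray
    partition: np.ndarray

    @property
    def total(self) -> float:
        return float(self.pattern_lnl @ self.weights)


@dataclass
class ModelFit:
    model: SubstitutionModel
    lnL: float
    k: int
    aicc: float
    tree: Tree | None = None


def _encode_rows(rows: dict[str, str], taxa: list[str]) -> np.ndarray:
    mat = np.zeros((len(taxa), len(next(iter(rows.values())))), dtype=np.uint8)
    for i, t in enumerate(taxa):
        seq = rows[t].upper()
        mat[i] = [_CODE.get(c, 15) for c in seq]
    return mat


def pack_alignment(source: Alignment | Supermatrix,
                   taxa: list[str] | None = None) -> PackedAlignment:
    """Compress an alignment (or partitioned supermatrix) into site patterns.

    Patterns never merge across partitions so per-partition models stay
    applicable after compression.
    """
    if isinstance(source, Supermatrix):
        aln = source.alignment
        bounds = [(m, s, e) for m, s, e, _ in source.scheme.parts]
    else:
        aln = source
        bounds = [(aln.marker or "all", 0, aln.n_columns)]
    taxa = list(taxa or aln.rows)
    full = _encode_rows(aln.rows, taxa)

    code_cols, weights, part_ids, names = [], [], [], []
    for pid, (name, s, e) in enumerate(bounds):
        names.append(name)
        block = full[:, s:e]
        uniq, counts = np.unique(block, axis=1, return_counts=True)
        code_cols.append(uniq)
        weights.append(counts)
        part_ids.append(np.full(uniq.shape[1], pid))
    return PackedAlignment(
        taxa=taxa,
        codes=np.concatenate(code_cols, axis=1),
        weights=np.concatenate(weights).astype(float),
        partition=np.concatenate(part_ids),
        partition_names=names,
        n_sites=aln.n_columns)


def _edge_probability_stack(model: SubstitutionModel, lengths: np.ndarray,
                            rates: np.ndarray) -> np.ndarray:
    """P matrices for every (edge, rate category) in one vectorized pass."""
    evals, right, left = model._decomposition()
    expo = np.exp(evals[None, None, :] * lengths[:, None, None] * rates[None, :, None])
    P = np.einsum("ij,ecj,jk->ecik", right, expo, left)
    return np.clip(P, 0.0, None)


def _invariant_site_likelihood(codes: np.ndarray, model: SubstitutionModel) -> np.ndarray:
    """Per-pattern likelihood of the rate-zero class (constant-site check)."""
    mask_all = np.bitwise_and.reduce(codes, axis=0)
    inv_l = _MASK_TO_PARTIAL[mask_all] @ model.base_frequencies
    return np.where(mask_all > 0, inv_l, 0.0)


def _pattern_lnl_one_model(tree: Tree, codes: np.ndarray, taxa_index: dict[str, int],
                           model: SubstitutionModel) -> np.ndarray:
    """Pruning over one partition's patterns under one model.

    Partials are kept as (n_categories, 4, n_patterns) so child messages are
    batched 4x4 matrix products; per-node rescaling guards underflow.
    """
    rates = model.category_rates()
    ncat = len(rates)
    npat = codes.shape[1]
    pi = model.base_frequencies

    post = tree.postorder()
    edge_index: dict[int, int] = {}
    lengths = []
    for node in post:
        if node.parent is not None:
            edge_index[id(node)] = len(lengths)
            lengths.append(max(node.length, 0.0))
    P = _edge_probability_stack(model, np.asarray(lengths), rates)

    partial: dict[int, np.ndarray] = {}
    log_scale = np.zeros((ncat, npat))
    for node in post:
        if node.is_leaf:
            if node.label not in taxa_index:
                raise ValueError(f"tree leaf {node.label!r} absent from alignment")
            lp = _MASK_TO_PARTIAL[codes[taxa_index[node.label]]].T   # (4, npat)
            partial[id(node)] = np.broadcast_to(lp, (ncat, 4, npat))
        else:
            acc = None
            for ch in node.children:
                msg = P[edge_index[id(ch)]] @ partial[id(ch)]        # (ncat,4,npat)
                acc = msg if acc is None else acc * msg
                del partial[id(ch)]
            mx = acc.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            log_scale += np.log(mx)
            partial[id(node)] = acc / mx[:, None, :]

    root_partial = partial[id(tree.root)]                            # (ncat,4,npat)
    cat_log_l = np.log(np.clip(np.einsum("i,cip->cp", pi, root_partial),
                               1e-300, None)) + log_scale

    terms = [cat_log_l + np.log((1.0 - model.p_inv) / ncat)]
    if model.p_inv > 0:
        with np.errstate(divide="ignore"):
            terms.append(np.log(model.p_inv
                                * _invariant_site_likelihood(codes, model))[None, :])
    stacked = np.concatenate(terms, axis=0)
    return logsumexp(stacked, axis=0)


def site_log_likelihoods(tree: Tree, packed: PackedAlignment,
                         models) -> SiteLikelihoodMatrix:
    """Per-pattern log-likelihoods of ``tree``.

    ``models`` is a single SubstitutionModel or a list with one model per
    partition of the packed alignment.
    """
    if isinstance(models, SubstitutionModel):
        models = [models] * len(packed.partition_names)
    if len(models) != len(packed.partition_names):
        raise ValueError("one model required per partition")
    if any(m is None for m in models):
        raise ValueError("partition without a model")
    tree_leaves = tree.leaf_labels()
    if tree_leaves != set(packed.taxa):
        raise ValueError(
            f"tree/alignment taxon mismatch: {sorted(tree_leaves ^ set(packed.taxa))}")
    taxa_index = {t: i for i, t in enumerate(packed.taxa)}
    lnl = np.empty(packed.n_patterns)
    for pid, model in enumerate(models):
        sel = packed.partition == pid
        lnl[sel] = _pattern_lnl_one_model(tree, packed.codes[:, sel], taxa_index, model)
    return SiteLikelihoodMatrix(pattern_lnl=lnl, weights=packed.weights,
                                partition=packed.partition)


def log_likelihood(tree: Tree, packed: PackedAlignment, models) -> float:
    return site_log_likelihoods(tree, packed, models).total


def partitioned_log_likelihood(tree: Tree, sm: Supermatrix,
                               packed: PackedAlignment | None = None) -> SiteLikelihoodMatrix:
    """Total and per-pattern lnL of a supermatrix under its partition models."""
    models = [p[3] for p in sm.scheme.parts]
    if any(m is None for m in models):
        missing = [p[0] for p in sm.scheme.parts if p[3] is None]
        raise ValueError(f"partitions without models: {missing}")
    if packed is None:
        packed = pack_alignment(sm)
    return site_log_likelihoods(tree, packed, models)


# ------------------------------------------------------------------ fitting

class _BranchWorkspace:
    """Inner/outer message cache giving O(one edge) profile likelihoods.

    For an edge (u parent, v child) the site likelihood factorizes as
    sum_i pi_i * U_v[i] * (P(t) D_v)[i] where D_v is the ordinary pruning
    partial below v and U_v collects the data outside the subtree of v as a
    function of the state at u; only P(t) depends on the branch length, so
    Brent iterations cost a single 4x4 product per category.
    """

    def __init__(self, tree: Tree, packed: PackedAlignment, models):
        if isinstance(models, SubstitutionModel):
            models = [models] * len(packed.partition_names)
        self.tree = tree
        self.packed = packed
        self.models = models
        taxa_index = {t: i for i, t in enumerate(packed.taxa)}
        self.parts = []
        for pid, model in enumerate(models):
            sel = packed.partition == pid
            codes = packed.codes[:, sel]
            rates = model.category_rates()
            inv_l = _invariant_site_likelihood(codes, model) if model.p_inv > 0 else None
            self.parts.append({
                "model": model, "rates": rates, "codes": codes,
                "weights": packed.weights[sel], "inv_l": inv_l,
                "leaf": {t: _MASK_TO_PARTIAL[codes[i]].T for t, i in taxa_index.items()},
            })

    def refresh(self) -> None:
        """Recompute all messages for the tree's current branch lengths."""
        post = self.tree.postorder()
        edge_nodes = [n for n in post if n.parent is not None]
        lengths = np.array([max(n.length, 0.0) for n in edge_nodes])
        eidx = {id(n): i for i, n in enumerate(edge_nodes)}
        self._eidx = eidx
        for part in self.parts:
            model, rates = part["model"], part["rates"]
            ncat, npat = len(rates), part["codes"].shape[1]
            P = _edge_probability_stack(model, lengths, rates)
            D, Dlog, M = {}, {}, {}
            for node in post:
                if node.is_leaf:
                    D[id(node)] = np.broadcast_to(part["leaf"][node.label],
                                                  (ncat, 4, npat))
                    Dlog[id(node)] = np.zeros((ncat, npat))
                else:
                    acc, lg = None, 0.0
                    for ch in node.children:
                        acc = M[id(ch)] if acc is None else acc * M[id(ch)]
                        lg = lg + Dlog[id(ch)]
                    mx = acc.max(axis=1)
                    mx = np.where(mx > 0, mx, 1.0)
                    D[id(node)] = acc / mx[:, None, :]
                    Dlog[id(node)] = lg + np.log(mx)
                if node.parent is not None:
                    M[id(node)] = P[eidx[id(node)]] @ D[id(node)]
            U, Ulog = {}, {}
            for node in reversed(post):                     # preorder
                for ch in node.children:
                    if node.parent is None:
                        acc, lg = None, 0.0
                    else:
                        # reversibility: pi_i P[i,k] = pi_k P[k,i] lets the
                        # outward message reuse the same orientation as M
                        acc = P[eidx[id(node)]] @ U[id(node)]
                        lg = Ulog[id(node)]
                    for sib in node.children:
                        if sib is ch:
                            continue
                        acc = M[id(sib)] if acc is None else acc * M[id(sib)]
                        lg = lg + Dlog[id(sib)]
                    if acc is None:                          # root with one child
                        acc = np.ones((ncat, 4, npat))
                        lg = np.zeros((ncat, npat))
                    mx = acc.max(axis=1)
                    mx = np.where(mx > 0, mx, 1.0)
                    U[id(ch)] = acc / mx[:, None, :]
                    Ulog[id(ch)] = lg + np.log(mx)
            part["D"], part["Dlog"] = D, Dlog
            part["U"], part["Ulog"] = U, Ulog

    def edge_lnl(self, node, t: float) -> float:
        """Total lnL with the edge above ``node`` set to length ``t``."""
        total = 0.0
        for part in self.parts:
            model, rates = part["model"], part["rates"]
            ncat = len(rates)
            Pt = _edge_probability_stack(model, np.array([t]), rates)[0]
            Mv = Pt @ part["D"][id(node)]
            Lc = np.einsum("i,cip,cip->cp", model.base_frequencies,
                           part["U"][id(node)], Mv)
            cat_log = np.log(np.clip(Lc, 1e-300, None)) \
                + part["Ulog"][id(node)] + part["Dlog"][id(node)]
            terms = [cat_log + np.log((1.0 - model.p_inv) / ncat)]
            if part["inv_l"] is not None:
                with np.errstate(divide="ignore"):
                    terms.append(np.log(model.p_inv * part["inv_l"])[None, :])
            site = logsumexp(np.concatenate(terms, axis=0), axis=0)
            total += float(site @ part["weights"])
        return total


def optimize_branch_lengths(tree: Tree, packed: PackedAlignment, models,
                            rounds: int = 1) -> float:
    """Coordinate ascent over branch lengths (bounded Brent per branch).

    The lnL is non-decreasing across updates: a proposal is kept only when
    it improves on the current length.
    """
    ws = _BranchWorkspace(tree, packed, models)
    best = None
    for _ in range(rounds):
        for node in tree.postorder():
            if node.parent is None:
                continue
            ws.refresh()
            cur = ws.edge_lnl(node, max(node.length, MIN_BRANCH))
            if best is None:
                best = cur

            def neg(t: float) -> float:
                return -ws.edge_lnl(node, t)

            res = minimize_scalar(neg, bounds=(MIN_BRANCH, MAX_BRANCH),
                                  method="bounded",
                                  options={"xatol": 1e-7, "maxiter": 40})
            if -res.fun > cur:
                node.length = float(res.x)
                best = -res.fun
            else:
                best = cur
    return log_likelihood(tree, packed, models) if best is None else best


def _build_model(family: str, theta: np.ndarray, with_inv: bool, with_gamma: bool,
                 equal_freqs: bool) -> SubstitutionModel:
    """Decode an unconstrained parameter vector into a model."""
    i = 0
    n_exch = {"JC": 0, "K80": 1, "HKY": 1, "TIM1": 3, "GTR": 5}[family]
    ex = np.exp(np.clip(theta[i:i + n_exch], -10, 10))
    i += n_exch
    if family == "JC":
        exch = np.ones(6)
    elif family in ("K80", "HKY"):
        exch = np.array([1.0, ex[0], 1.0, 1.0, ex[0], 1.0])
    elif family == "TIM1":
        exch = np.array([1.0, ex[0], ex[2], ex[2], ex[1], 1.0])  # AC=GT=1, AT=CG
    else:
        exch = np.array([ex[0], ex[1], ex[2], ex[3], ex[4], 1.0])  # GT reference
    if equal_freqs:
        pi = np.full(4, 0.25)
    else:
        logits = np.concatenate([np.clip(theta[i:i + 3], -12, 12), [0.0]])
        i += 3
        pi = np.exp(logits)
        pi /= pi.sum()
    p_inv = 0.0
    if with_inv:
        p_inv = 0.98 / (1.0 + np.exp(-np.clip(theta[i], -30, 30)))
        i += 1
    alpha = None
    if with_gamma:
        alpha = float(np.exp(np.clip(theta[i], -4, 5)))
        i += 1
    return SubstitutionModel(family=family, exchangeabilities=exch,
                             base_frequencies=pi, p_inv=p_inv, gamma_shape=alpha)


def _init_theta(family: str, packed: PackedAlignment, with_inv: bool,
                with_gamma: bool, equal_freqs: bool) -> np.ndarray:
    n_exch = {"JC": 0, "K80": 1, "HKY": 1, "TIM1": 3, "GTR": 5}[family]
    theta = [0.0] * n_exch
    if n_exch >= 1:
        theta[0] = np.log(2.0)        # transitions usually faster
    if not equal_freqs:
        counts = np.zeros(4)
        part = _MASK_TO_PARTIAL[packed.codes]
        single = part.sum(axis=2) == 1          # unambiguous cells
        for b in range(4):
            counts[b] = (part[:, :, b] * single * packed.weights[None, :]).sum()
        counts = np.clip(counts, 1.0, None)
        pi = counts / counts.sum()
        theta += list(np.log(pi[:3] / pi[3]))
    if with_inv:
        theta.append(-1.0)
    if with_gamma:
        theta.append(0.0)
    return np.asarray(theta, dtype=float)


def optimize(tree: Tree, packed: PackedAlignment, model: SubstitutionModel,
             optimize_model: bool = True, tol: float = 1e-6,
             max_rounds: int = 10, n_columns: int | None = None) -> tuple[ModelFit, Tree]:
    """Joint coordinate ascent over branch lengths and model parameters.

    Alternates full branch-length sweeps with bounded multivariate
    optimization of the substitution parameters until the lnL improvement
    drops below ``tol`` or the round cap is reached.  The topology is fixed.
    Returns the fit (with AICc computed over ``n_columns`` sites, branch
    lengths counted as free parameters) and the updated tree.
    """
    tree = tree.copy()
    with_inv = model.p_inv > 0
    with_gamma = model.gamma_shape is not None
    equal_freqs = model.family in ("JC", "K80")

    cur = log_likelihood(tree, packed, model)
    if not np.isfinite(cur):
        raise ValueError("non-finite log-likelihood at the starting point")
    theta = None
    for _ in range(max_rounds):
        prev = cur
        cur = optimize_branch_lengths(tree, packed, model)
        if optimize_model and (with_inv or with_gamma or model.family != "JC"):
            if theta is None:
                theta = _init_theta(model.family, packed, with_inv, with_gamma,
                                    equal_freqs)

            def neg(th: np.ndarray) -> float:
                m = _build_model(model.family, th, with_inv, with_gamma, equal_freqs)
                return -log_likelihood(tree, packed, m)

            res = minimize(neg, theta, method="L-BFGS-B",
                           options={"maxiter": 60, "ftol": 1e-10})
            if -res.fun > cur:
                theta = res.x
                model = _build_model(model.family, theta, with_inv, with_gamma,
                                     equal_freqs)
                cur = -res.fun
        if cur - prev < tol:
            break
    n_leaves = len(tree.leaf_labels())
    k = model.n_free_parameters + (2 * n_leaves - 3)
    n = n_columns if n_columns is not None else int(packed.weights.sum())
    fit = ModelFit(model=model, lnL=cur, k=k,
                   aicc=aicc(cur, k, n) if n > k + 1 else np.inf, tree=tree)
    return fit, tree


def select_model(aln: Alignment, guide_tree: Tree,
                 families=FAMILIES,
                 variants=((False, False), (True, False), (False, True), (True, True)),
                 tol: float = 1e-4, max_rounds: int = 4):
    """AICc model selection over families x {plain, +I, +G, +I+G}.

    Every candidate is fitted on the fixed guide-tree topology with branch
    lengths re-optimized; candidates whose parameter count reaches the AICc
    singularity (n <= k+1) are skipped with a warning.  Returns
    ``(best_fit, table)`` where the table is a list of fits sorted by AICc
    (ties broken by fewer parameters).
    """
    packed = pack_alignment(aln)
    n = aln.n_columns
    fits: list[ModelFit] = []
    for family in families:
        for with_inv, with_gamma in variants:
            start = SubstitutionModel(
                family=family,
                p_inv=0.25 if with_inv else 0.0,
                gamma_shape=1.0 if with_gamma else None)
            n_leaves = len(guide_tree.leaf_labels())
            k = start.n_free_parameters + (2 * n_leaves - 3)
            if n <= k + 1:
                logger.warning("skipping %s%s%s: n=%d <= k+1=%d", family,
                               "+I" if with_inv else "", "+G" if with_gamma else "",
                               n, k + 1)
                continue
            fit, _ = optimize(guide_tree, packed, start, tol=tol,
                              max_rounds=max_rounds, n_columns=n)
            fits.append(fit)
    fits.sort(key=lambda f: (f.aicc, f.k))
    return fits[0], fits
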