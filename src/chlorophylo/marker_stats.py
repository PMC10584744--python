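"""Composition and pairwise evolutionary statistics for barcode markers.

Implements GC content, the Kimura two-parameter (K2P) distance with its
transition/transversion decomposition, and the disparity index I_D with its
Monte-Carlo homogeneity test, plus within/between-genus aggregation.

Site handling follows pairwise deletion: a column is usable for a pair only
when both characters are unambiguous bases (A, C, G, T).  Transitions are
A<->G and C<->T; every other differing pair is a transversion.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i


def _encode(residues: str) -> np.ndarray:
    """Map a nucleotide string to base indices; non-ACGT become -1."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _BASE_INDEX[arr]


@dataclass
class PairwiseStats:
    """K2P / Ts-Tv / disparity record for one sequence pair."""

    seq_a: str
    seq_b: str
    n_sites: int
    P: float                  # transition proportion
    Q: float                  # transversion proportion
    d_k2p: float
    s_component: float        # transition part of the distance
    v_component: float        # transversion part
    ts_tv_ratio: float        # s / v, nan when v == 0
    Nd: int                   # differing usable sites
    Dc: float                 # composition distance
    I_D: float                # disparity index
    p_value: float | None = None
    saturated: bool = False


def gc_content(residues: str) -> float:
    """GC percentage over unambiguous bases; gaps/ambiguity codes excluded."""
    if not residues:
        raise ValueError("empty sequence")
    enc = _encode(residues)
    usable = enc >= 0
    denom = int(usable.sum())
    if denom == 0:
        raise ValueError("no unambiguous A/C/G/T residues; GC content undefined")
    gc = int(np.isin(enc, (1, 2)).sum())  # C=1, G=2
    return 100.0 * gc / denom


def count_site_patterns(a: str, b: str):
    """Usable-site tally for a pair drawn from a common alignment.

    Returns ``(n_sites, n_transitions, n_transversions, x, y)`` where x and
    y are length-4 base-count vectors (A, C, G, T order) over usable sites.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal sequence lengths: {len(a)} vs {len(b)}")
    ea, eb = _encode(a), _encode(b)
    usable = (ea >= 0) & (eb >= 0)
    ua, ub = ea[usable], eb[usable]
    n_sites = int(usable.sum())
    diff = ua != ub
    # transitions are within the purine pair {A,G}={0,2} and pyrimidine {C,T}={1,3}
    transition = diff & ((ua % 2) == (ub % 2))
    n_ts = int(transition.sum())
    n_tv = int(diff.sum()) - n_ts
    x = np.bincount(ua, minlength=4).astype(float)
    y = np.bincount(ub, minlength=4).astype(float)
    return n_sites, n_ts, n_tv, x, y


def k2p_distance(P: float, Q: float) -> tuple[float, bool]:
    """K2P distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).

    Returns ``(distance, saturated)``; saturation (a log argument <= 0)
    yields ``(inf, True)``.
    """
    if P < 0 or Q < 0:
        raise ValueError("proportions must be non-negative")
    if P + Q > 1:
        raise ValueError("P + Q must not exceed 1")
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return math.inf, True
    return -0.5 * math.log(w1) - 0.25 * math.log(w2), False


def k2p_components(P: float, Q: float) -> tuple[float, float, bool]:
    """Transition (s) and transversion (v) parts of the K2P distance.

    s = -1/2 ln(1-2P-Q) + 1/4 ln(1-2Q); v = -1/2 ln(1-2Q); d = s + v.
    """
    if P < 0 or Q < 0:
        raise ValueError("proportions must be non-negative")
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return math.inf, math.inf, True
    s = -0.5 * math.log(w1) + 0.25 * math.log(w2)
    v = -0.5 * math.log(w2)
    return s, v, False


def ts_tv_ratio(P: float, Q: float) -> float:
    """Per-pair Ts/Tv ratio R = s/v from the K2P components; nan when v=0."""
    s, v, saturated = k2p_components(P, Q)
    if saturated:
        return math.inf
    if v == 0.0:
        return math.nan
    return s / v


def disparity_index(a: str, b: str) -> tuple[float, float, int]:
    """Disparity index I_D = Dc - Nd with Dc = 1/2 sum_i (x_i - y_i)^2.

    x, y are base-count vectors over usable sites and Nd is the count of
    usable sites where the sequences differ.  Positive I_D indicates more
    compositional difference than the observed number of substitutions
    explains under a homogeneous process.
    """
    n_sites, n_ts, n_tv, x, y = count_site_patterns(a, b)
    Dc = 0.5 * float(((x - y) ** 2).sum())
    Nd = n_ts + n_tv
    return Dc - Nd, Dc, Nd


def disparity_test(a: str, b: str, n_reps: int = 1000, seed: int = 0) -> float:
    """Monte-Carlo homogeneity test for the disparity index.

    Null replicates swap the two observed states between the sequences,
    independently with probability 1/2, at every differing usable site
    (identical sites contribute nothing to Dc or Nd and are left alone).
    The add-one estimator p = (1 + #{I_D* >= I_D_obs}) / (1 + n_reps)
    avoids p = 0.  Deterministic given the seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(a) != len(b):
        raise ValueError("unequal sequence lengths")
    ea, eb = _encode(a), _encode(b)
    usable = (ea >= 0) & (eb >= 0)
    ua, ub = ea[usable], eb[usable]
    diff = ua != ub
    m = int(diff.sum())
    if m == 0:
        return 1.0
    du, dv = ua[diff], ub[diff]
    # identical sites cancel in x - y, so
    # x - y = sum over differing sites of +-(e_u - e_v); Nd is swap-invariant
    U = np.zeros((m, 4))
    V = np.zeros((m, 4))
    U[np.arange(m), du] = 1.0
    V[np.arange(m), dv] = 1.0
    D = U - V                                    # (m, 4)
    obs = 0.5 * float((D.sum(axis=0) ** 2).sum())  # observed Dc; I_D = Dc - m
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_reps, m))
    null_dc = 0.5 * ((signs @ D) ** 2).sum(axis=1)
    # Nd cancels: compare Dc* against observed Dc directly
    n_ge = int((null_dc >= obs - 1e-12).sum())
    return (1 + n_ge) / (1 + n_reps)


def pairwise_stats(seq_a, seq_b, n_reps: int = 1000, seed: int = 0,
                   with_test: bool = True) -> PairwiseStats:
    """Full pairwise record for two aligned MarkerSequence objects."""
    n_sites, n_ts, n_tv, x, y = count_site_patterns(seq_a.residues, seq_b.residues)
    if n_sites == 0:
        raise ValueError(f"no usable sites for pair {seq_a.accession}/{seq_b.accession}")
    P, Q = n_ts / n_sites, n_tv / n_sites
    d, saturated = k2p_distance(P, Q)
    s, v, _ = k2p_components(P, Q)
    Dc = 0.5 * float(((x - y) ** 2).sum())
    Nd = n_ts + n_tv
    p = disparity_test(seq_a.residues, seq_b.residues, n_reps, seed) if with_test else None
    return PairwiseStats(
        seq_a=seq_a.accession, seq_b=seq_b.accession, n_sites=n_sites,
        P=P, Q=Q, d_k2p=d, s_component=s, v_component=v,
        ts_tv_ratio=ts_tv_ratio(P, Q), Nd=Nd, Dc=Dc, I_D=Dc - Nd,
        p_value=p, saturated=saturated)


def aggregate_stats(dataset, alignments: dict, alpha: float = 0.05,
                    n_reps: int = 1000, seed: int = 0):
    """Within/between-genus pairwise statistics per marker.

    ``alignments`` maps marker -> Alignment whose rows are keyed by
    accession.  Returns ``(pair_table, group_table)`` as pandas DataFrames:
    one row per pair (with a within/between flag, Ts/Tv and K2P columns
    matching a Ts/Tv-vs-distance scatter) and per-group summaries of the
    K2P distance plus the percentage of pairs whose disparity test is
    significant at ``alpha``.
    """
    import pandas as pd

    pair_rows = []
    for mi, marker in enumerate(dataset.markers):
        aln = alignments[marker]
        seqs = [s for s in dataset.by_marker(marker) if s.accession in aln.rows]
        by_genus: dict[str, int] = {}
        for s in seqs:
            by_genus[s.genus] = by_genus.get(s.genus, 0) + 1
        for g, n in by_genus.items():
            if n < 2:
                logger.info("marker %s: genus %s has %d sequence(s); no within pairs",
                            marker, g, n)
        for k, (sa, sb) in enumerate(itertools.combinations(seqs, 2)):
            aligned_a = aln.rows[sa.accession]
            aligned_b = aln.rows[sb.accession]
            ps = pairwise_stats(
                type(sa)(sa.accession, sa.species, sa.genus, sa.marker, aligned_a),
                type(sb)(sb.accession, sb.species, sb.genus, sb.marker, aligned_b),
                n_reps=n_reps, seed=seed + 7919 * mi + k)
            pair_rows.append({
                "marker": marker, "seq_a": sa.accession, "seq_b": sb.accession,
                "genus_a": sa.genus, "genus_b": sb.genus,
                "scope": "within" if sa.genus == sb.genus else "between",
                "group": sa.genus if sa.genus == sb.genus
                         else "--".join(sorted((sa.genus, sb.genus))),
                "d_k2p": ps.d_k2p, "ts_tv": ps.ts_tv_ratio, "I_D": ps.I_D,
                "p_value": ps.p_value, "significant": ps.p_value < alpha,
            })
    pairs = pd.DataFrame(pair_rows)
    if pairs.empty:
        return pairs, pd.DataFrame()
    grouped = pairs.groupby(["marker", "scope", "group"], as_index=False).agg(
        n_pairs=("d_k2p", "size"), mean_k2p=("d_k2p", "mean"),
        min_k2p=("d_k2p", "min"), max_k2p=("d_k2p", "max"),
        pct_significant_id=("significant", lambda s: 100.0 * s.mean()))
    return pairs, grouped
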