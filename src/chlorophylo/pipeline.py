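"""End-to-end orchestration: filter -> stats -> trim -> infer -> concatenate
-> compare, with explicit seeds and table outputs.

The congruence stage mirrors the classic multi-marker congruency layout:
(a) an all-pairs normalized Robinson-Foulds matrix over single-marker and
supermatrix trees, (b) a dataset x tree SH-test p-value matrix, and (c) the
same after collapsing conspecific tips.  One representative sequence per
species per marker feeds tree inference and concatenation; the mechanical
selection rule (longest sequence, ties to the smallest accession) replaces
the manual best-supported-clade choice a curator would make, and is flagged
in reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

from . import tree_compare
from .alignment_ops import (Alignment, all_arrangements, concatenate,
                            trim_gappy_columns)
from .likelihood import (ModelFit, log_likelihood, optimize,
                         optimize_branch_lengths, pack_alignment,
                         site_log_likelihoods)
from .models import SubstitutionModel
from .seq_data import MarkerDataset
from .tree_inference import (bootstrap_trees, fbp_support, k2p_distance_matrix,
                             ml_search, nj_tree, root_with_outgroup,
                             tbe_support)
from .trees import Tree

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    markers: list[str] = field(default_factory=lambda: ["18S", "ITS", "rbcL"])
    outgroup_species: set[str] = field(default_factory=set)
    e_max: float = 1e-15
    id_min_pct: float = 40.0
    cov_min_pct: float = 40.0
    gap_threshold: float = 0.70
    min_retained: float = 0.80
    model_families: tuple = ("GTR",)       # candidate families for fitting
    select_models: bool = False            # full AICc scan vs direct +I+G fit
    n_bootstrap: int = 1000
    bootstrap_method: str = "nj"
    n_rell: int = 1000
    alpha_heterogeneity: float = 0.05
    alpha_sh: float = 0.01
    support_threshold: float = 70.0
    ml_sweeps: int = 30
    seed: int = 0
    out_dir: str | None = None

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["outgroup_species"] = sorted(self.outgroup_species)
        return d


@dataclass
class SingleMarkerResult:
    marker: str
    alignment: Alignment           # trimmed representative alignment
    removed_columns: list[int]
    fit: ModelFit
    tree: Tree                     # rooted, with FBP/TBE annotations
    unrooted_tree: Tree
    fbp: dict
    tbe: dict


@dataclass
class SupermatrixResult:
    name: str
    supermatrix: object
    tree: Tree
    lnL: float
    arrangement_lnls: dict[tuple, float]


def _species_label(species: str) -> str:
    return species.replace(" ", "_")


def select_representatives(dataset: MarkerDataset) -> dict[str, dict[str, str]]:
    """Per marker: species label -> representative accession.

    The representative is the longest sequence (gaps excluded); ties go to
    the lexicographically smallest accession.
    """
    out: dict[str, dict[str, str]] = {}
    for marker in dataset.markers:
        best: dict[str, tuple[int, str]] = {}
        for s in dataset.by_marker(marker):
            ln = len(s.residues.replace("-", ""))
            key = _species_label(s.species)
            cur = best.get(key)
            if cur is None or (-ln, s.accession) < (-cur[0], cur[1]):
                best[key] = (ln, s.accession)
        out[marker] = {sp: acc for sp, (ln, acc) in best.items()}
    return out


def representative_alignment(aln: Alignment, mapping: dict[str, str]) -> Alignment:
    rows = {}
    for sp, acc in mapping.items():
        if acc not in aln.rows:
            raise ValueError(f"representative {acc} missing from alignment")
        rows[sp] = aln.rows[acc]
    return Alignment(rows=rows, marker=aln.marker)


def _fit_marker_model(aln: Alignment, guide: Tree, config: PipelineConfig,
                      family: str = "GTR") -> tuple[ModelFit, Tree]:
    packed = pack_alignment(aln)
    if config.select_models:
        from .likelihood import select_model
        best, _table = select_model(aln, guide, families=config.model_families)
        return best, best.tree
    start = SubstitutionModel(family=family, p_inv=0.25, gamma_shape=1.0)
    fit, tree = optimize(guide, packed, start, tol=1e-4, max_rounds=4,
                         n_columns=aln.n_columns)
    return fit, tree


def run_single_marker(dataset: MarkerDataset, alignments: dict[str, Alignment],
                      config: PipelineConfig) -> dict[str, SingleMarkerResult]:
    """Trim, fit, and infer one ML tree per marker on representative taxa."""
    reps = select_representatives(dataset)
    outgroup_labels = {_species_label(s) for s in config.outgroup_species
                       or dataset.outgroup_species}
    results: dict[str, SingleMarkerResult] = {}
    for mi, marker in enumerate(dataset.markers):
        rep_aln = representative_alignment(alignments[marker], reps[marker])
        if rep_aln.n_rows < 4:
            raise ValueError(f"marker {marker}: fewer than 4 taxa with sequences")
        trimmed, removed = trim_gappy_columns(rep_aln, config.gap_threshold,
                                              config.min_retained)
        labels, D = k2p_distance_matrix(trimmed)
        guide = nj_tree(labels, D).unroot()
        fit, guide = _fit_marker_model(trimmed, guide, config)
        packed = pack_alignment(trimmed)
        tree, lnl = ml_search(guide, packed, fit.model,
                              max_sweeps=config.ml_sweeps)
        fit = dataclasses.replace(fit, lnL=lnl, tree=tree)
        boots = bootstrap_trees(trimmed, fit.model, n=config.n_bootstrap,
                                seed=config.seed + 31 * (mi + 1),
                                method=config.bootstrap_method)
        fbp = fbp_support(tree, boots)
        tbe = tbe_support(tree, boots)
        rooted = root_with_outgroup(tree, outgroup_labels & tree.leaf_labels()) \
            if outgroup_labels & tree.leaf_labels() else tree
        results[marker] = SingleMarkerResult(
            marker=marker, alignment=trimmed, removed_columns=removed,
            fit=fit, tree=rooted, unrooted_tree=tree, fbp=fbp, tbe=tbe)
        logger.info("marker %s: lnL=%.2f, %d taxa", marker, lnl, trimmed.n_rows)
    return results


def run_supermatrix(single: dict[str, SingleMarkerResult],
                    config: PipelineConfig) -> dict[str, SupermatrixResult]:
    """Partitioned ML trees for every marker pair and the full set.

    Taxa are the species shared by all involved markers; every arrangement
    of each marker set is scored to confirm the likelihood and the inferred
    topology do not depend on concatenation order.
    """
    import itertools
    markers = list(single)
    if len(markers) < 2:
        raise ValueError("supermatrix stage needs at least two markers")
    combos = list(itertools.combinations(markers, 2))
    if len(markers) > 2:
        combos.append(tuple(markers))
    results: dict[str, SupermatrixResult] = {}
    for combo in combos:
        alns = {m: single[m].alignment for m in combo}
        models = {m: single[m].fit.model for m in combo}
        taxa = sorted(set.intersection(*(set(alns[m].rows) for m in combo)))
        arrangements = all_arrangements(list(combo))
        sm0 = concatenate(alns, taxa, arrangements[0], models=models)
        packed = pack_alignment(sm0)
        model_list = [p[3] for p in sm0.scheme.parts]
        labels, D = k2p_distance_matrix(sm0.alignment)
        guide = nj_tree(labels, D).unroot()
        optimize_branch_lengths(guide, packed, model_list, rounds=2)
        tree, lnl = ml_search(guide, packed, model_list,
                              max_sweeps=config.ml_sweeps)
        arrangement_lnls = {}
        for arr in arrangements:
            sm = concatenate(alns, taxa, arr, models=models)
            p = pack_alignment(sm)
            ml = [q[3] for q in sm.scheme.parts]
            arrangement_lnls[arr] = log_likelihood(tree, p, ml)
        name = "-".join(combo)
        results[name] = SupermatrixResult(
            name=name, supermatrix=sm0, tree=tree, lnL=lnl,
            arrangement_lnls=arrangement_lnls)
        logger.info("supermatrix %s: lnL=%.2f over %d taxa", name, lnl, len(taxa))
    return results


def run_congruence(single: dict[str, SingleMarkerResult],
                   supers: dict[str, SupermatrixResult],
                   config: PipelineConfig,
                   datasets: list[str] | None = None,
                   bl_rounds: int = 3):
    """Congruency tables: all-pairs nRF and dataset x tree SH p-values.

    Trees are restricted to their shared leaf set implicitly by the
    representative selection (one tip per species).  For the SH matrix,
    each candidate topology gets its branch lengths re-optimized on each
    dataset (topology fixed) before site log-likelihoods are extracted;
    under-converged re-optimization would make a dataset spuriously reject
    a topology identical to its own ML tree, so several sweeps are used.
    ``datasets`` restricts which alignments are used as SH datasets.
    """
    trees: dict[str, Tree] = {m: r.unrooted_tree for m, r in single.items()}
    trees.update({n: r.tree for n, r in supers.items()})

    sources: dict[str, tuple] = {}
    for m, r in single.items():
        sources[m] = (pack_alignment(r.alignment), r.fit.model)
    for n, r in supers.items():
        sm = r.supermatrix
        sources[n] = (pack_alignment(sm), [p[3] for p in sm.scheme.parts])
    if datasets is not None:
        sources = {k: v for k, v in sources.items() if k in datasets}

    site_lnls: dict[str, dict] = {}
    common = set.intersection(*(t.leaf_labels() for t in trees.values()))
    for ds, (packed, models) in sources.items():
        ds_taxa = set(packed.taxa)
        per_tree = {}
        for label, tree in trees.items():
            if tree.leaf_labels() != ds_taxa:
                if not ds_taxa <= common:
                    raise ValueError(
                        f"dataset {ds} taxa not shared by tree {label}")
                continue
            t = tree.copy()
            optimize_branch_lengths(t, packed, models, rounds=bl_rounds)
            per_tree[label] = site_log_likelihoods(t, packed, models)
        site_lnls[ds] = per_tree
    return tree_compare.congruence_matrix(
        trees, site_lnls, alpha=config.alpha_sh, n_rell=config.n_rell,
        seed=config.seed + 9973)


def report(dataset_summary: dict, nrf, sh, flags,
           single: dict[str, SingleMarkerResult] | None = None,
           support_threshold: float = 70.0) -> str:
    """Human-readable run summary mirroring the analysis tables."""
    lines = ["# Multi-marker congruence report", ""]
    lines.append(f"Dataset: {dataset_summary.get('n_sequences', 0)} sequences, "
                 f"{dataset_summary.get('n_species', 0)} species, "
                 f"{dataset_summary.get('n_genera', 0)} genera "
                 f"(+{dataset_summary.get('n_outgroup_species', 0)} outgroup species)")
    if single:
        lines.append("")
        lines.append("High-confidence branches "
                     f"(> {support_threshold:g}% FBP or TBE; representative "
                     "tips chosen mechanically: longest sequence per species):")
        for m, r in single.items():
            strong = sum(1 for s, v in r.fbp.items()
                         if v > support_threshold or r.tbe.get(s, 0) > support_threshold)
            lines.append(f"  {m}: {strong}/{len(r.fbp)} internal branches")
    if nrf is not None and len(nrf):
        lines += ["", "## Pairwise nRF distance (%)", nrf.round(1).to_string()]
    if sh is not None and len(sh):
        lines += ["", "## SH test p-values (dataset x tree)", sh.round(3).to_string(),
                  "", "Rejected (p < alpha) entries:"]
        rejected = [(d, t) for d in flags.index for t in flags.columns
                    if bool(flags.loc[d, t])]
        lines.append("  " + (", ".join(f"{d} rejects {t}" for d, t in rejected)
                             if rejected else "none"))
    return "\n".join(lines)


def write_manifest(out_dir: str, config: PipelineConfig, outputs: list[str]) -> None:
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"config": config.to_manifest(), "outputs": sorted(outputs)}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
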