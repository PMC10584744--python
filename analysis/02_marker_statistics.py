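"""Sequence heterogeneity statistics per marker.

Computes GC content per sequence, all pairwise K2P distances with their
Ts/Tv decomposition, and the disparity-index homogeneity test within and
between genera, mirroring the descriptive tables of a multi-marker barcode
survey.  Reads the scenario from results/scenario/, writes tidy TSVs under
results/stats/.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from chlorophylo import marker_stats as ms
from chlorophylo.alignment_ops import read_fasta_alignment
from chlorophylo.seq_data import read_dataset

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 11


def main() -> None:
    scen = os.path.join(BASE, "scenario")
    meta = os.path.join(scen, "metadata.tsv")
    markers = sorted(pd.read_csv(meta, sep="\t")["marker"].unique())
    paths = {m: os.path.join(scen, f"{m}.aln.fasta") for m in markers}
    ds = read_dataset(paths, meta, outgroup_species={"Outgenus distans"})
    alns = {m: read_fasta_alignment(paths[m], marker=m) for m in markers}

    out_dir = os.path.join(BASE, "stats")
    os.makedirs(out_dir, exist_ok=True)

    gc_rows = [{"accession": s.accession, "species": s.species,
                "genus": s.genus, "marker": s.marker,
                "gc_pct": round(ms.gc_content(s.residues), 2)}
               for s in ds.sequences]
    gc = pd.DataFrame(gc_rows)
    gc.to_csv(os.path.join(out_dir, "gc_content.tsv"), sep="\t", index=False)
    print("mean GC% per marker (ingroup):")
    ingroup = gc[~gc["species"].isin(ds.outgroup_species)]
    print(ingroup.groupby("marker")["gc_pct"].agg(["mean", "std"]).round(2))

    pairs, groups = ms.aggregate_stats(ds, alns, alpha=0.05, n_reps=1000,
                                       seed=SEED)
    pairs.to_csv(os.path.join(out_dir, "pairwise_stats.tsv"), sep="\t",
                 index=False)
    groups.to_csv(os.path.join(out_dir, "group_summaries.tsv"), sep="\t",
                  index=False)
    print("\nK2P distance and significant-I_D frequency by scope:")
    print(pairs.groupby(["marker", "scope"]).agg(
        mean_k2p=("d_k2p", "mean"), mean_tstv=("ts_tv", "mean"),
        pct_sig=("significant", lambda s: 100 * s.mean())).round(3))
    print(f"\nwrote tables to {os.path.abspath(out_dir)}")


if __name__ == "__main__":
    main()
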