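"""Congruency assessment of single-marker and supermatrix trees.

Builds the two headline tables: (a) the all-pairs normalized
Robinson-Foulds distance matrix over the 3 single-marker and 4 supermatrix
trees, and (b) the dataset x tree SH-test p-value matrix at alpha = 0.01
(branch lengths re-optimized per candidate per dataset).  A planted
discordance should appear as nRF > 0 against the perturbed marker only,
with its tree SH-rejected by the other markers' datasets, while the
supermatrix trees side with the majority signal.  Writes TSVs under
results/congruence/.
"""

import os
import pickle
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from chlorophylo import pipeline as pl
from chlorophylo.seq_data import dataset_summary, read_dataset

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 11


def main() -> None:
    trees_dir = os.path.join(BASE, "trees")
    with open(os.path.join(trees_dir, "single_results.pkl"), "rb") as fh:
        single = pickle.load(fh)
    with open(os.path.join(trees_dir, "super_results.pkl"), "rb") as fh:
        supers = pickle.load(fh)
    cfg = pl.PipelineConfig(markers=list(single), n_rell=1000, seed=SEED)
    nrf, sh, flags = pl.run_congruence(single, supers, cfg)

    out_dir = os.path.join(BASE, "congruence")
    os.makedirs(out_dir, exist_ok=True)
    nrf.round(2).to_csv(os.path.join(out_dir, "nrf_matrix.tsv"), sep="\t")
    sh.round(4).to_csv(os.path.join(out_dir, "sh_pvalues.tsv"), sep="\t")
    flags.to_csv(os.path.join(out_dir, "sh_rejections.tsv"), sep="\t")

    scen = os.path.join(BASE, "scenario")
    import pandas as pd
    meta = os.path.join(scen, "metadata.tsv")
    markers = sorted(pd.read_csv(meta, sep="\t")["marker"].unique())
    ds = read_dataset({m: os.path.join(scen, f"{m}.aln.fasta") for m in markers},
                      meta, outgroup_species={"Outgenus distans"})
    text = pl.report(dataset_summary(ds), nrf, sh, flags, single,
                     cfg.support_threshold)
    with open(os.path.join(out_dir, "report.txt"), "w") as fh:
        fh.write(text + "\n")
    print(text)
    print(f"\nwrote congruence tables to {os.path.abspath(out_dir)}")


if __name__ == "__main__":
    main()
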