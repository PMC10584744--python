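# chlorophylo

Multi-marker DNA-barcode congruence analysis for phylogenetics, built around
the question every barcoding study of a messy group (here: the green-algal
family Chlorellaceae and its markers 18S rRNA, ITS, and chloroplast *rbcL*)
has to answer: **do the markers tell the same evolutionary story, and does
concatenating them help when they do not?**

The package is aimed at molecular systematists who have per-marker
alignments (plus taxonomy metadata and, optionally, a similarity-search hit
table for quality filtering) and want a reproducible, testable route from
sequences to a congruence verdict, without hand-driving half a dozen
separate tools.

## What it computes

**Sequence heterogeneity.** GC content; pairwise distances under the
Kimura two-parameter model,

d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),

with its transition/transversion decomposition d = s + v and the per-pair
ratio R = s/v; and the disparity index I_D = D_c − N_d, where
D_c = ½ Σ_i (x_i − y_i)² compares the base-count vectors of two sequences
and N_d counts their differing sites. Positive I_D signals compositional
heterogeneity beyond what the substitution count explains; significance
comes from a Monte-Carlo null that swaps the two observed states at each
differing site with probability ½.

**Trees.** GTR-family substitution models (JC, K80, HKY, TIM1, GTR, each
optionally +I and discrete-Γ) with AICc selection; Felsenstein-pruning
log-likelihoods; ML tree search by NNI hill climbing from a K2P
neighbor-joining start; nonparametric bootstrap with both classical branch
support (FBP) and the transfer bootstrap expectation
TBE(b) = 1 − E[δ(b, T*)/(p−1)], which grants partial credit through the
transfer index δ (minimum leaves to move so branch b appears in replicate
T*); outgroup rooting.

**Supermatrices.** Concatenation of shared taxa in *every* marker
arrangement, per-partition models, and a proof-by-computation that the
partitioned likelihood is invariant to arrangement order.

**Congruence.** Normalized Robinson–Foulds distances
nRF = RF / (2(n−3)) between all single-marker and supermatrix trees, and
the Shimodaira–Hasegawa test (RELL resampling, original centering) asking
which candidate topologies each dataset rejects at P < 0.01.

**Synthetic truth.** A generator that emulates the real markers'
signatures — GC ≈ 59% (ITS-like), 50% (18S-like), 41% (*rbcL*-like),
marker-specific +I+Γ models and rates, intraspecific sampling, an outgroup
— with controllable planted discordance (random NNI moves on one marker's
tree), so every stage above is verifiable against a known answer.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic scenario (14 species, 10 genera, 43 sequences per marker, *rbcL*
perturbed by 3 NNI moves; seed 11):

```bash
python analysis/01_simulate_scenario.py
python analysis/02_marker_statistics.py
python analysis/03_single_marker_trees.py
python analysis/04_supermatrix_trees.py
python analysis/05_congruence.py
```

Script 01 reports the planted truth:

```
dataset: 129 ingroup sequences, 14 species, 10 genera
planted marker-tree discordance (nRF %): {'18S|ITS': 0.0, '18S|rbcL': 27.27, 'ITS|rbcL': 27.27}
```

Script 02 recovers the marker composition contrast (mean GC%: ITS 59.04,
18S 49.29, rbcL 40.47). Script 03 infers the three ML trees (12/12, 12/12
and 11/12 internal branches above 70% FBP/TBE); script 04 builds the four
supermatrix trees and verifies arrangement invariance (lnL spread 0.0e+00
across all arrangements). Script 05 prints the congruence verdict:

```
## Pairwise nRF distance (%)
               18S   ITS  rbcL  18S-ITS  18S-rbcL  ITS-rbcL  18S-ITS-rbcL
18S            0.0   0.0  33.3      0.0      16.7      16.7           0.0
rbcL          33.3  33.3   0.0     33.3      16.7      16.7          33.3
...
## SH test p-values (dataset x tree)
                18S    ITS   rbcL  ...
18S           1.000  0.807  0.000
ITS           0.810  1.000  0.000
rbcL          0.000  0.000  1.000
```

Read: the two congruent markers recover identical topologies (nRF 0,
mutual SH p ≈ 0.81), the perturbed *rbcL* tree is rejected by both other
datasets (p < 0.001) and rejects them in return, and the three-marker
supermatrix tree sides with the majority signal (nRF 0 to 18S/ITS vs 33.3
for *rbcL*) — concatenation resolves the planted conflict.

A `chlorophylo` command-line interface wraps the same library calls
(`simulate`, `ingest`, `filter`, `trim`, `run`; see `chlorophylo --help`).

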