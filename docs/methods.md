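# Methods

This note records the models, estimators, numerical choices and known
limitations behind `chlorophylo`, at the level of detail a user would need
to interpret results or reproduce them with other software.

## Pairwise statistics

**Usable sites.** All pairwise statistics use pairwise deletion: a column
counts only when both characters are unambiguous A/C/G/T. Transitions are
A↔G and C↔T; all other differing pairs are transversions. GC content is
computed per sequence over unambiguous bases only (gaps and IUPAC
ambiguity codes excluded from numerator and denominator), i.e. on the
unaligned residues.

**K2P distance.** With transition proportion P and transversion proportion
Q, d = −½ln(1−2P−Q) − ¼ln(1−2Q), split into a transition component
s = −½ln(1−2P−Q) + ¼ln(1−2Q) and transversion component v = −½ln(1−2Q),
so that d = s + v exactly. The per-pair Ts/Tv ratio is reported as R = s/v
(undefined and flagged when v = 0; distances with a non-positive log
argument return +∞ with a saturation flag). The component ratio was chosen
over the raw count ratio so the same model underlies the distance and the
ratio.

**Disparity index.** I_D = D_c − N_d with D_c = ½Σ(x_i − y_i)² over the
usable-site base-count vectors and N_d the differing-site count. The
Monte-Carlo homogeneity test swaps the two observed states at each
differing usable site with probability ½, independently per site and
replicate; identical sites cancel in x − y and N_d is swap-invariant, so
the null only needs the differing-site contributions (the implementation
vectorizes this as signed sums). The p-value uses the add-one estimator
p = (1 + #{I_D* ≥ I_D}) / (1 + n_reps), which cannot return 0 and makes
the test conservative at the resolution limit; 1000 replicates by default,
seed mandatory. Measured on homogeneous K2P pairs (1000 sites), the type-I
error at α = 0.05 sits within the 99% binomial interval of 5%, and a
directional shift of 30 A→G sites per 1000 is detected in the large
majority of pairs (the acceptance run reports the measured rate).

## Likelihood engine

**Models.** Families JC, K80, HKY, TIM1, GTR over the exchangeability
order (AC, AG, AT, CG, CT, GT). TIM1 is implemented with AC = GT and
AT = CG tied while AG, CT and the reference transversion vary — four free
exchangeabilities, three after fixing the scale. Frequencies are equal for
JC/K80 and ML-estimated (initialized from empirical counts) otherwise.
Rate variation is the usual mixture of an invariant-sites spike (+I) and a
discrete Gamma (+G) with 4 categories whose rates are the means of
equal-probability quantile bins, renormalized to mean one. The generator
is scaled so one unit of branch length is one expected substitution per
site *including* the mixture (the Q matrix is divided by (1 − p_inv)).

**Pruning.** Alignments are compressed to site patterns per partition
before any likelihood work; ambiguity codes become 0/1 partial vectors
over their compatible bases and gaps are fully missing. Partials are kept
as (categories × 4 × patterns) arrays so each message is a batched 4×4
product; transition matrices for all edges and categories come from one
eigendecomposition of the reversible generator. Per-node rescaling by the
column maximum guards underflow; category and invariant components combine
per pattern by log-sum-exp. The two-taxon JC closed form is reproduced to
1e−9 and the likelihood is invariant to rerooting (reversibility) and to
pattern compression.

**Branch-length optimization.** Coordinate ascent with bounded Brent
(bounds 1e−8 to 20, xatol 1e−7) per branch. For an edge (u, v) the site
likelihood factorizes as Σ_i π_i U_v[i] (P(t) D_v)[i], where D_v is the
pruning partial below v and U_v collects everything outside the subtree
(computed by one extra preorder pass using reversibility), so each Brent
iteration costs a single 4×4 product per category instead of a full tree
traversal. Messages are refreshed before each branch; a proposal is kept
only if it improves the current likelihood, making lnL non-decreasing by
construction.

**Model parameters.** Bounded L-BFGS-B on unconstrained transforms
(log exchangeabilities, softmax frequencies, scaled-sigmoid p_inv capped
at 0.98, log α clipped to [e⁻⁴, e⁵]), alternated with branch-length sweeps
until the improvement drops below the tolerance (1e−6 by default, 1e−4 in
the pipeline's fitting stage) or a round cap.

**AICc.** AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) with n = alignment columns
and k counting substitution parameters *plus* branch lengths (2·taxa − 3),
matching the convention of the common model-selection tools; candidates
hitting the n ≤ k+1 singularity are skipped with a warning. Selection
fits families × {plain, +I, +G, +I+G} on a fixed guide topology with
branch re-optimization; ties break toward fewer parameters. The candidate
set is deliberately this 20-model grid rather than a full 88-model space:
it covers every family the analyses here select while keeping a fit under
a minute.

## Tree search and support

The ML search is NNI hill climbing from a neighbor-joining start
(scikit-bio's NJ on K2P distances, negative branch lengths clamped to 0):
each sweep scores both rearrangements of every internal edge at current
branch lengths, accepts the best improving move, and re-optimizes all
branch lengths. When no move clears the tolerance on raw scores, every
neighborhood is re-scored with a branch-length pass before declaring a
local optimum — rearrangements across short branches are often downhill
until their neighborhood lengths adapt, and the earlier implementation
that skipped this pass measurably under-fitted. The contract is a local
optimum under NNI, verified by simulation (6-taxon JC recovery and a
4-taxon exhaustive-enumeration oracle), not equivalence to any particular
external search heuristic.

Bootstrap replicates resample columns with replacement, independently
within each partition of a supermatrix. Support comes in two forms: FBP
(percentage of replicates containing the exact bipartition) and TBE,
100·(1 − mean δ/(p−1)) with p the light-side size and δ the transfer
index, computed as the minimum Hamming distance between the reference
bipartition and any edge bipartition (pendant edges included) of the
replicate; an exhaustive move-k-leaves oracle confirms δ on ≤8-taxon
trees. TBE ≥ FBP always, with equality on cherries. Replicate trees for
support estimation default to NJ per replicate (a short per-replicate NNI
search is available as `method="ml"`); this trades a slight conservative
bias in support values for two orders of magnitude in speed and does not
affect the congruence stage, which uses the point-estimate trees.

## Congruence

**nRF.** RF is the symmetric difference of nontrivial bipartition sets on
a shared leaf set (no implicit pruning; mismatched leaf sets are an
error), normalized by 2(n−3) and reported as a percentage.

**Species collapsing.** Maximal single-species clades in the rooted tree
collapse to one leaf carrying the clade's stem length; species whose tips
do not form one exclusive clade are reported and left untouched.

**SH test.** RELL resampling: site counts are drawn multinomially within
each partition (respecting pattern weights), per-tree resampled totals are
centered by their own replicate mean, the per-replicate statistic is the
centered maximum minus the tree's centered value, and p is the proportion
of replicates at or above the observed δ = lnL_max − lnL_tree. This is
the original centering convention — not the KH or AU null. The observed
best tree has δ = 0 and p = 1 by construction. Because the null maximum
is taken over all candidates, one grossly poor candidate legitimately
inflates everyone's p-values; the test's conservativeness under the true
tree (rejection ≤ 1% + 3σ at α = 0.01 over 500 simulations) is part of
the test suite.

For the dataset × tree matrix, each foreign topology gets its branch
lengths re-optimized on the evaluating dataset (three sweeps; topology
fixed) before site likelihoods are extracted. Fewer sweeps leave the
foreign tree's likelihood short of its optimum and make a dataset
spuriously reject topologies identical to its own ML tree, which is why
the re-optimization depth is not a free knob here.

## Synthetic scenarios

The generator draws a Yule species tree (uniform lineage splitting,
exponential waiting times) scaled to a root-to-tip height of 0.15
substitutions/site, assigns genera by cutting the tree where the target
lineage count exists, attaches one outgroup species on a long stem (2×
height), expands species into their sampled sequences as short pendant
tips (0.008 expected substitutions/site, scaled per marker), and simulates
gap-free alignments forward along each marker's gene tree.

Default markers mirror the real barcode contrast: an 18S analogue
(TIM1+I+Γ, GC 50.3%, rate ×0.7, 1800 nt), an ITS analogue (GTR+I+Γ, GC
59.0%, rate ×1.6, 1500 nt) and an *rbcL* analogue (GTR+I+Γ, GC 40.8%,
rate ×1.0, 1430 nt); the default scenario is 14 species in 10 genera with
43 ingroup sequences per marker. Discordance is planted topologically by
random NNI moves on a marker's species-level tree before sequence-level
expansion; the truth bundle records the trees, models and realized
pairwise nRF exactly as used.

Internal branches are floored at 10% of tree height. Raw Yule trees
routinely contain internal branches carrying ~1 expected substitution on
the slowest marker, which no finite alignment can resolve; the scenario's
contract, however, is the strong-signal regime in which every *unperturbed*
marker recovers the species topology, so the floor is set where the
shortest branch still leaves ≳13 expected changes on the slowest marker.
Consequences worth knowing: the generator does **not** emulate indels (the
trimming rule is tested on separately constructed gapped fixtures),
alignment error, coalescent gene-tree discordance, or horizontal transfer —
planted NNI discordance is a topological stand-in. Passing the end-to-end
tests therefore demonstrates that the pipeline detects and resolves
*topological* conflict under clean alignments, not robustness to those
real-data pathologies.

Three random NNI moves can partially cancel; at some seeds the realized
discordance is a single effective NNI and the SH rejection of that barely
wrong tree sits at the significance boundary — the truth bundle's recorded
nRF values are the reference for interpreting such runs.

## Pipeline conventions and problem sizes

Quality filtering keeps a sequence iff some hit has e-value ≤ 1e−15 and
identity and coverage strictly > 40%; redundancy removal collapses exact
duplicate strings (after uppercasing and terminal-gap stripping) within a
(species, marker) group, keeping the smallest accession. Trimming removes
columns with gap fraction strictly > 0.70, gappiest first (ties leftmost),
never dropping below ⌈0.80 × original length⌉ columns. Concatenation
requires exactly one representative per species per marker — the longest
sequence, ties to the smallest accession, a mechanical substitute for
manual best-clade curation that is flagged in reports. Column coordinates
are 0-based half-open internally and 1-based inclusive in exported
partition files.

The analysis scripts and the acceptance run use desk-scale sizes chosen to
keep a full pass in minutes on one CPU: 15-taxon representative trees,
100 bootstrap replicates for support (the pipeline default is 1000), 1000
RELL replicates, 2000 pairs for disparity calibration, 500 simulations for
SH conservativeness, and 20 replicates at 50k sites for model-selection
recovery. Every random draw descends from a single explicit seed; reruns
are bit-identical.
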