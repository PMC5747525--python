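# Methods

`peptinet` infers a *peptidergic connectome* — the directed graph of
potential non-synaptic, volume-transmission signaling between cells —
from single-cell expression of proneuropeptide genes and their
deorphanized GPCR receptors, and compares gene co-expression structure
between two species over orthologous markers. This note documents the
models, the numerical choices, and what the synthetic benchmarks do and
do not demonstrate.

## Normalization and duplicate-cell merging

Raw per-gene RPKM values are converted to counts-per-million by dividing
by the sample's total mapped reads and multiplying by 10^6, then
log-transformed. We use `log10(1 + cpm)` rather than `log10(cpm)` so
that zero counts map to exactly zero and stay finite; the transform is
monotone and agrees with `log10(cpm)` to <0.05 above ~10 cpm, the range
where signaling genes live.

Single-cell samples dissociated from pooled larvae can re-isolate the
same biological cell. Duplicates are detected from the all-against-all
Pearson correlation of the normalized log profiles (computed over all
genes) and merged above a cutoff of r >= 0.95, the value separating the
duplicate peak from the bulk of the pairwise-correlation histogram in
this kind of data. Grouping is single-linkage: connected components of
the thresholded correlation graph, computed once on the input matrix.
An `iterative=True` flag instead re-correlates after each merge round
until a fixed point, for users who prefer the contractive reading;
the two agree whenever duplicate groups are well separated, which is the
regime the cutoff presupposes. Each group is replaced by one cell whose
value per gene is the arithmetic mean over members (so group means are
conserved exactly); member ids are kept as provenance. Zero-variance
samples cannot be compared and are excluded from merging with a warning.

## Mirror-node layout

Cells carry a spatial-symmetry code: `N` (no prediction), `Y1`
(asymmetric single cell), `Y2` (bilaterally symmetric pair). For the
planar map a `Y2` cell becomes two mirror-image nodes at (-x, y) and
(x, y) (ids `<cell>__L`, `<cell>__R`); `N`/`Y1` cells become one node. A
`Y2` cell sitting exactly on the midline produces two coincident nodes
and a warning rather than an error.

## Channel graphs and the combined connectome

For a ligand→receptor channel, a directed edge runs from every cell
expressing the proneuropeptide to every cell expressing the receptor,
with weight

    w(s→t) = sqrt( expr(s, ligand) · expr(t, receptor) )

the geometric mean of the two log-normalized expression values, used as
a proxy for signaling strength. "Expressing" means strictly positive
log-normalized value by default; the threshold is exposed (`min_expr`)
because zero-inflated data admit no universally correct cutoff. A cell
expressing both partners yields an autocrine self-loop.

Graphs can be built at cell level (merged cells as nodes) or node level
(mirror nodes): at node level a cell's edges are replicated across its
node instances, including cross-side edges between distinct cells;
autocrine loops stay per-node self-loops (a bilateral pair is two
instances of one transcriptomic cell, and its self-signaling is local to
each instance). The multichannel connectome sums parallel edges across
channels into a single weighted edge, keeping per-channel weights as an
edge attribute — the same merge a graph tool performs when several
channel files are imported into one workspace.

## Graph statistics

All statistics follow the conventions of the Gephi toolbox that
originally produced such maps:

* density = E/(N(N-1)) over ordered pairs, self-loops excluded;
* weighted in-/out-degree = sum of incoming/outgoing edge weights,
  self-loops counting once toward each;
* HITS authority/hub by power iteration on the weighted adjacency
  (L1 convergence tolerance 1e-8, cap 10^4 iterations), sum-normalized
  to 1; authority marks cells receiving from many strong senders;
* average clustering coefficient of the unweighted digraph (directed
  triangle definition; the undirected-projection value is also emitted
  because the original tool's convention is ambiguous — the directed
  value is the headline one);
* average path length = mean unweighted hop count over ordered reachable
  pairs (s ≠ t); components are weakly connected;
* Louvain communities on the weighted undirected projection,
  deterministic given a seed, with modularity reported;
* small-world sigma = (C/C_rand)/(L/L_rand) against degree-preserving
  edge rewirings (default 100), computed on the largest component with a
  warning if the graph is disconnected. sigma > 1 flags a small-world
  topology.

## Cell taxonomy

A cell is *peptide-positive* if any proneuropeptide gene exceeds
`min_expr` (default 0) and *transmitter-positive* if any small-
transmitter synthesis/transporter marker does. The cross yields four
classes (purely peptidergic, transmitter-only, dual, neither), reported
with percentages to one decimal. The transmitter-marker list is supplied
by the gene-role table, not hard-coded. Peptide counts per cell are the
number of distinct proneuropeptide genes above threshold. Autocrine
channels are the self-loops of the cell-level channel graphs.

## Cross-species co-expression comparison

Within each species, Pearson correlations between marker genes are
computed across cells, with two-sided p-values from the t-distribution
with n-2 degrees of freedom. One-to-many ortholog candidates are
resolved by a correlation-*profile* test: a direct cross-species
expression correlation is undefined (the two species have different
cells), so each candidate's off-diagonal correlation profile over the
unambiguous single-candidate "anchor" genes is tested against the
A-gene's profile and the candidate with the lowest test p-value is
retained (ties break lexicographically). If no anchors exist the first
candidate is taken with a warning.

The global statistic is the Pearson correlation between the two
correlation matrices over matched off-diagonal entries; identical-marker
(diagonal) entries are excluded because they are 1 in both species and
would fabricate signal.

Significance uses a per-gene cell-permutation scheme: in each of
`n_perm` replicates (default 1000), every gene's values are permuted
independently across cells in both datasets and the entire statistic
chain is recomputed. The empirical global p is
`(1 + #{null r >= observed r})/(n_perm + 1)`. The ortholog resolution is
held fixed at the observed one inside the null (re-resolving per
replicate is switchable but makes the null depend on a data-adaptive
selection step whose variability is not the quantity under test; note
that for the same reason the calibration guarantee applies to
single-candidate designs — with decoy candidates the observed statistic
inherits a selection optimism the fixed-resolution null does not model).

Per-pair family-wise correction is single-step minP (Westfall–Young):
the corrected p of a pair is the fraction of replicates whose *minimum*
null p over all pairs is at most the observed p (plus-one corrected).
This is never anti-conservative relative to the raw empirical p, and a
step-down variant is available. A pair is `significant_in_both` when its
corrected p is <= 0.05 in both species, each species corrected within
its own null. Presence/absence co-occurrence is additionally scored with
a two-sided Fisher exact test (degenerate margins return p = 1 with a
warning), and non-linear association with the Maximal Information
Coefficient.

### MIC implementation

No installed library provides MIC, so it is implemented here: grid
bound B = n^0.6, clump factor c = 15, both axis orientations searched;
one axis is equipartitioned (tie groups atomic) and the other optimized
by dynamic programming over clumps, using the additivity of
`sum_r n_cr log n_cr - n_c log n_c` per column. Noiseless functional
relationships score exactly 1; independent samples at n = 200 score
~0.2. Constant input returns 0 with a warning.

## Synthetic data

The generator drafts expression in log10(1+cpm) space and converts to
RPKM with per-sample library sizes drawn uniformly from 0.5–2 million
reads, so normalization recovers the planted log values exactly.
Default study conditions: 120 samples, 300 genes (20 proneuropeptides,
12 GPCRs, 6 transmitter markers), 10 channels with 6 senders and 6
receivers each, 8 duplicate groups of 2 (within-group log-noise sd
0.05, giving within-group r ≈ 0.99 against a ≤0.9 background), 50%
bilateral cells, background zero-inflation 85% with log-normal(1.5,
0.5) signal, channel-gene signal log-normal(2.5, 0.3) truncated at 0.5,
and 1% dropout on planted signal — deeply sequenced full-length scRNA-
seq rarely loses transcripts as abundant as proneuropeptides. Channel
genes are private per channel and zero outside their designated
subsets, so each channel's true edge set is exactly the designated
sender × receiver product. Transmitter markers are planted in 20% of
cells so the four taxonomy classes occur at realistic proportions.

The two-species mode gives both species K = 3 latent co-expression
modules of 4 genes each (of 24 markers, 60 cells per species): module
genes load on a per-cell standard-normal factor with loading
sqrt(0.9), so within-module gene-gene correlation is ~0.9. A quarter of
markers receive decoy ortholog candidates of pure noise. `n_modules=0`
is the null configuration used for calibration.

What the generator does *not* emulate: batch effects, gene-length or
GC biases, count-level (negative binomial) noise, realistic gene-gene
correlation outside planted modules, spatial expression gradients, and
doublets. Passing benchmarks therefore demonstrate algorithmic
correctness and statistical calibration under the planted model, not
robustness to every artifact of real data.

## Problem sizes in the standard benchmarks

Recovery benchmarks use 20 generated datasets at the default
conditions; graph-statistic checks enumerate all digraphs on up to 4
nodes exhaustively and sample 200 digraphs on 5–12 nodes; calibration
uses 200 null replicates of a 20-gene, 40-cell two-species design with
200 permutations each; module recovery uses 1000 permutations. These
sizes give stable estimates (binomial standard errors of a few percent)
while keeping a full run in minutes on one core.

## Known limitations

* Merging is single-pass by default; pathological chains of borderline
  correlations could in principle bridge distinct cells (single-linkage
  is transitive), which the 0.95 cutoff makes unlikely but not
  impossible.
* The expression threshold for "expressing" is 0 on log values; any
  nonzero mapped read makes a cell a sender/receiver. Real analyses may
  want a small positive `min_expr`.
* HITS on graphs whose top eigenvalue of AᵀA is degenerate converges to
  an eigenspace projection rather than a unique vector; this does not
  occur for generic weighted graphs.
* Ortholog resolution for genes with no co-expression signal is a
  guess among statistically equivalent candidates; accuracy is high only
  for genes participating in shared structure.
* The empirical p-value floor is 1/(n_perm+1); claims below 0.001
  require more than 1000 permutations.
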