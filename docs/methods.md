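# Methods

## Problem

Single-cell spatial omics technologies (CODEX, MERFISH, MIBI-TOF, IMC)
produce maps of cells with physical coordinates and phenotype
annotations.  A *tissue cellular neighborhood* (TCN) is a spatially
coherent multicellular region in which cell types organize to support a
tissue function — splenic compartments, brain nuclei, or immune/tumour
compartments.  `tcncommunity` frames TCN detection as community
detection on a node-attributed spatial graph and learns a mapping from
cell phenotypes directly to TCN membership, without clustering of
intermediate embeddings.

## Model

For one map with `n` cells and `m` phenotypes, a directed k-NN graph on
cell coordinates (Euclidean distance) is symmetrised and stripped of
self-edges, giving an unweighted adjacency `A` with one-hot phenotype
attributes `F`.  The default `k` is the square root of the mean cell
count over the dataset (SRM rule), shared by all maps of a dataset.
Distance ties are broken toward the lower cell index, so graphs are
reproducible across platforms; the k-NN search is exact (kd-tree with
tie-widened candidate sets, verified against brute force).

The soft assignment model is

    X = ReLU(F Th1' + (A F) Th2')        # one graph-convolution layer
    S = softmax(X Th3')                  # n x c row-stochastic

with embedding width `d` (128 unsupervised, 512 supervised) and at most
`c` TCNs.  The convolution is a plain neighbour sum — no degree
normalization — matching the model definition.  Training minimizes the
relaxed normalized-MinCut loss

    L = - tr(S'AS) / tr(S'DS) + || S'S/||S'S||_F - I_c/sqrt(c) ||_F

whose cut term (in [-1, 0]) rewards assignments that cut few edges
relative to degree mass and whose orthogonality term (in [0, 2]) pushes
`S` toward balanced, unambiguous clusters.  An edgeless graph makes the
cut term 0/0; the loss raises an error instead of returning NaN.

Supervised mode pools each graph to a TCN-level graph,
`X_pooled = S'X`, `A_pooled = S'AS`, applies a second convolution on
the coarse graph, mean-pools the `c` rows into a whole-graph embedding
and classifies the sample with a two-layer softmax head (hidden width
`d/4`).  The loss is `beta * L_MinCut + (1-beta) * L_CE` with
`beta = 0.9`.  Because one assignment head serves all maps, TCN columns
correspond across samples, which is what makes condition-specific TCNs
discoverable without post hoc alignment.

Numerical note: the raw pooled adjacency has entries of order `n*k/c`,
which saturates the classifier head at initialization.  Inside the
classifier convolution the pooled adjacency is therefore diagonal-zeroed
and symmetrically degree-normalized — the convention of the
differentiable MinCut pooling operator this model builds on — and the
cross-entropy is computed from logits via log-sum-exp.  The public
`pool` function returns the literal `S'AS`.

## Training

The whole model runs on a small in-package reverse-mode autodiff tape
over numpy (dense/sparse matmul, broadcasting arithmetic, ReLU, row
softmax, reductions) with an Adam optimizer.  Training uses single
precision; public loss evaluation and gradient checks run in double
precision, and autodiff gradients agree with central finite differences
to better than 1e-4 relative.

Unsupervised: `n_models` (default 20) models are trained from
independent seeds derived from one master seed; each keeps the `S` with
the lowest loss seen.  Defaults: Adam lr 1e-3, at most 300 epochs,
early stop after 20 epochs without an improvement of 1e-5.  A model
whose loss turns non-finite is dropped with a warning.

Supervised: stratified k-fold cross-validation (default 10 folds,
repeatable with fresh fold shuffles).  Minibatches are whole graphs;
the default size is the power of two closest to half the training-set
size, and the default learning rate follows the size-scaled convention
(1e-4 up to 16 graphs per batch, 1e-3 above).  Maps are shuffled each
epoch, so the model sees class labels only.  Each trained fold model
produces a soft assignment for every map (training and held-out), and
held-out class probabilities for its test fold.

## Ensemble

Hard assignments (`argmax` per row, ties to the lower column) from the
trained models are aligned to the first run by Hungarian matching on
the contingency table — the run-to-run label correspondence is not
defined by the model itself, so the package makes this choice explicit —
then consolidated per cell by majority vote (vote ties prefer the
larger summed soft probability).  Empty TCNs are dropped and labels
renumbered by descending size.  For supervised cohorts the vote runs on
cohort-concatenated label vectors so the final label space is shared by
all maps.  The robustness score between partitions is the mean
size-weighted Jaccard index of matched TCNs, symmetrized over the two
anchorings of each pair.

## Evaluation

* macro-F1: predicted TCNs are matched one-to-one to ground-truth
  classes by Hungarian assignment maximizing total F1 (visual matching
  of regions is not an algorithm, so the package fixes this rule).
  Unmatched ground-truth classes contribute F1 = 0; cells in unmatched
  predicted TCNs count as false negatives.
* AMI: arithmetic-mean normalization with the exact permutation-model
  (hypergeometric) expected mutual information; entropies in nats.  A
  constant partition on either side gives 0 by convention (the 0/0
  limit), so `ami(x, x) = 1` holds for non-constant `x` only.
* AUC: rank-based Mann-Whitney statistic with midrank ties.

All three are cross-checked in the test suite against independent
implementations (scikit-learn, exhaustive matching, pair counting).

## Downstream statistics

Cell-type enrichment in a TCN is the one-sided hypergeometric
over-representation tail P(X >= x) given (cells of the type in the TCN,
TCN size, cells of the type in the map, map size), Benjamini-Hochberg
adjusted across all TCN x type tests *within one map* — per-map families
keep maps exchangeable for group averaging — and reported as
-log10(adjusted p).  Group averages ignore TCNs absent from a map
rather than imputing zero.

Within-TCN association of two cell types across samples uses Spearman
rank correlation (robust to the skewed enrichment-score distribution);
constant vectors yield a missing value.  Between-TCN communication uses
canonical correlation analysis of each TCN pair's five most enriched
cell types (by mean score across maps), computed by QR + SVD; the
permutation test permutes one side's rows and uses Wilks' lambda over
all canonical pairs as the statistic (default 999 permutations,
significance threshold 0.1).  Collinear columns are dropped with a
warning.  First-pair weights are reported scaled to unit maximum
absolute value; "dominant" types are those with normalized |weight|
>= 0.5.

## Synthetic data

The generator emulates three archetypes on the unit square with a
uniform point process:

* compartmentalized — two half-planes with disjoint default
  compositions (types 0-1 vs types 2-3), mimicking tumours with immune
  cells segregated from neoplastic cells;
* mixed — one homogeneous region (single ground-truth TCN);
* nuclei — four discs of radius 0.12 arranged as two pairs mirrored
  across the vertical midline on a background; mirrored discs share a
  composition and a ground-truth label (bilateral nuclei of one type),
  giving three ground-truth TCNs.

Region borders mix compositions logistically over a `boundary_softness`
width (default 0.02).  The labeled-cohort generator pairs 20
compartmentalized with 20 mixed maps of 800 cells (the scale used
throughout the validation suite), shares a five-type vocabulary whose
fifth "marker" type appears at 2% everywhere, and injects a central
marker-dominated disc (60% marker, radius 0.15) into class-1 maps only,
emulating a condition-specific neighbourhood.

What the generator does not emulate: inhomogeneous cell density,
irregular region shapes, segmentation or phenotyping noise, multiple
images per patient, and class imbalance.  Passing tests therefore
demonstrate correctness of the machinery and recoverability under clean
geometry, not performance on real tissue.

## Known limitations

* The orthogonality term prefers clusters of equal size.  When `c`
  exceeds the number of natural regions and one region dominates (the
  nuclei fixture: 83% background), optimizing the objective *splits the
  large homogeneous region* — the ground-truth partition has a strictly
  worse loss (+0.10 vs -0.49 on that fixture) than a background-split
  partition.  Small distinct regions are still recovered cleanly, but
  agreement scores against a ground truth that keeps the background
  whole are capped near 0.5; choosing `c` close to the expected region
  count avoids this regime.
* A model can collapse to a single TCN (dead-ReLU/saddle); with the
  default widths this is rare, and the majority-vote ensemble absorbs
  occasional collapsed runs.
* Only binary condition labels are supported in supervised mode; cells
  must arrive phenotyped (no expression matrices, no spot
  deconvolution).

## Problem sizes in the validation suite

Unsupervised recovery runs at n = 2,000 (compartmentalized) and
n = 3,000 (nuclei) with 5- and 20-model ensembles; supervised runs one
set of 10-fold CV on 40 maps of 800 cells.  These sizes exercise every
code path at a few minutes per stage on a single core while matching
the generator's default study conditions.
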