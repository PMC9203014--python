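# Methods

## The model

chromecho predicts multi-label chromatin features — transcription-factor
(TF) binding, histone modifications, DNase I hypersensitive sites — for
fixed-width genomic bins (default 200 bp) by combining local DNA sequence
with 3D chromatin organization.

The genome is tiled into non-overlapping bins ordered by genomic position;
the bins are the nodes V of a graph G = (V, E, A) whose weighted edges are
chromatin contacts from Micro-C (or up-sampled Hi-C) maps.  Each bin's
flanked sequence x is one-hot encoded (rows A, C, G, T; uncalled bases and
positions beyond chromosome ends are 0.25 in all four rows, so columns
always sum to one).

**Sequence layers f.**  A convolutional encoder maps x to a hidden vector
phi of length K.  It is pre-trained on the same multi-label task with a
temporary fully connected classification head; the checkpoint at minimum
validation loss is kept, the head is dropped, and the encoder is frozen.
Freezing means the parameters never change during graph training —
gradients still flow through it, which sequence attribution relies on.

**SAMPLE / STACK.**  Convolution needs fixed-shape inputs, so each bin's
neighborhoods are converted to grids:

* sequential neighbors: the window i−k_s … i+k_s along the chromosome, in
  genomic order, center included; slots crossing a chromosome boundary
  become a virtual dummy node;
* spatial neighbors: the k_c partners with the largest contact values among
  {t : A[i,t] ≥ tau} (ties broken by smaller genomic distance, then smaller
  index, so sampling is deterministic); missing slots are dummy-padded.

Formally the stacked feature matrix is Xi = P · phi+, where P is a binary
sampling matrix with exactly one 1 per row and phi+ is the hidden matrix
augmented with a final all-zero dummy row.  The matrix-product and
row-gather formulations are bit-identical (tested); training uses the
gather, attribution uses the product form.

**Graph layers g_c, g_s and prediction layer p.**  Each graph stack treats
the neighbors as channels and convolves along the feature axis, ending in
global average pooling; g_c and g_s share their architecture except for the
first layer's channel count.  By default the first convolution spans the
entire feature axis (kernel = K, valid).  This choice matters: a narrow
kernel plus global pooling is translation-invariant along the feature axis
and therefore cannot selectively read a *specific* hidden-feature
coordinate of a specific neighbor — exactly what collaborative rules
require ("neighbor carries motif B").  With the full-width first kernel the
width collapses to one position, the second convolution is pointwise, and
pooling is trivial; narrow same-padded kernels remain available through
`ModelConfig.graph_first_kernel`.  The prediction layer is a single fully
connected map from h_s ‖ h_c to L logits followed by sigmoids.

**Loss and optimization.**  Mean binary cross entropy over bins and
features, with probabilities clamped to [1e−7, 1−1e−7] so the loss is
finite at the boundary.  Optimization is mini-batch SGD with momentum 0.9
and batch size 64.  `TrainConfig` defaults to learning rate 0.5; the
desk-scale presets use 0.1 (pre-training) and 0.05 (graph training) because
0.5 diverges at a few thousand training examples.  Model selection is
always the minimum-validation-loss checkpoint.  Splits are by chromosome
(train / validation / test), never by position, so no information leaks
through overlapping flanks or contacts.

**Reverse-complement averaging** (off by default) re-encodes every sequence
on the opposite strand and averages the two forward passes.

## Contact-map processing

Input maps are symmetric sparse bin-pair records ("i j value" triplets or
pairs-style "chrom1 pos1 chrom2 pos2 [count]"); duplicate records for a
pair are summed and self-contacts dropped.  The preprocessing chain is
normalize → merge → threshold:

1. *normalize_pair*: per chromosome, the map with the larger
   intra-chromosomal total read count is scaled by (smaller/larger), so
   both maps end at the smaller total; inter-chromosomal edges are never
   scaled, and a chromosome with zero total in exactly one map is left
   unscaled with a warning.
2. *merge_maps*: entrywise maximum across cell types (commutative,
   associative, idempotent).
3. *threshold_contacts*: edges with value < tau are removed; values equal
   to tau are kept (default tau = 2, matching a "remove < 2" rule).

Contact distance is |start_i − start_j| (equal-width bins make start-based
and midpoint-based distances identical); inter-chromosomal contacts have
infinite distance and are excluded from distance stratification, which uses
lower-inclusive / upper-exclusive ranges ("over 20 kb" = [20 kb, ∞)).
Coarse Hi-C maps are up-sampled to the fine tiling by connecting every
fine bin to the *central* fine bin of each coarse neighbor of its enclosing
coarse bin; this requires the coarse resolution to be an odd multiple of
the fine width, and even multiples are rejected rather than picking between
two central bins.

## Attribution

All attribution is gradient × input.  For feature l at center i:

* **Contacts.**  S = P ⊙ (∂ŷ_l/∂P); since Xi = P · phi+, the gradient
  factors as (∂ŷ_l/∂Xi) · phi+ᵀ, leaving one score per sampled row.  The
  gradient is taken at the probability by default (matching ŷ); a logit
  option exists because saturated sigmoids shrink probability-space
  gradients.  Scores per matrix are compressed to per-neighbor vectors
  (dummy column dropped; rows that select the same neighbor twice are
  summed within a matrix), the sequential/spatial vectors are combined by
  taking the maximum over the routes that actually sampled the neighbor,
  and the result is row i of the interaction importance matrix M_l.
  Normalization divides each row's absolute values by the row's maximum
  absolute value; all-zero rows stay zero (avoiding 0/0), so M̂ ∈ [0,1]
  with every nonzero row attaining 1.
* **Sequences.**  The same output gradient is pushed through the stacks and
  the frozen encoder to each neighbor's one-hot input:
  S^(j) = x^(j) ⊙ (∂ŷ_l/∂Xi · ∂Xi/∂x^(j)).  Gap positions encoded 0.25
  receive 0.25 × gradient — the formula is applied literally rather than
  masking gaps.
* **Combined.**  Collaborative-pair selection keeps contacts with
  M̂[i,j] ≥ threshold whose center is both truly positive and successfully
  predicted (probability ≥ 0.5, configurable), then attributes both
  anchors' sequences.  The interaction-percentage analysis reports, per
  contact-distance bin and attribution threshold (plus an unfiltered "all"
  baseline), the fraction of qualifying contacts whose far anchor also
  carries the feature; empty cells are NA, not 0.

## Synthetic data

The generator emulates the pipeline's three inputs with planted,
fully-known structure; its defaults are the study conditions of the
recovery experiments.

* **Genome**: i.i.d. uniform background; motif instances (exact 10-mer
  consensi by default) planted per bin with rate 0.3 per motif on a random
  strand, confined within one bin so the labelling rule is unambiguous; an
  instance registry records every placement.
* **Contacts**: intra-chromosomal Poisson counts with mean
  scale · d^(−exponent) (scale 10 at one-bin separation, exponent 1 —
  a generic distance-decay polymer scaling); planted loops add strength 50
  to their anchor pair.  Loops anchor at each bin with probability 0.7 and
  reach 5–50 bins (collaborative preset) or 1.2–4.8 kb (distance preset,
  inside the wired stratum; an extra population of >20 kb loops keeps the
  far stratum populated but uninformative).
* **Labels**: sequence-only rules (motif A on the bin) or collaborative
  rules (motif A on the bin AND motif B on a spatial neighbor with contact
  ≥ 20, optionally restricted to a distance range), evaluated on the same
  thresholded graph the model samples from; emitted peaks cover positive
  bins entirely so the ">half of the bin" labelling reproduces the rule
  exactly.  Label noise is off by default.

Presets: `tiny` (500 bins, 3 chromosomes — CI speed), `collaborative` and
`distance-specific` (2,000 bins over 4 chromosomes; chromosome c2 is the
test set, c3 validation).  A fixed seed reproduces every file byte for
byte.

What the generator does *not* emulate: realistic base composition,
spatially autocorrelated chromatin state, replication of genome-wide
contact statistics, inter-chromosomal contacts, peak-width variation.
Passing recovery tests therefore demonstrates that the architecture and
attribution machinery can exploit contact-mediated information when it
exists, not that they will reach any particular accuracy on real genomes.

## Desk-scale architecture choices

The published-scale configuration (1000-bp windows, K = 2600, k_c = 50,
k_s = 10, deep conv stack with flatten readout) is expressible in
`ModelConfig`, but the tested presets are deliberately small: 400-bp
windows (200-bp bin + 100-bp flanks), K = 64, k_c = 8, k_s = 2, a
single-conv encoder, 16-channel graph stacks.  Two desk-scale findings
shaped the defaults:

* A deep flatten-readout encoder memorizes a ~1,200-example training set
  without learning motifs.  The preset encoder instead uses a global max
  over positions (the classic motif-presence readout), restricted to the
  central bin plus a motif-length margin (`CenterCrop1d`): flanks show
  *neighboring* bins' motifs, and an unrestricted max would make the
  in-window presence signal disagree with the center-restricted label.
* The full-width first graph convolution (above) is what lets the graph
  layers read "neighbor #1 carries motif B" out of phi.

## Numerical and policy choices

* All network math is float32; the layer library has explicit
  forward/backward passes validated against central finite differences.
* Neighbor ordering, mini-batch shuffling and initialization derive from a
  single integer seed per stage; two runs with equal inputs and seed are
  byte-identical, which the test suite asserts at the artifact level.
* AUROC uses midrank tie handling; AUPR is step-wise precision-recall
  integration (no interpolation); recall at FDR sweeps distinct score
  thresholds (tied blocks enter together) and returns 0 when no threshold
  achieves the target FDR.  Features with a single class in the held-out
  set are NA and excluded from aggregate means, with the excluded count
  reported.
* Paired model comparisons use two-sided paired t-tests on per-feature
  differences, dropping NA pairs; zero-variance nonzero differences (a real
  possibility with three synthetic features) are flagged and reported as
  p → 0 rather than raising.
* The "more than half of the bin" labelling rule is strict: overlap exactly
  width/2 is negative.  Overlap is computed on the merged union of a
  feature's peaks.  Trailing partial bins at chromosome ends are dropped.
* The active-bin filter (keep bins with ≥ 1 TF-category label) is available
  but off in synthetic runs, whose negatives are informative by design.

## Problem sizes

The recovery experiments train on ~1,200 bins and evaluate on a held-out
400-bin chromosome; pre-training runs 30 epochs and graph training 40
epochs (~25 s per experiment on one CPU).  These sizes were chosen so the
full study — both recovery experiments plus a reproducibility check —
completes in about a minute while leaving the qualitative contrasts
(collaborative margin, distance-stratum margin) far above their assertion
thresholds.

## Known limitations

* The neural library is CPU-only numpy; genome-scale training (millions of
  bins, thousands of features) is out of reach and out of scope.
* Only first-order spatial neighbors are sampled; higher-order
  neighborhoods via adjacency powers are an extension hook, not
  implemented.
* The contact reader handles triplet and pairs text; binary cooler files
  are not read.
* Matrix balancing (ICE/KR), TAD/loop calling, peak calling and motif
  database matching are out of scope; attribution exports are laid out for
  external motif-discovery tools instead.
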