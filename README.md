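# chromecho

Graph-based multi-label chromatin feature prediction from DNA sequence and
3D chromatin contacts, with gradient×input attribution on both contacts and
base pairs.

## The problem

Transcription factors do not bind DNA in isolation: their binding at one
locus can depend on sequence elements at loci that are far away along the
chromosome but spatially adjacent in the folded genome.  Purely
sequence-based predictors (DeepSEA/DanQ-style convolutional networks) see
only a local window and cannot represent this collaboration.  chromecho is
for computational genomicists who want to (a) predict per-bin chromatin
features — TF binding, histone marks, DHS — using Micro-C/Hi-C contact
maps as a neighborhood structure, and (b) *explain* those predictions by
scoring which chromatin contacts and which base pairs, in the bin itself
and in its spatial neighbors, drove each prediction.

## The model

The genome is tiled into 200-bp bins, the nodes of a graph G = (V, E, A)
whose weighted edges are chromatin contacts.  For each bin i with one-hot
flanked sequence x⁽ⁱ⁾:

1. a pre-trained, frozen convolutional encoder f gives a hidden vector
   φ⁽ⁱ⁾ = f(x⁽ⁱ⁾) ∈ R^K;
2. SAMPLE/STACK turns the graph into grids: Ξ_s⁽ⁱ⁾ stacks
   φ⁽ⁱ⁻ᵏˢ⁾ … φ⁽ⁱ⁺ᵏˢ⁾ (sequential window, genomic order) and Ξ_c⁽ⁱ⁾ stacks
   the top-k_c spatial neighbors {t : A[i,t] ≥ τ} ranked by contact value,
   padding missing slots with an all-zero dummy node.  Equivalently
   Ξ = P·φ⁺ for a binary sampling matrix P with exactly one 1 per row;
3. graph layers convolve over the feature axis with neighbors as channels,
   h_s = g_s(Ξ_s), h_c = g_c(Ξ_c), and a single fully connected layer
   predicts ŷ⁽ⁱ⁾ = p(h_s ‖ h_c) through sigmoids;
4. training minimizes mean binary cross entropy with mini-batch SGD
   (momentum 0.9), splitting train/validation/test by chromosome and
   keeping the minimum-validation-loss checkpoint.

Attribution is gradient×input: on the sampling matrices,
S = P ⊙ ∂ŷ_l/∂P, compressed and combined into a row-normalized interaction
importance matrix M̂_l ∈ [0,1]^{N×N}; on sequences,
S⁽ʲ⁾ = x⁽ʲ⁾ ⊙ (∂ŷ_l/∂Ξ · ∂Ξ/∂x⁽ʲ⁾) scores every base of the center *and*
of each neighbor for its contribution to the center's feature l.  Combining
the two finds collaborative pairs: highly attributed contacts whose center
is truly and predictedly positive, with per-base scores on both anchors.

The neural network (layers, backprop, SGD) is a compact numpy
implementation inside the package — the same machinery serves training and
input-gradient attribution.  See `docs/methods.md` for the full model
description and design rationale.

## Worked example

Everything runs on synthetic data with planted ground truth.  The
`collaborative` preset generates a 2,000-bin genome where feature
`f_collab` is positive iff motif A is in the bin **and** motif B is in a
spatially contacting bin (contact ≥ 20) — information a sequence-only
model cannot see; `f_seqA`/`f_seqB` depend on the bin's own sequence only.

```python
from chromecho.pipeline import RunParams, load_fixture, run_experiment
from chromecho.synthetic import make_fixture
from chromecho.evaluation import auroc

make_fixture("collaborative", "fixture", seed=0)
params = RunParams(seed=0)
bundle = load_fixture("fixture", params)
res = run_experiment(bundle, params)

test = bundle.split_idx["test"]
for l, name in enumerate(bundle.labels.features["name"]):
    e = auroc(res["probs_echo"][:, l], bundle.labels.y[test, l])
    s = auroc(res["probs_seq"][:, l], bundle.labels.y[test, l])
    print(f"{name:10s}  graph-model AUROC {e:.3f}   sequence-only AUROC {s:.3f}")
```

Output (held-out chromosome, ~25 s on one CPU):

```
f_collab    graph-model AUROC 0.962   sequence-only AUROC 0.894
f_seqA      graph-model AUROC 0.998   sequence-only AUROC 0.999
f_seqB      graph-model AUROC 0.992   sequence-only AUROC 0.992
```

The graph model lifts the neighbor-dependent feature by ~0.07 AUROC while
matching the sequence-only baseline on the purely sequence-determined
features — the desk-scale analogue of the method's headline comparison.
The sequence-only ceiling on `f_collab` (~0.89) is the ranking achievable
from "motif A present" alone; closing the rest requires reading motif B off
the spatial neighbors.

## Command line

The same pipeline as composable stages, each writing a config snapshot and
refusing to overwrite without `--force`:

```bash
chromecho simulate   --preset tiny --out fx --seed 0
chromecho preprocess --fixture fx --out data --seed 0
chromecho pretrain   --data data --out pre  --seed 0
chromecho train      --data data --pretrained pre --out mdl --seed 0
chromecho predict    --data data --model mdl --out predictions.tsv
chromecho attribute  --data data --model mdl --feature f_collab --out attr
chromecho evaluate   --data data --pred predictions.tsv --out eval --compare-seq pre
```

`attribute` writes the normalized importance matrix as triplet text plus
per-base bedGraph tracks for the top collaborative pairs; `evaluate` writes
per-feature AUROC / AUPR / recall-at-50%-FDR tables and a paired t-test
against the sequence-only baseline.  Rerunning any stage with the same
inputs and seed reproduces its outputs byte for byte.

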