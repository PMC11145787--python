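# Methods

This note records the models implemented in `hmcnet`, the assumptions
behind them, the numerical choices that are not obvious from the code, and
what the synthetic study can and cannot demonstrate.

## Data model and conventions

All coordinates are 0-based, half-open (BED-native); GTF input is
converted on load. A gene is a stranded span; on the minus strand the TSS
is the last base of the span. Genes are retained only if strictly longer
than 1 kb. Multi-transcript annotations collapse to the gene-level span
(minimum start, maximum end). Coverage is stored as stepwise per-base
depth with a library size (`total_mapped`) used for RPKM; intervals
reaching outside covered territory contribute zero (implicit clipping).
Interval overlap is everywhere ">= 1 bp", so touching half-open intervals
do not overlap.

## 5hmC featurization

Each gene is summarised by 230 bins laid out 5'→3' in transcription
orientation: 15 fixed 100-bp bins over the 1.5 kb upstream of the TSS,
100 fixed 100-bp bins over the TSS ± 5 kb promoter window, 100
variable-width bins tiling [TSS, TTS) (edges at `floor(i·L/100)`, widths
differing by at most 1 bp), and 15 fixed 100-bp bins past the TTS. The
upstream flank overlaps the promoter window; the redundancy is kept so
the layout totals 230 features.

Per bin the feature is `log2((RPKM_IP + 0.5) / (RPKM_input + 0.5))`. The
0.5 pseudocount bounds the feature at zero-coverage bins. Features are
then z-scored per bin with statistics computed on the training genes only
and frozen for validation/test — the held-out chromosomes never touch the
normalisation. Expression labels dichotomise each sample's TPMs at the
median over retained genes, strictly above → High, so ties at the median
are Low and an odd gene count puts the extra gene in Low.

## Expression-state classifier (FCDNN)

A fully connected network 230 → 200 → 100 → 50 → 1 with rectifier hidden
layers and a sigmoid output, trained with binary cross-entropy, Adam at
learning rate 1e-4, hidden dropout 0.15, minibatch 128. Defaults are 40
epochs per-sample and 60 for combined fits. Loss and optimizer are this
package's choices; the rectifier hiddens are required by the attribution
module's Rescale rule. No early stopping: the final-epoch weights are the
model. All stochastic elements (init, minibatch order, dropout masks)
draw from one seeded generator, so runs are bit-reproducible at a fixed
BLAS configuration.

Evaluation is chromosome-held-out: one test and one distinct validation
chromosome, withheld for *every* sample in a combined fit so test genes
are globally unseen. `make_split_schedule` produces the rotation in which
each autosome appears exactly once as test and once as validation (a
seeded derangement).

**Training budget at synthetic scale.** The 40/60-epoch defaults are
calibrated to ~19k training genes per sample; with the synthetic study's
~200 training genes an epoch is two minibatch updates and 40 epochs would
leave Adam's 1e-4 steps far from convergence. Synthetic-scale fits
therefore keep the architecture, learning rate and batch size and train
for 3000 epochs (~6000 updates), matching the optimisation budget a
full-scale fit receives. This is a property of the study size, not a
model change.

## DeepLift (Rescale) decoding

Contributions are computed with respect to the pre-sigmoid logit,
relative to a neutral reference: a single constant broadcast to all bins,
located by grid search plus bisection so the network output is as close
as possible to 0.5, and accepted only inside (0.05, 0.95). Each
rectifier's multiplier is `(relu(z) − relu(z₀)) / (z − z₀)` where the
denominator exceeds 1e-12, otherwise the local derivative; linear layers
contribute their weight matrices. The resulting per-bin scores satisfy
summation-to-delta exactly for this architecture — the test suite asserts
it to 1e-5 relative, and it holds at machine precision. Decoding is done
separately for observed-High and observed-Low genes; profiles report
per-bin mean ± sd.

## Hi-C processing

Per-chromosome sparse symmetric matrices at 10 kb. ICE balancing divides
rows/columns by their relative nonzero-row sums until the coefficient of
variation drops below 1e-5 (default; max 200 iterations); zero rows are
untouched and biases are returned. A deliberately slow elementwise
fixed-point implementation (`ice_oracle`) exists purely as a test oracle.

Distance normalisation subtracts the per-offset median from every entry
and clamps at zero. The median at each offset is taken over *all* bin
pairs at that genomic distance, structural zeros included, so sparse
storage cannot bias it upward. The top-k graph selects each bin's k
strongest nonzero contacts (ties toward the smaller bin index) and takes
the undirected union, so hub bins may exceed degree k. Down-sampling of
valid-pair lists is an exact multivariate hypergeometric draw;
aggregation down-samples each dataset to a common depth, merges, re-bins
and re-balances, with a leave-one-out variant.

## Genome graph classifier (GhmCN)

Nodes are 10 kb windows carrying two features: log10(1 + RPKM) of the IP
and input signal over the window. Windows containing at least one TSS are
masked; a multi-TSS window gets the mean TPM of its genes, dichotomised
at the sample's gene-level median. Masked nodes split 70/15/15 into
train/validation/test by seeded permutation.

The network is a GraphSAGE-style stack: each convolution applies separate
affine maps to the node's own representation and to the mean of its
neighbours', adds them, and rectifies (depth 2 by default — the width-128
default and the 64→32→1 head with 50% dropout are this package's
choices). Inputs are z-scored with statistics frozen on the training
graph: window RPKMs sit on a large common offset with small informative
variation, and without centring a fraction of weight inits collapses to a
constant predictor. Freezing the statistics (rather than re-centring per
graph) keeps cross-graph application deterministic and preserves the
receptive-field property that a node's score depends only on nodes within
conv-depth hops.

Training is full-batch Adam at 1e-3 for 600 epochs by default. The
loop-dependence and explanation studies train for 1200 epochs: the
2-feature task converges slowly, and an underfit model is both less
accurate and explained worse. A trained model applies unchanged to any
graph with the same feature arity (cross-cell-type application).

The 1D control graph (`nearest1d_graph`) wires each bin to its 5 upstream
and 5 downstream neighbours, truncated at chromosome ends.

## Edge-mask explanation

For a target node, a sigmoid-parameterised mask over its 1-hop subgraph
edges minimises

    BCE(model(masked graph)[node], predicted label)
      + 0.005 · Σ mask  +  1.0 · mean(entropy(mask))

for 200 epochs of Adam at lr 0.01 (the regulariser coefficients and epoch
count follow the reference explainer's documented defaults). Two
numerical choices matter and were validated on a star-graph toy where one
edge provably carries the label:

* **Masked aggregation normalises by neighbour count, not mask sum.**
  Scaling a message by its mask and renormalising by the mask sum leaves
  the aggregate invariant to common rescaling — a flat direction in which
  the prediction term carries no per-edge information. Count
  normalisation (mask 1 everywhere reproduces the plain mean) makes each
  edge's contribution genuinely removable; the informative edge then
  ranks first in 20/20 seeded runs on the toy.
* **Mask logits initialise at 0 ± 1e-3** (mask ≈ 0.5, the entropy-neutral
  point). The entropy regulariser amplifies any initial spread into an
  arbitrary bifurcation toward 0/1 that swamps the prediction signal; a
  tiny jitter only breaks exact ties while the size penalty shrinks every
  edge until the prediction term rescues the ones the model relies on.

Explanations target the model's *predicted* label. The computation runs
on the subgraph's node set, which is exact because all other edges are
removed. With 1-hop explanation under a 2-conv model the explanation
subgraph is smaller than the receptive field; edges beyond 1 hop are
treated as fixed context.

## Activity-by-Contact scoring

Candidates: the 150,000 strongest peaks (by score), each trimmed to
summit ± 250 bp, merged when overlapping, blacklist-excluded. Activity:
geometric mean of RPKM-normalised accessibility and activity-track signal
over the element with a 0.1 pseudocount — the activity track is pluggable
(5hmC enrichment or H3K27ac), and swapping it changes scores only through
the activity factor. Contact: the balanced Hi-C entry at the (element,
TSS) bin pair, with a power law `κ·d^(−γ)` fitted per chromosome on
log–log mean contact over 20 kb–2 Mb used two ways: zero/missing entries
are imputed by `κ·d^(−γ)`, and a floor pseudocount `κ·max(d, 1 Mb)^(−γ)`
is always added. Same-bin lookups use the maximum observed contact at
offsets 1–2 (the post-balancing diagonal is ill-defined). Scores
normalise over all candidates within 5 Mb of the gene's TSS, so each
gene's scores sum to one before the 0.02 threshold; γ and κ are refit per
map rather than hard-coded.

## Synthetic study

The generator plants every statistical structure the pipeline assumes,
at defaults chosen once: 4 chromosomes × 10 Mb, 400 non-overlapping genes
(log-uniform lengths 1.5–100 kb), High fraction 0.5 with TPMs from two
log-normal components separated far enough that the median split recovers
the planted labels exactly; Poisson read tracks at 5 reads per 50-bp step
with High-gene bodies multiplied by `2^(d·w(u))` where d = 2 and the
profile w dips to zero at the TSS, is maximal over the first 1–5% of the
body, and decays to a half-strength plateau; planted intergenic enhancers
50–500 kb from High-gene TSSs (IP bump, accessibility peak); contact maps
with expected counts `60·offset^(−1)` Poisson-sampled and mirrored, loops
boosted 8×. These are the study conditions; tests do not move them.

A separate loop-label construction supports the loop-dependence and
explanation experiments: enhancers are planted for genes of both classes,
gene bodies carry *no* enrichment, and only High genes' enhancers carry
an IP bump — so a promoter node's label is encoded solely in a window
50–500 kb away, visible to a graph model only through the loop edge.

What passing shows: the pipeline recovers planted structure through the
full stack (tracks → bins → classifier → attribution; pairs → balancing →
graph → classifier → explanation; peaks + maps → ABC ranking). What it
does not show: robustness to mappability artefacts, copy-number and GC
biases, fragment-length effects, annotation errors, replicate variation,
or the CpG-density dependence of real 5hmC signal — none of which the
generator emulates.

One geometric caveat is documented in the ABC test: because all planted
enhancers share one activity level, score ranks by contact, and an 8×
loop at ≥ 50 kb is arithmetically below the distance-decay contact of a
foreign enhancer within a bin or two of the TSS. The planted element is
therefore asserted to dominate the top of its gene's ranking (top-3 in
≥ 90% of cases, outright winner in a clear majority) rather than to win
universally.

## Determinism and environment

Every stochastic step takes a seed and uses an isolated
`numpy.random.Generator`. Training is single-threaded linear algebra at
the sizes involved; results are bit-reproducible for a fixed numpy/BLAS
build. The test suite and the acceptance script regenerate all data
programmatically — no fixtures are stored.

## Known limitations

* The FCDNN and GhmCN are exact but not fast; they are sized for the
  datasets this package targets (tens of thousands of genes, ~10⁴ graph
  nodes per chromosome), not for GPU-scale sweeps.
* Quartile accuracies, variable-gene subsets and the majority-vote
  baseline assume complete label tables across samples.
* ABC's same-bin contact convention and the 5 Mb candidate window follow
  the reference tool's behaviour; other conventions would change scores
  near promoters.
* The edge-mask explainer inherits the known identifiability limits of
  post-hoc masking: when a model predicts a label from biases alone,
  "no edge needed" is a faithful explanation, and near-boundary genes
  yield flatter masks.
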