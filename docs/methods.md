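# Methods

`mirlink` predicts miRNA–gene associations from sequence alone. The
pipeline has five stages, run in order: (1) k-mer paragraph-vector
embedding of every miRNA and gene sequence; (2) construction of a
balanced labeled corpus by distance-threshold filtering of unknown pairs;
(3) autoencoder compression of the pair embeddings into latent feature
vectors; (4) stacked-LSTM binary classification with stratified 5-fold
cross-validation; (5) ranked scoring of the unknown pair universe for
novel-association discovery. This note records the model assumptions, the
parameters that matter, and the design choices that were genuinely open.

## Sequence representation

Both sequence classes are normalized to the DNA alphabet (U→T) so a
single vocabulary serves miRNAs and genes. Sequences are tokenized into
overlapping k-mers, by default **canonical** (strand-symmetric) k-mers:
each k-mer is replaced by the lexicographic minimum of itself and its
reverse complement, the convention used by k-mer counting tools for
double-stranded DNA. Canonicalization is load-bearing here, not
cosmetic: miRNA targeting is complementarity-based, so a miRNA seed and
its binding site on a target gene are reverse complements and would share
no tokens under plain tokenization — the embedding geometry would then
carry no information about who binds whom. With canonical tokens, binding
partners literally share vocabulary, and sequences that interact end up
closer in embedding space, which is also the premise of the
distance-based negative filter downstream. Default k = 5 (configurable):
a 7-nt seed site spans three 5-mers, each of which is individually rare
in a gene-length background, giving site presence a strong compositional
footprint; 3-mers are individually too common for a handful of sites to
shift their frequencies detectably.

The paragraph-vector model (distributed-memory variant by default) gives
each sequence a trainable 64-d document vector; each token position
predicts its center k-mer from the mean of the window-5 context vectors
plus the document vector, against 5 negative samples from the
unigram^0.75 noise distribution. The trainer is a vectorized numpy
implementation: positions are processed in chunks of 8,192 with summed
gradients, and each aggregated per-row update is norm-clipped at 1.0 —
per-position stochastic updates are not feasible in pure numpy, plain
summed updates diverge on gene-length documents, and mean updates are so
small the document vectors never leave their initialization. Context
sums are refreshed once per epoch (stale within an epoch); the learning
rate decays linearly from 0.025 to 1e-4. Training is single-threaded,
float32, and bit-deterministic for a fixed seed. Default 40 epochs; the
acceptance runs use 20 (embedding quality saturates by then on the
synthetic corpus).

A pair (m, g) is represented by the 128-d concatenation
[miRNA vector ‖ gene vector], miRNA first.

## Negative-pair construction

There is no experimentally validated negative data, so negatives are
constructed from the unknown universe (all miRNA×gene pairs minus the
known positives). For each of three metrics — Euclidean distance, cosine
distance (1 − cosine similarity), and Mahalanobis distance with the
covariance pooled over all miRNA and gene vectors and regularized as
Σ + εI (ε = 1e-6) — the threshold is the arithmetic mean of that metric
over all positive pairs. A pair becomes a negative candidate only if it
strictly exceeds **all three** thresholds (the conjunction is the
strictest reading of "too similar pairs are eliminated"; a `filter-mode
any` switch keeps the alternative). Cosine similarity is converted to a
distance so "exceeds the threshold" points the same way for every metric.
A balanced negative set of exactly the positive count is then sampled
uniformly without replacement, seeded. Candidate order is deterministic
(lexicographic), so the sample is reproducible.

## Autoencoder feature augmentation

The 128-d pair rows are min-max scaled to [0, 1] (the decoder output is a
sigmoid) and compressed by a three-layer ReLU encoder
(128 → 112 → 88 → L, widths tapering at 1/4 and 5/8 of the input→latent
gap; L defaults to 64 from {8, 16, 32, 64, 128}) and reconstructed by the
mirror-image decoder with sigmoid output. Training minimizes MSE with
Adam (lr 1e-3, batch 128), on a 9:1 train/test split of the given rows,
reporting both losses every epoch. Backpropagation uses a leaky
derivative (slope 0.01) on the exact-ReLU forward: with small latent
widths the bottleneck can die early in training, and a pure ReLU gradient
makes that state absorbing — the encoder would freeze at the
predict-the-mean solution. The forward contract (latent entries ≥ 0) is
unchanged. Biases initialize at 0.1 for the same reason. Default 200
epochs as a ceiling; 60 suffice at the synthetic corpus size and are the
desk-scale default in the evaluation harness.

Classifier inputs come in two modes: `latent_only` (rows are z, the
Experiment-A style) and `original_plus_latent` (rows are [x ‖ z], 128+L
wide, the Experiment-B style and the default).

## Classifier

Three stacked LSTM layers, 128 hidden units each, forget-gate bias 1,
followed by a dense head and a sigmoid unit; binary cross-entropy, Adam
(lr 2e-3 constant; an optional linear decay is exposed but off by
default), batch 128. Features are normalized by a
robust scaler (median/IQR) fit on training rows only. Four
regularization devices handle the parameter-to-sample imbalance that
desk-scale corpora create (≈400k weights vs a few thousand rows):
decoupled weight decay 1e-2, input dropout 0.1, an exponential moving
average of the weights (decay 0.99) which is the returned model, and —
for aligned shaping — random permutation of the input steps in every
training batch. Step shuffling encodes the prior that the discriminative
signal is an order-invariant per-step accumulation (a match score summed
over coordinates), so order-sensitive memorization is penalized while the
accumulative solution is untouched; it adds roughly +0.02 held-out AUC at
zero cost in the design experiments. The training budget is configurable
with a desk-scale default of 30 epochs; the multi-million-iteration
regime that full-scale corpora support is a ceiling, not a default.

**Input shaping.** How a flat feature row becomes a sequence for the
recurrent stack is a presentation choice exposed as `input_shaping`:

- `aligned` (default): the row's semantic segments (miRNA 64, gene 64,
  latent L) are interleaved coordinate-wise into 16 steps, each step
  carrying the corresponding 4-wide slice of every segment. This matters:
  the discriminative signal is pairwise (does this gene's vector match
  this miRNA's vector coordinate-by-coordinate?), and presenting
  corresponding coordinates together lets the LSTM's multiplicative gates
  accumulate per-coordinate products — a dot-product-like statistic —
  across steps. In design experiments the aligned presentation reached
  held-out AUC ≈ 0.85 where whole-vector steps plateaued near 0.75
  despite identical features, because the latter must first route
  coordinate correspondences through the recurrent state.
- `tokens3`: three steps — miRNA vector, gene vector, latent block —
  zero-padded to a common width.
- `flat`: one step, full width.

Latent-only features always form a single step.

## Evaluation

Stratified 5-fold cross-validation, seeded. Within each fold the
autoencoder and the robust scaler are fit on the training split only; a
`paper_mode` switch instead fits the autoencoder once on all rows with
its own internal 9:1 split, reproducing the simpler protocol that a
single pre-trained feature extractor implies (at the cost of information
leaking from evaluation rows into the feature extractor — which is why it
is not the default). Metrics per fold: confusion counts at threshold 0.5,
precision, recall, accuracy, F1, and AUC computed as the rank statistic
(ties counted ½), which equals trapezoidal ROC integration and is exactly
testable against O(n²) enumeration. The averages row is the arithmetic
mean of the fold values.

## Discovery

The unknown pool (cross-product minus known positives) is enumerated
lazily in lexicographic order and scored in chunks of 65,536 pairs; a
bounded heap keeps the running top-k, so memory does not grow with pool
size (the full-scale pool is tens of millions of pairs). Ties break by
(miRNA id, gene id). Per-gene ranking is the same scorer restricted to
one gene (top-10 by default; top-30 for the global list). Chunked and
whole-pool scoring agree to float32 accumulation order.

## Synthetic data

The generator emulates the pipeline's real inputs with a planted,
mechanistically faithful association rule: a positive (miRNA, gene) pair
means the gene carries the reverse complement of the miRNA's seed
(positions 2–8) as an embedded 7-mer site. Defaults: 200 miRNAs of
18–25 nt, 500 genes of 300–1,500 nt, 80% of genes targeted, 4 planted
partners per targeted gene, 10 site copies per pair (capped so planted
sites never exceed ~25% of a gene), 5% label noise implemented as
substitution — noisy positive rows are random unplanted pairs, while the
returned ground-truth table keeps the true planted pairs.

Copy number is the signal-strength dial and was set by a design-time
power analysis: one site in a ~900-nt gene shifts each affected k-mer
frequency by well under one standard deviation of the compositional
noise, which no composition-level embedding can detect; ~10 sites make
the affected 5-mers several-fold elevated, and a scalar
composition-match statistic then separates planted from random pairs at
AUC ≈ 0.96, so the end-to-end task is solvable but not trivial (5% label
noise and embedding noise keep the practical ceiling near 0.88).

What the generator does **not** emulate: real 3′UTR base composition and
conservation, RNA secondary structure, expression levels, multi-site
cooperativity, and the heavy-tailed degree distribution of real
interaction networks. Passing the synthetic acceptance suite shows the
pipeline recovers a complementarity-planted signal end to end; it does
not certify performance on biological data.

## Determinism and numerics

Every stochastic stage takes a seed; the pipeline fans a master seed out
per stage by hashing the stage name, so adding a stage never perturbs the
others. Reruns with the same config and master seed reproduce TSV/CSV
artifacts byte for byte. Model arithmetic is float32 (embedding and LSTM)
or float64 (autoencoder, metrics); scores from different batch sizes
agree only to float accumulation order, so ranking contracts are defined
on orderings, not bit-patterns. Degenerate inputs are handled explicitly:
zero vectors are rejected under cosine distance, the pooled covariance is
ε-regularized before inversion, all-identical autoencoder inputs converge
to the scaled-zero reconstruction, and single-class label sets raise (or
yield NaN AUC with a warning in reporting paths).

## Evaluation-harness problem sizes

The packaged evaluation harness uses the default synthetic corpus with
embedding 20 epochs, autoencoder 60 epochs, three seeds and both feature
modes, plus a 40×80 corpus for the byte-determinism check. The test
suite trains the classifier for 30 epochs (original+latent) / 20
(latent-only); the standalone reproduction script uses 18 / 12 so its
whole run stays near a quarter hour on one CPU — the epoch-AUC curve is
flat in this range, so the two report consistent values. These are the
package's desk-scale study conditions; all budgets are configurable
upward.

## Known limitations

- The embedding trainer approximates per-position SGD with chunked,
  clipped, summed updates and per-epoch context refresh; it is tuned for
  corpora of hundreds to thousands of sequences, not genome-scale input.
- Negative construction assumes embedding distance separates
  non-interacting pairs — inherited from the method being implemented;
  violations (e.g., paralogous targets) contaminate the negative set.
- The classifier's advantage over a plain distance rule is modest at
  desk scale; the architecture's capacity pays off only with much larger
  labeled corpora.
- Score calibration is not addressed; outputs are ranking scores, not
  probabilities of interaction.
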