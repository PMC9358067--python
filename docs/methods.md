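# Methods

## Model

The predictor maps an L × D per-residue feature matrix to a topology string
over {B, b, H, h, S, i, o} in three stages.

**Scoring network.** Four convolutional layers, all length-preserving
(zero-padded):

| layer | operation                       | output width |
|-------|---------------------------------|--------------|
| 1     | pointwise conv D → 64, norm, ReLU | 64         |
| 2     | depthwise conv, kernel 9, norm, ReLU (on layer 1) | 64 |
| 3     | depthwise conv, kernel 21, norm, ReLU (on layer 1) | 64 |
| 4     | pointwise conv on concat(1,2,3) → 5 class scores | 5 |

The two depthwise kernels (9 and 21) match the typical lengths of
transmembrane β-strands and helices, so each branch integrates evidence at
the scale of one membrane crossing. Normalization is a layer norm computed
jointly over the whole sequence × channel block of one protein, with
learned per-channel scale and shift. We read "along the sequence and
feature dimensions" literally as a single mean/variance over both axes;
per-channel affine parameters are the conventional choice. Statistics are
always computed per protein on its true length (proteins are processed
individually, so no padding ever enters a statistic).

During training, one Bernoulli(0.5) mask over the 192 concatenated channels
is drawn per protein and broadcast across all positions, with survivors
scaled ×2 (inverted dropout). Masking whole channels rather than individual
entries prevents the head from relying on any fixed subset of features for
an entire sequence.

**Gaussian filter.** Scores are smoothed per class column with the fixed
kernel `w_k ∝ exp(−k²/2σ²)`, σ = 1, size 7 (k = −3…3, covering ±3σ),
normalized to unit sum; sequence ends are zero-padded. The center weight is
≈ 0.399, so an isolated single-residue peak keeps ~40% of its height —
enough to suppress one- to three-residue noise without erasing genuine
short segments. A row-wise max-stabilized softmax then produces class
probabilities.

**Decoder.** The Viterbi decoder maximizes `Σ_t log p_t(class(state_t))`
over a fixed 27-state machine: loop states i and o, a 5-state signal
chain, and four 5-state minimum-duration chains (β and helix, each in both
orientations) whose last sub-state self-loops. Allowed transitions
contribute 0, forbidden ones −∞; there are no trainable transition
weights. The grammar encoded:

- S states are reachable only at residue 0 and exit to o (a translocated
  N-terminus);
- i connects only into in→out chains (exiting to o) and vice versa, and
  there is no direct i↔o arc, so orientation flips exactly at membrane
  crossings;
- all chains are also start and end states at their first/last sub-state,
  so proteins truncated inside a membrane segment at either terminus
  remain decodable.

Ties are broken deterministically by preferring the lowest state index
(order: i, o, S, B↑, B↓, H↑, H↓, low sub-state first) at every backtrack
step; an exhaustive-enumeration oracle with the same tie-break verifies the
dynamic program exactly on small instances. For L < 5 no S/TM chain can
complete its minimum duration, so short peptides decode to pure i/o.
When an input row assigns zero probability to every reachable class, all
path scores are −∞ and the tie-break yields the all-i path.

## Training protocol

Cross-entropy of the smoothed softmax against the five observable classes
(orientation case collapsed: B/b → B, H/h → H); the filter sits inside the
trained graph, the decoder does not (decoding is non-differentiable and is
only needed at inference). The loss is the unweighted mean over all
residues of a batch (16 proteins); gradients are analytic (hand-derived,
verified against finite differences to ~1e-9 relative error) and optimized
with AdamW (β = 0.9/0.999, decoupled weight decay on all trained tensors)
for 15 epochs at `lr₀·0.8^epoch`. Final-epoch weights are kept — no early
stopping.

Model development is a stratified 5-fold nested cross-validation: proteins
are grouped into {β-barrel, single-helix α, multi-helix α, globular} ×
{±SP} (a protein with both strand and helix segments counts as β), each
group shuffled with the run seed and dealt round-robin, so fold sizes
within a group differ by at most one. For each outer fold, hyperparameters
(initial learning rate, weight decay) are chosen by rotating a validation
fold through the remaining four and averaging validation loss; the best
configuration is retrained on all four folds, and only that model predicts
the held-out fold — no protein is ever predicted by a model that saw it.
The five outer models form the final ensemble: their smoothed probability
matrices are averaged (the mean of row-stochastic matrices is
row-stochastic) and the mean is decoded once.

Defaults when no grid is supplied: lr₀ = 1e-3, weight decay = 1e-2. The
benchmark grid explores lr₀ ∈ {1e-3, 1e-2}; on the synthetic sets the
larger rate is consistently selected and weight decay is inert, so the grid
is kept minimal.

## Synthetic data

The generator exists so that training, decoding and evaluation are testable
without curated structures or real embeddings. Topologies are built by
construction for the eight stratification groups: segment counts (even
8–22 strands for barrels, 2–12 helices for multi-helix proteins) and
lengths (helix ≈ round N(21,3) clipped to [12,35], strand ≈ N(9,2) in
[6,14], SP ≈ N(20,3) in [10,40]) are drawn, loops get ≥ 3 residues plus a
multinomial share of the remaining budget, orientation alternates, and
every draw is validated by the label parser. Protein lengths are uniform on
80–400; infeasible draws are resampled (error after 100 attempts).

Features are a deliberately crude embedding surrogate: five fixed random
unit directions in D = 32 dimensions (seeded per config), scaled so
centroid pairs sit ≈ `class_separation` = 2 apart, plus isotropic N(0,1)
noise per residue, then a moving average of half-width 2 along the
sequence to mimic local context mixing. Orientation case does **not**
influence features — the emission model sees five classes, so direction is
recoverable only through the decoder grammar, exactly as in the real
architecture. Consequences for interpretation: passing benchmarks show the
pipeline can recover a localized, class-conditional signal under the
topology grammar; they say nothing about the geometry of real protein
language model embeddings, amino-acid composition effects, or annotation
noise in curated membrane datasets.

## Evaluation

A predicted segment is correct iff |obs ∩ pred| ≥ ½|obs ∪ pred| and both
endpoint deviations are ≤ 5 residues (intervals are half-open; the end
deviation on half-open ends equals the deviation of last residues, keeping
both rules integer-exact). Splitting one observed segment into two
predicted pieces is punished: order-preserving same-kind pairing uses each
segment at most once, and a fragment fails the intersection rule. From the
matches: recall = correct/observed, precision = correct/predicted,
Q_num/Q_ok = % of proteins with the right count / with all segments
correct, Q_top = % of correct segments with the right orientation; only
proteins containing the segment kind contribute. Protein-level calls
(β > α > globular precedence for mixed predictions, since strands are the
rarer and more specific signal) give per-class recall and FPR, plus a
binary SP call.

Metrics are pooled over proteins within a cross-validation split; means
across the five splits carry 95% CIs of 1.96·SE (n−1 sd), and two values
differ significantly iff |A−B| > √(CI_A² + CI_B²). Note that Q_ok (a
per-protein rate) is bounded by recall per protein but not by the pooled
recall, which weights multi-segment proteins more heavily. Edge policies:
precision is NA when nothing of the kind was predicted anywhere in the
contributing set; a kind absent from all proteins reports NA throughout.

## Benchmark sizes and numerical choices

The standard desk-scale runs are: learnability on 500 synthetic proteins
(15 epochs, 72/8/20 train/val/test) with a zero-separation control reusing
the selected configuration; quick-mode nested CV on 200 proteins (2
epochs); 1000 random decodes at L = 50 for grammar soundness and 500
random L = 8 instances against the enumeration oracle. All arithmetic is
float64; layer-norm ε = 1e-5; softmax uses max subtraction; log(0) is kept
as −∞ under controlled error state rather than clamped. Checkpoints store
config, seed and tensors in a single `.npz`.

## Known limitations

- The feature model is a smoothed Gaussian mixture; no claim is made about
  transfer of the benchmark numbers to real embeddings (D = 1024 inputs are
  supported but not exercised by the benchmarks).
- Re-entrant membrane regions (segments entering and exiting on the same
  side) have no state in the grammar and cannot be predicted.
- Order-preserving segment pairing can mis-pair in pathological cases
  (e.g. a spurious prediction upstream of the true match); such cases are
  rare for collinear non-overlapping segments and are accepted.
- Hyperparameter search is deliberately small; the defaults are tuned for
  the synthetic benchmark scale, not for 1024-dim inputs.
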