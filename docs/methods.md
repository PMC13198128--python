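# Methods

## The model

`trialign` implements sequence-anchored tri-modal contrastive pretraining
for proteins.  Three encoders map a protein's modalities to pooled
embeddings:

* **Sequence** — a transformer over amino-acid tokens (alphabet: the 20
  standard residues plus `X`; `B/Z/U/O/J` collapse onto `X`).  A BOS
  token is prepended and an EOS token appended; the pooled embedding is
  the output at the BOS position, which attends to every residue.
* **Structure** — backbone N/CA/C coordinates become a k-nearest-
  neighbour residue graph (CA distances).  Node scalars are sin/cos of
  the backbone dihedrals φ, ψ, ω (zeroed at termini); node vectors are
  the forward and backward CA→CA unit vectors plus an imputed
  side-chain direction built from the N–CA–C frame; edges carry 16
  Gaussian radial-basis features of CA distance (centres evenly spaced
  on [0, 20] Å, σ = centre spacing) and a unit displacement vector.
  Geometric vector perceptron (GVP) message-passing layers update
  scalar channels through vector norms (rotation-invariant) and vector
  channels through channel-linear, invariantly gated maps with no
  vector bias (rotation-equivariant, translation-free by construction).
  The scalar channels then feed transformer layers and the pooled
  embedding is the mean over unmasked residues — exactly translation
  invariant and rotation invariant to floating-point precision.
* **Text** — a transformer over lowercased whitespace tokens from a
  corpus-built vocabulary (PAD/BOS/EOS/UNK specials, out-of-vocabulary
  → UNK); the pooled embedding is the output at the EOS position.  The
  vocabulary object is pluggable so a pretrained subword tokenizer can
  stand in at full scale.

Each pooled embedding passes through a per-modality projection head
(LayerNorm followed by one affine map) into a shared latent space of
equal dimension.  Projected vectors are L2-normalised by default: with
temperature τ = 0.07, unnormalised dot products are numerically
unstable, and 0.07 is the standard temperature for cosine-similarity
contrastive training.  The literal unnormalised reading remains
available (`normalize_projection=False`).

## Pretraining objective

Each step draws, uniformly at random without replacement, a batch of
sequence–structure pairs and a batch of sequence–text pairs.  For each
pair type the InfoNCE loss treats the sequence embedding as the query
and the other modality as keys:

    L = −(1/N) Σ_i log [ exp(sᵢ·kᵢ/τ) / Σ_j exp(sᵢ·kⱼ/τ) ]

with negatives drawn only from within the same pair-type subset and a
log-sum-exp evaluation for stability.  The total loss is the
equal-weight sum of the two terms (a per-term average is available;
the two differ only by a factor of two on the learning rate).  A record
appearing in both subsets in one step is encoded once and its sequence
embedding shared.  Structure and text are never contrasted directly by
default; an optional third structure–text term (`sta_weight`) can be
switched on.  Gradient flows into all three encoders and all heads —
there is no frozen anchor during pretraining.

Optimisation is AdamW (decoupled weight decay) under a cosine-annealed
learning rate.  Documented full-scale settings: 33-layer width-1280
sequence encoder, 4 GVP + 8 transformer structure encoder, 8-layer text
encoder; temperature 0.07; 80 + 80 pairs per step; learning rate 5e-6,
weight decay 1e-4, betas (0.9, 0.95); 20 epochs.  Desk scale (what the
tests and the acceptance script run): 2 transformer layers of width 64
(4 heads), 1 GVP layer (32 scalar / 8 vector channels, k = 16
neighbours), shared dimension 64, batch 32 + 32, learning rate 3e-4,
1,500 steps.  The full-scale learning rate is far too small for a
width-64 model trained for 1,500 steps; 3e-4 was chosen once as the
desk-scale recipe and is recorded here.

## Synthetic corpus

The generator emulates a tri-modal corpus in which the three modalities
share controlled information.  Every record has a latent class
`c ~ uniform(K)` and an instance code `u` (four base-20 letters over
the amino-acid alphabet, unique per record):

* the **sequence** (fixed length, default 32 residues of uniform random
  background) starts with the code flanked by `X` delimiters, followed
  by the class-specific 5-mer motif (`X` never occurs in the
  background, so the code span is locatable);
* the **text** is a template sentence containing a class keyword and
  the code spelled as per-character tokens;
* the **structure** (present for a `structure_coverage` fraction,
  assigned to exactly `round(coverage·n)` records) is an idealised
  helix whose rise per residue depends on the class only (default grid
  1.2 + 0.32·c Å at 100°/residue, radius 2.3 Å), with 0.01 Å Gaussian
  coordinate noise and a random global rigid pose applied last.

Hence sequence↔text share class- and instance-level information,
sequence↔structure share class-level information only, and any
structure↔text alignment must flow through the shared sequence anchor.
Three design points were forced by learnability experiments and are
worth recording, because each closes a shortcut by which desk-scale
contrastive training otherwise memorises training pairs instead of
learning the intended shared signal:

1. **Fixed-position instance code.**  With the code at a random
   position, training memorises the pairs (loss → 0.16) but held-out
   instance retrieval stays at chance — the compositional
   code→embedding map is never learned.  At a fixed position the map is
   position-wise readable and generalises to unseen codes.
   `code_placement="random"` restores the harder variant.
2. **Fixed sequence length and fixed motif position.**  Since a paired
   structure has one residue per sequence position, variable lengths
   leak instance identity into the structure branch; and a
   random-position motif loses to background memorisation, leaving
   held-out sequences without a class signal.  `motif_placement` and
   `background_length` control both.
3. **Small coordinate noise (0.01 Å).**  Per-record noise realisations
   are instance-specific information in the structures.  At 0.1 Å the
   structure encoder fingerprints the noise (the seq–struct loss falls
   to ~0, an instance-level fit that the class-only design is supposed
   to rule out) and held-out class retrieval degrades; 0.01 Å still
   breaks geometric ties but defeats fingerprinting.

What passing tests show — and do not show.  The corpus is deliberately
minimal: uniform backgrounds, one motif, idealised helices, template
text.  Recovery results demonstrate that the alignment mechanics work
(anchored InfoNCE aligns what is alignable, the anchor couples the two
non-anchor modalities, frozen embeddings are linearly/convolutionally
decodable), not that the method attains any particular accuracy on
natural proteins, which have secondary-structure mixtures, disorder,
homology structure and non-template text.

## Downstream task heads

All heads consume embeddings from **frozen** encoders (enforced by
comparing a SHA-256 digest of the encoder weights before and after
every run):

| head | input | architecture | recipe |
|---|---|---|---|
| variant | concat(wild-type, mutant) BOS embeddings | FC(2d→2d) → dropout 0.5 → leaky ReLU → FC → softmax | Adam 1e-4, wd 1e-3, batch 32, ≤200 epochs, early stop after 10 stagnant validation epochs |
| thermostability | structure embedding | FC(d→128) → LayerNorm → ReLU → FC(5) | Adam 1e-3, early stop 10 (recipe assumption, see below) |
| acr | stacked set of embeddings, query first | 2×[conv1d(k=7, d→4→4 ch) + BN + ReLU], masked mean, FC(4) ×2 | Adam 3e-3, wd 0.01→0.001, stop when epoch-loss decrease < 0.005, LR ×0.9 after 10 stagnant epochs |
| peptide | pooled embedding as 1-D signal | 2×[conv1d(k=3, pad 2) + BN + ReLU + maxpool(k=2, pad 1) + dropout 0.15], dense 64, sigmoid | SGD 1e-2, momentum 0.5, step decay ×0.5 / 50 epochs, early stop 40 |
| mic | pooled embedding | FC(d→256) → ReLU → FC(1), MSE | Adam 1e-4, 200 epochs, per-epoch LR lambda (default constant) |
| fitness | per-position embeddings | conv1d(k=7, same) → dropout 0.1 → ReLU → masked mean → FC(1) | AdamW, wd 5e-2, batch 64, cosine + 100 warm-up; 10,000 steps at 3e-4 at full scale, 2,000 steps at 1e-3 at desk scale (a fifth of the steps, compensated by the rate) |

Hidden sizes quoted for 1280-wide embeddings are full-scale literals;
at other widths the variant hidden layer defaults to 2d.  Where the
recipe monitors validation performance but only a train/test split
exists, 10% of the training set is carved out by seed.  Assumptions
the recipes leave open: the thermostability optimiser (unstated;
Adam 1e-3 chosen), the MIC per-epoch LR multiplier (default constant
1.0, pluggable), and the peptide step-decay factor (×0.5 every 50
epochs).  Batch-norm evaluation statistics are population statistics
computed over the training set after training (statistics over padded
set positions are masked out).

`run_task` repeats head training over seeds and reports per-seed
metrics with mean ± SD (sample SD, ddof = 1); `paired_t_report` runs a
two-sided paired t test on per-seed metrics at α = 0.05, flagging the
zero-variance case instead of emitting an undefined p value.

## Metrics

Classification metrics follow the definitional formulas from the 2×2
confusion table; any 0/0 ratio evaluates to 0.0 by convention, and MCC
is 0.0 when a marginal is empty.  AUC is the rank-sum (Mann–Whitney)
form with midrank tie correction; it raises an explicit error for
single-class truth rather than returning a number.  Regression metrics
are MSE, Spearman, Pearson and R².

## Numerical choices

* Compute backend: all model components are pure functions of a
  parameter pytree of numpy arrays, differentiated end-to-end with
  `autograd`; repeated evaluation is bit-identical and every random
  behaviour takes an explicit seed or generator.
* Weight initialisation: truncated normal (σ = 0.02, resampled beyond
  2σ); GVP channel maps use σ = 0.1.
* Learned absolute positional embeddings in all transformers (the
  simplest scheme consistent with an unspecified one).
* Attention masking by additive −1e9 bias; appending PAD after EOS
  changes no valid position's output (asserted to 1e-6).
* GVP vector norms use √(Σv² + 1e-8); zero vector channels stay exactly
  zero through the gated linear path.
* k-NN graphs: self-edges excluded, k capped at n−1, stable argsort;
  altloc ambiguity in PDB input resolves to the first-listed conformer,
  insertion codes order lexicographically after their base number.
* Degenerate inputs: empty structures, empty texts, single-row InfoNCE
  batches, single-class AUC and oversized batch requests raise typed
  errors; consecutive CA–CA distances outside (2.0, 5.0) Å warn but do
  not fail.

## Problem sizes

The test suite and acceptance script run the desk-scale study: a
600-record corpus (8 classes, structure coverage 0.5, seed 0) with an
80:20 split, 1,500 pretraining steps at batch 32 + 32, and single-seed
head training on the 480/120 task splits.  These sizes were chosen as
the smallest at which the alignment and recovery properties are
clearly expressed.

## Known limitations

* Desk-scale encoders are far below the documented full-scale
  configuration; no claim is made about full-scale behaviour.
* The adapter interface for loading externally pretrained encoder
  weights is left open but untested.
* Single-process execution only; no data parallelism, mixed precision,
  or hard-negative mining.
* The text tokenizer is whitespace-based; natural-language realism is
  out of scope.
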