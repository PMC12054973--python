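# Methods

## The model

`funcmatch` frames protein function annotation as binary classification
over (sequence, description) pairs: given a protein's amino-acid sequence
and the free-text description of a candidate function term, the model
outputs the probability p that the term truly annotates the protein.
Because the label enters as *text* rather than as an index into a fixed
output layer, the same trained model can score terms it never saw during
training — zero-shot prediction — including labels from an entirely
different nomenclature (demonstrated with four-level EC numbers, whose
single description is the comma-joined concatenation of the four level
descriptions).

Two frozen encoders map the inputs to vectors: a sequence encoder and a
text encoder. Each vector passes through its own projection head — an MLP
with `n_hidden = 3` hidden layers of `3d` units and a `d`-unit output — and
the two `d`-vectors are concatenated and fused by a third MLP (three hidden
layers of `3d` units, one output unit, logistic link). Hidden activations
are ReLU. With batch normalization on (the default) linear layers carry no
bias; each hidden linear map is followed by normalization, in the order
linear → normalize → ReLU (the relative placement of normalization and
activation is a choice; this order keeps the pre-activation distribution
standardized). At inference, normalization uses accumulated running
statistics, so scoring a single pair and scoring a batch agree exactly.

The network, backpropagation, batch normalization, Adam, and global-norm
gradient clipping are implemented directly in NumPy (`model_core`,
`training`). The first linear layer of each head accepts `scipy.sparse`
inputs and skips its (unused) input gradient, so very wide hashed encodings
cost only their non-zeros.

### Loss and sampling

Annotation corpora are extremely label-imbalanced, which is countered in
two places:

* **Focal loss** `FL = (1 − p_t)^γ (−ln p_t)` with `p_t = p` for a true
  pair and `1 − p` otherwise, and γ = 2 by default, no α class weight.
  Natural logarithm; probabilities are clamped to `[1e−7, 1 − 1e−7]`
  because the loss diverges at `p_t = 0`. The batch loss is the mean over
  all pairs in the batch.
* **Inverse-√frequency sequence sampling.** With `f_j` the number of
  training sequences annotated (after ancestor propagation) with term `j`,
  a sequence `i` is drawn with weight `w_i = Σ_{j ∈ annotations(i)} 1/√f_j`.
  The square root prevents the rarest terms from dominating the sampler.
  Terms requested but absent from the frequency table count as frequency 1,
  avoiding division by zero with minimal distortion.

Each drawn sequence contributes positive pairs for all its (propagated)
annotations and negative pairs for catalog terms outside its annotation
set — all of them by default (`negatives_per_sequence="all"`), or a uniform
subsample for large vocabularies.

### Augmentations

Three stochastic augmentations regularize training; all are off at
inference:

* **BLOSUM62 corruption** — each residue is independently selected with
  probability `corruption_rate` (default 0.1) and replaced by a uniform
  draw from its non-identical residues with strictly positive BLOSUM62
  score. Residues with no positive partner, and X, pass through; length is
  always preserved.
* **Description sampling** — each time a term is encountered, its short or
  long description is used with probability ½ each. At inference the pair
  is scored once with each description and the two probabilities are
  averaged (one pass when the descriptions coincide).
* **Label-embedding noise** — i.i.d. Gaussian noise (σ default 0.1, on
  unit-norm toy embeddings) is added to the text embedding before the
  projection head, smoothing the description space so nearby texts receive
  nearby scores — the property zero-shot transfer leans on.

The substitution distribution (uniform over positive-scoring partners), the
corruption rate, the ½/½ description split, and the Gaussian noise shape
are implementation choices; only the use of each mechanism is prescribed.

### Optimization

Adam with global-norm gradient clipping at 1. The reference recipe uses
learning rate 3e-4 (the `TrainConfig` default); at the package's desk-scale
defaults (200 training sequences, batches of 8 sequences, 60 epochs) the
estimator uses 1e-3, which converges in the available step budget. After
each epoch the validation set is scored (ensembled inference) and the
checkpoint with the best validation macro mAP is returned; without a
validation set, the final epoch.

## Evaluation

Average precision is the non-interpolated estimator: sort by descending
score with a *stable* sort (ties keep input order) and average the
precision at each positive's rank. Terms with no positive example have
undefined AP; they are skipped and counted (`n_terms_skipped`), never
scored zero. Macro mAP is the unweighted mean of per-term APs — every term
counts equally, which is the model-selection metric because the label
distribution is so skewed — and micro mAP is the AP of all (sequence, term)
pairs pooled, hence prevalence-weighted. Micro pooling flattens pairs
across terms (the alternative, averaging within sequences, is not used).
Per-group breakdowns restrict to a term grouping (ontology namespace, or
the first dotted field of an EC code).

Two reference points for zero-shot results:

* **Prevalence floor** — an uninformative scorer's expected AP on a term
  equals the term's positive prevalence, so the mean prevalence over
  scoreable terms is the chance level for macro mAP.
* **Description-similarity baseline** — each out-of-vocabulary term is
  mapped to the in-vocabulary term with the most cosine-similar description
  embedding (mean of short/long embeddings; ties broken by smallest term
  id) and inherits that term's scores wholesale. This uses no trained
  fusion — only text similarity plus in-vocabulary predictions — and is the
  natural lower bound a zero-shot model must beat.

The concordance analysis asks whether sequence embeddings carry function
information *before* the fusion MLP: for every unordered pair of sequences
it compares the cosine similarity of their projection-head embeddings with
the Jaccard similarity of their annotation sets, and reports the Pearson
correlation between the two.

## The synthetic world

The generator (`synthetic_data`) builds worlds with the statistical
structure the method assumes, so every mechanism is exercisable on one CPU
without downloads:

* **Motif-determined function.** Each term is a conjunction of 1–3 sequence
  motifs drawn from a shared pool (8 motifs of length 10 by default); a
  term is positive for a sequence iff all its motifs occur as substrings.
  Sequences are i.i.d. background residues with the motifs of their
  intended terms implanted at non-overlapping positions. Motif length 10 —
  the span of a short functional sequence motif — means each motif spans
  six overlapping 5-mers, giving the k-mer encoder redundant evidence per
  motif; with single-k-mer motifs the world would hinge on individual hash
  buckets and corruption would act as label noise rather than
  regularization.
* **Compositional descriptions.** Descriptions name a term's motifs in a
  shared vocabulary ("motif-3 and motif-7 dependent activity", plus a
  longer templated variant), so unseen terms share tokens with training
  terms — the compositionality zero-shot transfer requires.
* **Skewed labels.** Intended terms are drawn from a Zipf-like law
  (exponent 1.0); the most frequent training term appears ~15× as often
  as the rarest.
* **A consistent DAG.** Parent edges run only from a term to terms whose
  motif set is a *proper subset* of its own, so "ancestor" coincides with
  "logically implied": whenever a child's motifs are present, so are every
  ancestor's, and all emitted annotation sets are closed under ancestor
  propagation by construction. Zero-shot terms take parents only among
  zero-shot terms, keeping the held-out split disjoint from the training
  vocabulary yet still propagation-closed.
* **In/out-of-vocabulary split.** A fraction of terms (6 of 26 by default)
  is held out entirely: they carry ≥ 2 motifs (so recognizing them requires
  genuine composition, not motif identity), appear only in the dedicated
  zero-shot test sequences, and are reachable only through their
  descriptions. Zero-shot sequences carry one held-out label (occasionally
  two), mirroring the sparsity of newly introduced labels in real release
  pairs, plus an occasional in-vocabulary distractor motif set.

Background motif collisions (a term's motifs appearing by chance) are
tolerated and logged rather than rejection-sampled away; at the default
configuration they are far below 1% of positive pairs because a specific
10-mer essentially never arises in ~150 residues of background.

What the world does *not* emulate: real encoder geometry (the toy encoders
are hashed count vectors, not learned representations), homology structure
between sequences, annotation noise/incompleteness, vocabulary scale
(tens of terms vs tens of thousands), and inter-ontology structure.
Passing tests here show the *framework* — losses, sampling, augmentation,
propagation, ensembling, baselines, metrics — behaves as specified and that
the architecture can genuinely compose text and sequence evidence for
unseen labels; they say nothing quantitative about SwissProt-scale
performance.

## Toy encoders

`toy_sequence` hashes k-mer counts (k = 5 by default) into `dim` buckets
with a seeded, platform-stable keyed hash (BLAKE2b) and L2-normalizes;
`toy_text` does the same for lowercased, punctuation-split word tokens.
Both are pure functions of (input, params). The default sequence dimension
is 8192: a background k-mer lands in any given bucket with probability
≈ 146/dim per sequence, so 8192 keeps the false-positive rate per bucket
near 2%; the resulting vectors are ~98% zeros, which the sparse input layer
exploits. The text dimension default is 256 (descriptions have few
tokens, and collisions among the ~dozen motif-naming tokens are what
matter). Real pretrained encoders enter only as precomputed id → vector
tables (`table_lookup`); they are never invoked in-process.

## Numerical choices and degenerate inputs

* Probability clamp `[1e−7, 1 − 1e−7]` before the loss and its gradient.
* Batch-norm ε = 1e−5, running-statistic momentum 0.1.
* He initialization, seeded; identical configs and seeds give bit-identical
  parameters and training streams (single device).
* AP tie-break: stable sort, input order. Baseline argmax tie-break:
  smallest in-vocabulary id.
* Duplicate sequences: first occurrence kept, annotations not merged.
* Non-standard residues other than X are rejected at parse time (BLOSUM62
  lookups need the 20-letter alphabet; X passes through uncorrupted).
* Concordance with < 2 pairs, or constant similarity lists, returns
  Pearson r = NaN rather than raising.
* A NaN training loss aborts with the epoch and step in the message.

## Problem sizes

Defaults are sized for a single CPU: 200/50/50/60 sequences
(train/val/test/zero-shot), 26 terms, d = 64 (hidden width 192), 8192-dim
sparse sequence encodings, 60 epochs of 25 steps. One training run takes
roughly 1.5–2 minutes; the overfit check (augmentations off) reaches
train macro mAP ≥ 0.95 in about the same time; the five-seed zero-shot
comparison stays under 15 CPU-minutes.

## Known limitations

* Single-device, float64 NumPy training; no mixed precision or data
  parallelism, and no learning-rate schedule.
* The OBO reader handles only id/name/namespace/def/is_a — no
  relationship types beyond `is_a`, no obsolete-term replacement.
* Validation macro mAP on 50 sequences is noisy, so best-epoch selection
  can favor a lucky early epoch; training without a validation set keeps
  the final epoch instead.
* The similarity baseline inherits whatever biases the in-vocabulary
  scores carry; with very few in-vocabulary terms its mapping is coarse.
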