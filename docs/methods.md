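# Methods

`rpinet` predicts whether an ncRNA and a protein interact, from sequence
(and optionally secondary-structure) content alone. This note records the
model, the conventions the implementation fixes where the underlying method
leaves freedom, and what the synthetic benchmark does and does not show.

## Sequence coding

Variable-length sequences are mapped to fixed-length k-mer relative
frequency vectors (the conjoint-triad-feature family):

* **Protein.** The 20 standard amino acids are first collapsed to seven
  groups by dipole moment and side-chain volume — {A,G,V}, {I,L,F,P},
  {Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E}, {C}, written as symbols 1..7. The
  baseline coding (`ctf`) counts 3-mers over this alphabet (7³ = 343
  entries); the extended coding (`ictf`) adds the 1- and 2-mer blocks
  (7 + 49 + 343 = 399); the structure-augmented coding (`isctf`) further
  appends 1..3-mer blocks over the three-state secondary-structure alphabet
  H/E/C (+3 + 9 + 27 = 438).
* **RNA.** Nucleotides A,C,G,U (T is read as U); `ctf` counts 4-mers
  (4⁴ = 256), `ictf` uses k = 1..4 (340), and `isctf` appends 1..4-mer
  blocks over the two-state structure alphabet unpaired/paired obtained by
  collapsing dot-bracket strings ('.' → unpaired, '(' and ')' → paired),
  giving 340 + 2 + 4 + 8 + 16 = 370.

Conventions the implementation fixes:

* **Frequency normalization.** Each k-block is count / (number of valid
  k-mer windows of that length), so every block sums to 1 (or is all-zero
  when the sequence is shorter than k). This makes vectors invariant to
  sequence length, which is the point of the representation.
* **Entry order.** Lexicographic in the k-mer under the declared alphabet
  orders (A,C,G,U; groups 1..7; H,E,C; unpaired,paired), blocks concatenated
  in ascending k, sequence blocks before structure blocks. Any fixed order
  would do; this one is stable and documented.
* **Ambiguity codes.** Residues outside the standard alphabets (X, B, Z,
  selenocysteine U in proteins, N in RNA, ...) become an unknown marker;
  k-mer windows covering the marker are skipped (they count toward neither
  numerator nor denominator) rather than the sequence being rejected,
  because curated FASTA collections routinely contain them.
* Pseudoknot characters in dot-bracket strings are rejected rather than
  silently collapsed.

## Datasets, negatives and identity

Interaction data arrive as FASTA files plus a tab-separated pair table
(rna_id, protein_id, label). Curated collections usually ship only observed
(positive) pairs, so balanced training sets are built by randomly re-pairing
the RNAs and proteins occurring in positives and discarding any candidate
that resembles a known interaction: candidate (R1, P1) is discarded when
some positive (R2, P2) satisfies identity(R1,R2) ≥ 0.80 **and**
identity(P1,P2) ≥ 0.40. Sampling is uniform with replacement over the
positive-set entities, reproducible under a seed, and capped at a
configurable attempt budget (default 1000 × the number of positives) before
reporting the shortfall.

Sequence identity is computed internally as the maximum number of aligned
matches (global alignment, match +1, mismatch 0, gaps free — equivalently
the longest common subsequence) divided by the length of the *shorter*
sequence, the convention used by clustering tools of the CD-HIT family.
Two caveats follow from this convention and are worth knowing:

* Unrelated sequences have substantial background identity under LCS
  (≈0.63 for random RNA, ≈0.33–0.35 for random protein of equal length),
  comfortably below the 0.80/0.40 thresholds.
* The shorter-sequence denominator inflates identity when lengths are very
  heterogeneous (a short sequence embeds well into a much longer random
  one). With length ratios ≳2 within a molecule class, the discard rule
  becomes very restrictive and negative generation may legitimately fail
  with an insufficient-candidates error.

Positive-set near-duplicate removal (same conjunction) is available as an
optional step (`deduplicate_positives`), off by default.

## Model

Each (RNA, protein) pair is scored by four "basic modules" and an ensemble
head:

| module | input coding | branch architecture |
|---|---|---|
| Conjoint-CNN | ictf (340 / 399) | Conv-45-64-45, kernel 6, max-pool 2 between convs, flatten, Dense-128 |
| Conjoint-SAE | ictf (340 / 399) | Dense-256-128-64, greedily pretrained |
| Conjoint-Struct-CNN | isctf (370 / 438) | as Conjoint-CNN |
| Conjoint-Struct-SAE | isctf (370 / 438) | as Conjoint-SAE |

Within a module the RNA and protein branches are parallel; their embeddings
are concatenated into a Dense-128-64-2 softmax head. The ensemble model
concatenates the four modules' two-class probability outputs (8 values)
into a Dense-16-8-2 softmax head trained with the basic modules frozen
(their weights are bit-identical before and after head training). Batch
normalization precedes ReLU in the convolution stacks and dense heads
(conv/dense → batch-norm → ReLU); SAE branches are plain dense + ReLU.
Dropout (rate 0.2) follows the dense embedding and head layers.

The networks are implemented in a small numpy layer library inside the
package (`rpinet.nn`): dense and same-padding 1-D convolution layers,
non-overlapping max pooling, batch normalization with running statistics,
inverted dropout, a fused softmax/cross-entropy loss, and Adam/SGD
optimizers, all seeded through `numpy.random.Generator`. Batch-norm
inference statistics use a bias-corrected exponential moving average of the
batch statistics (correction 1 − m^t, as in Adam), so inference behaves
sensibly even when training involved only a handful of minibatch updates —
a regime that matters for small datasets.

### Training protocol

Each module minimizes binary cross-entropy in two optimizer phases — Adam
(default lr 1e-3) for fast convergence, then plain SGD (default lr 1e-4)
for fine-tuning. After every epoch the accuracy on the *training* pairs is
recorded; whenever it beats the running best the full network state
(including batch-norm running statistics) is checkpointed. When the best
has not improved for `patience` consecutive epochs, training stops — in
whichever phase — and the best checkpoint is restored. Monitoring training
accuracy (not a validation split) is deliberate: it matches the protocol
this architecture was described with; a validation-based variant can be had
by splitting pairs upstream.

The ensemble head trains under its own schedule (`ensemble_*` config
fields: Adam lr 1e-2 then SGD lr 1e-3, up to 50 + 10 epochs, patience 10),
independent of however the basic modules are budgeted. The head is a
192-parameter network over 8 probability inputs, so these epochs are
essentially free; giving it a fixed, generous schedule avoids a failure
mode in which a tightly budgeted module schedule leaves the head
under-trained near its (possibly confidently wrong) initialization.

SAE branches are pretrained greedily before supervised training: each dense
layer in turn is paired with a throwaway linear decoder and optimized on
mean-squared reconstruction error of its input (20 epochs per layer by
default), the trained encodings feeding the next layer; the supervised head
is untouched.

### Input standardization

k-mer frequencies are small (order 1/|alphabet|^k) and nearly constant in
scale, which makes optimization needlessly slow. Each module therefore
z-scores every input feature using mean/std fitted on its *training* data
(constant features are left unscaled); the parameters are stored with the
module and applied at prediction time. This is a preprocessing choice of
this implementation; it changes convergence speed, not representational
content, and can be disabled (`standardize=False`).

### Defaults and seeds

`ModuleConfig` defaults: conv filters (45, 64, 45), kernel 6, pool 2,
branch dense 128, SAE widths (256, 128, 64), heads (128, 64, 2) and
(16, 8, 2), dropout 0.2, Adam lr 1e-3 (≤50 epochs), SGD lr 1e-4 (≤50
epochs), patience 10, batch 64. Widths are the published architecture;
optimizer settings are conventional defaults, all exposed.
`ModuleConfig.quick()` is a scaled schedule (Adam ≤5 + SGD ≤1 epochs,
patience 2, batch 128, 10 pretraining epochs) that suffices on the planted
synthetic benchmark, where the signal is strong. Every stochastic step
(initialization, shuffling, dropout, sampling) derives from explicit seeds;
repeated runs with the same seed on the same platform reproduce identical
results under single-threaded BLAS.

## Synthetic benchmark

The generator (`rpinet.synthetic`) emulates the *shape* of curated RPI
benchmarks: entities with lengths drawn from a configurable range (default
50–250; real collections span roughly 0–4000 but most chains are a few
hundred units), balanced pair tables, and per-sequence structure strings.
Interaction is a planted motif conjunction — positive iff the RNA contains
a 4-nt motif and the protein a 3-aa motif — optionally flipped with
probability `label_noise`. Motifs are planted into half of the entities by
default; labels are then assigned from actual containment, so with zero
noise the rule is exactly decidable from sequence content, and the motif
lengths sit inside the encoders' k ranges, so the signal is representable
by the features. Protein structures are H/E/C strings with geometric run
lengths (mean 5); RNA structures are random balanced dot-bracket strings.

What passing on this benchmark shows: the encoders preserve the planted
k-mer signal, the modules and ensemble can learn a motif-conjunction rule
from ~2000 pairs, and the pipeline is leak-free (permuting labels drops
held-out AUC to ≈0.5). What it does not show: performance on real
interaction data, where the signal is weaker, distributed, and entangled
with composition and homology structure; structure strings here carry no
signal at all, so the struct modules' added value on real data is not
exercised.

## Problem sizes used by the test suite and acceptance script

The acceptance run simulates 1000 positive + 1000 negative pairs over
150 RNAs × 150 proteins, runs stratified five-fold cross-validation of the
full ensemble with `ModuleConfig.quick()`, repeats it with permuted labels,
and generates negatives for a 50-positive dataset (entity lengths 150–250,
where the identity backgrounds are well separated from the thresholds).
Unit tests use smaller instances of the same generator. These sizes are the
package's benchmark conditions; larger runs only sharpen the same
comparisons.

## Known limitations

* The identity measure is an LCS ratio, not a banded alignment identity;
  it is exact for the stated scoring but more permissive than CD-HIT's
  banded identity on length-heterogeneous inputs (see caveats above). An
  external `cd-hit` binary can be substituted upstream by filtering the
  pair table before loading.
* Early stopping on training accuracy can overfit noisy data; the planted
  benchmark is noise-free by default, so this is visible only with
  `label_noise > 0`.
* The CNN treats the feature vector as a 1-D signal; adjacency in the
  vector is lexicographic, not biological. This mirrors the original
  design; the convolution is best thought of as a learned local feature
  mixer rather than a sequence scanner.
* Training is CPU-bound numpy; wall-clock scales linearly in pairs ×
  epochs. The published-size schedules (50+50 epochs) are practical up to
  a few thousand pairs.
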