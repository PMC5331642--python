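# Methods

## Problem and model

`rbpdeep` predicts whether a 101-nt RNA window centred on a CLIP-seq
crosslink site is a binding site of the assayed RNA-binding protein, and
extracts the sequence motifs the trained model relies on.  Five
representations of the window are modelled jointly:

1. **Region type** — each position labelled exon, intron, 5'UTR, 3'UTR or
   CDS, one-hot encoded per position (505 features).  Position-major
   layout: index `i*5 + rank(category)`.
2. **Co-binding** — for each of E other CLIP experiments (30 in the
   benchmark layout), a presence bit per position (count > 0), flattened
   position-major (3030 features).
3. **Structure** — a per-nucleotide pairing-probability track in [0,1],
   taken as supplied (e.g. RNAplfold output); the encoder validates and
   passes through.  The values are treated as opaque probabilities — the
   model is agnostic to whether they are paired or unpaired probabilities.
4. **Motif scores** — the best log2-odds hit of each library PWM
   (pseudocount 1e-3, uniform background), one score per motif.  This is
   a deliberate simplification of HMM-based motif-cluster scoring: the
   network only needs a monotone per-motif affinity, not a calibrated
   cluster probability.  `N` bases contribute the background log-odds (0).
5. **Sequence** — one-hot, columns A,C,G,U; `N` becomes uniform 0.25.

The network has one branch per modality.  The sequence branch is a CNN:
valid cross-correlation with `nb_filter=102` filters of length 10
(filters are motif detectors: 1.5× the typical 7-nt verified RBP motif
width), ReLU, max pooling, flatten, dense 128.  Each other branch is two
dense layers — (256,128) region type, (768,256) co-binding, (128,64)
structure, (128,64) motif — with batch normalisation, ReLU and dropout
0.5 after each.  Branch outputs are concatenated (640 units with all five
branches), batch-normalised, passed through a 128-unit shared dense layer
with dropout, and a single sigmoid unit outputs P(bound).

Training: binary cross-entropy, RMSprop (rho 0.9), batch size 100, at
most 20 epochs, early stopping on validation loss with patience 3 and
restoration of the best-validation parameters.  All randomness — weight
initialisation (Glorot uniform), minibatch shuffling, dropout masks —
derives from one seeded generator, so runs are bitwise reproducible.

Everything is implemented in numpy: the convolution, pooling, batch-norm
and RMSprop steps are explicit and checked against naive loop oracles and
finite-difference gradients in the test suite.

## RBM pre-training

`rbpdeep.rbm` provides binary and Gaussian-visible restricted Boltzmann
machines trained by CD-k (default k=1, lr 0.01, 10 epochs), stackable
into a DBN whose weights can seed the dense branches
(`NetConfig.use_pretraining`).  Binary RBMs serve the binary modalities
(region type, co-binding); the Gaussian-visible variant, which assumes
standardised unit-variance inputs, serves structure and motif scores.
Deeper stack layers are trained on *sampled* hidden states so the binary
data contract holds at every level.  Pre-training defaults to **off**:
supervised training from Glorot initialisation reaches the same
desk-scale performance without the extra cost, and the pure dense+dropout
configuration is itself a faithful architecture; both paths are tested.
An exhaustive-enumeration oracle (`rbm_prob_brute`, ≤20 total units)
verifies that CD-1 actually climbs the exact likelihood.

## Motif discovery

For each trained filter, every (sequence, offset) whose post-ReLU
activation exceeds 0.5× that filter's maximum activation over the scanned
set is collected; the corresponding length-10 subsequences are tallied
into per-column nucleotide counts and normalised with pseudocount 1.0
into a PWM.  By default only positive-class sequences are scanned (the
binding class is where motifs live); a flag uses all.  PWMs are exported
in MEME-minimal format for external matching (e.g. TOMTOM).  The internal
matcher scores query/target alignments by the mean per-column Pearson
correlation over the best overlap (≥4 columns; zero-variance columns
contribute 0) and attaches an empirical p-value from ≥1000 seeded
column-shuffle permutations of the library.  Filter enrichment between
classes uses a sequence-level 2×2 table (≥1 above-threshold hit vs none)
tested by two-sided Fisher's exact test with Benjamini–Hochberg
adjustment across filters; the enrichment statistic in the original
analyses is unnamed, so this standard choice is documented rather than
claimed.  Filter clustering is average-linkage hierarchical clustering on
cosine distances of flattened PWMs.

## Evaluation protocol

AUC is the midrank Mann–Whitney statistic (ties count half), with the ROC
curve swept over grouped thresholds.  The benchmark protocol is a fixed
4000/1000/1000 train/validation/test split for datasets of ≥6000 windows;
smaller datasets use stratified 5-fold cross-validation (hand-rolled
seeded round-robin dealing so fold sizes differ by at most one and class
balance is preserved; each fold's training part donates a validation
subset for early stopping).

## Synthetic data generator

The generator emulates the structure of CLIP-derived training data so
every stage is testable with known ground truth:

* **Sequences** — i.i.d. uniform ACGU (optionally a mildly sticky
  first-order chain).  Each positive carries, with probability
  `motif_strength` (default 0.8), one realisation *sampled column-wise*
  from the planted PWM at a uniform offset; implant offsets are recorded.
* **Planted PWM** — width 7 (the typical verified RBP motif width), one
  dominant base per column with probability 0.95.  The dominance was set
  against the ideal-detector oracle: the matched log-odds filter of the
  plant itself scores held-out AUC ≈0.96 at 0.95 dominance, while at 0.85
  even the ideal detector cannot exceed ≈0.87, leaving no headroom for a
  learned model to demonstrate recovery.
* **Structure** — Beta(2,5) noise (loop-probability-like, mean ≈0.29)
  with the central 10 nt of positives shifted by `structure_effect`
  (default +0.2), clipped to [0,1].
* **Region labels** — one or (30% of windows) two segments per window,
  categories drawn from class-specific distributions: negatives
  intron-heavy (0.20/0.40/0.10/0.15/0.15 over
  exon/intron/5'UTR/3'UTR/CDS), positives exon/3'UTR-enriched
  (0.35/0.15/0.10/0.25/0.15) — RBP sites concentrate in mature-transcript
  context.
* **Co-binding** — presence Bernoulli at rate 0.15 (positives) vs 0.10
  (negatives), counts 1+Poisson(1) where present.
* **Motif-score library** — 102 Dirichlet-column PWMs with the planted
  motif as the first entry, mirroring a catalogue that contains the true
  binder.

`SimConfig.null()` switches every class asymmetry off for calibration
runs.  What the generator does **not** emulate: real genomic base
composition and repeat structure, transcript-boundary effects, correlated
co-binding across experiments, peak-shaped crosslink pile-ups, and the
negative-selection rules of real benchmarks.  Passing tests therefore
demonstrate correctness and recoverability of the machinery, not
genome-scale accuracy; the published-scale benchmark requires the
external 31-experiment dataset, for which only a directory loader is
provided.

## Numerical and design choices

* **Learning rate 0.003.**  The paper-style description fixes optimizer,
  batch size and epoch cap but no rate.  0.003 lets the numpy RMSprop
  trainer fit the planted-motif task within the 20-epoch cap; 0.001 needs
  several times more epochs.
* **Global max pooling by default.**  With local pooling (window 3) the
  flattened 30×102 map feeds a dense layer that, at desk-scale n,
  memorises training sequences outright (train loss →0.04 while
  validation never improves); a single max per filter regularises the
  branch and recovers held-out AUC ≈0.95.  Local pooling remains a config
  option (`pooling="local"`) and is oracle-tested.
* **Batch normalisation after every dense layer.**  With merge-only
  normalisation the five-branch model could lose ≈0.08 AUC to the
  sequence-only ablation when the other modalities are pure noise;
  per-layer normalisation balances branch scales and closes the gap.
* **Early stopping** restores the best-validation snapshot; with no
  validation set it is disabled with a warning.  Improvement threshold
  1e-6 on the loss.
* **Degenerate inputs** — empty activation tables yield a flagged uniform
  PWM (n_sites=0); single-class training labels warn and proceed;
  zero-margin enrichment tables return p=1; all-tie score vectors give
  AUC 0.5 by the midrank convention.
* **Coordinates** are 0-based half-open; minus-strand windows are
  reverse-complemented with all positional tracks reversed so index 0 is
  always 5'-most; T→U on read.

## Desk-scale problem sizes

The bundled tests and the acceptance script run the recovery benchmark at
n=2000 windows × 5 seeds (sequence branch), the null calibration at
n=200 with the full five-branch model, and RBM likelihood checks on
2-visible/2-hidden machines where exact enumeration is feasible.  These
sizes give stable statistics (recovery similarity ≈1.0 in 5/5 seeds, null
CV AUC within 0.5±0.08) while keeping a full run in minutes on one CPU.

## Known limitations

* No recurrent layers, GPU path, or hyperparameter search.
* The motif-score encoder is a max-log-odds scan, not an HMM cluster
  model; scores are comparable within a motif, not across motifs.
* The internal PWM matcher is a substitute for TOMTOM, suitable for
  ranking and testing; published-style motif match p-values should come
  from TOMTOM on the exported MEME file.
* Gaussian-RBM pre-training assumes standardised inputs and uses
  mean-field reconstructions; no persistent CD or partition-function
  estimation beyond the brute-force oracle.
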