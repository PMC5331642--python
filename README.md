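# rbpdeep

Multimodal deep learning for predicting RNA-binding-protein (RBP)
interaction sites on RNAs from CLIP-seq-derived features, with
convolutional-filter motif discovery.

RBPs recognise short sequence and structure elements on transcripts.
CLIP-seq experiments pinpoint single-nucleotide crosslink sites genome-wide,
and around each site a 101-nt window carries several complementary kinds of
evidence: the sequence itself, the transcript region it falls in
(exon/intron/UTR/CDS), whether other RBPs bind the same positions
(co-binding), the local secondary-structure profile, and how well known
RBP motifs score there. `rbpdeep` fuses all five, trains a hybrid network
— a convolutional branch over the one-hot sequence plus a two-layer dense
branch per non-sequence modality, merged into a shared hidden layer with a
sigmoid output — and then reads the trained convolutional filters back out
as position weight matrices (PWMs) to discover binding motifs.

The package is aimed at computational biologists who want a transparent,
dependency-light (pure numpy) implementation of this architecture that can
be trained, interrogated and unit-tested at desk scale, together with a
synthetic CLIP-like data generator with planted motifs so every stage has
known ground truth.

## The model

Each window is encoded as five fixed-size representations:

| modality     | encoding                                   | dim       |
|--------------|--------------------------------------------|-----------|
| region type  | 5-category one-hot per position            | 101×5=505 |
| co-binding   | cDNA-count presence per experiment         | 101×30=3030 |
| structure    | per-nucleotide pairing probability         | 101       |
| motif scores | best log-odds PWM hit per library motif    | 102       |
| sequence     | one-hot over A,C,G,U                       | 101×4     |

The sequence branch convolves 102 filters of length 10 (ReLU, max pooling,
dense 128); the dense branches use 256→128 (region type), 768→256
(co-binding), 128→64 (structure) and 128→64 (motif scores) hidden units,
each with batch normalisation, ReLU and dropout 0.5.  The concatenated
branch outputs feed a 128-unit shared layer and a single sigmoid output
P(bound).  Training minimises binary cross-entropy with RMSprop (batch
100, ≤20 epochs, early stopping on validation loss).  The dense branches
can optionally be initialised by greedy layer-wise pre-training of
(Gaussian-)restricted Boltzmann machines via contrastive divergence;
`rbpdeep.rbm` implements the RBMs with an exhaustive-enumeration
likelihood oracle used in the tests.

Motif discovery follows the DeepBind/Basset recipe: for every filter,
collect all subsequences whose post-ReLU activation exceeds half the
filter's maximum over the data, tally them into a count matrix, normalise
with a pseudocount into a PWM, and export in MEME-minimal format (ready
for TOMTOM).  An internal matcher (mean per-column Pearson correlation
over the best overlap, permutation p-values) aligns discovered motifs
against a known-motif library; per-filter class enrichment uses Fisher's
exact test with Benjamini–Hochberg correction.

## Worked example

```python
import numpy as np
from rbpdeep.synthetic import SimConfig, generate_dataset
from rbpdeep.network import NetConfig, build_model, train, predict, stack_bundles
from rbpdeep.evaluation import roc_auc
from rbpdeep.motif_miner import mine_motifs, match_pwms

# 2000 windows; every positive carries one planted width-7 motif
cfg = SimConfig(n_pos=1000, n_neg=1000, motif_strength=1.0, seed=100)
bundles, labels, truth = generate_dataset(cfg)
X = stack_bundles(bundles)

net = NetConfig(seed=0, modalities=("sequence",))   # sequence-only ablation
model = build_model(net)
idx = np.random.default_rng(0).permutation(2000)
trn, val, te = idx[:1400], idx[1400:1700], idx[1700:]
train(model, {k: v[trn] for k, v in X.items()}, labels[trn],
      {k: v[val] for k, v in X.items()}, labels[val], net)

auc = roc_auc(predict(model, {k: v[te] for k, v in X.items()}), labels[te]).auc
pwms = mine_motifs(model, truth["sequences"], labels)
best = max(match_pwms(p, truth["library"], n_permutations=100)[0].similarity
           for p in pwms[:10])
print(f"test AUC {auc:.3f}")
print(f"planted motif: {truth['planted_pwm'].consensus()}")
```

Output:

```
test AUC 0.938
planted motif: UUAGACC
```

The held-out AUC of 0.94 says the convolutional branch found the planted
signal; mining the filters yields PWMs whose per-column correlation with
the planted motif reaches 0.8 among just the first ten filters and ≈1.0
over all 102.  With
`motif_strength=0` and symmetric class distributions (`SimConfig.null`)
the same pipeline stays at AUC ≈ 0.5 — the model does not invent signal.

The same pipeline is available from the shell:

```bash
rbpdeep simulate --n-pos 1000 --n-neg 1000 --seed 1 --out data/
rbpdeep train --data data/ --out run/
rbpdeep predict --model run/ --data data/ --out run/scores.tsv
rbpdeep eval --scores run/scores.tsv --labels data/labels.tsv
rbpdeep motifs --model run/ --data data/ --out run/motifs/
```

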