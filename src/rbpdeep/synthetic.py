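"""Synthetic CLIP-like datasets with controllable signal per modality.

Positives are uniform-random 101-nt windows that (with probability
``motif_strength``) carry one sampled realisation of a planted PWM at a
uniform random offset, plus class-shifted structure probabilities, a
class-biased region-type composition, and class-specific co-binding
rates.  Negatives draw from the baseline distributions.  Every stage of
the pipeline is therefore testable at desk scale with known ground
truth: the generator records the planted PWM and per-sequence implant
offsets.

All randomness flows from one seeded generator: equal seeds give
bitwise-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .encoders import (FeatureBundle, encode_cobinding, encode_region_type,
                       encode_structure, one_hot, score_library)
from .pwm import ALPHABET, PWM, PWMLibrary, pwm_from_probs, write_meme
from .sample_io import REGION_CATEGORIES, WINDOW_FLANK, WINDOW_LEN

__all__ = ["SimConfig", "make_pwm_library", "make_planted_pwm",
           "generate_dataset", "write_dataset", "load_dataset"]

N_EXPERIMENTS = 30        # co-binding tracks from the other experiments
PLANT_WIDTH = 7           # width of experimentally verified RBP motifs
CENTER_HALF = 5           # structure effect acts on the central 10 nt

# baseline / positive-class region-type composition (exon, intron, 5'UTR,
# 3'UTR, CDS): negatives intron-heavy, positives enriched for exonic and
# 3'UTR context, the usual place RBP sites concentrate
_REGION_NEG = (0.20, 0.40, 0.10, 0.15, 0.15)
_REGION_POS = (0.35, 0.15, 0.10, 0.25, 0.15)


@dataclass
class SimConfig:
    """Generator settings; defaults give a moderately informative dataset."""

    n_pos: int = 1000
    n_neg: int = 1000
    motif_strength: float = 0.8   # P(a positive carries the plant)
    planted_pwm: PWM | None = None
    structure_effect: float = 0.2  # mean center shift of structure probs
    region_bias: dict | None = None  # {"pos": 5-vector, "neg": 5-vector}
    cobind_rates: tuple[float, float] = (0.15, 0.10)  # (positive, negative)
    library_size: int = 102
    n_experiments: int = N_EXPERIMENTS
    seed: int = 0
    markov_background: bool = False  # first-order sticky background

    def __post_init__(self) -> None:
        if not (0.0 <= self.motif_strength <= 1.0):
            raise ValueError("motif_strength must be in [0, 1]")
        if any(not 0.0 <= r <= 1.0 for r in self.cobind_rates):
            raise ValueError("cobind_rates must be in [0, 1]")
        if self.region_bias is None:
            self.region_bias = {"pos": np.asarray(_REGION_POS),
                                "neg": np.asarray(_REGION_NEG)}
        else:
            self.region_bias = {k: np.asarray(v, dtype=float)
                                for k, v in self.region_bias.items()}
            for v in self.region_bias.values():
                if v.shape != (5,) or not np.isclose(v.sum(), 1.0):
                    raise ValueError("region_bias entries must be 5-vectors summing to 1")

    @classmethod
    def null(cls, n_pos: int = 100, n_neg: int = 100, seed: int = 0,
             **kw) -> "SimConfig":
        """A label-uninformative configuration: no plant, no class shift."""
        bg = np.asarray(_REGION_NEG)
        return cls(n_pos=n_pos, n_neg=n_neg, motif_strength=0.0,
                   structure_effect=0.0,
                   region_bias={"pos": bg, "neg": bg},
                   cobind_rates=(0.10, 0.10), seed=seed, **kw)


def make_planted_pwm(seed: int = 0, width: int = PLANT_WIDTH,
                     dominance: float = 0.95) -> PWM:
    """A sharp random motif: one dominant base per column."""
    rng = np.random.default_rng(seed)
    probs = np.full((4, width), (1.0 - dominance) / 3.0)
    consensus = rng.integers(0, 4, size=width)
    probs[consensus, np.arange(width)] = dominance
    return pwm_from_probs(probs, id="planted")


def make_pwm_library(n: int, width: int = PLANT_WIDTH, seed: int = 0) -> PWMLibrary:
    """``n`` random Dirichlet-column PWMs with a uniform background."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if width < 4:
        raise ValueError("width must be >= 4")
    rng = np.random.default_rng(seed)
    pwms = [
        pwm_from_probs(rng.dirichlet(np.full(4, 0.5), size=width).T, id=f"lib_{i}")
        for i in range(n)
    ]
    return PWMLibrary(pwms=pwms)


def _random_sequences(rng: np.random.Generator, n: int,
                      markov: bool) -> np.ndarray:
    """(n, 101) base-index matrix; optionally a sticky first-order chain."""
    if not markov:
        return rng.integers(0, 4, size=(n, WINDOW_LEN))
    seqs = np.empty((n, WINDOW_LEN), dtype=np.int64)
    seqs[:, 0] = rng.integers(0, 4, size=n)
    for j in range(1, WINDOW_LEN):
        stay = rng.random(n) < 0.4  # mild dinucleotide stickiness
        fresh = rng.integers(0, 4, size=n)
        seqs[:, j] = np.where(stay, seqs[:, j - 1], fresh)
    return seqs


def _region_labels(rng: np.random.Generator, dist: np.ndarray) -> list[str]:
    """One or two region segments per window, categories from ``dist``."""
    cats = rng.choice(5, size=2, p=dist)
    labels = [REGION_CATEGORIES[cats[0]]] * WINDOW_LEN
    if rng.random() < 0.3:
        bp = int(rng.integers(20, 81))
        labels[bp:] = [REGION_CATEGORIES[cats[1]]] * (WINDOW_LEN - bp)
    return labels


def generate_dataset(config: SimConfig):
    """Generate a labelled dataset with its ground-truth record.

    Returns ``(bundles, labels, truth)`` where ``truth`` holds the planted
    PWM, the scoring library, the raw sequences and the per-sample implant
    offset (-1 when no motif was implanted).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    planted = cfg.planted_pwm or make_planted_pwm(seed=cfg.seed)
    w = planted.width
    if w > WINDOW_LEN:
        raise ValueError(f"planted PWM width {w} exceeds window length {WINDOW_LEN}")
    # library used for the motif-score modality; the planted motif is its
    # first entry, mirroring a catalogue that contains the true binder
    lib = make_pwm_library(max(cfg.library_size - 1, 1), width=w,
                           seed=cfg.seed + 1)
    library = PWMLibrary(pwms=[planted] + list(lib.pwms)[: cfg.library_size - 1],
                         background=lib.background)

    n = cfg.n_pos + cfg.n_neg
    labels = np.r_[np.ones(cfg.n_pos, dtype=int), np.zeros(cfg.n_neg, dtype=int)]
    seq_idx = _random_sequences(rng, n, cfg.markov_background)
    offsets = np.full(n, -1, dtype=int)

    # implant a PWM realisation into motif-carrying positives
    for i in range(cfg.n_pos):
        if rng.random() < cfg.motif_strength:
            off = int(rng.integers(0, WINDOW_LEN - w + 1))
            for j in range(w):
                seq_idx[i, off + j] = rng.choice(4, p=planted.probs[:, j])
            offsets[i] = off
    sequences = ["".join(ALPHABET[b] for b in row) for row in seq_idx]

    # structure: loop-probability-like Beta noise, center-shifted in positives
    structure = rng.beta(2.0, 5.0, size=(n, WINDOW_LEN))
    center = slice(WINDOW_FLANK - CENTER_HALF, WINDOW_FLANK + CENTER_HALF)
    structure[: cfg.n_pos, center] += cfg.structure_effect
    structure = np.clip(structure, 0.0, 1.0)

    # co-binding: Bernoulli presence at the class rate, 1+Poisson counts
    rate = np.where(labels == 1, cfg.cobind_rates[0], cfg.cobind_rates[1])
    present = rng.random((n, WINDOW_LEN, cfg.n_experiments)) < rate[:, None, None]
    cobind = present * (1 + rng.poisson(1.0, size=present.shape))

    region = [
        _region_labels(rng, cfg.region_bias["pos" if y == 1 else "neg"])
        for y in labels
    ]

    motif_scores = score_library(sequences, library)
    bundles = [
        FeatureBundle(
            region_type=encode_region_type(region[i]),
            cobinding=encode_cobinding(cobind[i]),
            structure=encode_structure(structure[i]),
            motif_scores=motif_scores[i],
            onehot=one_hot(sequences[i]),
        )
        for i in range(n)
    ]
    truth = {
        "planted_pwm": planted,
        "library": library,
        "sequences": sequences,
        "offsets": offsets,
        "region_labels": region,
        "cobind_counts": cobind,
        "structure_probs": structure,
        "config": cfg,
    }
    return bundles, labels, truth


def write_dataset(truth: dict, labels, outdir: str | Path) -> None:
    """Write a generated dataset in the plain-text layout ``sample_io`` reads.

    FASTA sequences, TSV matrices for structure and (flattened) co-binding
    counts, a TSV of region labels, a labels file, and the scoring library
    in MEME-minimal format.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "sequences.fa", "w") as fh:
        for i, s in enumerate(truth["sequences"]):
            fh.write(f">seq_{i}\n{s}\n")
    np.savetxt(outdir / "labels.tsv", np.asarray(labels, dtype=int), fmt="%d")
    np.savetxt(outdir / "structure.tsv", truth["structure_probs"],
               fmt="%.6f", delimiter="\t")
    cobind = truth["cobind_counts"]
    np.savetxt(outdir / "cobinding.tsv",
               cobind.reshape(cobind.shape[0], -1), fmt="%d", delimiter="\t")
    pd.DataFrame(truth["region_labels"]).to_csv(
        outdir / "region.tsv", sep="\t", header=False, index=False)
    write_meme(list(truth["library"]), outdir / "library.meme",
               background=truth["library"].background)
    np.savetxt(outdir / "offsets.tsv", truth["offsets"], fmt="%d")


def load_dataset(indir: str | Path):
    """Read a :func:`write_dataset` directory back into model inputs.

    Returns ``(inputs, labels, library)`` with ``inputs`` the stacked
    per-modality arrays the network consumes.
    """
    from .pwm import read_meme
    from .sample_io import read_matrix

    indir = Path(indir)
    sequences = []
    name = None
    for line in (indir / "sequences.fa").read_text().splitlines():
        if line.startswith(">"):
            name = line
        elif line:
            sequences.append(line.strip().upper().replace("T", "U"))
    labels = np.loadtxt(indir / "labels.tsv", dtype=int, ndmin=1)
    structure = np.atleast_2d(read_matrix(indir / "structure.tsv").astype(float))
    cobind_flat = np.atleast_2d(read_matrix(indir / "cobinding.tsv"))
    n = len(sequences)
    cobind = cobind_flat.reshape(n, WINDOW_LEN, -1)
    region = pd.read_csv(indir / "region.tsv", sep="\t", header=None).to_numpy(str)
    library = read_meme(indir / "library.meme")
    inputs = {
        "region_type": np.stack([encode_region_type(list(r)) for r in region]),
        "cobinding": np.stack([encode_cobinding(c) for c in cobind]),
        "structure": structure,
        "motif": score_library(sequences, library),
        "sequence": np.stack([one_hot(s) for s in sequences]),
    }
    return inputs, labels, library
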