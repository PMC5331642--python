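"""Encode a 101-nt crosslink window into the five model input modalities.

The five representations, with their fixed dimensionalities:

====================  ==========================================  =========
modality              encoding                                    dimension
====================  ==========================================  =========
region type           one-hot of 5 categories per position        101x5=505
co-binding            count>0 indicator per position/experiment   101x30=3030
structure             per-nucleotide pairing probability          101
motif scores          best log-odds PWM hit per library motif     102
sequence              one-hot over A,C,G,U (N = uniform 0.25)     101x4
====================  ==========================================  =========

Motif scoring is a max-log-odds PWM scan with a small pseudocount against a
uniform background — a deliberate simplification of HMM-based motif-cluster
scoring: the downstream network only needs a monotone per-motif affinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pwm import ALPHABET, PWM, PWMLibrary, read_meme, read_matrix_library  # noqa: F401  (re-exported surface)
from .sample_io import REGION_CATEGORIES, WINDOW_LEN, Window

N_REGION_CATEGORIES = len(REGION_CATEGORIES)  # 5
_REGION_RANK = {c: i for i, c in enumerate(REGION_CATEGORIES)}
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
N_INDEX = 4  # sentinel row index for the ambiguous base

__all__ = [
    "FeatureBundle",
    "PWMLibrary",
    "PWM",
    "encode_region_type",
    "encode_cobinding",
    "encode_structure",
    "encode_motif_scores",
    "score_library",
    "one_hot",
    "encode_window",
    "MODALITIES",
]

MODALITIES = ("region_type", "cobinding", "structure", "motif", "sequence")


@dataclass
class FeatureBundle:
    """The five per-sample modality arrays fed to the network."""

    region_type: np.ndarray  # (505,) binary
    cobinding: np.ndarray    # (101*E,) binary
    structure: np.ndarray    # (101,) real in [0,1]
    motif_scores: np.ndarray  # (P,) real
    onehot: np.ndarray       # (101, 4) rows sum to 1

    def __post_init__(self) -> None:
        self.region_type = np.asarray(self.region_type, dtype=float)
        self.cobinding = np.asarray(self.cobinding, dtype=float)
        self.structure = np.asarray(self.structure, dtype=float)
        self.motif_scores = np.asarray(self.motif_scores, dtype=float)
        self.onehot = np.asarray(self.onehot, dtype=float)
        if self.onehot.shape != (WINDOW_LEN, 4):
            raise ValueError(f"onehot must be {WINDOW_LEN}x4, got {self.onehot.shape}")


def encode_region_type(region_labels) -> np.ndarray:
    """Per-position one-hot of the five transcript region categories.

    Position i with category of rank r sets index ``i*5 + r``; ranks are
    exon=0, intron=1, 5'UTR=2, 3'UTR=3, CDS=4.  Exactly 101 ones.
    """
    labels = list(region_labels)
    if len(labels) != WINDOW_LEN:
        raise ValueError(f"expected {WINDOW_LEN} region labels, got {len(labels)}")
    out = np.zeros(WINDOW_LEN * N_REGION_CATEGORIES)
    for i, lab in enumerate(labels):
        try:
            out[i * N_REGION_CATEGORIES + _REGION_RANK[lab]] = 1.0
        except KeyError:
            raise ValueError(
                f"unknown region category {lab!r} at position {i}; "
                f"expected one of {REGION_CATEGORIES}"
            ) from None
    return out


def encode_cobinding(cobind_counts: np.ndarray) -> np.ndarray:
    """Binarise a 101 x E cDNA-count matrix and flatten position-major.

    Entry (i, e) maps to index ``i*E + e`` and is 1 iff the count is > 0.
    """
    counts = np.asarray(cobind_counts)
    if counts.ndim != 2 or counts.shape[0] != WINDOW_LEN:
        raise ValueError(f"cobind_counts must be {WINDOW_LEN} x E, got {counts.shape}")
    if np.any(counts < 0):
        raise ValueError("cobind_counts must be non-negative")
    return (counts > 0).astype(float).ravel(order="C")


def encode_structure(structure_probs: np.ndarray) -> np.ndarray:
    """Validated pass-through of per-nucleotide structure probabilities."""
    p = np.asarray(structure_probs, dtype=float)
    if p.shape != (WINDOW_LEN,):
        raise ValueError(f"structure_probs must have length {WINDOW_LEN}, got {p.shape}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("structure_probs must lie in [0, 1]")
    return p.copy()


def _seq_to_index(sequence: str) -> np.ndarray:
    """Map A,C,G,U to 0..3 and N to the sentinel 4; reject anything else."""
    idx = np.fromiter((_BASE_INDEX.get(c, N_INDEX) for c in sequence),
                      dtype=np.int64, count=len(sequence))
    bad = set(sequence) - set(ALPHABET) - {"N"}
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return idx


def one_hot(sequence: str) -> np.ndarray:
    """One-hot encode a 101-nt RNA string (columns A, C, G, U; N = 0.25 each)."""
    if len(sequence) != WINDOW_LEN:
        raise ValueError(f"sequence must be {WINDOW_LEN} nt, got {len(sequence)}")
    idx = _seq_to_index(sequence)
    lookup = np.vstack([np.eye(4), np.full((1, 4), 0.25)])
    return lookup[idx]


def score_library(sequences: list[str], library: PWMLibrary,
                  pseudocount: float = 1e-3) -> np.ndarray:
    """Best log2-odds hit of every library motif in every sequence.

    For motif p and sequence s the score is the maximum over offsets o of
    ``sum_j log2(PWM_p[s[o+j], j] / bg[s[o+j]])``; N positions contribute 0
    (the background log-odds of an uninformative base).  Returns an
    ``(n_sequences, n_motifs)`` matrix.
    """
    if len(library) == 0:
        raise ValueError("empty PWM library")
    n = len(sequences)
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("all sequences must have equal length")
    idx = np.stack([_seq_to_index(s) for s in sequences])  # (n, L)
    scores = np.empty((n, len(library)))
    for p, pwm in enumerate(library):
        w = pwm.width
        if w > L:
            raise ValueError(f"PWM {pwm.id!r} width {w} exceeds sequence length {L}")
        lo = pwm.log_odds(library.background, pseudocount=pseudocount)  # (4, w)
        lo = np.vstack([lo, np.zeros((1, w))])  # N row scores 0
        windows = np.lib.stride_tricks.sliding_window_view(idx, w, axis=1)  # (n, L-w+1, w)
        per_pos = lo[windows, np.arange(w)]  # (n, L-w+1, w)
        scores[:, p] = per_pos.sum(axis=2).max(axis=1)
    return scores


def encode_motif_scores(sequence: str, library: PWMLibrary,
                        pseudocount: float = 1e-3) -> np.ndarray:
    """Length-P vector of best log-odds hits for one sequence."""
    return score_library([sequence], library, pseudocount=pseudocount)[0]


def encode_window(window: Window, library: PWMLibrary) -> FeatureBundle:
    """Produce all five modality encodings for one fully-annotated window."""
    return FeatureBundle(
        region_type=encode_region_type(window.region_labels),
        cobinding=encode_cobinding(window.cobind_counts),
        structure=encode_structure(window.structure_probs),
        motif_scores=encode_motif_scores(window.sequence, library),
        onehot=one_hot(window.sequence),
    )
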