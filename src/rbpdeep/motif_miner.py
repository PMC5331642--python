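"""Turn learned convolutional filters into motifs.

Following the DeepBind/Basset recipe: scan every trained filter over the
input sequences, keep all positions whose post-ReLU activation exceeds half
of that filter's maximum activation anywhere in the set, tally the aligned
subsequences into a count matrix, and normalise with a pseudocount into a
PWM.  The resulting motif library can be exported in MEME-minimal format
(e.g. to feed TOMTOM), matched against a known-motif catalogue with the
internal aligner, clustered, and tested for class enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .encoders import _seq_to_index
from .network import MultimodalNet
from .pwm import ALPHABET, PWM, PWMLibrary, pwm_from_counts, read_meme, write_meme  # noqa: F401

__all__ = [
    "PWM",
    "MotifMatch",
    "EnrichmentResult",
    "filter_max_activations",
    "build_pwm",
    "mine_motifs",
    "export_meme",
    "match_pwms",
    "enrichment",
    "cluster_filters",
]

ACTIVATION_FRACTION = 0.5  # keep activations above this fraction of the max

export_meme = write_meme


@dataclass(frozen=True)
class MotifMatch:
    """One query-vs-target motif alignment."""

    query_id: str
    target_id: str
    offset: int
    similarity: float
    p_value: float


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-filter 2x2 activation-by-label association."""

    filter_id: str
    pos_active: int
    pos_total: int
    neg_active: int
    neg_total: int
    p_value: float
    adjusted_p: float


def filter_max_activations(model: MultimodalNet, sequences: list[str],
                           fraction: float = ACTIVATION_FRACTION) -> list[np.ndarray]:
    """High-activation (sequence, offset, activation) triples per filter.

    For each filter, returns an array of rows ``(seq_index, offset,
    activation)`` covering every position whose post-ReLU activation
    exceeds ``fraction`` x the filter's maximum over all sequences.  A
    filter that never activates (max <= 0) yields an empty table.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    from .encoders import one_hot

    acts = model.conv_activations(np.stack([one_hot(s) for s in sequences]))
    # acts: (n, L, F)
    tables: list[np.ndarray] = []
    for f in range(acts.shape[2]):
        a = acts[:, :, f]
        peak = a.max()
        if peak <= 0:
            tables.append(np.empty((0, 3)))
            continue
        si, oi = np.nonzero(a > fraction * peak)
        tables.append(np.column_stack([si, oi, a[si, oi]]))
    return tables


def build_pwm(activation_table: np.ndarray, sequences: list[str],
              filter_length: int, pseudocount: float = 1.0,
              id: str = "") -> PWM:
    """Tally the selected subsequences into a pseudocount-normalised PWM.

    An empty table gives a degenerate uniform PWM with ``n_sites=0``.
    Ambiguous N positions are skipped in the tally.
    """
    counts = np.zeros((4, filter_length))
    n_sites = 0
    for row in np.atleast_2d(np.asarray(activation_table, dtype=float)):
        if row.size == 0:
            continue
        si, off = int(row[0]), int(row[1])
        sub = sequences[si][off:off + filter_length]
        if len(sub) < filter_length:
            raise ValueError(
                f"offset {off} leaves no room for a length-{filter_length} "
                f"subsequence in sequence {si}"
            )
        idx = _seq_to_index(sub)
        for j, b in enumerate(idx):
            if b < 4:
                counts[b, j] += 1
        n_sites += 1
    return pwm_from_counts(counts, pseudocount=pseudocount, n_sites=n_sites, id=id)


def mine_motifs(model: MultimodalNet, sequences: list[str],
                labels=None, positives_only: bool = True,
                pseudocount: float = 1.0) -> list[PWM]:
    """Filter -> PWM conversion for every filter of the trained model.

    By default only positive-class sequences contribute subsequences (the
    binding class is where motifs live); pass ``positives_only=False`` or
    no labels to use all sequences.
    """
    if positives_only and labels is not None:
        labels = np.asarray(labels)
        keep = [s for s, y in zip(sequences, labels) if y == 1]
        sequences = keep if keep else list(sequences)
    tables = filter_max_activations(model, sequences)
    w = model.config.filter_length
    return [
        build_pwm(tab, sequences, w, pseudocount=pseudocount, id=f"filter_{f}")
        for f, tab in enumerate(tables)
    ]


def _column_similarity(q: np.ndarray, t: np.ndarray) -> float:
    """Mean per-column Pearson correlation of two aligned 4 x k blocks.

    Zero-variance columns (no preference at all) contribute 0.
    """
    qc = q - q.mean(axis=0)
    tc = t - t.mean(axis=0)
    qn = np.linalg.norm(qc, axis=0)
    tn = np.linalg.norm(tc, axis=0)
    ok = (qn > 1e-12) & (tn > 1e-12)
    r = np.zeros(q.shape[1])
    r[ok] = (qc[:, ok] * tc[:, ok]).sum(axis=0) / (qn[ok] * tn[ok])
    return float(r.mean())


def _best_alignment(q: np.ndarray, t: np.ndarray, min_overlap: int = 4):
    """Best (similarity, offset) over all overlaps of >= min_overlap columns.

    Offset is the position of the query's first column relative to the
    target's first column (negative = query starts before the target).
    """
    wq, wt = q.shape[1], t.shape[1]
    best, best_off = -np.inf, 0
    for off in range(-(wq - min_overlap), wt - min_overlap + 1):
        lo_q, lo_t = max(0, -off), max(0, off)
        k = min(wq - lo_q, wt - lo_t)
        if k < min_overlap:
            continue
        sim = _column_similarity(q[:, lo_q:lo_q + k], t[:, lo_t:lo_t + k])
        if sim > best:
            best, best_off = sim, off
    return best, best_off


def match_pwms(query: PWM, library: PWMLibrary, min_overlap: int = 4,
               n_permutations: int = 1000, seed: int = 0) -> list[MotifMatch]:
    """Align a query PWM against every library motif.

    Similarity is the mean per-column Pearson correlation over the best
    overlap (>= ``min_overlap`` columns).  The p-value is empirical: the
    fraction of column-shuffled library motifs (plus one) whose best
    alignment scores at least as well, over ``n_permutations`` seeded
    shuffles.  Matches are returned sorted best-first.
    """
    if len(library) == 0:
        raise ValueError("empty motif library")
    rng = np.random.default_rng(seed)
    all_cols = np.concatenate([p.probs for p in library], axis=1)
    n_cols = all_cols.shape[1]

    matches = []
    for target in library:
        sim, off = _best_alignment(query.probs, target.probs, min_overlap)
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            cols = rng.integers(0, n_cols, size=target.width)
            null[i], _ = _best_alignment(query.probs, all_cols[:, cols], min_overlap)
        p = (1.0 + np.count_nonzero(null >= sim)) / (1.0 + n_permutations)
        matches.append(MotifMatch(query_id=query.id, target_id=target.id,
                                  offset=off, similarity=sim, p_value=p))
    return sorted(matches, key=lambda m: (-m.similarity, m.target_id))


def enrichment(activation_tables: list[np.ndarray], labels) -> list[EnrichmentResult]:
    """Two-sided Fisher exact test of per-filter activation vs class label.

    A sequence counts as "active" for a filter if it has at least one
    above-threshold offset in that filter's activation table.  P-values are
    Benjamini-Hochberg adjusted across filters.
    """
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    raw = []
    counts = []
    for tab in activation_tables:
        tab = np.atleast_2d(np.asarray(tab, dtype=float))
        active = set() if tab.size == 0 else set(tab[:, 0].astype(int))
        pa = sum(1 for i in active if y[i] == 1)
        na = len(active) - pa
        table = [[pa, n_pos - pa], [na, n_neg - na]]
        if min(n_pos, n_neg) == 0 or len(active) in (0, len(y)):
            p = 1.0
        else:
            _, p = fisher_exact(table, alternative="two-sided")
        raw.append(p)
        counts.append((pa, na))
    adj = multipletests(raw, method="fdr_bh")[1] if raw else []
    return [
        EnrichmentResult(filter_id=f"filter_{f}", pos_active=pa, pos_total=n_pos,
                         neg_active=na, neg_total=n_neg, p_value=p,
                         adjusted_p=max(q, p))
        for f, ((pa, na), p, q) in enumerate(zip(counts, raw, adj))
    ]


def cluster_filters(pwms: list[PWM], method: str = "average"):
    """Average-linkage hierarchical clustering of equal-width PWMs on
    cosine distance of the flattened probability matrices.

    Returns the scipy linkage matrix (deterministic for a fixed input
    order).
    """
    if len(pwms) < 2:
        raise ValueError("need at least 2 PWMs to cluster")
    widths = {p.width for p in pwms}
    if len(widths) != 1:
        raise ValueError(f"all PWMs must share one width, got {sorted(widths)}")
    flat = np.stack([p.probs.ravel() for p in pwms])
    return linkage(pdist(flat, metric="cosine"), method=method)
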