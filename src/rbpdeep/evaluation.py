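"""ROC/AUC and the evaluation protocol (fixed split, 5-fold CV).

AUC is computed as the midrank Mann-Whitney statistic: the probability
that a random positive outscores a random negative, with ties counted
half.  The protocol mirrors the benchmark design: a fixed
4000/1000/1000 train/validation/test split when the dataset is large
enough, stratified k-fold cross-validation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "RocResult",
    "roc_auc",
    "kfold_split",
    "fixed_split",
    "run_protocol",
    "FIXED_SPLIT_SIZES",
]

FIXED_SPLIT_SIZES = (4000, 1000, 1000)  # train / validation / test


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and rank-based AUC.

    AUC equals the normalised Mann-Whitney U with midrank tie handling;
    the curve is the cumulative true/false-positive sweep over score
    thresholds (ties grouped).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC")

    ranks = rankdata(s)  # midranks
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, y.size - 1]
    tp = np.cumsum(y_sorted == 1)[idx]
    fp = np.cumsum(y_sorted == 0)[idx]
    return RocResult(
        thresholds=np.r_[np.inf, s_sorted[idx]],
        fpr=np.r_[0.0, fp / n_neg],
        tpr=np.r_[0.0, tp / n_pos],
        auc=float(auc),
    )


def kfold_split(n: int, k: int, seed: int = 0, labels=None) -> list[np.ndarray]:
    """Seeded k disjoint folds of 0..n-1 with sizes differing by at most 1.

    With ``labels`` the folds are stratified: each class is shuffled and
    dealt round-robin, starting each class at the currently smallest fold
    so total sizes stay balanced.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k cannot exceed n")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if labels is None:
        groups = [np.arange(n)]
    else:
        y = np.asarray(labels)
        if y.shape != (n,):
            raise ValueError("labels length must equal n")
        groups = [np.nonzero(y == c)[0] for c in np.unique(y)]
    for idx in groups:
        idx = rng.permutation(idx)
        sizes = np.array([len(f) for f in folds])
        start = int(np.argmin(sizes))
        for j, i in enumerate(idx):
            folds[(start + j) % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def fixed_split(n: int, seed: int = 0,
                sizes: tuple[int, int, int] = FIXED_SPLIT_SIZES):
    """Shuffled (train, validation, test) index arrays of the fixed sizes."""
    need = sum(sizes)
    if n < need:
        raise ValueError(
            f"fixed split needs >= {need} samples, got {n}; use CV mode instead"
        )
    perm = np.random.default_rng(seed).permutation(n)
    a, b, c = sizes
    return perm[:a], perm[a:a + b], perm[a + b:a + b + c]


def run_protocol(inputs: dict[str, np.ndarray], labels, config=None,
                 mode: str = "cv", k: int = 5, seed: int = 0,
                 train_fn=None) -> dict:
    """Run the evaluation protocol and report AUCs.

    ``mode="fixed"`` uses the 4000/1000/1000 train/validation/test split;
    ``mode="cv"`` runs stratified k-fold cross-validation (each fold's
    training part donates a small validation subset for early stopping).
    ``train_fn(train_inputs, train_labels, val_inputs, val_labels) ->
    score_fn`` may replace the default network trainer (used for
    ablations and dry runs); ``score_fn(inputs) -> scores``.

    Returns a dict with per-run AUCs, their mean and sd, and the split
    sizes actually used.
    """
    from .network import NetConfig, build_model, predict, train

    y = np.asarray(labels, dtype=int)
    n = y.size
    cfg = config or NetConfig(seed=seed)

    if train_fn is None:
        def train_fn(Xtr, ytr, Xva, yva):  # noqa: ANN001
            dims = {m: Xtr[m].shape[1] for m in Xtr if m != "sequence"}
            model = build_model(cfg, dims)
            train(model, Xtr, ytr, Xva, yva, cfg)
            return lambda X: predict(model, X)

    def take(sel):
        return {m: v[sel] for m, v in inputs.items()}

    aucs: list[float] = []
    sizes: list[tuple] = []
    if mode == "fixed":
        tr, va, te = fixed_split(n, seed=seed)
        score = train_fn(take(tr), y[tr], take(va), y[va])
        aucs.append(roc_auc(score(take(te)), y[te]).auc)
        sizes.append((len(tr), len(va), len(te)))
    elif mode == "cv":
        folds = kfold_split(n, k, seed=seed, labels=y)
        for i, test_idx in enumerate(folds):
            train_idx = np.sort(np.concatenate([f for j, f in enumerate(folds) if j != i]))
            inner = kfold_split(len(train_idx), max(k, 5),
                                seed=seed + 1000 + i, labels=y[train_idx])[0]
            val_idx = train_idx[inner]
            tr_idx = np.setdiff1d(train_idx, val_idx)
            score = train_fn(take(tr_idx), y[tr_idx], take(val_idx), y[val_idx])
            aucs.append(roc_auc(score(take(test_idx)), y[test_idx]).auc)
            sizes.append((len(tr_idx), len(val_idx), len(test_idx)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    aucs_arr = np.asarray(aucs)
    return {
        "mode": mode,
        "aucs": aucs,
        "mean_auc": float(aucs_arr.mean()),
        "sd_auc": float(aucs_arr.std(ddof=1)) if len(aucs) > 1 else 0.0,
        "split_sizes": sizes,
    }
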