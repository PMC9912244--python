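"""Cross-validation protocols and screen-prediction metrics.

Predicted deep scores are compared with measured log2 fold changes on
four axes: R² (against the sigmoid-normalized target), Pearson
correlation with the raw LFC (expected negative — high score means
depletion), and AUC/AUPR for classifying effective guides
(LFC ≤ −0.5 by default).

Beyond plain k-fold CV the module implements the two screen-specific
protocols: restricting AUPR to guides of the top-fraction negatively
selected genes (the circRNA protocol, where most genes are inert and
global AUPR is washed out by guides whose perfect prediction can never
be observed), and dataset-transfer evaluation (pooled CV or
leave-one-dataset-out, optionally keeping only each gene's top/bottom
ranked guides).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import clone
from sklearn.metrics import average_precision_score, r2_score, roc_auc_score

from .encoding import DEFAULT_LFC_THRESHOLD, lfc_to_target


@dataclass
class EvalReport:
    """Metrics for one prediction set (NaN = undefined, never 0)."""

    r2: float
    pcc: float
    auc: float
    aupr: float
    n: int
    positives: int

    def to_dict(self) -> dict:
        return {"r2": self.r2, "pcc": self.pcc, "auc": self.auc,
                "aupr": self.aupr, "n": self.n, "positives": self.positives}


def _subset(X, idx: np.ndarray):
    if isinstance(X, (list, tuple)):
        return [X[i] for i in idx]
    return X[idx]


def assign_folds(n: int, k: int = 5, genes=None, grouping: str = "guide",
                 seed: int = 0) -> np.ndarray:
    """Fold label in [0, k) per sample.

    ``grouping="guide"``: seeded shuffle, fold sizes differ by at most 1.
    ``grouping="gene"``: all guides of a gene share a fold (greedy
    balancing over shuffled genes), so sequence context never leaks
    across the train/test boundary.
    """
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if grouping == "guide":
        order = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(order, k)):
            folds[chunk] = f
    elif grouping == "gene":
        if genes is None:
            raise ValueError("gene grouping requires per-guide gene labels")
        genes = np.asarray(genes)
        uniq = rng.permutation(np.unique(genes))
        sizes = np.zeros(k, dtype=int)
        for g in uniq:
            members = np.flatnonzero(genes == g)
            f = int(sizes.argmin())
            folds[members] = f
            sizes[f] += len(members)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return folds


def kfold_predictions(estimator, X, y, k: int = 5, grouping: str = "guide",
                      genes=None, seed: int = 0) -> np.ndarray:
    """Out-of-fold predictions: each guide predicted exactly once by a
    model that never saw it in training."""
    y = np.asarray(y, dtype=float)
    folds = assign_folds(len(y), k=k, genes=genes, grouping=grouping, seed=seed)
    out = np.full(len(y), np.nan)
    for f in range(k):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        est = clone(estimator)
        est.fit(_subset(X, train), y[train])
        out[test] = est.predict(_subset(X, test))
    return out


def compute_metrics(predictions, lfcs,
                    threshold: float = DEFAULT_LFC_THRESHOLD) -> EvalReport:
    """Score predictions against measured LFCs.

    R² is computed against the sigmoid-normalized target; PCC against
    the raw LFC (a good model is anti-correlated); AUC/AUPR use the
    score to rank positives (LFC ≤ threshold).  With a single class or
    constant predictions the undefined metrics are reported as NaN.
    """
    pred = np.asarray(predictions, dtype=float)
    lfc = np.asarray(lfcs, dtype=float)
    if pred.shape != lfc.shape:
        raise ValueError("predictions and lfcs differ in length")
    labels = (lfc <= threshold).astype(int)
    n, pos = len(lfc), int(labels.sum())
    r2 = float(r2_score(lfc_to_target(lfc), pred))
    pcc = float(pearsonr(pred, lfc)[0]) if np.ptp(pred) > 0 and np.ptp(lfc) > 0 else float("nan")
    if 0 < pos < n:
        auc = float(roc_auc_score(labels, pred))
        aupr = float(average_precision_score(labels, pred))
    else:
        auc = aupr = float("nan")
    return EvalReport(r2=r2, pcc=pcc, auc=auc, aupr=aupr, n=n, positives=pos)


def topfrac_gene_eval(predictions, lfcs, genes, gene_rank: pd.Series,
                      fraction: float | None = None, top_n: int | None = None,
                      threshold: float = DEFAULT_LFC_THRESHOLD) -> float:
    """AUPR restricted to guides of top negatively selected genes.

    ``gene_rank`` maps gene → negative-selection rank (1 = most strongly
    negatively selected, as in a gene summary table).  Either
    ``fraction`` of genes or an absolute ``top_n`` is kept.
    """
    if (fraction is None) == (top_n is None):
        raise ValueError("give exactly one of fraction or top_n")
    ranked = gene_rank.sort_values()
    n_keep = top_n if top_n is not None else int(round(fraction * len(ranked)))
    if n_keep < 1:
        raise ValueError("selection yields zero genes")
    keep_genes = set(ranked.index[:n_keep])
    genes = np.asarray(genes)
    sel = np.array([g in keep_genes for g in genes])
    if not sel.any():
        raise ValueError("no guides map to the selected genes")
    return compute_metrics(np.asarray(predictions)[sel], np.asarray(lfcs)[sel],
                           threshold=threshold).aupr


def top_bottom_filter(lfcs, genes, k: int = 4) -> np.ndarray:
    """Indices of each gene's k most and k least depleted guides.

    "Top" = most negative LFC.  For genes with ≤ 2k guides the two sets
    overlap and are deduplicated, so every guide is kept at most once.
    """
    lfc = np.asarray(lfcs, dtype=float)
    genes = np.asarray(genes)
    keep: list[int] = []
    for g in np.unique(genes):
        members = np.flatnonzero(genes == g)
        order = members[np.argsort(lfc[members], kind="stable")]
        chosen = list(order[:k]) + [i for i in order[-k:] if i not in order[:k]]
        keep.extend(dict.fromkeys(chosen))
    return np.array(sorted(keep), dtype=int)


def dataset_transfer(estimator, datasets: dict, test_source: str,
                     mode: str = "mixed_cv", top_bottom: int | None = None,
                     k: int = 5, seed: int = 0,
                     threshold: float = DEFAULT_LFC_THRESHOLD) -> EvalReport:
    """Cross-dataset evaluation.

    ``datasets`` maps source tag → (X, lfcs, genes).  ``mixed_cv`` pools
    every source, runs k-fold CV, then evaluates only the test source's
    out-of-fold predictions.  ``leave_one_dataset_out`` trains on all
    other sources and predicts the held-out one.  ``top_bottom`` keeps
    only each gene's top/bottom ranked guides (by LFC) before scoring.
    """
    if test_source not in datasets:
        raise ValueError(f"unknown test source {test_source!r}")
    if mode == "leave_one_dataset_out" and len(datasets) < 2:
        raise ValueError("leave_one_dataset_out needs at least two datasets")

    X_test, lfc_test, genes_test = datasets[test_source]
    lfc_test = np.asarray(lfc_test, dtype=float)

    if mode == "mixed_cv":
        X_all: list = []
        lfc_all: list[float] = []
        tags: list[str] = []
        for tag, (X, lfc, _genes) in datasets.items():
            X_all.extend(X)
            lfc_all.extend(np.asarray(lfc, dtype=float))
            tags.extend([tag] * len(lfc))
        pred_all = kfold_predictions(estimator, X_all, np.array(lfc_all), k=k, seed=seed)
        sel = np.array([t == test_source for t in tags])
        pred, lfc_eval = pred_all[sel], np.array(lfc_all)[sel]
    elif mode == "leave_one_dataset_out":
        X_tr: list = []
        lfc_tr: list[float] = []
        for tag, (X, lfc, _genes) in datasets.items():
            if tag == test_source:
                continue
            X_tr.extend(X)
            lfc_tr.extend(np.asarray(lfc, dtype=float))
        est = clone(estimator)
        est.fit(X_tr, np.array(lfc_tr))
        pred, lfc_eval = est.predict(X_test), lfc_test
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if top_bottom is not None:
        idx = top_bottom_filter(lfc_eval, genes_test, k=top_bottom)
        pred, lfc_eval = pred[idx], lfc_eval[idx]
    return compute_metrics(pred, lfc_eval, threshold=threshold)
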