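"""Evaluation utilities: PCA variance proportions, naive-Bayes CV AUC, ROC AUC."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

from hdcn._log import derive_seed, get_logger
from hdcn.containers import MIXED, ExpressionMatrix

log = get_logger("hdcn.evaluation")


def pca_explained_variance(
    matrix: ExpressionMatrix, feature_gene_list: list[str], k: int = 3
) -> np.ndarray:
    """Proportions of variance explained by the first k principal components.

    Samples are projected on the principal components of the gene-subset
    matrix after log2(x+1) transform and centering; proportion_i is
    eigenvalue_i over the sum of all eigenvalues.
    """
    if len(matrix.sample_ids) < 2:
        raise ValueError("PCA needs at least 2 samples")
    missing = [g for g in feature_gene_list if g not in set(matrix.gene_ids)]
    if missing:
        raise ValueError(f"features absent from matrix: {missing[:5]}")
    X = np.log2(
        matrix.values.loc[feature_gene_list].to_numpy(dtype=float).T + 1.0
    )
    rank = min(X.shape[0] - 1, X.shape[1])
    if k > rank:
        log.warning("k=%d exceeds rank %d; truncating", k, rank)
        k = rank
    pca = PCA(n_components=rank)
    pca.fit(X)
    return pca.explained_variance_ratio_[:k]


def roc_auc(scores, binary_labels) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 * P(tie), via the rank-sum identity."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binary_labels)
    pos = labels == np.max(labels)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def nb_cv_auc(
    matrix: ExpressionMatrix,
    feature_gene_list: list[str],
    labels=None,
    n_folds: int = 10,
    n_repeats: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Repeated stratified-CV Gaussian naive Bayes AUC on log2(x+1) features.

    Per repeat, out-of-fold class scores are pooled into one AUC; the mean
    and sd over repeats are returned. ``labels`` defaults to the matrix
    group labels (mixed = positive class).
    """
    X = np.log2(
        matrix.values.loc[feature_gene_list].to_numpy(dtype=float).T + 1.0
    )
    if labels is None:
        y = np.array([1 if matrix.groups[s] == MIXED else 0 for s in matrix.sample_ids])
    else:
        y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain exactly 2 classes")
    aucs = np.empty(n_repeats)
    for rep in range(n_repeats):
        rep_seed = derive_seed(seed, "nb_cv", rep)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
        scores = np.empty(len(y))
        for train, test in skf.split(X, y):
            clf = GaussianNB(var_smoothing=1e-9)
            clf.fit(X[train], y[train])
            scores[test] = clf.predict_proba(X[test])[:, list(clf.classes_).index(1)]
        aucs[rep] = roc_auc(scores, y)
    return float(aucs.mean()), float(aucs.std(ddof=0))


__all__ = ["pca_explained_variance", "nb_cv_auc", "roc_auc"]
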