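"""Protein subcellular localization prediction from co-expression evidence.

A protein's evidence vector over the 10 compartments sums, for each
compartment, the MIC between the protein and its annotated interaction
partners in that compartment (L1-normalized). A multi-class maximum-margin
classifier (SVM with calibrated probabilities) trained on reference-condition
features of annotated proteins turns evidence into per-condition probability
vectors; proteins whose maximal probability shift between conditions exceeds
a permutation-null quantile are called localization changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from hdcn._log import derive_seed, get_logger
from hdcn.containers import COMPARTMENTS, ExpressionMatrix, LocalizationAnnotation
from hdcn.mic import mic

log = get_logger("hdcn.localization")

THRESHOLD_QUANTILE = 0.95
MIN_TRAINING_PER_COMPARTMENT = 5


@dataclass
class LocalizationProfile:
    probs_mixed: pd.DataFrame  # protein x compartment
    probs_reference: pd.DataFrame
    change_score: pd.Series  # max_l |P_mixed - P_reference|
    top_mixed: pd.Series
    top_reference: pd.Series
    excluded: list[str] = field(default_factory=list)


def edge_mics(
    values: pd.DataFrame, edges, alpha_exponent: float = 0.6
) -> dict[tuple[str, str], float]:
    """MIC per (sorted) edge over the samples (columns) of ``values``."""
    out: dict[tuple[str, str], float] = {}
    present = set(values.index)
    for a, b in edges:
        key = (a, b) if a <= b else (b, a)
        if key in out:
            continue
        if a not in present or b not in present:
            continue
        out[key] = mic(
            values.loc[a].to_numpy(),
            values.loc[b].to_numpy(),
            alpha_exponent=alpha_exponent,
        )
    return out


def build_features(
    protein: str,
    network: nx.Graph,
    annotations: LocalizationAnnotation,
    mic_values: dict[tuple[str, str], float],
) -> np.ndarray:
    """Partner-weighted compartment evidence for one protein.

    feature[l] = sum of MIC(protein, q) over annotated partners q in
    compartment l, L1-normalized. A protein with no annotated partners
    yields an all-zero vector (flagged by the caller).
    """
    if protein not in network:
        raise ValueError(f"protein {protein!r} not in network")
    comp_index = {c: i for i, c in enumerate(annotations.compartments)}
    feat = np.zeros(len(annotations.compartments))
    for q in network.neighbors(protein):
        if q not in annotations:
            continue
        key = (protein, q) if protein <= q else (q, protein)
        weight = mic_values.get(key, 0.0)
        feat[comp_index[annotations[q]]] += weight
    total = feat.sum()
    return feat / total if total > 0 else feat


def feature_matrix(
    proteins,
    network: nx.Graph,
    annotations: LocalizationAnnotation,
    mic_values: dict[tuple[str, str], float],
) -> pd.DataFrame:
    rows = [build_features(p, network, annotations, mic_values) for p in proteins]
    return pd.DataFrame(rows, index=list(proteins), columns=annotations.compartments)


def features_from_expression(
    matrix: ExpressionMatrix,
    network: nx.Graph,
    annotations: LocalizationAnnotation,
    proteins=None,
) -> pd.DataFrame:
    """Convenience: MIC weights from one condition's expression, then features."""
    if proteins is None:
        proteins = [p for p in network if p in set(matrix.gene_ids)]
    needed = [
        (p, q)
        for p in proteins
        for q in network.neighbors(p)
        if q in annotations
    ]
    mics = edge_mics(matrix.values, needed)
    return feature_matrix(proteins, network, annotations, mics)


def train_localization_classifier(
    features: pd.DataFrame,
    annotations: LocalizationAnnotation,
    seed: int = 0,
) -> tuple[CalibratedClassifierCV, float]:
    """Train the multi-class margin classifier on annotated proteins.

    Compartments with fewer than 5 annotated training proteins are dropped
    with a warning. Returns the fitted classifier (with calibrated
    per-class probabilities) and its 5-fold cross-validated accuracy.
    """
    annotated = [p for p in features.index if p in annotations]
    labels = pd.Series({p: annotations[p] for p in annotated})
    counts = labels.value_counts()
    small = counts[counts < MIN_TRAINING_PER_COMPARTMENT]
    if not small.empty:
        log.warning(
            "dropping compartments with < %d training proteins: %s",
            MIN_TRAINING_PER_COMPARTMENT,
            list(small.index),
        )
        labels = labels[~labels.isin(small.index)]
    if labels.nunique() < 2:
        raise ValueError("need at least 2 trainable compartments")
    X = features.loc[labels.index].to_numpy()
    y = labels.to_numpy()
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    accuracy = float(np.mean(cross_val_score(SVC(kernel="rbf", C=10.0), X, y, cv=cv)))
    n_cal = min(5, int(labels.value_counts().min()))
    clf = CalibratedClassifierCV(
        SVC(kernel="rbf", C=10.0),
        method="sigmoid",
        cv=StratifiedKFold(n_splits=n_cal, shuffle=True, random_state=seed),
        ensemble=False,
    )
    clf.fit(X, y)
    return clf, accuracy


def _predict_probs(
    classifier, features: pd.DataFrame, compartments
) -> pd.DataFrame:
    probs = classifier.predict_proba(features.to_numpy())
    full = pd.DataFrame(0.0, index=features.index, columns=list(compartments))
    for j, cls in enumerate(classifier.classes_):
        full[cls] = probs[:, j]
    return full


def predict_profiles(
    classifier,
    features_mixed: pd.DataFrame,
    features_reference: pd.DataFrame,
    compartments=COMPARTMENTS,
) -> LocalizationProfile:
    """Per-condition probability vectors and the per-protein change score.

    Proteins with an all-zero feature vector in either condition are
    excluded (no evidence to score) and listed in the profile.
    """
    shared = [p for p in features_mixed.index if p in set(features_reference.index)]
    fm = features_mixed.loc[shared]
    fr = features_reference.loc[shared]
    zero = (fm.sum(axis=1) == 0) | (fr.sum(axis=1) == 0)
    excluded = list(fm.index[zero])
    if excluded:
        log.info("excluding %d protein(s) with zero feature vectors", len(excluded))
    fm, fr = fm[~zero], fr[~zero]
    pm = _predict_probs(classifier, fm, compartments)
    pr = _predict_probs(classifier, fr, compartments)
    change = (pm - pr).abs().max(axis=1)
    return LocalizationProfile(
        probs_mixed=pm,
        probs_reference=pr,
        change_score=change.rename("change_score"),
        top_mixed=pm.idxmax(axis=1).rename("top_mixed"),
        top_reference=pr.idxmax(axis=1).rename("top_reference"),
        excluded=excluded,
    )


def detect_changes(
    profile: LocalizationProfile,
    classifier,
    network: nx.Graph,
    annotations: LocalizationAnnotation,
    matrix_mixed: ExpressionMatrix,
    matrix_reference: ExpressionMatrix,
    threshold_quantile: float = THRESHOLD_QUANTILE,
    n_null: int = 100,
    n_null_proteins: int = 12,
    seed: int = 0,
) -> tuple[set[str], float, np.ndarray]:
    """Changed-protein set via a condition-label permutation null.

    The null distribution of change scores is built by pooling the two
    conditions' samples, permuting them into pseudo-conditions of the
    original sizes, and recomputing features and profiles for a random
    subsample of proteins, ``n_null`` times. A protein is changed iff its
    change score exceeds the ``threshold_quantile`` quantile of the null.

    Returns (changed set, threshold, null scores).
    """
    if n_null < 20:
        raise ValueError("n_null < 20 gives an unstable null quantile")
    rng = np.random.default_rng(derive_seed(seed, "localization_null"))
    scored = list(profile.change_score.index)
    pool = pd.concat(
        [matrix_mixed.values[matrix_mixed.sample_ids],
         matrix_reference.values[matrix_reference.sample_ids]],
        axis=1,
    )
    n_mix = len(matrix_mixed.sample_ids)
    n_all = pool.shape[1]
    subset = list(
        rng.choice(scored, size=min(n_null_proteins, len(scored)), replace=False)
    )
    needed = [
        (p, q) for p in subset for q in network.neighbors(p) if q in annotations
    ]
    null_scores = []
    for _ in range(n_null):
        perm = rng.permutation(n_all)
        pseudo_a = pool.iloc[:, perm[:n_mix]]
        pseudo_b = pool.iloc[:, perm[n_mix:]]
        feats_a = feature_matrix(
            subset, network, annotations, edge_mics(pseudo_a, needed)
        )
        feats_b = feature_matrix(
            subset, network, annotations, edge_mics(pseudo_b, needed)
        )
        null_profile = predict_profiles(
            classifier, feats_a, feats_b, annotations.compartments
        )
        null_scores.extend(null_profile.change_score.tolist())
    null_scores = np.asarray(null_scores)
    # quantile 1.0 is a degenerate bound: nothing can exceed it
    threshold = (
        float("inf")
        if threshold_quantile >= 1.0
        else float(np.quantile(null_scores, threshold_quantile))
    )
    changed = {p for p, s in profile.change_score.items() if s > threshold}
    return changed, threshold, null_scores


def summarize_compartment_changes(
    changed: set[str], profile: LocalizationProfile
) -> pd.DataFrame:
    """Per-compartment counts over the changed set.

    A change is attributed to every compartment that is the top compartment
    in either condition for that protein; percent = 100 * count / total
    changed, one decimal. An empty changed set gives an empty summary.
    """
    total = len(changed)
    counts: dict[str, int] = {}
    for p in changed:
        comps = {profile.top_mixed[p], profile.top_reference[p]}
        for c in comps:
            counts[c] = counts.get(c, 0) + 1
    rows = [
        {
            "compartment": c,
            "count": n,
            "percent": round(100.0 * n / total, 1),
        }
        for c, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["compartment", "count", "percent"])


__all__ = [
    "LocalizationProfile",
    "edge_mics",
    "build_features",
    "feature_matrix",
    "features_from_expression",
    "train_localization_classifier",
    "predict_profiles",
    "detect_changes",
    "summarize_compartment_changes",
    "THRESHOLD_QUANTILE",
]
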