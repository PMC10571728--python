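"""Disease classifier: kNN imputation, stratified 70/30 split, 5-fold
cross-validated random forest, holdout ROC/AUC and 0-100 feature relevance.

Two imputation orders are exposed: ``mode="safe"`` (default) computes the
imputation reference on the training split only, so no holdout statistic
leaks into fitting; ``mode="impute_first"`` imputes the full matrix
before splitting, reproducing the published workflow's order of operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split


@dataclass
class ClassifierConfig:
    positive_class: str = "MM"
    train_fraction: float = 0.7
    n_folds: int = 5
    n_trees: int = 500
    max_features_grid: Sequence = ("sqrt", 0.2, 0.5)
    knn_k: int = 10
    max_missing_fraction: float = 0.5
    threshold: float = 0.5
    mode: str = "safe"            # "safe" | "impute_first"
    seed: int = 0


def knn_impute(
    matrix: pd.DataFrame,
    k: int = 10,
    max_missing_fraction: float = 0.5,
    reference: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Fill missing values with the k-nearest-peptides average.

    For a missing (sample, peptide) cell, distances between the target
    peptide and every other peptide are Euclidean over their shared
    observed samples (scaled to a per-sample mean so unequal overlap is
    comparable), computed on the *reference* rows (defaults to the matrix
    itself; pass the training rows for leakage-safe use).  The cell is
    filled with the average of the sample's own values for the k nearest
    peptides that are observed in that sample.  Peptides missing in more
    than ``max_missing_fraction`` of reference rows, or cells with no
    usable neighbour, fall back to the peptide's reference mean.
    """
    if k >= matrix.shape[1]:
        raise ValueError(f"k={k} must be < number of peptides ({matrix.shape[1]})")
    ref = matrix if reference is None else reference
    ref_arr = ref.to_numpy(dtype=float)
    arr = matrix.to_numpy(dtype=float).copy()
    n_pep = arr.shape[1]

    col_means = np.nanmean(ref_arr, axis=0)
    # Columns entirely missing in the reference: fall back to overall mean.
    col_means = np.where(np.isfinite(col_means), col_means,
                         np.nanmean(ref_arr))
    missing_frac = np.isnan(ref_arr).mean(axis=0)

    obs = np.isfinite(ref_arr)
    filled0 = np.where(obs, ref_arr, 0.0)

    # Pairwise peptide distances over shared observed reference samples:
    # mean squared difference where both observed.
    shared = obs.T.astype(float) @ obs.astype(float)            # (P, P)
    sq = (filled0 ** 2).T @ obs.astype(float)                    # sum_i x_ij^2 over shared
    cross = filled0.T @ filled0
    with np.errstate(invalid="ignore", divide="ignore"):
        msd = (sq + sq.T - 2.0 * cross) / shared
    np.fill_diagonal(msd, np.inf)
    msd[shared == 0] = np.inf

    out = arr.copy()
    miss_rows, miss_cols = np.nonzero(np.isnan(arr))
    for i, j in zip(miss_rows, miss_cols):
        if missing_frac[j] > max_missing_fraction:
            out[i, j] = col_means[j]
            continue
        order = np.argsort(msd[j])
        neighbours: List[float] = []
        for cand in order:
            if len(neighbours) == k:
                break
            if not np.isfinite(msd[j, cand]):
                break
            val = arr[i, cand]
            if np.isfinite(val):
                neighbours.append(val)
        out[i, j] = float(np.mean(neighbours)) if neighbours else col_means[j]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def split_cohort(
    labels: pd.Series,
    fraction: float = 0.7,
    seed: int = 0,
) -> Tuple[List[str], List[str]]:
    """Stratified split of sample ids into (train, test)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("train fraction must be in (0, 1)")
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need two classes to split")
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 members for stratification")
    train, test = train_test_split(
        labels.index.to_numpy(), train_size=fraction,
        stratify=labels.to_numpy(), random_state=seed, shuffle=True)
    return list(train), list(test)


def relevance_scores(model: RandomForestClassifier,
                     feature_names: Sequence[str]) -> pd.Series:
    """Mean-impurity-decrease importances rescaled to max = 100."""
    imp = np.asarray(model.feature_importances_, dtype=float)
    top = imp.max()
    scores = imp / top * 100.0 if top > 0 else imp
    return pd.Series(scores, index=list(feature_names), name="relevance")


def train_and_evaluate(
    matrix: pd.DataFrame,
    labels: pd.Series,
    config: ClassifierConfig | None = None,
) -> Dict[str, object]:
    """Tune, train and evaluate the random-forest classifier.

    ``matrix`` is the samples x peptides log2 concentration matrix (may
    contain missing values; imputation runs according to ``config.mode``).
    ``labels`` maps sample id to class label; the positive class is
    ``config.positive_class``.  Returns the classifier report dict.
    """
    cfg = config or ClassifierConfig()
    labels = labels.loc[matrix.index]
    y_all = (labels == cfg.positive_class).astype(int)
    if y_all.sum() == 0 or y_all.sum() == len(y_all):
        raise ValueError("both classes must be present")

    train_ids, test_ids = split_cohort(labels, cfg.train_fraction, cfg.seed)

    if cfg.mode == "impute_first":
        full = knn_impute(matrix, k=cfg.knn_k,
                          max_missing_fraction=cfg.max_missing_fraction)
        X_train = full.loc[train_ids]
        X_test = full.loc[test_ids]
    elif cfg.mode == "safe":
        X_train = knn_impute(matrix.loc[train_ids], k=cfg.knn_k,
                             max_missing_fraction=cfg.max_missing_fraction)
        X_test = knn_impute(matrix.loc[test_ids], k=cfg.knn_k,
                            max_missing_fraction=cfg.max_missing_fraction,
                            reference=matrix.loc[train_ids])
    else:
        raise ValueError(f"unknown mode {cfg.mode!r}")

    y_train = y_all.loc[train_ids].to_numpy()
    y_test = y_all.loc[test_ids].to_numpy()
    if y_train.min() == y_train.max():
        raise ValueError("training split is single-class")

    cv = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    search = GridSearchCV(
        RandomForestClassifier(n_estimators=cfg.n_trees, random_state=cfg.seed),
        param_grid={"max_features": list(cfg.max_features_grid)},
        scoring="roc_auc", cv=cv, refit=True,
    )
    search.fit(X_train.to_numpy(), y_train)
    model: RandomForestClassifier = search.best_estimator_

    scores = model.predict_proba(X_test.to_numpy())[:, 1]
    fpr, tpr, thresholds = roc_curve(y_test, scores)
    auc = float(roc_auc_score(y_test, scores))

    pred = (scores >= cfg.threshold).astype(int)
    tp = int(((pred == 1) & (y_test == 1)).sum())
    tn = int(((pred == 0) & (y_test == 0)).sum())
    fp = int(((pred == 1) & (y_test == 0)).sum())
    fn = int(((pred == 0) & (y_test == 1)).sum())
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")

    relevance = relevance_scores(model, matrix.columns)

    return {
        "auc": auc,
        "roc": {
            "fpr": fpr.tolist(),
            "tpr": tpr.tolist(),
            "thresholds": thresholds.tolist(),
        },
        "sensitivity": sensitivity,
        "specificity": specificity,
        "threshold": cfg.threshold,
        "relevance": relevance.sort_values(ascending=False).to_dict(),
        "holdout_scores": dict(zip(test_ids, scores.tolist())),
        "holdout_labels": dict(zip(test_ids, y_test.tolist())),
        "best_params": search.best_params_,
        "cv_best_auc": float(search.best_score_),
        "config": {
            "positive_class": cfg.positive_class,
            "train_fraction": cfg.train_fraction,
            "n_folds": cfg.n_folds,
            "n_trees": cfg.n_trees,
            "max_features_grid": list(cfg.max_features_grid),
            "knn_k": cfg.knn_k,
            "mode": cfg.mode,
            "seed": cfg.seed,
        },
        "train_ids": list(train_ids),
        "test_ids": list(test_ids),
        "n_train": len(train_ids),
        "n_test": len(test_ids),
    }


def run_classification(
    matrix: pd.DataFrame,
    manifest: pd.DataFrame,
    config: ClassifierConfig | None = None,
) -> Dict[str, object]:
    """Patient-only classification from a concentration matrix.

    Log2-transforms the concentrations, keeps patient samples, labels them
    positive iff their cancer equals the configured positive class, and
    delegates to :func:`train_and_evaluate`.
    """
    cfg = config or ClassifierConfig()
    mani = manifest.set_index("sample_id")
    patients = [s for s in matrix.index
                if s in mani.index and mani.loc[s, "sample_type"] == "patient"]
    X = np.log2(matrix.loc[patients])
    labels = mani.loc[patients, "cancer"]
    return train_and_evaluate(X, labels, cfg)
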