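"""Feature fusion and condition classification of single mitochondria.

Per-object products from the morphometry, topology, morphotype,
biomarker, and dynamics stages are inner-joined on the object id into a
single feature table; a random-forest classifier (majority voting over
an ensemble of decision trees) is trained to distinguish physiological
conditions, either binary (e.g. normoxia vs hypoxia) or a 4-level
severity scale (control / mild / moderate / severe).  Evaluation uses
ROC/AUC on a stratified 7:3 train/test split, stratified 5-fold
cross-validation across seeds, impurity-decrease feature importances
(permutation importance optional), and unweighted one-vs-rest macro-AUC
in the multi-class mode.  An unsupervised k-means (k=2) subpopulation
analysis on z-scored features provides silhouette, a 2-component PCA
projection, and per-object cluster assignment probabilities (softmax of
negative squared distances scaled by the mean within-cluster
dispersion) which can be appended to the table as one extra feature.

Forest defaults: 500 trees, sqrt(p) features per split, no depth cap,
and an explicit seed.  Trees consume raw (unscaled) features; z-scoring
is applied only for k-means and PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score, roc_curve, silhouette_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler

LABEL_COLUMN = "condition"
ID_COLUMN = "object_id"

#: ablation feature sets, keyed the way the CLI exposes them
FEATURE_SETS = {
    "morphology": [
        "area_px2",
        "solidity",
        "extent",
        "form_factor",
        "roundness",
        "ratio_major_minor",
        "length_px",
        "branch_count",
        "loops",
        "mean_branch_length_px",
    ],
    "type": ["type_dot", "type_rod", "type_network"],
    "biomarker": ["viscosity_fraction", "ros_fraction", "mmp_fraction"],
    "dynamics": ["speed_px_s", "directionality", "net_displacement_px"],
}

MOTILITY_COLUMNS = FEATURE_SETS["dynamics"]


@dataclass
class ClassifierReport:
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    importances: pd.Series
    n_train: int
    n_test: int
    seed: int
    cv_scores: np.ndarray | None = None
    macro_auc: float | None = None


@dataclass
class ClusteringReport:
    labels: np.ndarray
    silhouette: float
    pca_coords: np.ndarray
    explained_variance_ratio: np.ndarray
    probabilities: np.ndarray  # (n, k), rows sum to 1
    feature_names: list[str] = field(default_factory=list)


def _feature_columns(table: pd.DataFrame) -> list[str]:
    drop = {LABEL_COLUMN, ID_COLUMN}
    return [
        c
        for c in table.columns
        if c not in drop and pd.api.types.is_numeric_dtype(table[c])
    ]


def assemble_feature_table(products: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Inner-join per-object product tables on the object id.

    Each value in ``products`` is a DataFrame carrying an ``object_id``
    column.  Motility columns may be missing for objects never tracked;
    those rows are kept, their motility entries filled with NaN and a
    ``motility_missing`` indicator set to 1.
    """
    frames = []
    for name, df in products.items():
        if ID_COLUMN not in df.columns:
            raise ValueError(f"product {name!r} lacks an {ID_COLUMN} column")
        if df[ID_COLUMN].duplicated().any():
            raise ValueError(f"product {name!r} has duplicated object ids")
        frames.append(df)
    motility = [df for df in frames if any(c in df.columns for c in MOTILITY_COLUMNS)]
    core = [df for df in frames if not any(c in df.columns for c in MOTILITY_COLUMNS)]
    if core:
        table = reduce(lambda a, b: a.merge(b, on=ID_COLUMN, how="inner"), core)
    else:
        table = motility.pop(0)
    if table.empty:
        raise ValueError("no overlapping object ids across products")
    for df in motility:
        table = table.merge(df, on=ID_COLUMN, how="left")
    present = [c for c in MOTILITY_COLUMNS if c in table.columns]
    if present:
        table["motility_missing"] = table[present].isna().any(axis=1).astype(int)
    return table


def split_train_test(
    table: pd.DataFrame, ratio: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified, reproducible train/test split (default 7:3)."""
    labels = table[LABEL_COLUMN]
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every condition needs at least 2 rows to stratify")
    train, test = train_test_split(
        table, train_size=ratio, stratify=labels, random_state=seed
    )
    return train, test


def train_random_forest(
    train: pd.DataFrame,
    seed: int,
    n_estimators: int = 500,
    feature_columns: list[str] | None = None,
    **forest_kwargs,
) -> RandomForestClassifier:
    """Fit the condition classifier on a training table."""
    if train[LABEL_COLUMN].nunique() < 2:
        raise ValueError("training set must contain at least 2 classes")
    cols = feature_columns or _feature_columns(train)
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=seed,
        **forest_kwargs,
    )
    X = train[cols].to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0)
    model.fit(X, train[LABEL_COLUMN])
    model.feature_names_used_ = list(cols)
    return model


def predict(model: RandomForestClassifier, rows: pd.DataFrame) -> np.ndarray:
    """Class score matrix (fraction of tree votes per class) for new rows."""
    X = rows[model.feature_names_used_].to_numpy(dtype=float)
    return model.predict_proba(np.nan_to_num(X, nan=0.0))


def evaluate_roc(scores, labels, positive_label=None) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC of binary scores.

    AUC equals the Mann-Whitney pairwise-concordance probability (ties
    counted half).  Returns ``(fpr, tpr, auc)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("evaluate_roc needs exactly 2 label values")
    pos = positive_label if positive_label is not None else uniq.max()
    y = (labels == pos).astype(int)
    fpr, tpr, _ = roc_curve(y, scores)
    return fpr, tpr, float(roc_auc_score(y, scores))


def feature_importances(
    model: RandomForestClassifier,
    mode: str = "impurity",
    X: pd.DataFrame | None = None,
    y=None,
    seed: int = 0,
) -> pd.Series:
    """Per-feature importances normalized to sum 1, sorted descending.

    ``impurity`` (default) uses mean impurity decrease; ``permutation``
    shuffles each feature on held-out data (requires X, y).
    """
    names = model.feature_names_used_
    if mode == "impurity":
        raw = model.feature_importances_
    elif mode == "permutation":
        if X is None or y is None:
            raise ValueError("permutation importance requires X and y")
        res = permutation_importance(
            model, np.nan_to_num(X[names].to_numpy(dtype=float)), y, random_state=seed
        )
        raw = np.clip(res.importances_mean, 0, None)
    else:
        raise ValueError("mode must be 'impurity' or 'permutation'")
    total = raw.sum()
    if total > 0:
        raw = raw / total
    return pd.Series(raw, index=names).sort_values(ascending=False)


def cross_validate(
    table: pd.DataFrame,
    k: int = 5,
    seeds: tuple[int, ...] = (0,),
    n_estimators: int = 500,
    feature_columns: list[str] | None = None,
) -> np.ndarray:
    """Stratified k-fold AUC scores, repeated over seeds.

    Returns an array of shape ``(len(seeds), k)``.  Multi-class labels
    are scored with macro one-vs-rest AUC per fold.
    """
    labels = table[LABEL_COLUMN]
    if labels.value_counts().min() < k:
        raise ValueError(f"every class needs at least k={k} rows")
    cols = feature_columns or _feature_columns(table)
    scores = np.empty((len(seeds), k))
    for si, seed in enumerate(seeds):
        folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        idx = np.arange(len(table))
        for fi, (tr, te) in enumerate(folds.split(idx, labels)):
            model = train_random_forest(
                table.iloc[tr], seed=seed, n_estimators=n_estimators, feature_columns=cols
            )
            proba = predict(model, table.iloc[te])
            y_te = labels.iloc[te]
            if proba.shape[1] == 2:
                _, _, auc = evaluate_roc(proba[:, 1], y_te, positive_label=model.classes_[1])
            else:
                auc = macro_auc_multiclass(proba, y_te, classes=model.classes_)
            scores[si, fi] = auc
    return scores


def macro_auc_multiclass(score_matrix, labels, classes=None) -> float:
    """Unweighted mean of one-vs-rest AUCs over the observed classes."""
    scores = np.asarray(score_matrix, dtype=float)
    labels = np.asarray(labels)
    classes = np.asarray(classes) if classes is not None else np.unique(labels)
    present = [i for i, c in enumerate(classes) if (labels == c).any()]
    if len(present) < 2:
        raise ValueError("need at least 2 classes present")
    aucs = []
    for i in present:
        y = (labels == classes[i]).astype(int)
        if y.all():
            continue
        aucs.append(roc_auc_score(y, scores[:, i]))
    return float(np.mean(aucs))


def cluster_subpopulations(
    table: pd.DataFrame, k: int = 2, seed: int = 0, feature_columns: list[str] | None = None
) -> ClusteringReport:
    """K-means subpopulation analysis on z-scored features.

    Returns cluster labels, silhouette score, a 2-component PCA
    projection with explained-variance ratios, and soft assignment
    probabilities computed as a softmax of negative squared distances to
    the centroids, scaled by the mean within-cluster squared distance.
    """
    cols = feature_columns or _feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0)
    if len(X) < 2 * k:
        raise ValueError(f"need at least {2 * k} rows for k={k}")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate input: all features constant")
    Z = StandardScaler().fit_transform(X)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(Z)
    sil = float(silhouette_score(Z, labels))
    pca = PCA(n_components=2, random_state=seed)
    coords = pca.fit_transform(Z)
    d2 = ((Z[:, None, :] - km.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
    tau = float(d2[np.arange(len(Z)), labels].mean())
    tau = tau if tau > 0 else 1.0
    logits = -d2 / tau
    logits -= logits.max(axis=1, keepdims=True)
    proba = np.exp(logits)
    proba /= proba.sum(axis=1, keepdims=True)
    return ClusteringReport(
        labels=labels,
        silhouette=sil,
        pca_coords=coords,
        explained_variance_ratio=pca.explained_variance_ratio_,
        probabilities=proba,
        feature_names=list(cols),
    )


def augment_with_cluster_probability(
    table: pd.DataFrame, report: ClusteringReport, column: str = "cluster_probability"
) -> pd.DataFrame:
    """Append the probability of cluster 1 as one extra feature column."""
    if len(report.probabilities) != len(table):
        raise ValueError("clustering report does not match the table rows")
    out = table.copy()
    out[column] = report.probabilities[:, 1]
    return out
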