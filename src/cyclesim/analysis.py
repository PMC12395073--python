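"""Phenotype-discrimination pipeline.

Standardization -> PCA (first two components plotted/reported) and
k-means (k=2) for unsupervised separation, plus a stratified 70/30
logistic-regression evaluation reporting accuracy, sensitivity,
specificity and ROC AUC with PCOS as the positive class.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import train_test_split

from .config import PCOS
from .features import feature_columns, split_features_labels

POSITIVE_CLASS = PCOS


@dataclass
class Standardizer:
    """Column-wise (x - mean) / sd transform with sample SD (ddof=1).

    Fitted statistics are kept so the same transform can be applied to
    held-out data without leakage.
    """

    means: np.ndarray
    sds: np.ndarray
    columns: list[str] = field(default_factory=list)

    @classmethod
    def fit(cls, X: pd.DataFrame | np.ndarray) -> "Standardizer":
        cols = list(X.columns) if isinstance(X, pd.DataFrame) else []
        arr = np.asarray(X, dtype=float)
        means = arr.mean(axis=0)
        sds = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
        constant = np.flatnonzero(sds == 0.0)
        if constant.size:
            names = [cols[i] if cols else str(i) for i in constant]
            raise ValueError(f"cannot standardize constant column(s): {names}")
        return cls(means=means, sds=sds, columns=cols)

    def transform(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.sds


def standardize(X: pd.DataFrame | np.ndarray):
    """Standardize a feature matrix; returns (Z, standardizer)."""
    sc = Standardizer.fit(X)
    return sc.transform(X), sc


@dataclass
class PCAResult:
    scores: np.ndarray                    # subjects x components
    explained_variance_ratio: np.ndarray  # per component
    loadings: np.ndarray                  # features x components


def pca_project(Z: np.ndarray, n_components: int = 2) -> PCAResult:
    """Principal components of a standardized matrix.

    Deterministic up to sign; the sign of each component is fixed by
    making its largest-magnitude loading positive, so scores reproduce
    across runs and platforms.
    """
    Z = np.asarray(Z, dtype=float)
    if n_components > Z.shape[1]:
        raise ValueError(f"n_components={n_components} exceeds {Z.shape[1]} features")
    if Z.shape[0] < n_components:
        raise ValueError("fewer samples than requested components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # features x components
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return PCAResult(scores=scores,
                     explained_variance_ratio=pca.explained_variance_ratio_.copy(),
                     loadings=loadings)


def label_agreement(cluster_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Best fraction of matches over cluster-to-class permutations."""
    cluster_labels = np.asarray(cluster_labels)
    true_codes, _ = pd.factorize(pd.Series(np.asarray(true_labels)))
    k = max(cluster_labels.max(), true_codes.max()) + 1
    cm = np.zeros((k, k), dtype=int)
    for c, y in zip(cluster_labels, true_codes):
        cm[c, y] += 1
    rows, cols = linear_sum_assignment(-cm)
    return cm[rows, cols].sum() / len(cluster_labels)


def kmeans_cluster(Z: np.ndarray, k: int = 2, seed: int = 0, n_init: int = 10,
                   true_labels=None):
    """Seeded k-means with restarts; optionally scores phenotype agreement.

    Returns (labels, agreement) where agreement is None unless true labels
    are supplied; agreement is reporting-only and never influences the fit.
    """
    Z = np.asarray(Z, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > Z.shape[0]:
        raise ValueError("k exceeds the number of samples")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)
    agreement = None if true_labels is None else label_agreement(labels, true_labels)
    return labels, agreement


@dataclass
class ClassificationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    confusion: dict
    n_train: int
    n_test: int
    seed: int
    positive_class: str = POSITIVE_CLASS


def train_eval_logistic(X: pd.DataFrame, y, train_fraction: float = 0.7,
                        seed: int = 0) -> ClassificationReport:
    """Stratified split, train-only standardization, logistic regression.

    The model carries weak L2 regularization (C=1000) purely to keep the
    MLE finite on perfectly separable classes; at this strength it does
    not move the reported metrics.  Sensitivity/specificity treat PCOS as
    the positive class; AUC comes from the ranked decision scores.
    """
    y = pd.Series(np.asarray(y))
    if y.nunique() < 2:
        raise ValueError("both phenotype classes must be present")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, stratify=y, random_state=seed)
    if y_tr.nunique() < 2 or y_te.nunique() < 2:
        raise ValueError("a class is absent from one side of the split")

    Z_tr, scaler = standardize(X_tr)
    Z_te = scaler.transform(X_te)  # train statistics only: no leakage
    clf = LogisticRegression(C=1000.0, max_iter=5000)
    clf.fit(Z_tr, (y_tr == POSITIVE_CLASS).astype(int))

    y_true = (y_te == POSITIVE_CLASS).astype(int).to_numpy()
    y_pred = clf.predict(Z_te)
    scores = clf.decision_function(Z_te)
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    return ClassificationReport(
        accuracy=(tp + tn) / len(y_true),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        auc=float(roc_auc_score(y_true, scores)),
        confusion={"tn": int(tn), "fp": int(fp), "fn": int(fn), "tp": int(tp)},
        n_train=len(y_tr),
        n_test=len(y_te),
        seed=seed,
    )


def run_analysis(feature_table: pd.DataFrame, preset: str = "pca6",
                 seed: int = 0) -> dict:
    """Full discrimination pipeline on a feature table; returns the report.

    Features that are constant across the cohort (e.g. the AMH daily SD,
    which is structurally zero for a trait-like hormone) carry no
    discriminative information and cannot be standardized; they are
    dropped and listed in the report.
    """
    X, y = split_features_labels(feature_table, preset)
    constant_cols = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=constant_cols)
    if X.shape[1] == 0:
        raise ValueError("all feature columns are constant")
    Z, _ = standardize(X)
    pca = pca_project(Z, n_components=2)
    _, agreement = kmeans_cluster(Z, k=2, seed=seed, true_labels=y)
    logistic = train_eval_logistic(X, y, seed=seed)
    return {
        "preset": preset,
        "dropped_constant_features": constant_cols,
        "n_subjects": len(feature_table),
        "seed": seed,
        "pca": {
            "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
            "pc1_pc2_explained": float(pca.explained_variance_ratio[:2].sum()),
        },
        "kmeans": {"k": 2, "label_agreement": agreement},
        "logistic": asdict(logistic),
        "pca_scores": pd.DataFrame({
            "subject_id": feature_table["subject_id"],
            "phenotype": y,
            "PC1": pca.scores[:, 0],
            "PC2": pca.scores[:, 1],
        }),
    }


def write_report(report: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write analysis_report.json and pca_scores.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores = report.pop("pca_scores")
    paths = {"report": out / "analysis_report.json",
             "pca_scores": out / "pca_scores.csv"}
    paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True))
    scores.to_csv(paths["pca_scores"], index=False, float_format="%.6g")
    report["pca_scores"] = scores
    return paths


def pca_scatter(scores: pd.DataFrame, path: str | Path) -> Path:
    """Save a PC1/PC2 scatter colored by phenotype (mirrors the usual
    two-cluster projection figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for phen, marker, color in (("EUM", "o", "tab:red"), (PCOS, "x", "tab:blue")):
        sub = scores[scores["phenotype"] == phen]
        ax.scatter(sub["PC1"], sub["PC2"], marker=marker, s=18,
                   color=color, label=phen, alpha=0.7)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(title="phenotype")
    ax.set_title("PCA of standardized mean hormone levels")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
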