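"""QSAR model building, prediction and chemical-space embedding.

Datasets of (structure, activity) pairs are featurized with ECFP6, FCFP6
(2048-bit radius-3 circular fingerprints) or a fixed physicochemical
descriptor set (z-scored inside each CV fold so no test statistics leak into
training). Models — random forest, SVM, k-NN — are tuned by grid search
under 5-fold cross-validation (stratified for classification), refit on the
full data, and applied with a 0.5 probability threshold for classification.
Chemical space is embedded with PCA on the standardized descriptor set,
keeping the top three components.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    mean_absolute_percentage_error,
    mean_squared_error,
    precision_score,
    r2_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from . import features
from .dataset import QSARDataset, Task
from .store import Outcome, resolve_outcome_conflicts

__all__ = [
    "FeatureKind",
    "FeatureScheme",
    "Algorithm",
    "ModelBundle",
    "import_assay_table",
    "featurize",
    "train_qsar",
    "build_model_suite",
    "predict",
    "chemspace_pca",
]

CLASSIFICATION_THRESHOLD = 0.5


class FeatureKind(enum.Enum):
    ECFP6 = "ecfp6"
    FCFP6 = "fcfp6"
    PHYSCHEM = "physchem"


@dataclass(frozen=True)
class FeatureScheme:
    kind: FeatureKind
    n_bits: int = features.N_BITS
    radius: int = features.RADIUS

    @classmethod
    def of(cls, kind: "FeatureKind | str") -> "FeatureScheme":
        return cls(FeatureKind(kind) if isinstance(kind, str) else kind)


class Algorithm(enum.Enum):
    RF = "rf"
    SVM = "svm"
    KNN = "knn"


#: Default hyperparameter grids for grid search (kept small on purpose).
DEFAULT_GRIDS = {
    Algorithm.RF: {"model__n_estimators": [100, 500], "model__max_depth": [None, 20]},
    Algorithm.SVM: {"model__C": [0.1, 1.0, 10.0], "model__kernel": ["rbf", "linear"]},
    Algorithm.KNN: {"model__n_neighbors": [3, 5, 7], "model__weights": ["uniform", "distance"]},
}


@dataclass
class ModelBundle:
    """A trained QSAR model plus everything needed to reuse it."""

    dataset_name: str
    scheme: FeatureScheme
    algorithm: Algorithm
    task: Task
    pipeline: Pipeline
    best_params: dict
    cv_metrics: pd.DataFrame
    threshold: float = CLASSIFICATION_THRESHOLD
    seed: int = 0

    @property
    def name(self) -> str:
        return f"{self.dataset_name}_{self.scheme.kind.value}_{self.algorithm.value}"

    def mean_metric(self, metric: str) -> float:
        sub = self.cv_metrics[self.cv_metrics["fold"] == "mean"]
        return float(sub[metric].iloc[0])

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        import joblib

        return joblib.load(path)


def import_assay_table(records, registry, name: str | None = None) -> QSARDataset:
    """Build a binary QSAR dataset from one assay's bioactivity records.

    Active/probe outcomes become 1, inactive becomes 0; inconclusive and
    unspecified results are discarded. Duplicate compounds collapse to the
    defined-activity entry (the more active call wins if several are
    defined). Structures are attached from the registry.
    """
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    aids = {r.aid for r in records}
    if len(aids) > 1:
        raise ValueError(f"records span multiple assays: {sorted(aids)}")
    aid = next(iter(aids))

    defined = [r for r in records
               if r.outcome.is_active or r.outcome is Outcome.INACTIVE]
    defined = resolve_outcome_conflicts(defined)
    rows = []
    for r in defined:
        structure = registry.structure_for(r.cid)
        if structure is None:
            continue
        rows.append({"id": r.cid, "smiles": structure,
                     "activity": 1 if r.outcome.is_active else 0})
    if not rows:
        raise ValueError(f"assay {aid}: no records with a defined activity survive import")
    return QSARDataset(name or f"assay_{aid}", pd.DataFrame(rows), Task.BINARY)


def featurize(
    ds: QSARDataset, scheme: FeatureScheme, scaler: StandardScaler | None = None
) -> tuple[np.ndarray, list[int], StandardScaler | None]:
    """Feature matrix for a dataset; rows for unparseable structures are dropped.

    For the physchem scheme the matrix is z-scored; pass a fitted scaler to
    reuse training-set statistics at prediction time, otherwise one is fit
    and returned. Fingerprint schemes need no scaling.

    Returns (matrix, kept_record_indices, scaler-or-None).
    """
    smiles = ds.records["smiles"].tolist()
    if scheme.kind is FeatureKind.PHYSCHEM:
        X, kept = features.physchem_matrix(smiles)
        if len(kept) == 0:
            raise ValueError("no structure could be featurized")
        if scaler is None:
            scaler = StandardScaler().fit(X)
        return scaler.transform(X), kept, scaler
    X, kept = features.fingerprint_matrix(
        smiles, feature_based=(scheme.kind is FeatureKind.FCFP6)
    )
    if len(kept) == 0:
        raise ValueError("no structure could be featurized")
    return X.astype(float), kept, None


def _raw_features(smiles_list, scheme: FeatureScheme) -> tuple[np.ndarray, list[int]]:
    if scheme.kind is FeatureKind.PHYSCHEM:
        return features.physchem_matrix(smiles_list)
    X, kept = features.fingerprint_matrix(
        smiles_list, feature_based=(scheme.kind is FeatureKind.FCFP6)
    )
    return X.astype(float), kept


def _make_pipeline(scheme: FeatureScheme, algorithm: Algorithm, task: Task, seed: int) -> Pipeline:
    steps = []
    if scheme.kind is FeatureKind.PHYSCHEM:
        # scaler inside the pipeline => refit per CV fold, no train/test leakage
        steps.append(("scale", StandardScaler()))
    if task is Task.BINARY:
        model = {
            Algorithm.RF: RandomForestClassifier(random_state=seed, n_jobs=1),
            Algorithm.SVM: SVC(probability=True, random_state=seed),
            Algorithm.KNN: KNeighborsClassifier(),
        }[algorithm]
    else:
        model = {
            Algorithm.RF: RandomForestRegressor(random_state=seed, n_jobs=1),
            Algorithm.SVM: SVR(),
            Algorithm.KNN: KNeighborsRegressor(),
        }[algorithm]
    steps.append(("model", model))
    return Pipeline(steps)


def _positive_proba(est, X) -> np.ndarray:
    clf = est[-1] if isinstance(est, Pipeline) else est
    proba = est.predict_proba(X)
    return proba[:, list(clf.classes_).index(1)]


def _ranking_scores(est, X) -> np.ndarray:
    """Scores for threshold-free ranking metrics: decision scores if available."""
    if hasattr(est, "decision_function"):
        try:
            return np.asarray(est.decision_function(X)).ravel()
        except Exception:
            pass
    return _positive_proba(est, X)


def _cv_metrics(pipe: Pipeline, X, y, task: Task, seed: int) -> pd.DataFrame:
    rows = []
    if task is Task.BINARY:
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=5, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(splitter.split(X, y if task is Task.BINARY else None)):
        from sklearn.base import clone

        est = clone(pipe)
        est.fit(X[tr], y[tr])
        if task is Task.BINARY:
            proba = _positive_proba(est, X[te])
            scores = _ranking_scores(est, X[te])
            pred = (proba >= CLASSIFICATION_THRESHOLD).astype(int)
            row = {
                "fold": fold,
                "accuracy": accuracy_score(y[te], pred),
                "precision": precision_score(y[te], pred, zero_division=0),
                "recall": recall_score(y[te], pred, zero_division=0),
                "f1": f1_score(y[te], pred, zero_division=0),
                "roc_auc": roc_auc_score(y[te], scores),
                "pr_auc": average_precision_score(y[te], scores),
            }
        else:
            pred = est.predict(X[te])
            row = {
                "fold": fold,
                "r2": r2_score(y[te], pred),
                "mse": mean_squared_error(y[te], pred),
                "mape": mean_absolute_percentage_error(y[te], pred),
            }
        rows.append(row)
    df = pd.DataFrame(rows)
    agg = df.drop(columns="fold").agg(["mean", "std"]).reset_index()
    agg = agg.rename(columns={"index": "fold"})
    return pd.concat([df, agg], ignore_index=True)


def train_qsar(
    ds: QSARDataset,
    scheme: FeatureScheme | str,
    algorithm: Algorithm | str,
    seed: int = 0,
    grid: dict | None = None,
) -> ModelBundle:
    """Grid-search, cross-validate and fit one QSAR model.

    Hyperparameters are tuned by grid search with 5-fold CV (stratified for
    classification); the winning configuration is re-evaluated fold by fold
    for the reported metrics and refit on the full data. Deterministic given
    the seed.
    """
    scheme = FeatureScheme.of(scheme) if not isinstance(scheme, FeatureScheme) else scheme
    algorithm = Algorithm(algorithm) if isinstance(algorithm, str) else algorithm

    y_all = ds.records["activity"].to_numpy()
    X, kept = _raw_features(ds.records["smiles"].tolist(), scheme)
    y = y_all[kept]
    if ds.task is Task.BINARY:
        y = y.astype(int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("binary training requires both classes present")
        if counts.min() < 5:
            raise ValueError("each class needs >= 5 members for stratified 5-fold CV")
    elif len(y) < 5:
        raise ValueError("need at least 5 records for 5-fold CV")

    pipe = _make_pipeline(scheme, algorithm, ds.task, seed)
    if ds.task is Task.BINARY:
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        scoring = "roc_auc"
    else:
        cv = KFold(n_splits=5, shuffle=True, random_state=seed)
        scoring = "r2"
    search = GridSearchCV(
        pipe, grid if grid is not None else DEFAULT_GRIDS[algorithm],
        cv=cv, scoring=scoring, n_jobs=1, refit=True,
    )
    search.fit(X, y)
    best = search.best_estimator_
    metrics = _cv_metrics(best, X, y, ds.task, seed)
    return ModelBundle(
        dataset_name=ds.name,
        scheme=scheme,
        algorithm=algorithm,
        task=ds.task,
        pipeline=best,
        best_params=search.best_params_,
        cv_metrics=metrics,
        seed=seed,
    )


def build_model_suite(
    ds: QSARDataset,
    schemes: Sequence[FeatureScheme | str] = ("ecfp6", "fcfp6", "physchem"),
    algorithms: Sequence[Algorithm | str] = ("rf", "svm", "knn"),
    seed: int = 0,
) -> tuple[list[ModelBundle], pd.DataFrame]:
    """Train one model per (scheme, algorithm) pair and compare them.

    Failures in one cell are recorded in the comparison table without
    aborting the rest. The best model is flagged by mean CV ROC-AUC
    (classification) or R² (regression), ties by accuracy / lower MSE then
    by name.
    """
    bundles: list[ModelBundle] = []
    rows = []
    for scheme in schemes:
        for algorithm in algorithms:
            s = FeatureScheme.of(scheme) if not isinstance(scheme, FeatureScheme) else scheme
            a = Algorithm(algorithm) if isinstance(algorithm, str) else algorithm
            try:
                bundle = train_qsar(ds, s, a, seed=seed)
            except Exception as exc:
                rows.append({"scheme": s.kind.value, "algorithm": a.value,
                             "status": f"failed: {exc}"})
                continue
            bundles.append(bundle)
            mean = bundle.cv_metrics[bundle.cv_metrics["fold"] == "mean"].iloc[0]
            row = {"scheme": s.kind.value, "algorithm": a.value, "status": "ok"}
            row.update({k: float(v) for k, v in mean.items() if k != "fold"})
            rows.append(row)
    table = pd.DataFrame(rows)
    if bundles:
        if ds.task is Task.BINARY:
            key = lambda b: (-b.mean_metric("roc_auc"), -b.mean_metric("accuracy"), b.name)
        else:
            key = lambda b: (-b.mean_metric("r2"), b.mean_metric("mse"), b.name)
        best_name = min(bundles, key=key).name
        table["best"] = [
            row["status"] == "ok"
            and f"{ds.name}_{row['scheme']}_{row['algorithm']}" == best_name
            for _, row in table.iterrows()
        ]
    return bundles, table


def predict(bundle: ModelBundle, structures: Sequence[str]) -> tuple[pd.DataFrame, list[str]]:
    """Batch prediction; invalid structures are removed and listed.

    Classification rows carry the predicted label (probability >= 0.5 → 1)
    and the active-probability; regression rows carry the predicted value.
    The prediction column is named ``<ModelName>_Prediction``.
    """
    structures = list(structures)
    if not structures:
        raise ValueError("no structures supplied")
    X, kept = _raw_features(structures, bundle.scheme)
    if not kept:
        raise ValueError("no valid structure among inputs")
    invalid = [structures[i] for i in range(len(structures)) if i not in set(kept)]
    col = f"{bundle.name}_Prediction"
    if bundle.task is Task.BINARY:
        proba = _positive_proba(bundle.pipeline, X)
        labels = (proba >= bundle.threshold).astype(int)
        df = pd.DataFrame({
            "smiles": [structures[i] for i in kept],
            col: labels,
            f"{bundle.name}_Probability": proba,
        })
    else:
        pred = bundle.pipeline.predict(X)
        df = pd.DataFrame({"smiles": [structures[i] for i in kept], col: pred})
    return df, invalid


def chemspace_pca(ds: QSARDataset, seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Three-component PCA embedding of the standardized descriptor space.

    Returns (coordinates keyed by compound id with the activity column for
    coloring, explained-variance ratios for PC1..PC3).
    """
    X, kept = features.physchem_matrix(ds.records["smiles"].tolist())
    if len(kept) < 4:
        raise ValueError("need at least 4 compounds with valid structures for PCA")
    Xs = StandardScaler().fit_transform(X)
    Xs = np.nan_to_num(Xs)  # constant descriptor columns scale to NaN
    pca = PCA(n_components=3, random_state=seed)
    coords = pca.fit_transform(Xs)
    sub = ds.records.iloc[kept]
    df = pd.DataFrame(
        {"id": sub["id"].values, "PC1": coords[:, 0], "PC2": coords[:, 1],
         "PC3": coords[:, 2], "activity": sub["activity"].values}
    )
    return df, pca.explained_variance_ratio_
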