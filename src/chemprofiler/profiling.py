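"""Bioprofile construction, mutual-information assay selection and ML gap filling.

The bioprofile is a chemicals × assays matrix over {1, -1, 0}: 1 for
active/probe outcomes, -1 for inactive, 0 for inconclusive, unspecified or
untested. Assays are ranked by the mutual information between their
binarized outcomes and each chemical's overall activity label (active in at
least one assay). For the selected assays, per-assay random-forest
classifiers trained on ECFP6 fingerprints of the assay's tested compounds
impute the remaining zeros, yielding a complete bioprofile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from . import features
from .store import BioassayDatabase, Outcome

__all__ = [
    "Bioprofile",
    "MIScore",
    "GapFillTrainingSet",
    "GapFillModel",
    "build_initial_bioprofile",
    "compute_overall_labels",
    "compute_mi_scores",
    "select_assays",
    "sample_training_set",
    "train_gapfill_model",
    "fill_gaps",
    "export_heatmap",
]

DEFAULT_CAP = 500
DEFAULT_MIN_PER_CLASS = 100
DEFAULT_N_TREES = 500
DEFAULT_N_SELECT = 50


@dataclass
class Bioprofile:
    """Chemicals × assays activity matrix over {1, -1, 0}."""

    chemicals: list[str]
    assays: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.chemicals), len(self.assays)):
            raise ValueError("matrix shape does not match identifier lists")
        if not np.isin(self.matrix, (1, -1, 0)).all():
            raise ValueError("bioprofile entries must be in {1, -1, 0}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.chemicals, columns=self.assays)

    def column(self, aid: str) -> np.ndarray:
        return self.matrix[:, self.assays.index(aid)]


@dataclass(frozen=True)
class MIScore:
    aid: str
    mi: float


@dataclass
class GapFillTrainingSet:
    """Capped per-class structure sample for one assay's gap-fill model."""

    aid: str
    actives: list[str]
    inactives: list[str]
    cap: int
    min_per_class: int
    seed: int

    def __post_init__(self):
        if len(self.actives) > self.cap or len(self.inactives) > self.cap:
            raise ValueError("class sample exceeds cap")
        if len(self.actives) < self.min_per_class or len(self.inactives) < self.min_per_class:
            raise ValueError("class sample below minimum")


class TrainingSetRejected(ValueError):
    """Assay has fewer than the minimum usable compounds in some class."""

    def __init__(self, aid: str, reason: str):
        super().__init__(f"assay {aid} rejected: {reason}")
        self.aid = aid
        self.reason = reason


@dataclass
class GapFillModel:
    """Per-assay RF classifier over 2048-bit radius-3 circular fingerprints."""

    aid: str
    classifier: RandomForestClassifier
    metrics: pd.DataFrame | None
    seed: int
    n_bits: int = features.N_BITS
    radius: int = features.RADIUS

    def predict(self, structures: Sequence[str]) -> tuple[np.ndarray, np.ndarray, list[int]]:
        """Predict class in {1,-1} and active-probability for each structure.

        Returns (classes, probabilities, kept_indices); structures that fail
        fingerprinting are absent from kept_indices.
        """
        X, kept = features.fingerprint_matrix(structures)
        if not kept:
            return np.array([], dtype=int), np.array([]), []
        proba = self.classifier.predict_proba(X)[:, list(self.classifier.classes_).index(1)]
        classes = np.where(proba >= 0.5, 1, -1)
        return classes, proba, kept


def build_initial_bioprofile(
    chemicals: Sequence[str], db: BioassayDatabase
) -> tuple[Bioprofile, list[str]]:
    """Assemble the initial bioprofile for the given compounds.

    ``chemicals`` may be cids, InChIKeys, or SMILES (resolved to registry
    compounds via standardized InChIKey). Columns are restricted to assays
    with at least one active entry. Returns (profile, unresolved inputs).
    """
    resolved: list[str] = []
    unresolved: list[str] = []
    seen: set[str] = set()
    for key in chemicals:
        cid = _resolve_chemical(str(key), db)
        if cid is None:
            unresolved.append(str(key))
        elif cid not in seen:
            seen.add(cid)
            resolved.append(cid)
    if not resolved:
        raise ValueError("no input chemical could be resolved in the database")

    aid_index: dict[str, int] = {}
    cols: list[str] = []
    entries: list[tuple[int, int, int]] = []
    for ci, cid in enumerate(resolved):
        for rec in db.records_for_cid(cid):
            j = aid_index.setdefault(rec.aid, len(aid_index))
            if j == len(cols):
                cols.append(rec.aid)
            entries.append((ci, j, rec.outcome.encoded))
    matrix = np.zeros((len(resolved), len(cols)), dtype=np.int8)
    for ci, j, v in entries:
        matrix[ci, j] = v

    keep = (matrix == 1).any(axis=0)
    kept_assays = [a for a, k in zip(cols, keep) if k]
    order = np.argsort(kept_assays)
    kept_assays = [kept_assays[i] for i in order]
    matrix = matrix[:, keep][:, order]
    return Bioprofile(resolved, kept_assays, matrix), unresolved


def compute_overall_labels(profile: Bioprofile) -> np.ndarray:
    """Binary overall activity: 1 iff the chemical is active in ≥1 assay."""
    if profile.matrix.size == 0:
        raise ValueError("empty bioprofile")
    return (profile.matrix == 1).any(axis=1).astype(int)


def binary_mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in discrete mutual information (nats) between two binary vectors.

    MI = Σ_{a,b} p(a,b) · ln( p(a,b) / (p(a)·p(b)) ), with 0·ln0 = 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)
    if n == 0 or len(y) != n:
        raise ValueError("inputs must be equal-length and non-empty")
    mi = 0.0
    for a in (0, 1):
        pa = np.mean(x == a)
        for b in (0, 1):
            pb = np.mean(y == b)
            pab = np.mean((x == a) & (y == b))
            if pab > 0:
                mi += pab * math.log(pab / (pa * pb))
    return max(mi, 0.0)


def compute_mi_scores(profile: Bioprofile, labels: np.ndarray) -> list[MIScore]:
    """Score each assay column by MI with the overall labels.

    Columns are binarized first (1 stays 1; -1 and 0 both become 0), matching
    the convention that only a confirmed active is evidence of activity.
    """
    labels = np.asarray(labels)
    if len(labels) != len(profile.chemicals):
        raise ValueError("labels length must equal number of chemicals")
    scores = []
    for j, aid in enumerate(profile.assays):
        col = (profile.matrix[:, j] == 1).astype(int)
        scores.append(MIScore(aid, binary_mutual_information(col, labels)))
    return scores


def select_assays(scores: Sequence[MIScore], n: int = DEFAULT_N_SELECT) -> list[str]:
    """Top-n assays by MI, descending; ties broken by ascending aid."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(scores, key=lambda s: (-s.mi, s.aid))
    return [s.aid for s in ranked[:n]]


def sample_training_set(
    aid: str,
    db: BioassayDatabase,
    cap: int = DEFAULT_CAP,
    min_per_class: int = DEFAULT_MIN_PER_CLASS,
    seed: int = 0,
) -> GapFillTrainingSet:
    """Sample up to ``cap`` actives and ``cap`` inactives tested in an assay.

    Uniform without replacement, seeded. Compounds without a resolvable
    structure are skipped before capping. Raises :class:`TrainingSetRejected`
    if either class has fewer than ``min_per_class`` usable compounds.
    """
    recs = db.records_for_aid(str(aid))
    if not recs:
        raise KeyError(f"assay not found: {aid}")
    actives, inactives = [], []
    for rec in sorted(recs, key=lambda r: r.cid):
        structure = db.registry.structure_for(rec.cid)
        if structure is None:
            continue
        if rec.outcome.is_active:
            actives.append(structure)
        elif rec.outcome is Outcome.INACTIVE:
            inactives.append(structure)
    if len(actives) < min_per_class:
        raise TrainingSetRejected(str(aid), f"only {len(actives)} usable actives (< {min_per_class})")
    if len(inactives) < min_per_class:
        raise TrainingSetRejected(str(aid), f"only {len(inactives)} usable inactives (< {min_per_class})")
    rng = np.random.default_rng(seed)
    if len(actives) > cap:
        actives = [actives[i] for i in sorted(rng.choice(len(actives), cap, replace=False))]
    if len(inactives) > cap:
        inactives = [inactives[i] for i in sorted(rng.choice(len(inactives), cap, replace=False))]
    return GapFillTrainingSet(str(aid), actives, inactives, cap, min_per_class, seed)


def _classification_metrics(y_true, y_pred, y_proba) -> dict[str, float]:
    out = {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision": precision_score(y_true, y_pred, zero_division=0),
        "recall": recall_score(y_true, y_pred, zero_division=0),
        "f1": f1_score(y_true, y_pred, zero_division=0),
    }
    try:
        out["roc_auc"] = roc_auc_score(y_true, y_proba)
    except ValueError:
        out["roc_auc"] = float("nan")
    return out


def train_gapfill_model(
    ts: GapFillTrainingSet,
    n_trees: int = DEFAULT_N_TREES,
    cv_metrics: bool = True,
) -> GapFillModel:
    """Fit the per-assay RF gap-fill classifier on ECFP6 fingerprints.

    Metrics (accuracy, precision, recall, F1, ROC-AUC) come from stratified
    5-fold cross-validation, reported per fold plus mean and sd; the final
    classifier is refit on the full sample. Deterministic given the
    training-set seed.
    """
    structures = list(ts.actives) + list(ts.inactives)
    y_all = np.array([1] * len(ts.actives) + [-1] * len(ts.inactives))
    X, kept = features.fingerprint_matrix(structures)
    y = y_all[kept]
    n_dropped = len(structures) - len(kept)
    if n_dropped:
        if (np.sum(y == 1) < ts.min_per_class) or (np.sum(y == -1) < ts.min_per_class):
            raise ValueError(
                f"assay {ts.aid}: unfingerprintable structures push a class "
                f"below the {ts.min_per_class} minimum"
            )

    metrics_df = None
    if cv_metrics:
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=ts.seed)
        rows = []
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            clf = RandomForestClassifier(n_estimators=n_trees, random_state=ts.seed, n_jobs=1)
            clf.fit(X[tr], y[tr])
            proba = clf.predict_proba(X[te])[:, list(clf.classes_).index(1)]
            pred = np.where(proba >= 0.5, 1, -1)
            m = _classification_metrics(y[te] == 1, pred == 1, proba)
            rows.append({"fold": fold, **m})
        metrics_df = pd.DataFrame(rows)
        agg = metrics_df.drop(columns="fold").agg(["mean", "std"])
        metrics_df = pd.concat(
            [metrics_df, agg.reset_index().rename(columns={"index": "fold"})],
            ignore_index=True,
        )

    final = RandomForestClassifier(n_estimators=n_trees, random_state=ts.seed, n_jobs=1)
    final.fit(X, y)
    return GapFillModel(ts.aid, final, metrics_df, ts.seed)


def fill_gaps(
    profile: Bioprofile,
    models: dict[str, GapFillModel] | Sequence[GapFillModel],
    selected: Sequence[str],
    structures: dict[str, str] | None = None,
    db: BioassayDatabase | None = None,
) -> tuple[Bioprofile, np.ndarray]:
    """Impute the zeros of the selected columns, producing a complete bioprofile.

    Observed entries (1/-1) are never changed. Each 0 becomes the model's
    hard class (1 if active-probability >= 0.5 else -1). Chemicals whose
    structure cannot be fingerprinted keep 0 and are flagged in the mask.

    Returns (complete profile restricted to ``selected`` columns, mask) where
    mask entries are "observed", "imputed" or "unpredictable".
    """
    if not isinstance(models, dict):
        models = {m.aid: m for m in models}
    missing = [a for a in selected if a not in models]
    if missing:
        raise ValueError(f"no model for assay(s): {', '.join(missing)}")
    if structures is None:
        if db is None:
            raise ValueError("provide chemical structures or a database")
        structures = {c: db.registry.structure_for(c) for c in profile.chemicals}

    sel_idx = [profile.assays.index(a) for a in selected]
    sub = profile.matrix[:, sel_idx].copy()
    mask = np.where(sub != 0, "observed", "imputed").astype(object)

    struct_list = [structures.get(c) for c in profile.chemicals]
    for k, aid in enumerate(selected):
        todo = np.where(sub[:, k] == 0)[0]
        if len(todo) == 0:
            continue
        classes, _, kept = models[aid].predict([struct_list[i] for i in todo])
        kept_rows = todo[kept]
        sub[kept_rows, k] = classes
        unpred = np.setdiff1d(todo, kept_rows)
        mask[unpred, k] = "unpredictable"

    return Bioprofile(profile.chemicals, list(selected), sub), mask


def imputation_probabilities(
    profile: Bioprofile,
    models: dict[str, GapFillModel],
    selected: Sequence[str],
    structures: dict[str, str],
) -> pd.DataFrame:
    """Active-probabilities for the imputed cells (side output of gap filling)."""
    rows = []
    struct_list = [structures.get(c) for c in profile.chemicals]
    for aid in selected:
        j = profile.assays.index(aid)
        todo = np.where(profile.matrix[:, j] == 0)[0]
        if len(todo) == 0:
            continue
        _, proba, kept = models[aid].predict([struct_list[i] for i in todo])
        for p, i in zip(proba, (todo[k] for k in kept)):
            rows.append({"cid": profile.chemicals[i], "aid": aid, "p_active": p})
    return pd.DataFrame(rows, columns=["cid", "aid", "p_active"])


def export_heatmap(profile: Bioprofile, path: str | Path) -> tuple[Path, Path]:
    """Write a clustered heatmap PNG plus a text file with the leaf orders.

    Rows and columns are ordered by average-linkage hierarchical clustering
    on Euclidean distance; degenerate profiles (a single row or column) are
    rendered without clustering.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list, linkage

    if profile.matrix.size == 0:
        raise ValueError("empty bioprofile")
    path = Path(path)
    order_path = path.with_suffix(".order.txt")

    mat = profile.matrix.astype(float)
    row_order = np.arange(mat.shape[0])
    col_order = np.arange(mat.shape[1])
    if mat.shape[0] > 1:
        row_order = leaves_list(linkage(mat, method="average", metric="euclidean"))
    if mat.shape[1] > 1:
        col_order = leaves_list(linkage(mat.T, method="average", metric="euclidean"))

    fig, ax = plt.subplots(figsize=(max(4, mat.shape[1] * 0.08), max(3, mat.shape[0] * 0.06)))
    ax.imshow(mat[np.ix_(row_order, col_order)], aspect="auto", cmap="coolwarm",
              vmin=-1, vmax=1, interpolation="nearest")
    ax.set_xlabel("assays (clustered)")
    ax.set_ylabel("chemicals (clustered)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)

    with open(order_path, "w") as fh:
        fh.write("# rows\n")
        for i in row_order:
            fh.write(profile.chemicals[i] + "\n")
        fh.write("# columns\n")
        for j in col_order:
            fh.write(profile.assays[j] + "\n")
    return path, order_path


def _resolve_chemical(key: str, db: BioassayDatabase) -> str | None:
    if key in db.registry:
        return key
    cid = db.registry.cid_for_inchikey(key)
    if cid is not None:
        return cid
    # SMILES input: standardize to InChIKey and match
    mol = features.mol_from_structure(key)
    if mol is not None:
        from rdkit import Chem

        return db.registry.cid_for_inchikey(Chem.MolToInchiKey(mol))
    return None
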