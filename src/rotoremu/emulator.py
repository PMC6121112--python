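"""Partitioned emulation: SVM class boundaries + per-region GP regressors.

Rotor biomarkers respond discontinuously to ionic parameters: the surfaces
jump where behavior changes (propagation failure, breakup, ...).  A single
smooth GP smears these jumps.  The partitioned emulator instead (i) trains
a multi-class SVM on the behavior labels, splitting parameter space into
behavior regions, and (ii) fits one GP per (class, biomarker) pair using
only that class's rows, so each GP sees a smooth surface.  Prediction
routes a query through the classifier to the GPs of its predicted class;
biomarkers undefined for that class come back null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .analysis import BehaviorClass
from .design import BIOMARKER_COLS, CampaignDataset, ParameterSpace
from .gp import GPModel, gp_predict, gp_train

__all__ = ["SVMClassifier", "PartitionedEmulator", "classifier_train",
           "partitioned_train", "partitioned_predict", "evaluate_emulator",
           "single_gp_train", "merge_chaotic_labels"]

log = logging.getLogger(__name__)

#: fewer non-null rows than this and a (class, biomarker) GP is undefined
MIN_GP_ROWS = 15

#: encoding of null biomarkers for the unpartitioned baseline GP
NULL_CODE = -1.0


def merge_chaotic_labels(labels) -> np.ndarray:
    """Fold transient + fibrillation into the single 'chaotic' label."""
    merge = {BehaviorClass.TRANSIENT.value: BehaviorClass.CHAOTIC.value,
             BehaviorClass.FIBRILLATION.value: BehaviorClass.CHAOTIC.value}
    return np.array([merge.get(l, l) for l in labels])


@dataclass
class SVMClassifier:
    """RBF-kernel SVM ensemble with CV-selected hyperparameters."""

    model: object
    coding: str                 # "one_vs_one" | "one_vs_rest"
    kernel_scale: float         # RBF gamma
    box_constraint: float       # C
    cv_accuracy: float
    cv_table: pd.DataFrame
    classes: tuple[str, ...]

    def predict(self, X) -> np.ndarray:
        return self.model.predict(np.asarray(X, float))


def _make_svc(coding: str, C: float, gamma: float, seed: int):
    svc = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
    if coding == "one_vs_rest":
        return OneVsRestClassifier(svc)
    return svc  # SVC is natively one-against-one


def classifier_train(X, labels, seed: int = 0,
                     C_grid=(0.1, 1.0, 10.0, 100.0, 1000.0),
                     gamma_grid=(0.1, 0.3, 1.0, 3.0, 10.0, 30.0),
                     codings=("one_vs_one", "one_vs_rest")) -> SVMClassifier:
    """Select (kernel scale, box constraint, coding design) by stratified
    5-fold CV accuracy and refit the winner on all data.

    Classes with fewer members than the fold count degrade the stratification
    gracefully (fold count shrinks, never below 2); the degradation is
    logged.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to train a classifier")
    n_splits = int(min(5, counts.min()))
    if n_splits < 5:
        log.warning("smallest class has %d members; using %d-fold CV",
                    counts.min(), max(2, n_splits))
    n_splits = max(2, n_splits)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    rows = []
    for coding in codings:
        for C in C_grid:
            for gamma in gamma_grid:
                est = _make_svc(coding, C, gamma, seed)
                scores = cross_val_score(est, X, labels, cv=cv,
                                         error_score=0.0)
                rows.append(dict(coding=coding, C=C, gamma=gamma,
                                 cv_accuracy=scores.mean()))
    table = pd.DataFrame(rows)
    best = table.iloc[int(table["cv_accuracy"].idxmax())]
    model = _make_svc(best["coding"], best["C"], best["gamma"], seed)
    model.fit(X, labels)
    return SVMClassifier(model=model, coding=str(best["coding"]),
                         kernel_scale=float(best["gamma"]),
                         box_constraint=float(best["C"]),
                         cv_accuracy=float(best["cv_accuracy"]),
                         cv_table=table, classes=tuple(classes))


@dataclass
class PartitionedEmulator:
    """Classifier + per-(class, biomarker) GPs over a parameter space."""

    space: ParameterSpace
    classifier: SVMClassifier
    gps: dict[tuple[str, str], GPModel]
    merge_chaotic: bool
    #: class -> biomarkers with a trained GP (the nullability table)
    defined: dict[str, tuple[str, ...]]
    train_X: np.ndarray = field(repr=False, default=None)
    train_biomarkers: pd.DataFrame = field(repr=False, default=None)

    def predict_classes(self, X) -> np.ndarray:
        return self.classifier.predict(self.space.normalize(X))

    def predict_biomarker(self, X, name: str,
                          classes: np.ndarray | None = None):
        """(values, variances) for one biomarker; NaN where null."""
        X = np.atleast_2d(np.asarray(X, float))
        U = self.space.normalize(X)
        if classes is None:
            classes = self.classifier.predict(U)
        vals = np.full(len(U), np.nan)
        var = np.full(len(U), np.nan)
        for cls in np.unique(classes):
            gp = self.gps.get((cls, name))
            if gp is None:
                continue
            sel = classes == cls
            m, v = gp_predict(gp, U[sel])
            vals[sel] = m
            var[sel] = v
        return vals, var

    def predict(self, X):
        """Full routing: (classes, biomarker DataFrame, variance DataFrame).

        Rows whose predicted class has no GP for a biomarker get NaN
        (null) in that column.
        """
        X = np.atleast_2d(np.asarray(X, float))
        classes = self.predict_classes(X)
        vals = {}
        var = {}
        for name in BIOMARKER_COLS:
            vals[name], var[name] = self.predict_biomarker(X, name,
                                                           classes=classes)
        return classes, pd.DataFrame(vals), pd.DataFrame(var)


def partitioned_train(train: CampaignDataset, merge_chaotic: bool = True,
                      seed: int = 0, min_rows: int = MIN_GP_ROWS,
                      restarts: int = 10) -> PartitionedEmulator:
    """Train the classifier and every defined (class, biomarker) GP."""
    ok = train.df["label"].notna()
    df = train.df[ok]
    X = df[list(train.space.names)].to_numpy(float)
    U = train.space.normalize(X)
    labels = df["label"].to_numpy()
    if merge_chaotic:
        labels = merge_chaotic_labels(labels)
    clf = classifier_train(U, labels, seed=seed)
    gps: dict[tuple[str, str], GPModel] = {}
    defined: dict[str, list[str]] = {}
    for cls in np.unique(labels):
        in_cls = labels == cls
        for name in BIOMARKER_COLS:
            y = pd.to_numeric(df[name], errors="coerce").to_numpy(float)
            sel = in_cls & np.isfinite(y)
            if sel.sum() < min_rows:
                continue
            gps[(cls, name)] = gp_train(U[sel], y[sel], restarts=restarts,
                                        seed=seed)
            defined.setdefault(cls, []).append(name)
    return PartitionedEmulator(
        space=train.space, classifier=clf, gps=gps,
        merge_chaotic=merge_chaotic,
        defined={k: tuple(v) for k, v in defined.items()},
        train_X=X, train_biomarkers=df[BIOMARKER_COLS].copy())


def save_emulator(em: PartitionedEmulator, path) -> None:
    """Persist a trained emulator (joblib archive)."""
    import joblib
    joblib.dump(em, path)


def load_emulator(path) -> PartitionedEmulator:
    import joblib
    return joblib.load(path)


def partitioned_predict(em: PartitionedEmulator, X_star):
    """Functional alias for :meth:`PartitionedEmulator.predict`."""
    return em.predict(X_star)


def single_gp_train(train: CampaignDataset, seed: int = 0,
                    restarts: int = 10) -> dict[str, GPModel]:
    """Unpartitioned baseline: one GP per biomarker over all rows, with
    null biomarkers encoded as -1."""
    ok = train.df["label"].notna()
    df = train.df[ok]
    U = train.space.normalize(df[list(train.space.names)].to_numpy(float))
    out = {}
    for name in BIOMARKER_COLS:
        y = pd.to_numeric(df[name], errors="coerce").to_numpy(float)
        y = np.where(np.isfinite(y), y, NULL_CODE)
        out[name] = gp_train(U, y, restarts=restarts, seed=seed)
    return out


def evaluate_emulator(em: PartitionedEmulator, test: CampaignDataset,
                      baseline: bool = False, seed: int = 0) -> dict:
    """Held-out metrics: class accuracy, per-biomarker RMSE on rows where
    both truth and prediction are non-null, null-agreement rates, and (with
    ``baseline``) the RMSE of the single unpartitioned GP and the ratio.
    """
    ok = test.df["label"].notna()
    df = test.df[ok]
    X = df[list(em.space.names)].to_numpy(float)
    true_labels = df["label"].to_numpy()
    if em.merge_chaotic:
        true_labels = merge_chaotic_labels(true_labels)
    classes, vals, _ = em.predict(X)
    metrics: dict = {
        "n_test": int(len(df)),
        "class_accuracy": float(np.mean(classes == true_labels)),
        "rmse": {}, "null_agreement": {},
    }
    for name in BIOMARKER_COLS:
        truth = pd.to_numeric(df[name], errors="coerce").to_numpy(float)
        pred = vals[name].to_numpy()
        both = np.isfinite(truth) & np.isfinite(pred)
        metrics["rmse"][name] = (
            float(np.sqrt(np.mean((truth[both] - pred[both]) ** 2)))
            if both.any() else None)
        metrics["null_agreement"][name] = float(
            np.mean(np.isfinite(truth) == np.isfinite(pred)))
    if baseline:
        train_ds = CampaignDataset(
            df=pd.concat([pd.DataFrame(em.train_X,
                                       columns=list(em.space.names)),
                          em.train_biomarkers.reset_index(drop=True)],
                         axis=1).assign(label="all"),
            space=em.space)
        base = single_gp_train(train_ds, seed=seed)
        U = em.space.normalize(X)
        metrics["baseline_rmse"] = {}
        metrics["rmse_ratio"] = {}
        for name in BIOMARKER_COLS:
            truth = pd.to_numeric(df[name], errors="coerce").to_numpy(float)
            truth_coded = np.where(np.isfinite(truth), truth, NULL_CODE)
            m, _ = gp_predict(base[name], U)
            rmse_b = float(np.sqrt(np.mean((truth_coded - m) ** 2)))
            metrics["baseline_rmse"][name] = rmse_b
            # ratio on a common footing: both models scored against the
            # null-coded truth, partitioned nulls coded the same way
            pred_coded = np.where(np.isfinite(vals[name].to_numpy()),
                                  vals[name].to_numpy(), NULL_CODE)
            rmse_p = float(np.sqrt(np.mean((truth_coded - pred_coded) ** 2)))
            metrics["rmse_ratio"][name] = (rmse_b / rmse_p
                                           if rmse_p > 0 else None)
    return metrics
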