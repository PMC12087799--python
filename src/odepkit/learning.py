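"""Feature filtering, sequential forward selection, LDA and LOPO evaluation.

The classification problem is three-class (CTRL / RIF / uRPL) at the
single-cell level, with generalization assessed by leave-one-patient-out
(LOPO) cross-validation: all cells of one patient are held out per round,
and filtering, selection, scaling and fitting see training patients only.

Features are first filtered by a multiclass AUC score: the maximum over
all class pairs and one-vs-rest splits of max(AUC, 1 - AUC), thresholded
per feature family (0.6 for the centroid-motion descriptors, 0.75 for the
local-displacement descriptors).  Survivors enter a plain sequential
forward selection wrapped around an LDA scored by nested-LOPO balanced
accuracy, stopping when the error reduction relative to the mean of the
previous five steps falls below 1e-6.  Patient-level calls are obtained by
majority voting over random cell groups (Monte-Carlo, sampling without
replacement).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "CohortDataset",
    "SelectionResult",
    "EvaluationReport",
    "auc_binary",
    "auc_multiclass",
    "filter_features",
    "sfs_select",
    "fit_lda",
    "LdaModel",
    "lopo_evaluate",
    "majority_vote_curve",
    "ks_compare",
    "balanced_accuracy",
]

logger = logging.getLogger(__name__)


@dataclass
class CohortDataset:
    """Per-cell feature vectors with patient / video / class annotations.

    ``feature_families`` maps each feature name to ``"centroid"`` or
    ``"local"`` so the family-specific filter thresholds can be applied.
    """

    features: pd.DataFrame  # index: cell_id
    labels: pd.Series
    patients: pd.Series
    videos: pd.Series
    feature_families: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.features.index
        for s in (self.labels, self.patients, self.videos):
            if not s.index.equals(idx):
                raise ValueError("annotation indices must match the feature table")
        by_patient = pd.DataFrame({"p": self.patients, "y": self.labels})
        if (by_patient.groupby("p")["y"].nunique() > 1).any():
            raise ValueError("every patient must have exactly one class")
        missing = set(self.features.columns) - set(self.feature_families)
        if missing:
            raise ValueError(f"features without family annotation: {sorted(missing)[:5]}")

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique())


@dataclass
class SelectionResult:
    """Filter + SFS outcome of one training set."""

    survivors: list[str]
    selected: list[str]
    error_trace: list[float]
    thresholds: dict[str, float]


@dataclass
class EvaluationReport:
    """LOPO predictions plus cell-, experiment- and selection-level summaries."""

    predictions: pd.DataFrame  # cell_id index: true, pred, patient, video, posteriors
    classes: list[str]
    confusion_cell: np.ndarray
    confusion_experiment: np.ndarray
    balanced_accuracy_cell: float
    balanced_accuracy_experiment: float
    selections: list[list[str]]
    train_checksums: list[str]
    canonical_scores: np.ndarray | None = None
    canonical_loadings: pd.DataFrame | None = None
    most_selected: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# AUC machinery


def balanced_accuracy(y_true, y_pred, classes=None) -> float:
    """Mean of per-class recalls over the classes present in ``y_true``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(y_true)
    recalls = [
        (y_pred[y_true == c] == c).mean() for c in classes if (y_true == c).any()
    ]
    return float(np.mean(recalls))


def auc_binary(values, labels, positive) -> float:
    """Rank-based two-class AUC with ties counted 0.5."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(values)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_multiclass(values, labels) -> float:
    """Multiclass discriminability: max over pairs and one-vs-rest of max(AUC, 1-AUC)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    best = 0.5
    for i, ci in enumerate(classes):
        for cj in classes[i + 1 :]:
            sel = (labels == ci) | (labels == cj)
            a = auc_binary(values[sel], labels[sel], positive=ci)
            best = max(best, a, 1.0 - a)
        a = auc_binary(values, (labels == ci), positive=True)
        best = max(best, a, 1.0 - a)
    return float(best)


def _auc_columns(X: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Rank-based AUC of every column of X for the boolean positive mask."""
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    ranks = rankdata(X, axis=0)
    return (ranks[pos].sum(axis=0) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def _aucm_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Columnwise multiclass AUC (same definition as :func:`auc_multiclass`)."""
    classes = np.unique(y)
    best = np.full(X.shape[1], 0.5)
    for i, ci in enumerate(classes):
        for cj in classes[i + 1 :]:
            sel = (y == ci) | (y == cj)
            a = _auc_columns(X[sel], (y[sel] == ci))
            best = np.maximum.reduce([best, a, 1.0 - a])
        a = _auc_columns(X, y == ci)
        best = np.maximum.reduce([best, a, 1.0 - a])
    return best


def filter_features(
    dataset: CohortDataset,
    rows: pd.Index | None = None,
    th_centroid: float = 0.6,
    th_local: float = 0.75,
) -> list[str]:
    """Features whose multiclass AUC exceeds their family threshold (strict).

    ``rows`` restricts the computation to the training cells; an empty
    survivor set is a warning, not an error.
    """
    X = dataset.features if rows is None else dataset.features.loc[rows]
    y = (dataset.labels if rows is None else dataset.labels.loc[rows]).to_numpy()
    th = {"centroid": th_centroid, "local": th_local}
    aucm = _aucm_columns(X.to_numpy(dtype=float), y)
    survivors = [
        name
        for name, a in zip(X.columns, aucm)
        if a > th[dataset.feature_families[name]]
    ]
    if not survivors:
        warnings.warn("feature filter left no survivors", stacklevel=2)
    return survivors


# ---------------------------------------------------------------------------
# LDA


@dataclass
class LdaModel:
    """A fitted LDA with its training z-score statistics and canonical axes."""

    features: list[str]
    classes: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    estimator: LinearDiscriminantAnalysis
    shrinkage_used: bool

    def _prepare(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.features].to_numpy(dtype=float) - self.mean) / self.std
        return Z

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self._prepare(X))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict_proba(self._prepare(X))

    def canonical_scores(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.transform(self._prepare(X))

    @property
    def loadings(self) -> pd.DataFrame:
        k = min(len(self.classes) - 1, len(self.features))
        return pd.DataFrame(
            self.estimator.scalings_[:, :k],
            index=self.features,
            columns=[f"canonical_{i + 1}" for i in range(k)],
        )


def fit_lda(X: pd.DataFrame, y: pd.Series, features: list[str]) -> LdaModel:
    """Fit a uniform-prior LDA on z-scored training features.

    When the class counts do not comfortably exceed the feature count (or
    the pooled covariance is singular) an eigen-solver with automatic
    shrinkage is used instead, and the substitution is logged.
    """
    Z = X[features].to_numpy(dtype=float)
    mean = Z.mean(axis=0)
    std = Z.std(axis=0)
    std[std == 0] = 1.0
    Z = (Z - mean) / std
    yv = y.to_numpy()
    classes, counts = np.unique(yv, return_counts=True)
    priors = np.full(classes.size, 1.0 / classes.size)
    shrink = counts.min() <= len(features)
    est = None
    if not shrink:
        est = LinearDiscriminantAnalysis(solver="svd", priors=priors)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Z, yv)
            if not np.all(np.isfinite(est.scalings_)):
                raise np.linalg.LinAlgError("non-finite scalings")
        except np.linalg.LinAlgError:
            est, shrink = None, True
    if est is None:
        logger.debug("LDA: using eigen solver with shrinkage")
        for shrinkage in ("auto", 0.5, 0.95):
            est = LinearDiscriminantAnalysis(
                solver="eigen", shrinkage=shrinkage, priors=priors
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(Z, yv)
                break
            except np.linalg.LinAlgError:
                continue
        else:  # last resort: heavy ridge on the within-class scatter
            est = LinearDiscriminantAnalysis(solver="eigen", priors=priors)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(
                    np.vstack([Z, Z + 1e-3, Z - 1e-3]), np.concatenate([yv, yv, yv])
                )
    return LdaModel(
        features=list(features),
        classes=classes,
        mean=mean,
        std=std,
        estimator=est,
        shrinkage_used=shrink,
    )


# ---------------------------------------------------------------------------
# SFS under nested LOPO


def _lda_predict_codes(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, n_classes: int
) -> np.ndarray:
    """Closed-form uniform-prior LDA prediction on z-scored training features.

    This is the fast inner scorer of the forward selection; a small ridge
    on the pooled covariance guards near-singular candidate sets.
    """
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    Zt = (Xtr - mu) / sd
    Ze = (Xte - mu) / sd
    means = np.stack([Zt[ytr == c].mean(axis=0) for c in range(n_classes)])
    resid = Zt - means[ytr]
    dof = max(Zt.shape[0] - n_classes, 1)
    S = resid.T @ resid / dof
    S[np.diag_indices_from(S)] += 1e-8
    try:
        W = np.linalg.solve(S, means.T)
    except np.linalg.LinAlgError:
        W = np.linalg.solve(S + 1e-3 * np.eye(S.shape[0]), means.T)
    scores = Ze @ W - 0.5 * np.sum(means.T * W, axis=0)
    return scores.argmax(axis=1)


def _balanced_accuracy_codes(y_true: np.ndarray, y_pred: np.ndarray, k: int) -> float:
    recalls = []
    for c in range(k):
        m = y_true == c
        if m.any():
            recalls.append((y_pred[m] == c).mean())
    return float(np.mean(recalls))


def _nested_lopo_error(
    X: np.ndarray, y: np.ndarray, folds: list[tuple[np.ndarray, np.ndarray]],
    idx: list[int], n_classes: int,
) -> float:
    """1 - balanced accuracy of LDA predictions over nested LOPO folds."""
    trues, preds = [], []
    cols = np.asarray(idx)
    for train, test in folds:
        ytr = y[train]
        if np.unique(ytr).size < n_classes:
            continue  # degenerate fold: leaving the patient out removed a class
        pr = _lda_predict_codes(X[np.ix_(train, cols)], ytr, X[np.ix_(test, cols)], n_classes)
        preds.append(pr)
        trues.append(y[test])
    if not trues:
        return 1.0
    return 1.0 - _balanced_accuracy_codes(
        np.concatenate(trues), np.concatenate(preds), n_classes
    )


def sfs_select(
    X: pd.DataFrame,
    y: pd.Series,
    patients: pd.Series,
    candidates: list[str],
    tol: float = 1e-6,
    window: int = 5,
    max_steps: int = 30,
) -> tuple[list[str], list[float]]:
    """Plain forward selection scored by nested-LOPO LDA error.

    At each step the candidate minimizing the error is added (ties broken
    by feature-name order); selection stops when the error reduction
    relative to the mean of the previous ``window`` step errors is below
    ``tol``, or when ``max_steps`` is reached.  Nested folds that lose a
    class when their patient is left out are skipped.
    """
    remaining = sorted(candidates)
    name_to_col = {n: i for i, n in enumerate(X.columns)}
    Xa = X.to_numpy(dtype=float)
    classes, y_codes = np.unique(y.to_numpy(), return_inverse=True)
    pat = patients.to_numpy()
    folds = []
    for p in pd.unique(pat):
        test = np.flatnonzero(pat == p)
        train = np.flatnonzero(pat != p)
        folds.append((train, test))

    selected: list[str] = []
    sel_idx: list[int] = []
    trace: list[float] = []
    while remaining and len(selected) < max_steps:
        best_name, best_err = None, np.inf
        for name in remaining:
            err = _nested_lopo_error(
                Xa, y_codes, folds, sel_idx + [name_to_col[name]], classes.size
            )
            if err < best_err:
                best_name, best_err = name, err
        if trace:
            ref = float(np.mean(trace[-window:]))
            if ref - best_err < tol:
                break
        selected.append(best_name)
        sel_idx.append(name_to_col[best_name])
        trace.append(best_err)
        remaining.remove(best_name)
    return selected, trace


# ---------------------------------------------------------------------------
# LOPO evaluation


def _confusion(y_true, y_pred, classes) -> np.ndarray:
    m = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        m[index[t], index[p]] += 1
    return m


def _checksum(X: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X.to_numpy(dtype=float)).tobytes())
    h.update(",".join(map(str, X.index)).encode())
    return h.hexdigest()


def lopo_evaluate(
    dataset: CohortDataset,
    th_centroid: float = 0.6,
    th_local: float = 0.75,
    tol: float = 1e-6,
    window: int = 5,
    max_steps: int = 30,
) -> EvaluationReport:
    """Leave-one-patient-out evaluation of the full filter + SFS + LDA chain.

    Per round, filtering and selection run on the training patients only;
    the held-out patient's cells are then predicted.  The report carries a
    checksum of each round's training matrix so the absence of leakage can
    be audited, plus a final all-data refit on the most-selected features
    for canonical scores/loadings.
    """
    classes = dataset.classes
    rows = []
    selections: list[list[str]] = []
    checksums: list[str] = []
    for patient in dataset.patients.unique():
        test_mask = dataset.patients == patient
        train_idx = dataset.features.index[~test_mask]
        test_idx = dataset.features.index[test_mask]
        y_train = dataset.labels.loc[train_idx]
        if y_train.nunique() < len(classes):
            logger.warning("round %s skipped: training set lost a class", patient)
            continue
        checksums.append(_checksum(dataset.features.loc[train_idx]))
        survivors = filter_features(
            dataset, rows=train_idx, th_centroid=th_centroid, th_local=th_local
        )
        if not survivors:
            survivors = list(dataset.features.columns)
        selected, _trace = sfs_select(
            dataset.features.loc[train_idx],
            y_train,
            dataset.patients.loc[train_idx],
            survivors,
            tol=tol,
            window=window,
            max_steps=max_steps,
        )
        if not selected:
            selected = survivors[:1]
        selections.append(selected)
        model = fit_lda(dataset.features.loc[train_idx], y_train, selected)
        pred = model.predict(dataset.features.loc[test_idx])
        proba = model.predict_proba(dataset.features.loc[test_idx])
        proba_cols = {f"p_{c}": proba[:, i] for i, c in enumerate(model.classes)}
        rows.append(
            pd.DataFrame(
                {
                    "patient": patient,
                    "video": dataset.videos.loc[test_idx],
                    "true": dataset.labels.loc[test_idx],
                    "pred": pred,
                    **proba_cols,
                },
                index=test_idx,
            )
        )
    predictions = pd.concat(rows)
    conf_cell = _confusion(predictions["true"], predictions["pred"], classes)
    ba_cell = balanced_accuracy(predictions["true"], predictions["pred"], classes)

    # experiment level: majority vote within each time-lapse video
    exp_true, exp_pred = [], []
    for _vid, grp in predictions.groupby("video"):
        exp_true.append(grp["true"].iloc[0])
        exp_pred.append(_plurality(grp, classes))
    conf_exp = _confusion(exp_true, exp_pred, classes)
    ba_exp = balanced_accuracy(np.array(exp_true), np.array(exp_pred), classes)

    counts = pd.Series([f for sel in selections for f in sel]).value_counts()
    most = counts[counts >= len(selections) / 2].index.tolist()
    if not most:
        most = counts.index[: max(1, min(3, counts.size))].tolist()
    final = fit_lda(dataset.features, dataset.labels, most)
    return EvaluationReport(
        predictions=predictions,
        classes=classes,
        confusion_cell=conf_cell,
        confusion_experiment=conf_exp,
        balanced_accuracy_cell=ba_cell,
        balanced_accuracy_experiment=ba_exp,
        selections=selections,
        train_checksums=checksums,
        canonical_scores=final.canonical_scores(dataset.features),
        canonical_loadings=final.loadings,
        most_selected=most,
    )


def _plurality(grp: pd.DataFrame, classes) -> str:
    """Plurality vote over predicted labels; ties by highest mean posterior."""
    counts = grp["pred"].value_counts()
    top = counts[counts == counts.max()].index.tolist()
    if len(top) == 1:
        return top[0]
    means = {c: grp[f"p_{c}"].mean() for c in top if f"p_{c}" in grp}
    if not means:
        return sorted(top)[0]
    return max(means, key=means.get)


def majority_vote_curve(
    report: EvaluationReport,
    max_cells: int,
    n_rep: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Patient-level accuracy of majority voting over random cell groups.

    For each group size g = 1..max_cells and each of ``n_rep`` Monte-Carlo
    repetitions, g cells are drawn per patient without replacement, the
    patient is assigned by plurality of the cells' predicted labels (ties
    broken by highest mean posterior) and the patient-level balanced
    accuracy is scored.  Returns columns ``n_cells``, ``mean``, ``sd``.
    """
    preds = report.predictions
    per_patient = {p: g for p, g in preds.groupby("patient")}
    for p, g in per_patient.items():
        if len(g) < max_cells:
            raise ValueError(
                f"max_cells={max_cells} exceeds the {len(g)} cells of patient {p}"
            )
    rng = np.random.default_rng(seed)
    out = []
    classes = report.classes
    for g_size in range(1, max_cells + 1):
        accs = np.empty(n_rep)
        for rep in range(n_rep):
            t, pr = [], []
            for _p, grp in per_patient.items():
                take = grp.iloc[rng.choice(len(grp), size=g_size, replace=False)]
                t.append(take["true"].iloc[0])
                pr.append(_plurality(take, classes))
            accs[rep] = balanced_accuracy(np.array(t), np.array(pr), classes)
        out.append({"n_cells": g_size, "mean": accs.mean(), "sd": accs.std()})
    return pd.DataFrame(out)


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov statistic and asymptotic p."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    res = ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
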