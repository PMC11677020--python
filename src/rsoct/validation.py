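"""Subject-wise validated linear-discriminant classification.

The study hierarchy makes record-wise cross-validation optimistic (records of
one biopsy in both partitions -> identity confounding), so all validation here
is leave-one-subject-out (LOSO): one outer fold per subject, and an inner LOSO
over the training subjects for hyperparameter tuning of the LDA (solver x
tolerance grid, AUC-ROC merit).  Standardization and PCA are always fitted on
training rows only and applied to the held-out subject with those frozen
parameters.

Pooling: the held-out predictions of all outer folds are pooled into a single
ROC curve per modality (one reported curve per modality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .datatypes import TUMOR

SOLVERS = ("svd", "lsqr", "eigen")
# Equal class priors everywhere: the fusion stage starts every sample at a
# prior of 0.5 and applies one fixed decision threshold across all folds,
# which presumes fold-to-fold comparable posterior calibration.  Empirical
# class priors would shift each fold's posterior level with its training
# class balance (and bias pooled null AUCs below 0.5).
EQUAL_PRIORS = (0.5, 0.5)
TOLERANCES = (1e-2, 1e-4, 1e-6, 1e-8, 1e-10, 1e-12, 1e-14)


# ---------------------------------------------------------------------------
# splitting


@dataclass
class FoldSplit:
    held_out_subject: str
    train_idx: np.ndarray
    test_idx: np.ndarray


def loso_split(subjects) -> list[FoldSplit]:
    """One fold per subject; no subject ever appears in both partitions."""
    subjects = np.asarray(subjects)
    unique = np.unique(subjects)
    if unique.size < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    logo = LeaveOneGroupOut()
    folds = []
    X_dummy = np.zeros((subjects.size, 1))
    for train, test in logo.split(X_dummy, groups=subjects):
        folds.append(FoldSplit(str(subjects[test[0]]), train, test))
    folds.sort(key=lambda f: f.held_out_subject)
    return folds


# ---------------------------------------------------------------------------
# standardization and PCA (training-parameter reuse is the whole point)


def fit_standardizer(train_features: np.ndarray) -> StandardScaler:
    """Z-score standardizer fitted on training rows.

    Constant features are centred and passed through with sd treated as 1
    (sklearn's convention); a warning notes how many such features there are.
    """
    X = np.asarray(train_features, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    scaler = StandardScaler().fit(X)
    n_const = int(np.sum(np.isclose(np.asarray(scaler.var_), 0.0)))
    if n_const:
        warnings.warn(f"{n_const} constant feature(s): sd treated as 1", stacklevel=2)
    return scaler


def apply_standardizer(features: np.ndarray, scaler: StandardScaler) -> np.ndarray:
    return scaler.transform(np.asarray(features, dtype=float))


def fit_pca(train_features: np.ndarray, n_components: int) -> PCA:
    """PCA basis of the leading principal directions, clamped to the data rank."""
    X = np.asarray(train_features, dtype=float)
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} clamped to {max_comp}", stacklevel=2
        )
        n_components = max_comp
    return PCA(n_components=n_components, svd_solver="full").fit(X)


def apply_pca(features: np.ndarray, basis: PCA) -> np.ndarray:
    return basis.transform(np.asarray(features, dtype=float))


class ClampedPCA(BaseEstimator, TransformerMixin):
    """PCA that clamps ``n_components`` to the training-data rank (with warning)."""

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.pca_ = fit_pca(np.asarray(X, dtype=float), self.n_components)
        return self

    def transform(self, X):
        return self.pca_.transform(np.asarray(X, dtype=float))


class BlockwisePCA(BaseEstimator, TransformerMixin):
    """Per-block standardize -> PCA -> concatenated scores.

    Used for the OCT composite feature vector: each texture descriptor block
    is standardized and reduced separately, and the per-block PCA scores are
    concatenated in fixed block order.
    """

    def __init__(self, block_slices: dict[str, slice] | None = None, n_components: int = 10):
        self.block_slices = block_slices
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if not self.block_slices:
            raise ValueError("block_slices must be provided")
        self.pipelines_ = {}
        for name, sl in self.block_slices.items():
            if sl.stop > X.shape[1]:
                raise ValueError(f"block {name!r} exceeds the feature matrix width")
            pipe = Pipeline(
                [("scale", StandardScaler()), ("pca", PCA(svd_solver="full"))]
            )
            block = X[:, sl]
            k = min(self.n_components, block.shape[0] - 1, block.shape[1])
            pipe.set_params(pca__n_components=k)
            pipe.fit(block)
            self.pipelines_[name] = pipe
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        parts = [pipe.transform(X[:, sl]) for (name, sl), pipe in
                 zip(self.block_slices.items(), self.pipelines_.values())]
        return np.hstack(parts)


def build_oct_composite(
    train_features: np.ndarray,
    block_slices: dict[str, slice],
    n_components: int = 10,
):
    """Fit the blockwise pipeline on training rows; returns (scores, transformer)."""
    for name in block_slices:
        if block_slices[name] is None:
            raise ValueError(f"missing block {name!r}")
    bw = BlockwisePCA(block_slices, n_components).fit(train_features)
    return bw.transform(train_features), bw


# ---------------------------------------------------------------------------
# ROC machinery


@dataclass
class ROCCurve:
    """Empirical ROC: decreasing thresholds with non-decreasing FPR/TPR."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @classmethod
    def from_scores(cls, labels, scores, positive_label=TUMOR) -> "ROCCurve":
        y = np.asarray(labels)
        s = np.asarray(scores, dtype=float)
        y_bin = (y == positive_label).astype(int)
        if y_bin.min() == y_bin.max():
            raise ValueError("both classes must be present to build a ROC curve")
        fpr, tpr, thr = _sk_roc_curve(y_bin, s)
        return cls(thr, fpr, tpr, float(np.trapezoid(tpr, fpr)))


def auc(roc: ROCCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(roc.tpr, roc.fpr))


@dataclass
class OperatingPoint:
    kind: str
    threshold: float
    fpr: float
    tpr: float


def youden_point(roc: ROCCurve) -> OperatingPoint:
    """Operating point maximizing TPR - FPR; ties resolved to the lowest FPR."""
    j = roc.tpr - roc.fpr
    best = np.max(j)
    candidates = np.flatnonzero(np.isclose(j, best))
    idx = candidates[np.argmin(roc.fpr[candidates])]
    return OperatingPoint("youden", float(roc.thresholds[idx]), float(roc.fpr[idx]), float(roc.tpr[idx]))


def point_at_fpr(roc: ROCCurve, q: float) -> OperatingPoint:
    """Confirmatory operating point: maximal TPR subject to FPR <= q.

    The last point (walking thresholds downward) whose achieved FPR still
    respects the cap; a confirmatory test must not exceed the target
    false-positive rate.
    """
    ok = np.flatnonzero(roc.fpr <= q)
    idx = int(ok[-1]) if ok.size else 0
    return OperatingPoint("fixed_fpr", float(roc.thresholds[idx]), float(roc.fpr[idx]), float(roc.tpr[idx]))


def point_at_tpr(roc: ROCCurve, q: float) -> OperatingPoint:
    """First point (walking thresholds downward) whose TPR meets or exceeds q."""
    idx = int(np.argmax(roc.tpr >= q))
    return OperatingPoint("fixed_tpr", float(roc.thresholds[idx]), float(roc.fpr[idx]), float(roc.tpr[idx]))


# ---------------------------------------------------------------------------
# confusion statistics


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def _round2(x: float | None) -> float | None:
    """Round half up to 2 decimals (0.825 -> 0.83), as printed tables do."""
    if x is None:
        return None
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Counts plus the five derived fractions; undefined ratios are None."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fn, self.fp, self.tn):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")
        if self.tp + self.fn + self.fp + self.tn == 0:
            raise ValueError("empty confusion matrix")

    @property
    def sensitivity(self):
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self):
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def precision(self):
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self):
        return _ratio(self.tn, self.tn + self.fn)

    @property
    def accuracy(self):
        return (self.tp + self.tn) / (self.tp + self.fn + self.fp + self.tn)

    def rounded(self) -> dict:
        """The five statistics at 2 decimals (half-up), as reported in tables."""
        return {
            "sensitivity": _round2(self.sensitivity),
            "specificity": _round2(self.specificity),
            "precision": _round2(self.precision),
            "npv": _round2(self.npv),
            "accuracy": _round2(self.accuracy),
        }

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
                **self.rounded()}


def confusion_stats(tp: int, fn: int, fp: int, tn: int) -> ConfusionMatrix:
    return ConfusionMatrix(tp, fn, fp, tn)


def confusion_at_threshold(labels, scores, threshold: float, positive_label=TUMOR) -> ConfusionMatrix:
    """Counts for the decision rule score >= threshold -> positive."""
    y = np.asarray(labels) == positive_label
    pred = np.asarray(scores, dtype=float) >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & y)),
        fn=int(np.sum(~pred & y)),
        fp=int(np.sum(pred & ~y)),
        tn=int(np.sum(~pred & ~y)),
    )


# ---------------------------------------------------------------------------
# tuned LDA


def _proba_positive(model, X, positive_label) -> np.ndarray:
    col = int(np.flatnonzero(model.classes_ == positive_label)[0])
    return model.predict_proba(X)[:, col]


class TunedLDA(BaseEstimator, ClassifierMixin):
    """LDA with nested leave-one-subject-out hyperparameter tuning.

    The grid is solver x tolerance (3 x 7 = 21 configurations by default).
    Each configuration is scored by the mean AUC over inner LOSO folds of the
    training subjects (inner folds whose held-out records contain one class
    are skipped); the first configuration in grid order achieving the best
    score is refitted on the full training set.  The class-probability output
    is the discriminant posterior of the positive class.
    """

    def __init__(self, solvers=SOLVERS, tolerances=TOLERANCES, positive_label=TUMOR):
        self.solvers = solvers
        self.tolerances = tolerances
        self.positive_label = positive_label

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("training data must contain both classes")
        if groups is None:
            raise ValueError("groups (subject ids) are required for nested tuning")
        groups = np.asarray(groups)
        if np.unique(groups).size < 2:
            raise ValueError("nested tuning needs at least 2 training subjects")

        scores = np.full((len(self.solvers), len(self.tolerances)), np.nan)
        folds = loso_split(groups)
        # sklearn's LDA uses tol only with the svd solver, so the 21-point
        # grid collapses to 9 distinct fits; evaluate each effective
        # configuration once and share the result across duplicates
        cache: dict = {}
        oof_cache: dict = {}
        for i, solver in enumerate(self.solvers):
            for j, tol in enumerate(self.tolerances):
                key = (solver, tol) if solver == "svd" else (solver, None)
                if key not in cache:
                    fold_aucs = []
                    oof = np.full(y.size, np.nan)
                    for f in folds:
                        ytr, yte = y[f.train_idx], y[f.test_idx]
                        if np.unique(ytr).size < 2:
                            continue
                        lda = LinearDiscriminantAnalysis(
                            solver=solver, tol=tol, priors=EQUAL_PRIORS
                        )
                        try:
                            lda.fit(X[f.train_idx], ytr)
                        except np.linalg.LinAlgError:
                            continue  # singular scatter: unscorable here
                        p = _proba_positive(lda, X[f.test_idx], self.positive_label)
                        oof[f.test_idx] = p
                        if np.unique(yte).size < 2:
                            continue  # one-class inner fold: no AUC defined
                        fold_aucs.append(
                            ROCCurve.from_scores(yte, p, self.positive_label).auc
                        )
                    cache[key] = float(np.mean(fold_aucs)) if fold_aucs else np.nan
                    oof_cache[key] = oof
                scores[i, j] = cache[key]

        self.inner_scores_ = scores
        if np.all(np.isnan(scores)):
            best_i, best_j = 0, 0  # no scorable inner fold; fall back to grid head
        else:
            best = np.nanmax(scores)
            # first in fixed grid order among ties (row-major: solver, then tol)
            flat = np.where(np.isclose(scores, best), 1, 0).ravel()
            best_i, best_j = np.unravel_index(int(np.argmax(flat)), scores.shape)
        self.best_solver_ = self.solvers[best_i]
        self.best_tolerance_ = self.tolerances[best_j]
        best_key = (
            (self.best_solver_, self.best_tolerance_)
            if self.best_solver_ == "svd"
            else (self.best_solver_, None)
        )
        # held-out inner predictions of the winning configuration: honest
        # training-set operating rates for downstream Bayes fusion
        self.inner_oof_proba_ = oof_cache[best_key]
        try:
            self.lda_ = LinearDiscriminantAnalysis(
                solver=self.best_solver_, tol=self.best_tolerance_, priors=EQUAL_PRIORS
            ).fit(X, y)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"refit with solver={self.best_solver_!r} failed on the full "
                "training set; falling back to 'svd'",
                stacklevel=2,
            )
            self.best_solver_ = "svd"
            self.lda_ = LinearDiscriminantAnalysis(
                solver="svd", tol=self.best_tolerance_, priors=EQUAL_PRIORS
            ).fit(X, y)
        self.classes_ = self.lda_.classes_
        return self

    def predict(self, X):
        return self.lda_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return self.lda_.predict_proba(np.asarray(X, dtype=float))

    def proba_positive(self, X) -> np.ndarray:
        return _proba_positive(self.lda_, np.asarray(X, dtype=float), self.positive_label)


def tune_lda(train_features, train_labels, train_subjects, **kwargs) -> TunedLDA:
    """Fit a :class:`TunedLDA` on a training set (thin functional wrapper)."""
    return TunedLDA(**kwargs).fit(train_features, train_labels, groups=train_subjects)


# ---------------------------------------------------------------------------
# modality validation


@dataclass
class FoldModel:
    """Everything fitted for one outer fold (training rows only)."""

    held_out_subject: str
    transform: object           # fitted feature transform (or None)
    model: TunedLDA
    train_proba: np.ndarray
    train_labels: np.ndarray
    train_roc: ROCCurve

    def predict_proba_positive(self, X) -> np.ndarray:
        Z = self.transform.transform(X) if self.transform is not None else X
        return self.model.proba_positive(Z)


class ModalityValidator(BaseEstimator):
    """Outer leave-one-subject-out validation of one modality.

    ``transform_factory`` builds the (unfitted) per-fold feature transform,
    e.g. ``lambda: Pipeline([("scale", StandardScaler()), ("pca", PCA(10))])``
    for Raman or a :class:`BlockwisePCA` factory for OCT.  After ``fit``:

    ``oof_proba_``  pooled held-out tumor probability per record,
    ``roc_``        single pooled ROC over all held-out predictions,
    ``auc_``        its area,
    ``folds_``      one :class:`FoldModel` per subject.
    """

    def __init__(self, transform_factory=None, solvers=SOLVERS, tolerances=TOLERANCES,
                 positive_label=TUMOR):
        self.transform_factory = transform_factory
        self.solvers = solvers
        self.tolerances = tolerances
        self.positive_label = positive_label

    def _fit_fold(self, X, y, groups, fold: FoldSplit) -> FoldModel:
        Xtr, ytr, gtr = X[fold.train_idx], y[fold.train_idx], groups[fold.train_idx]
        transform = None
        if self.transform_factory is not None:
            transform = self.transform_factory()  # fresh, unfitted per fold
            Ztr = transform.fit(Xtr, ytr).transform(Xtr)
        else:
            Ztr = Xtr
        model = TunedLDA(self.solvers, self.tolerances, self.positive_label)
        model.fit(Ztr, ytr, groups=gtr)
        train_p = model.proba_positive(Ztr)
        train_roc = ROCCurve.from_scores(ytr, train_p, self.positive_label)
        return FoldModel(fold.held_out_subject, transform, model, train_p, ytr, train_roc)

    def fit(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        groups = np.asarray(groups)
        folds = loso_split(groups)
        oof = np.full(y.size, np.nan)
        self.folds_ = []
        for fold in folds:
            fm = self._fit_fold(X, y, groups, fold)
            oof[fold.test_idx] = fm.predict_proba_positive(X[fold.test_idx])
            self.folds_.append(fm)
        self.oof_proba_ = oof
        self.roc_ = ROCCurve.from_scores(y, oof, self.positive_label)
        self.auc_ = self.roc_.auc
        return self


def loso_oof_proba(
    X,
    y,
    groups,
    transform_factory=None,
    solver: str = "svd",
    tol: float = 1e-4,
    positive_label=TUMOR,
) -> np.ndarray:
    """Out-of-fold positive-class probabilities under LOSO with a fixed config.

    Used to estimate honest (non-refit) operating rates on a training set:
    each subject's records are predicted by a model fitted on the remaining
    subjects.  Folds whose training part is single-class are skipped; their
    records get NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    oof = np.full(y.size, np.nan)
    for fold in loso_split(groups):
        ytr = y[fold.train_idx]
        if np.unique(ytr).size < 2:
            continue
        Xtr = X[fold.train_idx]
        if transform_factory is not None:
            tr = transform_factory()
            Ztr = tr.fit(Xtr, ytr).transform(Xtr)
            Zte = tr.transform(X[fold.test_idx])
        else:
            Ztr, Zte = Xtr, X[fold.test_idx]
        try:
            lda = LinearDiscriminantAnalysis(
                solver=solver, tol=tol, priors=EQUAL_PRIORS
            ).fit(Ztr, ytr)
        except np.linalg.LinAlgError:
            lda = LinearDiscriminantAnalysis(
                solver="svd", tol=tol, priors=EQUAL_PRIORS
            ).fit(Ztr, ytr)
        oof[fold.test_idx] = _proba_positive(lda, Zte, positive_label)
    return oof


def validate_modality(features, labels, subjects, transform_factory=None, **kwargs):
    """Thin wrapper: returns (per-record probabilities, pooled ROC, fold models)."""
    v = ModalityValidator(transform_factory=transform_factory, **kwargs)
    v.fit(np.asarray(features, dtype=float), np.asarray(labels), np.asarray(subjects))
    return v.oof_proba_, v.roc_, v.folds_


def leakage_probe(
    validator: ModalityValidator, X, y, groups, rng: np.random.Generator
) -> float:
    """Perturb each fold's held-out rows and refit: fitted parameters must not move.

    Returns the maximum absolute difference over all folds between the LDA
    coefficients fitted with original vs perturbed held-out records (0.0 means
    no information flows from test to train anywhere).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    worst = 0.0
    for fold, fm in zip(loso_split(groups), validator.folds_):
        Xp = X.copy()
        Xp[fold.test_idx] += rng.normal(size=Xp[fold.test_idx].shape) * (
            np.abs(Xp[fold.test_idx]) + 1.0
        )
        fm2 = validator._fit_fold(Xp, y, groups, fold)
        worst = max(worst, float(np.max(np.abs(fm2.model.lda_.coef_ - fm.model.lda_.coef_))))
    return worst
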