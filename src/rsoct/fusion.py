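"""Sequential Bayes fusion of per-record diagnostic decisions.

Every Raman or OCT record of a biopsy is treated as an independent binary
diagnostic test with a known operating point (TPR, FPR).  Starting from a
prior tumor probability of 0.5, the per-sample posterior is updated once per
record:

positive test:
    posterior = TPR * prior / (TPR * prior + FPR * (1 - prior))
negative test:
    posterior = 1 - (1-FPR)(1-prior) / ((1-FPR)(1-prior) + (1-TPR) * prior)

Both are Bayes' rule in odds form — the posterior odds are the prior odds
times the likelihood ratio TPR/FPR (positive) or (1-TPR)/(1-FPR) (negative) —
so the final posterior is invariant to the update order and equals the
closed-form odds product.

In the combined validation the per-fold operating points come from the fold's
*training* predictions thresholded at the fixed decision thresholds (0.56 for
Raman, 0.73 for OCT); rates are clipped to [eps, 1-eps] so a degenerate fold
cannot produce absorbing posteriors of exactly 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import HEALTHY, TUMOR
from .validation import (
    SOLVERS,
    TOLERANCES,
    ModalityValidator,
    OperatingPoint,
    ROCCurve,
    confusion_at_threshold,
    loso_oof_proba,
    loso_split,
    point_at_fpr,
    point_at_tpr,
    youden_point,
)

POSITIVE = "positive"
NEGATIVE = "negative"
MODES = ("RS", "OCT", "RS+OCT")

RS_THRESHOLD = 0.56
OCT_THRESHOLD = 0.73
RATE_EPS = 1e-3


@dataclass
class DiagnosticTestSpec:
    """One modality's binary test: fixed decision threshold plus (TPR, FPR)."""

    modality: str
    threshold: float
    tpr: float
    fpr: float

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    def clipped(self, eps: float = RATE_EPS) -> "DiagnosticTestSpec":
        return DiagnosticTestSpec(
            self.modality,
            self.threshold,
            float(np.clip(self.tpr, eps, 1.0 - eps)),
            float(np.clip(self.fpr, eps, 1.0 - eps)),
        )


@dataclass
class SamplePosterior:
    """Final tumor probability of one sample with its full update log."""

    sample_id: str | None
    subject_id: str | None
    label: str | None
    prior: float
    posterior: float
    update_log: list[tuple] = field(default_factory=list)
    # each log entry: (modality, threshold, decision, tpr, fpr, posterior)

    def replay(self) -> float:
        """Re-apply the logged updates from the prior; must equal posterior."""
        p = self.prior
        for _, _, decision, tpr, fpr, _ in self.update_log:
            p = update_posterior(p, tpr, fpr, decision)
        return p


def update_posterior(prior: float, tpr: float, fpr: float, decision: str) -> float:
    """One Bayes update of the tumor probability from a binary test result."""
    if not 0.0 <= prior <= 1.0:
        raise ValueError("prior must be in [0, 1]")
    if not (0.0 < tpr < 1.0 and 0.0 < fpr < 1.0):
        raise ValueError("tpr and fpr must lie strictly inside (0, 1); clip first")
    if decision == POSITIVE:
        num = tpr * prior
        return num / (num + fpr * (1.0 - prior))
    if decision == NEGATIVE:
        num = (1.0 - fpr) * (1.0 - prior)
        return 1.0 - num / (num + (1.0 - tpr) * prior)
    raise ValueError(f"decision must be {POSITIVE!r} or {NEGATIVE!r}")


def fuse_sample(
    record_decisions,
    prior: float = 0.5,
    sample_id: str | None = None,
    subject_id: str | None = None,
    label: str | None = None,
    eps: float = RATE_EPS,
) -> SamplePosterior:
    """Fold :func:`update_posterior` over an ordered list of test results.

    ``record_decisions`` is a list of ``(DiagnosticTestSpec, decision)``
    pairs; an empty list leaves the posterior at the prior.
    """
    p = prior
    log: list[tuple] = []
    for spec, decision in record_decisions:
        c = spec.clipped(eps)
        p = update_posterior(p, c.tpr, c.fpr, decision)
        log.append((c.modality, c.threshold, decision, c.tpr, c.fpr, p))
    return SamplePosterior(sample_id, subject_id, label, prior, p, log)


def posterior_odds_product(prior, tpr, fpr, n_pos, n_neg) -> float:
    """Closed-form posterior for homogeneous tests (oracle for fuse_sample)."""
    odds = prior / (1.0 - prior) * (tpr / fpr) ** n_pos * ((1 - tpr) / (1 - fpr)) ** n_neg
    return odds / (1.0 + odds)


# ---------------------------------------------------------------------------
# combined leave-one-subject-out validation


@dataclass
class ModalityData:
    """Per-record features and metadata for one modality."""

    X: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        self.samples = np.asarray(self.samples)
        n = self.X.shape[0]
        if not (self.labels.size == self.subjects.size == self.samples.size == n):
            raise ValueError("metadata arrays must match the feature matrix rows")


@dataclass
class CombinedValidationResult:
    posteriors: dict[str, list[SamplePosterior]]
    rocs: dict[str, ROCCurve]
    fold_info: list[dict]
    notes: list[str]

    def auc(self, mode: str) -> float:
        return self.rocs[mode].auc

    def posterior_table(self, mode: str):
        return [
            (sp.sample_id, sp.subject_id, sp.label, sp.prior, sp.posterior)
            for sp in self.posteriors[mode]
        ]


def _training_rates(labels, proba, threshold: float) -> tuple[float, float]:
    """TPR/FPR of the rule proba >= threshold on the fold's training records.

    NaN probabilities (records skipped by degenerate inner folds) are
    excluded from the rate estimate.
    """
    proba = np.asarray(proba, dtype=float)
    ok = np.isfinite(proba)
    y = (np.asarray(labels) == TUMOR)[ok]
    pred = proba[ok] >= threshold
    tpr = float(pred[y].mean()) if y.any() else 0.5
    fpr = float(pred[~y].mean()) if (~y).any() else 0.5
    return tpr, fpr


def run_combined_validation(
    rs: ModalityData | None,
    oct_: ModalityData | None,
    rs_transform_factory=None,
    oct_transform_factory=None,
    rs_threshold: float = RS_THRESHOLD,
    oct_threshold: float = OCT_THRESHOLD,
    eps: float = RATE_EPS,
    prior: float = 0.5,
    solvers=SOLVERS,
    tolerances=TOLERANCES,
    modes=MODES,
    rs_validator: ModalityValidator | None = None,
    oct_validator: ModalityValidator | None = None,
) -> CombinedValidationResult:
    """Leave-one-subject-out validation of the sequential Bayes fusion.

    Per outer fold (held-out subject): both modality models are trained on the
    remaining subjects exactly as in single-modality validation; the fold's
    operating point at the fixed threshold is read off the training
    predictions; each held-out sample starts at ``prior`` and is updated once
    per Raman record, then once per OCT record.  Every sample receives exactly
    one posterior per mode; single-modality modes skip the other modality's
    updates.  A sample with no records in the modalities a mode uses keeps the
    prior (logged in ``notes``).

    Already-fitted :class:`ModalityValidator` instances may be passed
    (``rs_validator`` / ``oct_validator``) to reuse their per-fold models
    instead of refitting; the fold partition must match.
    """
    if rs is None and oct_ is None:
        raise ValueError("at least one modality is required")
    modes = tuple(m for m in modes if _mode_feasible(m, rs, oct_))
    if not modes:
        raise ValueError("no feasible fusion mode for the supplied modalities")

    # sample -> (subject, label) consistency across modalities
    sample_subject: dict[str, str] = {}
    sample_label: dict[str, str] = {}
    for data in (rs, oct_):
        if data is None:
            continue
        for samp, subj, lab in zip(data.samples, data.subjects, data.labels):
            if samp in sample_subject and sample_subject[samp] != subj:
                raise ValueError(f"sample {samp!r} assigned to two subjects")
            if samp in sample_label and sample_label[samp] != lab:
                raise ValueError(f"sample {samp!r} carries two labels")
            sample_subject[samp] = str(subj)
            sample_label[samp] = str(lab)

    all_subjects = sorted(set(sample_subject.values()))
    if len(all_subjects) < 2:
        raise ValueError("need at least 2 subjects")

    posteriors: dict[str, list[SamplePosterior]] = {m: [] for m in modes}
    fold_info: list[dict] = []
    notes: list[str] = []

    for subject in all_subjects:
        info: dict = {"subject": subject}
        decisions_by_sample: dict[str, dict[str, list]] = {}

        for name, data, factory, threshold, prefit in (
            ("RS", rs, rs_transform_factory, rs_threshold, rs_validator),
            ("OCT", oct_, oct_transform_factory, oct_threshold, oct_validator),
        ):
            if data is None:
                continue
            test_mask = data.subjects == subject
            train_mask = ~test_mask
            ytr = data.labels[train_mask]
            if np.unique(ytr).size < 2 or np.unique(data.subjects[train_mask]).size < 2:
                notes.append(f"fold {subject}: {name} training set degenerate; skipped")
                continue
            fm = None
            if prefit is not None:
                for f in getattr(prefit, "folds_", []):
                    if f.held_out_subject == subject:
                        fm = f
                        break
            if fm is None:
                validator = ModalityValidator(
                    transform_factory=factory, solvers=solvers, tolerances=tolerances
                )
                fold = [
                    f for f in loso_split(data.subjects) if f.held_out_subject == subject
                ][0]
                fm = validator._fit_fold(data.X, data.labels, data.subjects, fold)
            # operating rates at the fixed threshold come from the *held-out*
            # inner-CV predictions of the training subjects: refit training
            # probabilities overstate tpr / understate fpr whenever the
            # discriminant separates its own training set
            tpr, fpr = _training_rates(
                fm.train_labels, fm.model.inner_oof_proba_, threshold
            )
            spec = DiagnosticTestSpec(name, threshold, tpr, fpr).clipped(eps)
            info[name] = {
                "solver": fm.model.best_solver_,
                "tolerance": fm.model.best_tolerance_,
                "tpr": spec.tpr,
                "fpr": spec.fpr,
            }
            if test_mask.any():
                proba = fm.predict_proba_positive(data.X[test_mask])
                for samp, p in zip(data.samples[test_mask], proba):
                    dec = POSITIVE if p >= threshold else NEGATIVE
                    decisions_by_sample.setdefault(str(samp), {"RS": [], "OCT": []})
                    decisions_by_sample[str(samp)][name].append((spec, dec))

        # samples of this subject that have no records at all in a modality
        subject_samples = sorted(
            s for s, subj in sample_subject.items() if subj == subject
        )
        for samp in subject_samples:
            decs = decisions_by_sample.get(samp, {"RS": [], "OCT": []})
            for mode in modes:
                seq: list = []
                if mode in ("RS", "RS+OCT"):
                    seq += decs["RS"]
                if mode in ("OCT", "RS+OCT"):
                    seq += decs["OCT"]
                if not seq:
                    notes.append(
                        f"sample {samp}: no records for mode {mode}; posterior stays {prior}"
                    )
                sp = fuse_sample(
                    seq,
                    prior=prior,
                    sample_id=samp,
                    subject_id=subject,
                    label=sample_label[samp],
                    eps=eps,
                )
                posteriors[mode].append(sp)
        fold_info.append(info)

    rocs = {
        m: ROCCurve.from_scores(
            [sp.label for sp in posteriors[m]], [sp.posterior for sp in posteriors[m]]
        )
        for m in modes
    }
    return CombinedValidationResult(posteriors, rocs, fold_info, notes)


def _mode_feasible(mode: str, rs, oct_) -> bool:
    if mode == "RS":
        return rs is not None
    if mode == "OCT":
        return oct_ is not None
    return rs is not None and oct_ is not None


# ---------------------------------------------------------------------------
# operating-point report


def operating_point_report(
    result: CombinedValidationResult,
    fixed_fpr: float = 0.1,
    fixed_tpr: float = 0.9,
) -> dict:
    """Sample-level ROC with three operating points per mode.

    For each mode: the Youden point, the confirmatory point (first point with
    FPR >= fixed_fpr, high specificity) and the screening point (first point
    with TPR >= fixed_tpr, high sensitivity), each with its threshold,
    confusion counts and the five confusion statistics at 2 decimals.
    """
    report: dict = {}
    for mode, roc in result.rocs.items():
        labels = np.array([sp.label for sp in result.posteriors[mode]])
        scores = np.array([sp.posterior for sp in result.posteriors[mode]])
        if np.unique(labels).size < 2:
            raise ValueError("operating points need both classes present")
        entry: dict = {"auc": roc.auc, "points": {}}
        for key, op in (
            ("youden", youden_point(roc)),
            ("c_test", point_at_fpr(roc, fixed_fpr)),
            ("s_test", point_at_tpr(roc, fixed_tpr)),
        ):
            cm = confusion_at_threshold(labels, scores, op.threshold)
            entry["points"][key] = {
                "threshold": op.threshold,
                "fpr": op.fpr,
                "tpr": op.tpr,
                "confusion": cm.as_dict(),
            }
        report[mode] = entry
    return report
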