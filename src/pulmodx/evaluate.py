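"""Evaluation protocols: LOSO, grouped k-fold, SNR robustness sweep,
ablation harness, metrics reports, Cohen's kappa and Wilson intervals.

All protocols enforce subject-level separation as a hard error: a clip
(or an augmented derivative) whose subject sits on the held-out side can
never enter training. Proportion confidence intervals use the Wilson
score; kappa intervals use the percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (cohen_kappa_score, confusion_matrix,
                             precision_recall_fscore_support, roc_auc_score)
from sklearn.model_selection import StratifiedGroupKFold
from statsmodels.stats.proportion import proportion_confint

from pulmodx.augment import audit_subject_separation
from pulmodx.diagnose import (DOCUMENTED_ONLY_VARIANTS, VARIANTS,
                              DiagnoserConfig, train_diagnoser)
from pulmodx.errors import LeakageError


@dataclass(frozen=True)
class FoldSpec:
    mode: str                      # loso | kfold | holdout
    held_out_subjects: frozenset
    fold_index: int = 0


@dataclass
class MetricsReport:
    accuracy: float
    per_class: pd.DataFrame        # precision/recall/f1/support rows per class
    confusion: pd.DataFrame
    ci95: tuple[float, float]
    per_class_auc: dict[str, float] = field(default_factory=dict)

    @property
    def macro_f1(self) -> float:
        return float(self.per_class.loc["macro avg", "f1-score"])

    @property
    def macro_auc(self) -> float:
        vals = [v for v in self.per_class_auc.values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")


def accuracy_ci(correct: int, total: int) -> tuple[float, float]:
    """95% Wilson score interval for a proportion, clipped to [0, 1]."""
    if total == 0:
        raise ValueError("total must be positive")
    if not 0 <= correct <= total:
        raise ValueError("need 0 <= correct <= total")
    lo, hi = proportion_confint(correct, total, alpha=0.05, method="wilson")
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


def compute_metrics(y_true, y_pred, classes, probs=None) -> MetricsReport:
    """Assemble the standard per-class report (Table-style: precision,
    recall, F1, support, macro/weighted averages) plus confusion matrix,
    Wilson CI for accuracy and optional one-vs-rest AUCs."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = list(classes)
    acc = float(np.mean(y_true == y_pred))
    p, r, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0)
    table = pd.DataFrame({"precision": p, "recall": r, "f1-score": f1,
                          "support": support}, index=classes)
    total = support.sum()
    macro = [p.mean(), r.mean(), f1.mean(), total]
    wts = support / max(total, 1)
    weighted = [(p * wts).sum(), (r * wts).sum(), (f1 * wts).sum(), total]
    table.loc["macro avg"] = macro
    table.loc["weighted avg"] = weighted
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    aucs = {}
    if probs is not None:
        probs = np.asarray(probs)
        for i, c in enumerate(classes):
            pos = (y_true == c).astype(int)
            aucs[c] = (roc_auc_score(pos, probs[:, i])
                       if 0 < pos.sum() < len(pos) else float("nan"))
    return MetricsReport(accuracy=acc, per_class=table, confusion=confusion,
                         ci95=accuracy_ci(int((y_true == y_pred).sum()), len(y_true)),
                         per_class_auc=aucs)


def loso_protocol(features, labels, subjects, train_fn, classes,
                  augment_fn=None, seed: int = 0):
    """Leave-one-subject-out: each fold retrains from scratch with the
    held-out subject fully excluded from training *and* augmentation.

    ``train_fn(features, labels, seed) -> predict_fn`` where
    ``predict_fn(features) -> predicted labels``; ``augment_fn`` (optional)
    maps (features, labels, subjects) of the training side to extra
    triples, each carrying the subject id of its source clip. Returns
    (per-fold reports, pooled MetricsReport).
    """
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    fold_reports = []
    pooled_true, pooled_pred = [], []
    for k, subject in enumerate(sorted(set(subjects))):
        test_mask = subjects == subject
        tr_idx = np.flatnonzero(~test_mask)
        te_idx = np.flatnonzero(test_mask)
        X_tr = [features[i] for i in tr_idx]
        y_tr = list(labels[tr_idx])
        s_tr = list(subjects[tr_idx])
        if augment_fn is not None:
            extra_X, extra_y, extra_s = augment_fn(X_tr, y_tr, s_tr)
            X_tr += list(extra_X)
            y_tr += list(extra_y)
            s_tr += list(extra_s)
        _audit_subjects(s_tr, {subject})
        predict_fn = train_fn(X_tr, y_tr, seed + k)
        y_hat = list(predict_fn([features[i] for i in te_idx]))
        pooled_true += list(labels[te_idx])
        pooled_pred += y_hat
        fold_reports.append(
            (FoldSpec("loso", frozenset([subject]), k),
             compute_metrics(labels[te_idx], y_hat, classes)))
    pooled = compute_metrics(pooled_true, pooled_pred, classes)
    return fold_reports, pooled


def _audit_subjects(train_subjects, held_out: set) -> None:
    bad = set(train_subjects) & held_out
    if bad:
        raise LeakageError(
            f"held-out subject(s) {sorted(bad)} present in training data")


def kfold_protocol(features, labels, subjects, train_fn, classes,
                   k: int = 10, seed: int = 0) -> MetricsReport:
    """Stratified, subject-grouped k-fold; pooled per-class report."""
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    n_groups = len(set(subjects))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_groups:
        raise ValueError(f"k={k} exceeds the {n_groups} subject groups")
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled_true, pooled_pred = [], []
    for fold, (tr_idx, te_idx) in enumerate(
            splitter.split(np.zeros(len(labels)), labels, groups=subjects)):
        _audit_subjects(subjects[tr_idx], set(subjects[te_idx]))
        predict_fn = train_fn([features[i] for i in tr_idx],
                              list(labels[tr_idx]), seed + fold)
        pooled_pred += list(predict_fn([features[i] for i in te_idx]))
        pooled_true += list(labels[te_idx])
    return compute_metrics(pooled_true, pooled_pred, classes)


def sensitivity_specificity(y_true, y_pred, classes) -> tuple[float, float]:
    """Macro-averaged one-vs-rest sensitivity and specificity."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    sens, spec = [], []
    for c in classes:
        tp = np.sum((y_true == c) & (y_pred == c))
        fn = np.sum((y_true == c) & (y_pred != c))
        tn = np.sum((y_true != c) & (y_pred != c))
        fp = np.sum((y_true != c) & (y_pred == c))
        if tp + fn > 0:
            sens.append(tp / (tp + fn))
        if tn + fp > 0:
            spec.append(tn / (tn + fp))
    return float(np.mean(sens)), float(np.mean(spec))


def noise_sweep(trained, clips, snr_grid=(5, 10, 15, 20), seed: int = 0,
                n_mfcc: int | None = None) -> pd.DataFrame:
    """Corrupt clean test clips at each SNR, re-featurize, re-classify.

    Returns a table with columns (snr_db, accuracy, sensitivity,
    specificity)."""
    from pulmodx.augment import inject_noise
    from pulmodx.diagnose import predict
    from pulmodx.features import extract_mfcc, normalize_length

    n_mfcc = n_mfcc or trained.config.n_mfcc
    rng = np.random.default_rng(seed)
    rows = []
    classes = [c for c in trained.codec.classes]
    for snr in snr_grid:
        y_true, y_pred = [], []
        for clip in clips:
            noisy = inject_noise(clip, snr, seed=int(rng.integers(2**31 - 1)))
            m = normalize_length(extract_mfcc(noisy, n_mfcc=n_mfcc),
                                 trained.config.frames)
            label, _ = predict(trained, m)
            y_true.append(clip.label)
            y_pred.append(label)
        sens, spec = sensitivity_specificity(y_true, y_pred, classes)
        rows.append({"snr_db": snr,
                     "accuracy": float(np.mean(np.array(y_true) == np.array(y_pred))),
                     "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)


def cohens_kappa(a, b, ci_bootstrap: int = 0, seed: int = 0):
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Returns (kappa, (lo, hi)) where the interval is a percentile bootstrap
    over ``ci_bootstrap`` resamples (NaN bounds when 0). Degenerate
    marginals with p_e = 1 yield NaN, reported as such.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError("label sequences differ in length")
    labels = sorted(set(a) | set(b))
    pa = np.array([np.mean(a == c) for c in labels])
    pb = np.array([np.mean(b == c) for c in labels])
    p_e = float(pa @ pb)
    if np.isclose(p_e, 1.0):
        return float("nan"), (float("nan"), float("nan"))
    kappa = float(cohen_kappa_score(a, b, labels=labels))
    if ci_bootstrap <= 0:
        return kappa, (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(ci_bootstrap):
        idx = rng.integers(0, len(a), size=len(a))
        aa, bb = a[idx], b[idx]
        paa = np.array([np.mean(aa == c) for c in labels])
        pbb = np.array([np.mean(bb == c) for c in labels])
        if np.isclose(float(paa @ pbb), 1.0):
            continue
        stats.append(cohen_kappa_score(aa, bb, labels=labels))
    lo, hi = np.percentile(stats, [2.5, 97.5]) if stats else (np.nan, np.nan)
    return kappa, (float(lo), float(hi))


def ablation_harness(train_features, train_labels, test_features, test_labels,
                     config: DiagnoserConfig, variants=VARIANTS,
                     seeds=(0,)) -> pd.DataFrame:
    """Train each architecture variant over the given seeds and report
    mean held-out accuracy plus the delta versus the full model."""
    from pulmodx.diagnose import predict

    for v in variants:
        if v in DOCUMENTED_ONLY_VARIANTS:
            raise NotImplementedError(
                f"variant {v!r} is registry-documented but not implemented")
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}")
    rows = {}
    for variant in variants:
        accs = []
        for seed in seeds:
            trained = train_diagnoser(train_features, train_labels, config,
                                      seed=seed, variant=variant)
            correct = sum(predict(trained, m)[0] == lb
                          for m, lb in zip(test_features, test_labels))
            accs.append(correct / len(test_labels))
        rows[variant] = float(np.mean(accs))
    out = pd.DataFrame({"accuracy": rows})
    full_acc = out.loc["full", "accuracy"] if "full" in out.index else np.nan
    out["delta_vs_full"] = out["accuracy"] - full_acc
    return out
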