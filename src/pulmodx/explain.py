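"""Model introspection: attention traces for the diagnoser and
feature attribution for the prescription recommender.

Attention traces expose the softmax weights the diagnoser places on
pooled time steps (length = frames // 2). Attribution defaults to
permutation importance (assumption-light, global); an exact Shapley-value
attribution (enumeration over feature coalitions, so practical for the
cohort's small feature count) provides local, additive explanations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

from pulmodx.diagnose import TrainedDiagnoser
from pulmodx.features import MFCCMatrix
from pulmodx.prescribe import (CATEGORICAL_FEATURES, NUMERIC_FEATURES,
                               PrescriptionRecommender)

FEATURES = list(NUMERIC_FEATURES + CATEGORICAL_FEATURES)


@dataclass
class AttentionTrace:
    alpha: np.ndarray
    clip_id: str
    predicted: str

    def __post_init__(self):
        if np.any(self.alpha < 0) or not np.isclose(self.alpha.sum(), 1.0, atol=1e-6):
            raise ValueError("attention trace must be a distribution")

    def top_decile_steps(self) -> np.ndarray:
        """Indices of the pooled steps carrying the top 10% of alpha mass."""
        k = max(len(self.alpha) // 10, 1)
        return np.sort(np.argsort(self.alpha)[-k:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"step": np.arange(len(self.alpha)),
                             "alpha": self.alpha})


def attention_trace(trained: TrainedDiagnoser, m: MFCCMatrix | np.ndarray,
                    clip_id: str = "") -> AttentionTrace:
    """Extract the attention distribution of one forward pass."""
    from pulmodx.diagnose import predict

    if trained.best_epoch == 0 and len(trained.history) == 0:
        raise ValueError("attention_trace requires a trained model")
    v = m.values if isinstance(m, MFCCMatrix) else np.asarray(m)
    label, _ = predict(trained, v)
    alpha = trained.attention_alpha(v.T[None])[0]
    return AttentionTrace(alpha=alpha, clip_id=clip_id, predicted=label)


def save_trace_heatmap(trace: AttentionTrace, m: MFCCMatrix, path) -> None:
    """Write a PNG with the MFCC matrix and the attention profile."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(8, 5), sharex=False,
                                   height_ratios=[3, 1])
    ax0.imshow(m.values, aspect="auto", origin="lower", cmap="magma")
    ax0.set_ylabel("MFCC coefficient")
    ax1.plot(trace.alpha)
    ax1.set_xlabel("pooled time step")
    ax1.set_ylabel("attention")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


@dataclass
class AttributionReport:
    global_importance: pd.DataFrame   # mean |attribution| per feature, ranked
    local: pd.DataFrame | None = None  # per-case signed attributions

    @property
    def ranking(self) -> list[str]:
        return list(self.global_importance.index)


def permutation_attribution(model: PrescriptionRecommender,
                            eval_df: pd.DataFrame, target: str = "drug",
                            n_repeats: int = 5, seed: int = 0,
                            ) -> AttributionReport:
    """Global permutation importance for one output (accuracy drop when a
    feature column is shuffled), averaged over repeats."""
    rng = np.random.default_rng(seed)
    base_pred = model.predict(eval_df)[target].to_numpy()
    y = eval_df[target].to_numpy()
    base_acc = np.mean(base_pred == y)
    rows = {}
    for feat in FEATURES:
        drops = []
        for _ in range(n_repeats):
            shuffled = eval_df.copy()
            shuffled[feat] = rng.permutation(shuffled[feat].to_numpy())
            acc = np.mean(model.predict(shuffled)[target].to_numpy() == y)
            drops.append(base_acc - acc)
        rows[feat] = float(np.mean(drops))
    table = pd.DataFrame({"importance": rows}).sort_values(
        "importance", ascending=False)
    return AttributionReport(global_importance=table)


def _coalition_value(predict_fn, x_row: pd.Series, background: pd.DataFrame,
                     subset: tuple, features: list[str]) -> float:
    """Expected model output with features in ``subset`` fixed to the case's
    values and the rest drawn from the background sample."""
    hybrid = background.copy()
    for f in subset:
        hybrid[f] = x_row[f]
    return float(np.mean(predict_fn(hybrid)))


def shapley_attribution(predict_fn, x_row: pd.Series,
                        background: pd.DataFrame,
                        features: list[str] | None = None) -> pd.Series:
    """Exact Shapley values by coalition enumeration.

    ``predict_fn`` maps a feature frame to a scalar model output per row
    (e.g. the probability of the recommended drug). Additivity holds:
    the attributions sum to f(x) - E[f(background)]. Exponential in the
    number of features — intended for the cohort's ~9 features or toys.
    """
    if len(background) == 0:
        raise ValueError("non-empty background required")
    features = list(features or FEATURES)
    n = len(features)
    values = {(): _coalition_value(predict_fn, x_row, background, (), features)}
    for r in range(1, n + 1):
        for subset in combinations(features, r):
            values[tuple(sorted(subset))] = _coalition_value(
                predict_fn, x_row, background, subset, features)
    phi = {}
    for f in features:
        others = [g for g in features if g != f]
        total = 0.0
        for r in range(len(others) + 1):
            w = factorial(r) * factorial(n - r - 1) / factorial(n)
            for subset in combinations(others, r):
                s = tuple(sorted(subset))
                s_with = tuple(sorted(subset + (f,)))
                total += w * (values[s_with] - values[s])
        phi[f] = total
    return pd.Series(phi)


def feature_attribution(model: PrescriptionRecommender,
                        background: pd.DataFrame, eval_rows: pd.DataFrame,
                        method: str = "permutation", seed: int = 0,
                        target: str = "drug") -> AttributionReport:
    """Attribution report for the recommender's ``target`` output.

    ``method='permutation'`` gives the global ranking; ``method='kernel'``
    computes per-case additive (Shapley) attributions of the probability
    assigned to each case's recommended drug, plus the mean-|value| global
    ranking.
    """
    missing = [f for f in FEATURES if f not in eval_rows.columns]
    if missing:
        raise ValueError(f"eval rows missing features: {missing}")
    if method == "permutation":
        return permutation_attribution(model, eval_rows, target=target,
                                       seed=seed)
    if method != "kernel":
        raise ValueError(f"unknown attribution method {method!r}")
    classes = list(model.classes_[target])
    local_rows = []
    for _, row in eval_rows.iterrows():
        pred = model.predict(row.to_frame().T)[target].iloc[0]
        ci = classes.index(pred)

        def prob_of_pred(frame: pd.DataFrame, _ci=ci) -> np.ndarray:
            return model.predict_proba(frame)[target][:, _ci]

        local_rows.append(shapley_attribution(prob_of_pred, row, background))
    local = pd.DataFrame(local_rows, index=eval_rows.index)
    table = local.abs().mean().to_frame("importance").sort_values(
        "importance", ascending=False)
    return AttributionReport(global_importance=table, local=local)
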