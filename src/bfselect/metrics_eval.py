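"""Evaluation: feature-selection score, ranking, sparsity, classification
metrics, Pareto filtering, the incremental filter protocol, and the
statistical comparison tests.

The feature-selection score (the informative-features weight ratio) is
the share of input-layer L1 weight mass carried by the ground-truth
informative columns. Feature importance is the L1 norm of each input
neuron's outgoing group. The sparsity score S counts connection weights
with magnitude below 1e−5 (biases excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

from bfselect.mlp_core import Dataset, NetworkParams, extract_groups, predict

__all__ = [
    "EvaluationReport",
    "ZERO_THRESHOLD",
    "fs_score",
    "feature_ranking",
    "sparsity_score",
    "classification_metrics",
    "pareto_filter",
    "incremental_filter_eval",
    "method_comparison",
    "evaluate_population",
    "default_filter_classifiers",
]

ZERO_THRESHOLD = 1e-5


def fs_score(params: NetworkParams, important_idx) -> float:
    """Fraction of total input-layer L1 weight mass on the informative
    features: Σ_{g informative} ‖g‖₁ / Σ_{g input} ‖g‖₁."""
    idx = np.asarray(list(important_idx), dtype=int)
    if idx.size == 0:
        raise ValueError("important_idx is empty")
    W1 = params.weights[0]
    if idx.min() < 0 or idx.max() >= W1.shape[0]:
        raise ValueError("important_idx out of range")
    mass = np.abs(W1).sum(axis=1)
    denom = float(mass.sum())
    if denom == 0.0:
        warnings.warn("input layer fully zero; feature-selection score undefined, returning 0")
        return 0.0
    return float(mass[idx].sum() / denom)


def feature_ranking(params: NetworkParams) -> list[tuple[int, float]]:
    """Features ordered by importance score(g) = ‖g‖₁, descending; ties
    broken by ascending feature index."""
    mass = np.abs(params.weights[0]).sum(axis=1)
    order = np.lexsort((np.arange(mass.size), -mass))
    return [(int(i), float(mass[i])) for i in order]


def sparsity_score(params: NetworkParams) -> float:
    """Fraction of connection weights with |w| < 1e−5 (biases excluded)."""
    null = sum(int((np.abs(w) < ZERO_THRESHOLD).sum()) for w in params.weights)
    return null / params.n_weights


def classification_metrics(y_true, y_pred, n_classes: int | None = None):
    """(accuracy, precision, recall, F1) with class-wise scores averaged
    by class support (so on balanced data with a balanced confusion
    matrix all four coincide)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    labels = list(range(n_classes)) if n_classes else None
    acc = accuracy_score(y_true, y_pred)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="weighted", zero_division=0
    )
    return float(acc), float(prec), float(rec), float(f1)


def pareto_filter(points) -> list[tuple[float, float]]:
    """Nondominated subset for minimization in both coordinates; all
    duplicates of a nondominated point are kept."""
    pts = [tuple(map(float, p)) for p in points]
    out = []
    for p in pts:
        dominated = any(
            (q[0] <= p[0] and q[1] <= p[1]) and (q[0] < p[0] or q[1] < p[1]) for q in pts
        )
        if not dominated:
            out.append(p)
    return out


def default_filter_classifiers(seed: int = 0) -> dict:
    """The standard filter-protocol trio: random forest, gradient
    boosting, max-margin classifier, each with a fixed seed."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.svm import SVC
    from xgboost import XGBClassifier

    return {
        "rf": RandomForestClassifier(n_estimators=100, random_state=seed),
        "xgb": XGBClassifier(
            n_estimators=100, random_state=seed, verbosity=0, use_label_encoder=False
        ),
        "svc": SVC(random_state=seed),
    }


def incremental_filter_eval(ranking, data: Dataset, classifiers: dict, steps) -> pd.DataFrame:
    """Filter-method evaluation: for each N in ``steps`` train every
    classifier on the top-N ranked features and record the mean test
    accuracy. A rapidly rising curve means the top of the ranking holds
    the informative features."""
    steps = [int(n) for n in steps]
    if any(n <= 0 for n in steps) or any(b <= a for a, b in zip(steps, steps[1:])):
        raise ValueError("steps must be strictly increasing positive integers")
    if steps[-1] > data.n_features:
        raise ValueError("step exceeds the number of features")
    order = [i for i, _ in ranking]
    y_train = data.labels_train
    y_test = data.labels_test
    rows = []
    for n in steps:
        cols = order[:n]
        accs = {}
        for name, clf in classifiers.items():
            try:
                clf.fit(data.X_train[:, cols], y_train)
                accs[name] = accuracy_score(y_test, clf.predict(data.X_test[:, cols]))
            except Exception as exc:  # surface which N broke the classifier
                raise RuntimeError(f"classifier {name!r} failed at N={n}") from exc
        rows.append({"n_features": n, **accs, "mean_accuracy": float(np.mean(list(accs.values())))})
    return pd.DataFrame(rows)


def method_comparison(per_run_scores_by_method: dict, control: str) -> pd.DataFrame:
    """Statistical validation: per competitor, a two-sided Wilcoxon
    signed-rank test against the control method (exact distribution for
    n ≤ 25), plus a Shapiro–Wilk normality p-value per method.

    Pairs with all-zero differences are reported as non-comparable
    (p-value NaN) rather than forced through the test.
    """
    if control not in per_run_scores_by_method:
        raise KeyError(f"control method {control!r} missing")
    scores = {m: np.asarray(v, dtype=float) for m, v in per_run_scores_by_method.items()}
    n = len(scores[control])
    if n < 5 or any(len(v) != n for v in scores.values()):
        raise ValueError("need >= 5 runs per method with equal counts")
    rows = []
    for method, vals in scores.items():
        shapiro_p = float(stats.shapiro(vals).pvalue) if np.ptp(vals) > 0 else np.nan
        if method == control:
            rows.append({"method": method, "wilcoxon_p": np.nan, "shapiro_p": shapiro_p,
                         "comparable": False})
            continue
        diff = scores[control] - vals
        if np.all(diff == 0):
            rows.append({"method": method, "wilcoxon_p": np.nan, "shapiro_p": shapiro_p,
                         "comparable": False})
            continue
        mode = "exact" if np.count_nonzero(diff) <= 25 else "auto"
        res = stats.wilcoxon(scores[control], vals, alternative="two-sided",
                             zero_method="wilcox", mode=mode)
        rows.append({"method": method, "wilcoxon_p": float(res.pvalue),
                     "shapiro_p": shapiro_p, "comparable": True})
    return pd.DataFrame(rows).set_index("method")


@dataclass
class EvaluationReport:
    """Per-network metrics for one trained population plus the per-run
    bests the reporting convention uses: classification metrics from the
    highest-accuracy network; the feature-selection and sparsity scores
    each from their own maximizing network."""

    table: pd.DataFrame
    best: dict = field(default_factory=dict)

    def to_json(self) -> str:
        import json

        return json.dumps({"best": self.best, "networks": self.table.to_dict(orient="records")})


def evaluate_population(
    nets: list[NetworkParams], data: Dataset, records=None
) -> EvaluationReport:
    """Score every network of a trained population on the test split."""
    from bfselect.metrics_eval import fs_score as _fs  # local alias for clarity

    y_test = data.labels_test
    rows = []
    for i, params in enumerate(nets):
        acc, prec, rec, f1 = classification_metrics(
            y_test, predict(params, data.X_test), data.n_classes
        )
        row = {
            "network": i,
            "accuracy": acc,
            "precision": prec,
            "recall": rec,
            "f1": f1,
            "sparsity": sparsity_score(params),
        }
        if data.important_idx is not None and len(data.important_idx):
            row["fs"] = _fs(params, data.important_idx)
        if records is not None:
            rec_i = records[i]
            row["region"] = rec_i.region
            row["f1_obj"], row["f2_obj"] = rec_i.f_raw[-1]
        rows.append(row)
    table = pd.DataFrame(rows)
    ibest = int(table["accuracy"].idxmax())
    best = {
        "accuracy": float(table.loc[ibest, "accuracy"]),
        "precision": float(table.loc[ibest, "precision"]),
        "recall": float(table.loc[ibest, "recall"]),
        "f1": float(table.loc[ibest, "f1"]),
        "sparsity": float(table["sparsity"].max()),
        "best_accuracy_network": ibest,
    }
    if "fs" in table:
        best["fs"] = float(table["fs"].max())
    return EvaluationReport(table=table, best=best)
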