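"""Classification of readmission status from session feature vectors.

Covers random-forest (Gini) feature selection, the three conventional
classifiers (KNN, MLP, XGBoost) behind a common thresholded interface,
leave-one-subject-out cross-validation with a leakage assertion, the five
confusion-matrix metrics, ROC/AUC, and pairwise group comparisons.

Class imbalance is handled by shifting the decision threshold rather than
resampling.  The threshold convention is configurable: with
``threshold_on='negative'`` (default) the cutoff applies to the
non-readmitted class probability, i.e. a session is called positive when
p(readmit) >= 1 - threshold; this is the sensitivity-maximizing reading of
a 0.7 cutoff.  ``threshold_on='positive'`` applies the cutoff to p(readmit)
directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import InvalidConfigError
from .features import FEATURE_NAMES

log = logging.getLogger(__name__)

POSITIVE_LABEL = "readmitted"
DEFAULT_THRESHOLD = 0.7

DEFAULT_HYPERPARAMS = {
    "knn": {"n_neighbors": 5, "weights": "distance"},
    "mlp": {"hidden_layer_sizes": (16,), "max_iter": 2000, "early_stopping": False,
            "alpha": 1e-3},
    # exact splits: histogram binning places cuts at bin edges, which is
    # badly behaved on cohorts of tens of sessions
    "xgboost": {"n_estimators": 200, "max_depth": 3, "learning_rate": 0.1,
                "tree_method": "exact"},
}


@dataclass
class EvalResult:
    predictions: pd.DataFrame  # subject_id, session_id, y_true, proba, y_pred, fold
    metrics: dict
    roc: pd.DataFrame  # fpr, tpr, threshold
    provenance: dict = field(default_factory=dict)


class ReadmissionClassifier(BaseEstimator, ClassifierMixin):
    """Thresholded binary classifier over session features.

    Parameters
    ----------
    kind : 'knn' | 'mlp' | 'xgboost'
    decision_threshold : probability cutoff in (0, 1)
    threshold_on : 'negative' applies the cutoff to the non-readmitted class
        probability (positive iff p(readmit) >= 1 - cutoff); 'positive'
        applies it to p(readmit) directly.
    seed : RNG seed for the underlying model
    hyperparams : overrides of the per-kind defaults

    Features are z-scored inside the estimator using training data only, so
    the classifier can be dropped into sklearn model selection without
    leakage.
    """

    def __init__(
        self,
        kind: str = "knn",
        decision_threshold: float = DEFAULT_THRESHOLD,
        threshold_on: str = "negative",
        seed: int = 0,
        hyperparams: dict | None = None,
    ):
        self.kind = kind
        self.decision_threshold = decision_threshold
        self.threshold_on = threshold_on
        self.seed = seed
        self.hyperparams = hyperparams

    def _build(self) -> Pipeline:
        if self.kind not in DEFAULT_HYPERPARAMS:
            raise InvalidConfigError(f"unknown model kind {self.kind!r}")
        if not (0.0 < self.decision_threshold < 1.0):
            raise InvalidConfigError("decision_threshold must lie in (0, 1)")
        if self.threshold_on not in ("negative", "positive"):
            raise InvalidConfigError("threshold_on must be 'negative' or 'positive'")
        hp = dict(DEFAULT_HYPERPARAMS[self.kind])
        hp.update(self.hyperparams or {})
        if self.kind == "knn":
            clf = KNeighborsClassifier(**hp)
        elif self.kind == "mlp":
            clf = MLPClassifier(random_state=self.seed, **hp)
        else:
            from xgboost import XGBClassifier

            clf = XGBClassifier(random_state=self.seed, eval_metric="logloss", **hp)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise InvalidConfigError("need both classes to train")
        self.classes_ = np.array([0, 1])
        self.pipeline_ = self._build()
        # KNN with distance weights can request more neighbors than samples
        if self.kind == "knn":
            k = self.pipeline_.named_steps["clf"].n_neighbors
            self.pipeline_.named_steps["clf"].n_neighbors = min(k, len(y))
        self.pipeline_.fit(X, y)
        return self

    def predict_proba(self, X):
        return self.pipeline_.predict_proba(np.asarray(X, dtype=float))

    def positive_cutoff(self) -> float:
        """Cutoff on p(readmit) implied by the threshold convention."""
        if self.threshold_on == "negative":
            return 1.0 - self.decision_threshold
        return self.decision_threshold

    def predict(self, X):
        proba = self.predict_proba(X)[:, 1]
        return (proba >= self.positive_cutoff()).astype(int)


def rf_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    n_trees: int = 500,
    k: int = 11,
    seed: int = 0,
) -> tuple[list[str], pd.Series]:
    """Random-forest (Gini mean-decrease-in-impurity) feature selection.

    Returns the top-``k`` feature names and the full importance series.
    """
    y = np.asarray(labels)
    if features.shape[1] < 2:
        raise InvalidConfigError("need at least 2 features")
    if len(np.unique(y)) < 2:
        raise InvalidConfigError("need both classes for feature selection")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(features.to_numpy(dtype=float), y)
    importances = pd.Series(rf.feature_importances_, index=features.columns)
    ranked = importances.sort_values(ascending=False, kind="stable")
    return list(ranked.index[:k]), importances


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Sensitivity, specificity, precision, F1 and accuracy from counts."""
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise InvalidConfigError(f"negative count {name}={v}")
    total = tp + tn + fp + fn
    if total == 0:
        raise InvalidConfigError("empty confusion matrix")

    def ratio(num, den, what):
        if den == 0:
            warnings.warn(f"{what} undefined (zero denominator)", stacklevel=3)
            return float("nan")
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    if np.isnan(sens) or np.isnan(prec) or (prec + sens) == 0:
        f1 = float("nan")
        warnings.warn("F1 undefined", stacklevel=2)
    else:
        f1 = 2 * prec * sens / (prec + sens)
    acc = (tp + tn) / total
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
        "accuracy": acc,
    }


def roc_auc(probabilities: np.ndarray, labels: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Trapezoidal AUC and the empirical ROC (threshold sweep)."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise InvalidConfigError("ROC requires both classes")
    fpr, tpr, thr = roc_curve(y, p)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def loocv(
    features: pd.DataFrame,
    model: ReadmissionClassifier | None = None,
    feature_names: list[str] | None = None,
) -> EvalResult:
    """Leave-one-subject-out cross-validation, pooled at the session level.

    ``features`` must carry subject_id, session_id, label columns plus the
    feature columns.  All sessions of the held-out subject are scored by a
    model trained on the remaining subjects' sessions.
    """
    model = model or ReadmissionClassifier()
    feature_names = feature_names or [c for c in FEATURE_NAMES if c in features.columns]
    X = features[feature_names].to_numpy(dtype=float)
    y = (features["label"] == POSITIVE_LABEL).to_numpy().astype(int)
    groups = features["subject_id"].to_numpy()
    n_subjects = len(np.unique(groups))
    if n_subjects < 2:
        raise InvalidConfigError("LOOCV needs at least 2 subjects")

    rows = []
    logo = LeaveOneGroupOut()
    for fold, (tr, te) in enumerate(logo.split(X, y, groups)):
        train_subjects = set(groups[tr])
        test_subjects = set(groups[te])
        assert not (train_subjects & test_subjects), "subject leakage across folds"
        est = clone(model)
        est.fit(X[tr], y[tr])
        proba = est.predict_proba(X[te])[:, 1]
        pred = (proba >= est.positive_cutoff()).astype(int)
        for i, idx in enumerate(te):
            rows.append(
                {
                    "subject_id": features["subject_id"].iloc[idx],
                    "session_id": features["session_id"].iloc[idx],
                    "y_true": int(y[idx]),
                    "proba": float(proba[i]),
                    "y_pred": int(pred[i]),
                    "fold": fold,
                }
            )
    pred_df = pd.DataFrame(rows)
    assert len(pred_df) == len(features), "every session must be scored exactly once"

    tp = int(((pred_df.y_true == 1) & (pred_df.y_pred == 1)).sum())
    tn = int(((pred_df.y_true == 0) & (pred_df.y_pred == 0)).sum())
    fp = int(((pred_df.y_true == 0) & (pred_df.y_pred == 1)).sum())
    fn = int(((pred_df.y_true == 1) & (pred_df.y_pred == 0)).sum())
    agg = metrics_from_counts(tp, tn, fp, fn)
    agg.update({"tp": tp, "tn": tn, "fp": fp, "fn": fn})
    auc, roc_df = roc_auc(pred_df.proba.to_numpy(), pred_df.y_true.to_numpy())
    agg["auc"] = auc
    return EvalResult(
        predictions=pred_df,
        metrics=agg,
        roc=roc_df,
        provenance={
            "model": model.get_params(),
            "feature_names": feature_names,
            "n_subjects": n_subjects,
            "positive_label": POSITIVE_LABEL,
        },
    )


def compare_groups(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise two-sample (pooled-variance) t-tests between groups."""
    names = list(values_by_group)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(values_by_group[names[i]], dtype=float)
            b = np.asarray(values_by_group[names[j]], dtype=float)
            if len(a) < 2 or len(b) < 2:
                raise InvalidConfigError("need >= 2 values per group")
            if a.std() == 0 and b.std() == 0:
                warnings.warn(
                    f"degenerate t-test between {names[i]} and {names[j]} "
                    "(zero variance in both groups)",
                    stacklevel=2,
                )
            t, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append(
                {"group_a": names[i], "group_b": names[j],
                 "t": float(t), "p_value": float(p),
                 "mean_a": float(a.mean()), "mean_b": float(b.mean())}
            )
    return pd.DataFrame(rows)


def group_boxplot(values_by_group: dict[str, np.ndarray], path, title: str = "") -> None:
    """Boxplot-style summary export for a feature across groups."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    names = list(values_by_group)
    ax.boxplot([values_by_group[n] for n in names], tick_labels=names)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
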