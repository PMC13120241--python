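"""Odour-classifier training, cross-validation schemes and metrics.

The suite covers logistic regression, random forest, gradient-boosted
trees, SVM and MLP (delegated to scikit-learn) plus a natively implemented
extreme learning machine (ELM): a single random sigmoid hidden layer with
output weights solved by ridge-regularised least squares on +/-1 targets.

Three cross-validation schemes are provided. Stratified k-fold is the
optimistic baseline; leave-k-day-out holds out temporally *contiguous*
blocks of calendar days so that day-correlated structure cannot leak between
train and test; the 24-hour group scheme is stratified grouping for
continuous acquisitions. Balanced class weights
``w_c = n_total / (n_classes * n_c)`` counter label imbalance, and every
evaluation is repeated over seeds with means and spreads reported.

Feature scaling is fitted inside each training fold and applied to its test
fold, so no test information reaches the scaler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .core import Prediction
from .features import FeatureScaler

__all__ = [
    "MODEL_NAMES",
    "Prediction",
    "CVPlan",
    "MetricsReport",
    "SuiteReport",
    "class_weights",
    "make_cv_plan",
    "ELMClassifier",
    "train_elm",
    "predict_elm",
    "compute_metrics",
    "run_suite",
]

MODEL_NAMES = ("LR", "RF", "GB", "SVM", "MLP", "ELM")


def class_weights(labels: Sequence[str]) -> dict[str, float]:
    """Balanced class weights ``n_total / (n_classes * n_c)``.

    The sample-weighted mean of the weights is 1 by construction.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts == 0) or len(classes) == 0:
        raise ValueError("every class needs at least one instance")
    n_total = labels.size
    return {
        str(c): n_total / (len(classes) * n) for c, n in zip(classes, counts)
    }


@dataclass
class CVPlan:
    """A realised cross-validation split: per-fold train/test index arrays."""

    folds: list[tuple[np.ndarray, np.ndarray]]
    scheme: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for tr, te in self.folds:
            if np.intersect1d(tr, te).size:
                raise ValueError("train and test indices overlap within a fold")

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_cv_plan(
    metadata: pd.DataFrame,
    scheme: str,
    params: dict | None = None,
    seed: int = 0,
) -> CVPlan:
    """Build a cross-validation plan over the sample metadata.

    ``metadata`` needs a ``label`` column, plus ``day`` for the block
    schemes and ``timestamp`` (hours) for 24-hour grouping.

    Schemes
    -------
    ``stratified_kfold``
        Label-stratified shuffled k-fold (default k=10).
    ``leave_k_day_out``
        Unique days sorted chronologically and partitioned into contiguous
        blocks of ``k`` days (default 5); each block serves once as the test
        set. No day ever appears on both sides of a fold.
    ``group_24h``
        Stratified grouped k-fold (default k=10) with 24-hour windows as
        groups, so temporally adjacent windows stay on one side.
    """
    params = dict(params or {})
    labels = metadata["label"].to_numpy()
    n = len(labels)
    idx = np.arange(n)

    if scheme == "stratified_kfold":
        k = int(params.get("k", 10))
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in splitter.split(idx, labels)]
    elif scheme == "leave_k_day_out":
        k = int(params.get("k", 5))
        days = metadata["day"].to_numpy()
        uniq = np.sort(np.unique(days))
        if len(uniq) < k:
            raise ValueError(
                f"only {len(uniq)} distinct days; cannot hold out blocks of {k}"
            )
        folds = []
        for start in range(0, len(uniq), k):
            block = set(uniq[start : start + k])
            te = idx[np.isin(days, list(block))]
            tr = idx[~np.isin(days, list(block))]
            if te.size and tr.size:
                folds.append((tr, te))
    elif scheme == "group_24h":
        k = int(params.get("k", 10))
        groups = (metadata["timestamp"].to_numpy() // 24.0).astype(int)
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in splitter.split(idx, labels, groups)]
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")

    return CVPlan(folds=folds, scheme=scheme, params=params, seed=seed)


# ---------------------------------------------------------------------------
# Extreme learning machine


class ELMClassifier:
    """Binary ELM: random sigmoid hidden layer + ridge least-squares readout.

    Input weights and biases are drawn once from a seeded uniform(-1, 1)
    stream and never trained; only the output weights are solved, in closed
    form, against +/-1 class targets. The decision confidence is the
    logistic of the output margin, so as the ridge penalty grows the output
    weights shrink to zero and confidences collapse to 0.5.
    """

    def __init__(self, hidden_units: int = 200, ridge: float = 1e-3, seed: int = 0):
        if hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if ridge < 0:
            raise ValueError("ridge must be >= 0")
        self.hidden_units = hidden_units
        self.ridge = ridge
        self.seed = seed

    @staticmethod
    def _sigmoid(z: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return self._sigmoid(X @ self.W_ + self.b_)

    def fit(self, X, y, sample_weight=None) -> "ELMClassifier":
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("ELMClassifier is binary")
        t = np.where(y == self.classes_[1], 1.0, -1.0)
        rng = np.random.default_rng(self.seed)
        self.W_ = rng.uniform(-1.0, 1.0, size=(X.shape[1], self.hidden_units))
        self.b_ = rng.uniform(-1.0, 1.0, size=self.hidden_units)
        H = self._hidden(X)
        if sample_weight is not None:
            sw = np.sqrt(np.asarray(sample_weight, float))
            Hw, tw = H * sw[:, None], t * sw
        else:
            Hw, tw = H, t
        A = Hw.T @ Hw + self.ridge * np.eye(self.hidden_units)
        self.beta_ = np.linalg.solve(A, Hw.T @ tw)
        return self

    def decision_function(self, X) -> np.ndarray:
        return self._hidden(np.asarray(X, float)) @ self.beta_

    def predict(self, X) -> np.ndarray:
        return np.where(
            self.decision_function(X) >= 0, self.classes_[1], self.classes_[0]
        )

    def predict_proba(self, X) -> np.ndarray:
        p1 = self._sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def get_params(self, deep=True):  # sklearn-compatible cloning
        return {"hidden_units": self.hidden_units, "ridge": self.ridge, "seed": self.seed}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self


def train_elm(
    features, labels, hidden_units: int = 200, ridge: float = 1e-3, seed: int = 0,
    sample_weight=None,
) -> ELMClassifier:
    return ELMClassifier(hidden_units=hidden_units, ridge=ridge, seed=seed).fit(
        features, labels, sample_weight=sample_weight
    )


def predict_elm(
    model: ELMClassifier, features, sample_ids: Sequence[str] | None = None
) -> list[Prediction]:
    return _to_predictions(model, np.asarray(features, float), sample_ids)


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class MetricsReport:
    """Accuracy, per-class precision/recall, macro F1 and the confusion matrix."""

    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1_macro: float
    confusion: np.ndarray
    classes: list[str]
    zero_division_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1_macro": self.f1_macro,
            "confusion": self.confusion.tolist(),
            "classes": self.classes,
            "zero_division_flags": self.zero_division_flags,
        }


def compute_metrics(
    y_pred: Sequence[str] | Sequence[Prediction],
    y_true: Sequence[str],
    classes: Sequence[str] | None = None,
) -> MetricsReport:
    """Accuracy, per-class precision/recall and macro F1 from first principles.

    ``y_pred`` may be raw labels or Prediction records (matched positionally;
    lengths must agree). Undefined ratios (empty denominator) are reported
    as 0 and flagged.
    """
    if y_pred and isinstance(y_pred[0], Prediction):
        y_pred = [p.label for p in y_pred]
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    if y_pred.shape != y_true.shape:
        raise ValueError("prediction/label length mismatch")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = [str(c) for c in classes]
    k = len(classes)
    conf = np.zeros((k, k), dtype=int)
    cindex = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        conf[cindex[str(t)], cindex[str(p)]] += 1

    accuracy = float(np.trace(conf) / conf.sum()) if conf.sum() else 0.0
    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    flags: list[str] = []
    f1s: list[float] = []
    for c in classes:
        i = cindex[c]
        pred_c = conf[:, i].sum()
        true_c = conf[i, :].sum()
        if pred_c == 0:
            flags.append(f"precision[{c}]")
        if true_c == 0:
            flags.append(f"recall[{c}]")
        p = conf[i, i] / pred_c if pred_c else 0.0
        r = conf[i, i] / true_c if true_c else 0.0
        precision[c] = float(p)
        recall[c] = float(r)
        f1s.append(2 * p * r / (p + r) if (p + r) else 0.0)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1_macro=float(np.mean(f1s)),
        confusion=conf,
        classes=classes,
        zero_division_flags=flags,
    )


# ---------------------------------------------------------------------------
# Model suite


def _build_model(name: str, seed: int, weights: dict[str, float], spec: dict):
    opts = dict(spec or {})
    if name == "LR":
        return LogisticRegression(
            max_iter=opts.pop("max_iter", 2000),
            class_weight=weights,
            random_state=seed,
            **opts,
        )
    if name == "RF":
        return RandomForestClassifier(
            n_estimators=opts.pop("n_estimators", 100),
            class_weight=weights,
            random_state=seed,
            **opts,
        )
    if name == "GB":
        return GradientBoostingClassifier(random_state=seed, **opts)
    if name == "SVM":
        return SVC(class_weight=weights, random_state=seed, **opts)
    if name == "MLP":
        # sklearn's MLP accepts no class/sample weights; fitted unweighted
        return MLPClassifier(
            hidden_layer_sizes=opts.pop("hidden_layer_sizes", (64,)),
            max_iter=opts.pop("max_iter", 500),
            random_state=seed,
            **opts,
        )
    if name == "ELM":
        return ELMClassifier(
            hidden_units=opts.pop("hidden_units", 200),
            ridge=opts.pop("ridge", 1e-3),
            seed=seed,
        )
    raise ValueError(f"unknown model name {name!r}; known: {MODEL_NAMES}")


def _confidences(model, X: np.ndarray) -> np.ndarray:
    """Winning-class confidence in [0, 1] for any suite model.

    Probability when the model provides one; otherwise the logistic of the
    decision margin (SVM without calibration).
    """
    if hasattr(model, "predict_proba"):
        return np.max(model.predict_proba(X), axis=1)
    margin = np.abs(model.decision_function(X))
    return 1.0 / (1.0 + np.exp(-margin))


def _to_predictions(model, X, sample_ids=None) -> list[Prediction]:
    labels = model.predict(X)
    confs = _confidences(model, X)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(len(labels))]
    return [
        Prediction(sample_id=str(sid), label=str(lb), confidence=float(cf),
                   modality="odour")
        for sid, lb, cf in zip(sample_ids, labels, confs)
    ]


@dataclass
class SuiteReport:
    """Aggregated cross-validation outcome for one model."""

    model: str
    mean_accuracy: float
    sd_accuracy: float
    fold_accuracies: np.ndarray  # (n_repeats, n_folds)
    metrics: MetricsReport  # pooled over folds of the first repeat
    predictions: pd.DataFrame  # sample_id, fold, repeat, label_pred, confidence

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "fold_accuracies": self.fold_accuracies.tolist(),
            "metrics": self.metrics.to_dict(),
        }


def run_suite(
    features: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    plan: CVPlan,
    model_specs: dict[str, dict] | Sequence[str] = ("LR",),
    n_repeats: int = 25,
    base_seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> dict[str, SuiteReport]:
    """Cross-validate each requested model under the plan, repeated over seeds.

    Per repeat and fold: fit the min-max scaler and the model (with balanced
    class weights) on the training side only, then predict the test side.
    Means and spreads aggregate over repeats x folds; per-sample test-fold
    predictions are retained for decision fusion.
    """
    if isinstance(features, pd.DataFrame):
        if sample_ids is None:
            sample_ids = [str(i) for i in features.index]
        X_all = features.to_numpy(float)
    else:
        X_all = np.asarray(features, float)
    labels = np.asarray([str(label) for label in labels])
    if sample_ids is None:
        sample_ids = [str(i) for i in range(len(labels))]
    sample_ids = np.asarray(sample_ids)
    if isinstance(model_specs, (list, tuple)):
        model_specs = {name: {} for name in model_specs}
    for name in model_specs:
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {name!r}; known: {MODEL_NAMES}")

    reports: dict[str, SuiteReport] = {}
    for name, spec in model_specs.items():
        accs = np.zeros((n_repeats, plan.n_folds))
        rows: list[dict] = []
        pooled_pred: list[str] = []
        pooled_true: list[str] = []
        for rep in range(n_repeats):
            name_tag = sum(ord(ch) for ch in name)  # stable across runs
            seed = (base_seed + 1009 * rep + name_tag) % (2**31 - 1)
            for f, (tr, te) in enumerate(plan.folds):
                scaler = FeatureScaler().fit(X_all[tr])
                Xtr, Xte = scaler.transform(X_all[tr]), scaler.transform(X_all[te])
                ytr = labels[tr]
                weights = class_weights(ytr)
                model = _build_model(name, seed, weights, spec)
                if name in ("GB",):  # weighting passed per sample
                    sw = np.array([weights[label] for label in ytr])
                    model.fit(Xtr, ytr, sample_weight=sw)
                elif name == "ELM":
                    sw = np.array([weights[label] for label in ytr])
                    model.fit(Xtr, ytr, sample_weight=sw)
                else:
                    model.fit(Xtr, ytr)
                preds = _to_predictions(model, Xte, sample_ids[te])
                accs[rep, f] = compute_metrics(preds, labels[te]).accuracy
                if rep == 0:
                    pooled_pred.extend(p.label for p in preds)
                    pooled_true.extend(labels[te])
                for p in preds:
                    rows.append(
                        {
                            "sample_id": p.sample_id,
                            "model": name,
                            "fold": f,
                            "repeat": rep,
                            "label_pred": p.label,
                            "confidence": p.confidence,
                        }
                    )
        reports[name] = SuiteReport(
            model=name,
            mean_accuracy=float(accs.mean()),
            sd_accuracy=float(accs.std()),
            fold_accuracies=accs,
            metrics=compute_metrics(pooled_pred, pooled_true),
            predictions=pd.DataFrame(rows),
        )
    return reports
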