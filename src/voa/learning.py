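"""Training pipeline: z-score normalization, linear SVM, LOOCV, metric selection.

The classifier is a linear support vector machine trained by iterative cost
reduction: deterministic full-batch subgradient descent on the regularized
hinge objective

    J(theta, b) = 1/2 ||theta||^2 + C * sum_i max(0, 1 - y_i (theta . z_i + b))

with step size 1/t (the schedule for a 1-strongly-convex objective).  Classes
are encoded skilled = +1, novice = -1, and every metric is z-scored against
the training cohort before it reaches the classifier, so the weights are
directly comparable across metrics.

Leave-one-out cross-validation (LOOCV) refits the normalizer *and* the model
on each fold's n-1 training members, so the held-out trial never influences
the statistics it is judged against.  Sensitivity is the fraction of skilled
members correctly classified and specificity the fraction of novices, the
convention used when the validated model's confusion matrix was reported.

Metric selection is a wrapper search over candidate metric subsets scored by
LOOCV accuracy: forward steps add the best single metric while accuracy
strictly improves, backward steps drop any metric whose removal does not hurt
accuracy, and the phases alternate until a full pass changes nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    CohortError,
    DegenerateMetricError,
    InputError,
    SchemaError,
    SelectionError,
    TrainingError,
)
from .metrics import MetricVector, metric_columns
from .recording import NOVICE, SKILLED

__all__ = [
    "NormalizationParams",
    "fit_normalizer",
    "normalize",
    "SVMConfig",
    "train_svm",
    "hinge_objective",
    "pegasos",
    "LinearModel",
    "CVResult",
    "loocv",
    "SelectionConfig",
    "SelectionTrace",
    "select_metrics",
    "save_model",
    "load_model",
    "load_reference_model",
    "encode_labels",
    "table_to_arrays",
    "CLASS_ENCODING",
]

MODEL_SCHEMA_VERSION = "voa-model/1"

#: Fixed class encoding: positive margins mean skilled performance.
CLASS_ENCODING = {1: SKILLED, -1: NOVICE}


def encode_labels(labels: Sequence[str]) -> np.ndarray:
    """Map group labels to the +/-1 encoding (skilled = +1, novice = -1)."""
    mapping = {SKILLED: 1, NOVICE: -1}
    try:
        return np.array([mapping[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise InputError(f"unknown group label: {exc.args[0]!r}") from exc


def table_to_arrays(
    table: pd.DataFrame,
    columns: Sequence[str] | None = None,
    label_column: str = "group",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a cohort metric table into (X, y, metric names)."""
    if columns is None:
        columns = metric_columns(table)
    if label_column not in table.columns:
        raise SchemaError(f"table has no {label_column!r} column")
    X = table[list(columns)].to_numpy(dtype=float)
    y = encode_labels(table[label_column].tolist())
    return X, y, list(columns)


# -- normalization -----------------------------------------------------------

@dataclass(frozen=True)
class NormalizationParams:
    """Per-metric mean and sample standard deviation (n-1 denominator),
    estimated on the training cohort and frozen into the model."""

    names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        k = len(self.names)
        if self.means.shape != (k,) or self.sds.shape != (k,):
            raise SchemaError("normalization arrays must match the metric names")
        if np.any(self.sds <= 0):
            bad = [n for n, s in zip(self.names, self.sds) if s <= 0]
            raise DegenerateMetricError(f"non-positive sd for metrics: {bad}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NormalizationParams):
            return NotImplemented
        return (
            self.names == other.names
            and np.array_equal(self.means, other.means)
            and np.array_equal(self.sds, other.sds)
        )

    def subset(self, names: Sequence[str]) -> "NormalizationParams":
        index = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise SchemaError(f"normalization is missing metrics: {missing}")
        idx = [index[n] for n in names]
        return NormalizationParams(tuple(names), self.means[idx], self.sds[idx])


def fit_normalizer(
    table: pd.DataFrame | np.ndarray, columns: Sequence[str] | None = None
) -> NormalizationParams:
    """Estimate per-metric mean and sample sd from a training cohort table."""
    if isinstance(table, pd.DataFrame):
        if columns is None:
            columns = metric_columns(table)
        X = table[list(columns)].to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        if columns is None:
            columns = [f"metric_{i}" for i in range(X.shape[1])]
    if X.shape[0] < 2:
        raise InputError("need at least 2 rows to estimate normalization")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = [n for n, s in zip(columns, sds) if s == 0]
    if constant:
        raise DegenerateMetricError(
            f"constant metric column(s) cannot be z-scored: {constant}"
        )
    return NormalizationParams(tuple(columns), means, sds)


def normalize(
    v: MetricVector | Sequence[float] | dict[str, float], params: NormalizationParams
) -> np.ndarray:
    """z-score a metric vector against frozen training statistics."""
    if isinstance(v, MetricVector):
        if set(v.names) != set(params.names):
            raise SchemaError(
                f"metric names {sorted(v.names)} do not match the "
                f"normalization's {sorted(params.names)}"
            )
        values = v.subset(params.names).values_array
    elif isinstance(v, dict):
        missing = [n for n in params.names if n not in v]
        extra = [n for n in v if n not in params.names]
        if missing or extra:
            raise SchemaError(f"metric name mismatch: missing {missing}, extra {extra}")
        values = np.array([v[n] for n in params.names], dtype=float)
    else:
        values = np.asarray(v, dtype=float)
        if values.shape != (len(params.names),):
            raise SchemaError(
                f"expected {len(params.names)} metric values, got shape {values.shape}"
            )
    return (values - params.means) / params.sds


# -- linear SVM by iterative cost reduction ----------------------------------

@dataclass(frozen=True)
class SVMConfig:
    """Trainer hyperparameters.

    C is the hinge penalty per violated margin, iterations the fixed budget of
    full-batch subgradient steps.  The solver itself is deterministic; the seed
    is carried into the model's provenance so any stochastic variant or
    downstream resampling stays reproducible.
    """

    C: float = 1.0
    iterations: int = 1000
    seed: int = 0


def hinge_objective(
    w: np.ndarray, b: float, Z: np.ndarray, y: np.ndarray, C: float
) -> float:
    margins = y * (Z @ w + b)
    return 0.5 * float(w @ w) + C * float(np.maximum(0.0, 1.0 - margins).sum())


def pegasos(
    Z: np.ndarray, y: np.ndarray, C: float = 1.0, iterations: int = 1000
) -> tuple[np.ndarray, float, np.ndarray]:
    """Full-batch subgradient descent on the regularized hinge objective.

    Returns (weights, bias, objective value at each iteration including the
    start).  Step size 1/t; the bias is unregularized.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = Z.shape
    w = np.zeros(k)
    b = 0.0
    objective = np.empty(iterations + 1)
    objective[0] = hinge_objective(w, b, Z, y, C)
    for t in range(1, iterations + 1):
        margins = y * (Z @ w + b)
        coef = np.where(margins < 1.0, y, 0.0)
        grad_w = w - C * (Z.T @ coef)
        grad_b = -C * coef.sum()
        eta = 1.0 / t
        w = w - eta * grad_w
        b = b - eta * grad_b
        objective[t] = hinge_objective(w, b, Z, y, C)
    return w, float(b), objective


# -- model container ---------------------------------------------------------

@dataclass(eq=False)
class LinearModel:
    """A trained linear classifier with its frozen normalization.

    The decision function is h(z) = theta . z + b on z-scored metrics; h > 0
    reads as skilled, h < 0 as novice.  The bias is a weight without a
    corresponding metric: it shifts the decision boundary but takes no part in
    per-metric feedback.
    """

    metric_names: tuple[str, ...]
    categories: tuple[str, ...]
    weights: np.ndarray
    bias: float
    normalization: NormalizationParams
    class_encoding: dict[int, str] = field(default_factory=lambda: dict(CLASS_ENCODING))
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.metric_names = tuple(self.metric_names)
        self.categories = tuple(self.categories)
        self.weights = np.asarray(self.weights, dtype=float)
        k = len(self.metric_names)
        if self.weights.shape != (k,):
            raise SchemaError("one weight per metric is required")
        if len(self.categories) != k:
            raise SchemaError("one category per metric is required")
        if self.normalization.names != self.metric_names:
            raise SchemaError("normalization metric names must match the model's")
        if self.class_encoding != CLASS_ENCODING:
            raise SchemaError(f"class encoding must be {CLASS_ENCODING}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinearModel):
            return NotImplemented
        return (
            self.metric_names == other.metric_names
            and self.categories == other.categories
            and np.array_equal(self.weights, other.weights)
            and self.bias == other.bias
            and self.normalization == other.normalization
            and self.class_encoding == other.class_encoding
            and self.training_meta == other.training_meta
        )


def train_svm(
    Z: np.ndarray,
    y: np.ndarray,
    config: SVMConfig | None = None,
    *,
    metric_names: Sequence[str] | None = None,
    categories: Sequence[str] | None = None,
    normalization: NormalizationParams | None = None,
    record_objective: bool = False,
) -> LinearModel:
    """Train the linear SVM on z-scored metrics ``Z`` with labels ``y``.

    ``normalization`` should be the parameters that produced ``Z``; if omitted
    an identity normalization is frozen in (useful for pre-scaled data).
    """
    if config is None:
        config = SVMConfig()
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise TrainingError("Z must be a 2-D matrix")
    y = np.asarray(y)
    if not np.all(np.isin(y, (-1, 1))):
        raise TrainingError("labels must be +/-1 (skilled = +1, novice = -1)")
    if len(set(y.tolist())) < 2:
        raise TrainingError("training requires both classes")
    if not np.all(np.isfinite(Z)):
        raise TrainingError("Z contains non-finite values")
    n, k = Z.shape
    if metric_names is None:
        metric_names = tuple(f"metric_{i}" for i in range(k))
    metric_names = tuple(metric_names)
    if categories is None:
        categories = tuple("other" for _ in metric_names)
    if normalization is None:
        normalization = NormalizationParams(metric_names, np.zeros(k), np.ones(k))
    w, b, objective = pegasos(Z, y, C=config.C, iterations=config.iterations)
    meta: dict = {
        "C": config.C,
        "iterations": config.iterations,
        "seed": config.seed,
        "n_training": int(n),
        "final_objective": float(objective[-1]),
    }
    if record_objective:
        meta["objective"] = objective.tolist()
    return LinearModel(
        metric_names=metric_names,
        categories=tuple(categories),
        weights=w,
        bias=b,
        normalization=normalization,
        training_meta=meta,
    )


# -- leave-one-out cross-validation ------------------------------------------

@dataclass(frozen=True)
class CVResult:
    """Leave-one-out confusion counts and the rates derived from them."""

    skilled_total: int
    novice_total: int
    skilled_correct: int
    novice_correct: int
    fold_errors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.skilled_correct <= self.skilled_total):
            raise InputError("skilled_correct out of range")
        if not (0 <= self.novice_correct <= self.novice_total):
            raise InputError("novice_correct out of range")

    @classmethod
    def from_counts(
        cls, skilled_correct: int, skilled_total: int,
        novice_correct: int, novice_total: int,
    ) -> "CVResult":
        return cls(
            skilled_total=skilled_total,
            novice_total=novice_total,
            skilled_correct=skilled_correct,
            novice_correct=novice_correct,
        )

    @property
    def n(self) -> int:
        return self.skilled_total + self.novice_total

    @property
    def confusion(self) -> dict[str, int]:
        """Counts keyed as true_label->predicted_label."""
        return {
            "skilled->skilled": self.skilled_correct,
            "skilled->novice": self.skilled_total - self.skilled_correct,
            "novice->novice": self.novice_correct,
            "novice->skilled": self.novice_total - self.novice_correct,
        }

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.skilled_correct + self.novice_correct) / self.n

    @property
    def sensitivity_pct(self) -> float:
        """Percent of skilled members correctly classified."""
        return 100.0 * self.skilled_correct / self.skilled_total

    @property
    def specificity_pct(self) -> float:
        """Percent of novice members correctly classified."""
        return 100.0 * self.novice_correct / self.novice_total

    def summary(self) -> dict:
        """Display-ready summary (rates to one decimal, as typically reported)."""
        return {
            "n": self.n,
            "confusion": self.confusion,
            "accuracy_pct": round(self.accuracy_pct, 1),
            "sensitivity_pct": round(self.sensitivity_pct, 1),
            "specificity_pct": round(self.specificity_pct, 1),
            "fold_errors": list(self.fold_errors),
        }


def loocv(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | Sequence[str] | None = None,
    config: SVMConfig | None = None,
    columns: Sequence[str] | None = None,
) -> CVResult:
    """Leave-one-out cross-validation on raw (un-normalized) metric values.

    Each fold refits the z-score normalization and the SVM on its n-1 training
    members before classifying the held-out member.  ``X`` may be a cohort
    metric table (with a ``group`` column) or a plain matrix with ``y`` given
    as +/-1 labels or group-label strings.
    """
    if config is None:
        config = SVMConfig()
    if isinstance(X, pd.DataFrame):
        X, y_arr, _ = table_to_arrays(X, columns)
    else:
        X = np.asarray(X, dtype=float)
        if y is None:
            raise InputError("labels are required when X is a plain matrix")
        y_arr = np.asarray(y)
        if y_arr.dtype.kind in "US":
            y_arr = encode_labels(list(y_arr))
    n = X.shape[0]
    if n < 3:
        raise CohortError("LOOCV needs at least 3 members")
    if len(set(y_arr.tolist())) < 2:
        raise CohortError("LOOCV needs both classes present")

    skilled_correct = novice_correct = 0
    skilled_total = int(np.sum(y_arr == 1))
    novice_total = int(np.sum(y_arr == -1))
    fold_errors: list[str] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y_arr[mask]
        if len(set(y_tr.tolist())) < 2:
            fold_errors.append(f"fold {i}: training set has a single class")
            continue
        means = X_tr.mean(axis=0)
        sds = X_tr.std(axis=0, ddof=1)
        if np.any(sds == 0):
            fold_errors.append(f"fold {i}: constant metric in training set")
            continue
        Z_tr = (X_tr - means) / sds
        w, b, _ = pegasos(Z_tr, y_tr, C=config.C, iterations=config.iterations)
        z_i = (X[i] - means) / sds
        pred = 1 if float(z_i @ w + b) > 0.0 else -1
        if pred == y_arr[i]:
            if y_arr[i] == 1:
                skilled_correct += 1
            else:
                novice_correct += 1
    return CVResult(
        skilled_total=skilled_total,
        novice_total=novice_total,
        skilled_correct=skilled_correct,
        novice_correct=novice_correct,
        fold_errors=tuple(fold_errors),
    )


# -- wrapper forward/backward metric selection --------------------------------

@dataclass(frozen=True)
class SelectionConfig:
    """Search configuration; the inner LOOCV uses a lighter iteration budget
    than final training because it is run once per candidate subset."""

    svm: SVMConfig = field(default_factory=lambda: SVMConfig(iterations=300))


@dataclass(frozen=True)
class SelectionTrace:
    """Every candidate subset visited, with its LOOCV accuracy, plus the
    final selected set.  The final accuracy equals the maximum over the trace
    (ties resolved toward smaller sets, then candidate order)."""

    entries: tuple[dict, ...]
    selected: tuple[str, ...]
    selected_accuracy_pct: float

    def to_dict(self) -> dict:
        return {
            "schema_version": "voa-selection/1",
            "entries": [dict(e) for e in self.entries],
            "selected": list(self.selected),
            "selected_accuracy_pct": self.selected_accuracy_pct,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def select_metrics(
    table: pd.DataFrame | np.ndarray,
    labels: Sequence[str] | np.ndarray | None = None,
    config: SelectionConfig | None = None,
    columns: Sequence[str] | None = None,
) -> SelectionTrace:
    """Combined forward/backward wrapper search maximizing LOOCV accuracy.

    Forward phase: repeatedly add the single metric that most improves LOOCV
    accuracy, stopping when no addition strictly improves it (ties go to the
    earliest candidate).  Backward phase: drop any metric whose removal does
    not decrease accuracy (preferring smaller sets).  Phases alternate until a
    full pass leaves the set unchanged.
    """
    if config is None:
        config = SelectionConfig()
    if isinstance(table, pd.DataFrame):
        X, y, names = table_to_arrays(table, columns)
    else:
        X = np.asarray(table, dtype=float)
        if labels is None:
            raise InputError("labels are required when table is a plain matrix")
        y = np.asarray(labels)
        if y.dtype.kind in "US":
            y = encode_labels(list(y))
        names = list(columns) if columns is not None else [
            f"metric_{i}" for i in range(X.shape[1])
        ]
    if len(names) == 0:
        raise SelectionError("candidate metric set is empty")

    index = {n: i for i, n in enumerate(names)}
    entries: list[dict] = []
    cache: dict[frozenset, float] = {}

    def evaluate(subset: list[str], phase: str) -> float:
        key = frozenset(subset)
        if key not in cache:
            cols = [index[n] for n in subset]
            cache[key] = loocv(X[:, cols], y, config.svm).accuracy_pct
        entries.append(
            {"metrics": list(subset), "accuracy_pct": cache[key], "phase": phase}
        )
        return cache[key]

    current: list[str] = []
    current_acc = -np.inf
    while True:
        changed = False
        # forward: add while strictly improving
        while True:
            remaining = [n for n in names if n not in current]
            if not remaining:
                break
            best_name, best_acc = None, -np.inf
            for name in remaining:
                acc = evaluate(current + [name], "forward")
                if acc > best_acc:
                    best_name, best_acc = name, acc
            if best_acc > current_acc:
                current.append(best_name)
                current_acc = best_acc
                changed = True
            else:
                break
        # backward: drop while not hurting
        while len(current) > 1:
            dropped = False
            for name in list(current):
                candidate = [n for n in current if n != name]
                acc = evaluate(candidate, "backward")
                if acc >= current_acc:
                    current = candidate
                    current_acc = acc
                    changed = dropped = True
                    break
            if not dropped:
                break
        if not changed:
            break
    return SelectionTrace(
        entries=tuple(entries),
        selected=tuple(current),
        selected_accuracy_pct=float(current_acc),
    )


# -- model serialization ------------------------------------------------------

def save_model(model: LinearModel, path: str | Path) -> None:
    """Serialize a model to JSON, preserving floats to full precision."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "metric_names": list(model.metric_names),
        "categories": list(model.categories),
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "normalization": {
            "means": model.normalization.means.tolist(),
            "sds": model.normalization.sds.tolist(),
        },
        "class_encoding": {str(k): v for k, v in model.class_encoding.items()},
        "training_meta": model.training_meta,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _model_from_doc(doc: dict, source: str) -> LinearModel:
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise SchemaError(
            f"{source}: unsupported schema_version {doc.get('schema_version')!r}; "
            f"expected {MODEL_SCHEMA_VERSION!r}"
        )
    required = (
        "metric_names", "categories", "weights", "bias",
        "normalization", "class_encoding",
    )
    missing = [k for k in required if k not in doc]
    if missing:
        raise SchemaError(f"{source}: missing keys {missing}")
    names = tuple(doc["metric_names"])
    weights = np.asarray(doc["weights"], dtype=float)
    if weights.shape != (len(names),):
        raise SchemaError(f"{source}: weight count does not match metric names")
    norm = doc["normalization"]
    if "means" not in norm or "sds" not in norm:
        raise SchemaError(f"{source}: normalization must carry means and sds")
    try:
        encoding = {int(k): v for k, v in doc["class_encoding"].items()}
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{source}: malformed class_encoding") from exc
    return LinearModel(
        metric_names=names,
        categories=tuple(doc["categories"]),
        weights=weights,
        bias=float(doc["bias"]),
        normalization=NormalizationParams(
            names, np.asarray(norm["means"], float), np.asarray(norm["sds"], float)
        ),
        class_encoding=encoding,
        training_meta=dict(doc.get("training_meta", {})),
    )


def load_model(path: str | Path) -> LinearModel:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON") from exc
    return _model_from_doc(doc, str(path))


def load_reference_model() -> LinearModel:
    """The shipped four-metric reference model.

    Weights are those of the validated two-group subpial-resection model
    (28 skilled vs 22 novice operators).  The original cohort's metric means
    and deviations were never published, so the frozen normalization is the
    identity: the model should be applied to already z-scored metrics.
    """
    data = resources.files("voa.data").joinpath("reference_model.json").read_text()
    return _model_from_doc(json.loads(data), "reference_model.json")
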