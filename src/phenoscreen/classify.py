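"""Supervised single-cell phenotype classification.

Each marker gets an ensemble of small fully connected networks (two hidden
layers of 54 and 18 ReLU units, softmax output) trained on standardized
single-cell features with SGD. The ensemble members share the training set
and hyper-parameters and differ only in their random initialization; a cell
is assigned the class with the highest mean probability across members,
unless that probability falls below 2/N (N = number of classes), in which
case it goes to the "None" class. Five-fold cross-validation with per-member
held-out predictions supports both performance evaluation and training-set
clean-up (cells misclassified in two or more initializations are flagged as
candidate mislabels).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from phenoscreen.core_data import FeatureTable
from phenoscreen.errors import ConfigurationError, DataError, InsufficientDataError

NONE_CLASS = "None"


@dataclass
class ClassifierConfig:
    """Architecture, optimizer and ensemble settings.

    The 2/N "None" rule threshold is ``none_rule_factor / n_classes`` with
    n_classes the class count of the marker's classifier. Optimizer settings
    (learning rate, momentum, epochs, batch size) are ordinary SGD defaults
    for networks of this size and are fully configurable. The validation
    split is carved from the training portion for loss monitoring when
    ``early_stopping`` is enabled; by default training runs a fixed number of
    epochs.
    """

    hidden1: int = 54
    hidden2: int = 18
    n_inits: int = 10
    n_folds: int = 5
    validation_fraction_of_train: float = 0.20
    none_rule_factor: float = 2.0
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 200
    batch_size: int = 32
    early_stopping: bool = False
    misclass_flag_min: int = 2
    auto_remove: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden1 < 1 or self.hidden2 < 1:
            raise ConfigurationError("hidden layer sizes must be >= 1")
        if self.n_inits < 1:
            raise ConfigurationError("n_inits must be >= 1")

    def none_threshold(self, n_classes: int) -> float:
        return self.none_rule_factor / n_classes


@dataclass
class TrainingSet:
    """Labeled single cells for one marker/screen-type classifier."""

    X: np.ndarray
    labels: np.ndarray
    cell_ids: np.ndarray
    classes: tuple[str, ...]
    marker: str = ""
    screen_type: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.cell_ids = np.asarray(self.cell_ids)
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise DataError(f"labels not in class list: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, mask: np.ndarray) -> "TrainingSet":
        return TrainingSet(
            self.X[mask], self.labels[mask], self.cell_ids[mask],
            self.classes, self.marker, self.screen_type,
        )


@dataclass
class MemberNetwork:
    """Weights of one trained ensemble member (explicit forward pass).

    Keeping raw weight arrays makes the saved model a plain numeric
    container and the prediction path independent of training internals.
    """

    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    class_order: tuple[str, ...]   # sklearn's sorted label order
    out_activation: str            # "softmax" (>=3 classes) or "logistic" (2)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        a = X
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        z = a @ self.coefs[-1] + self.intercepts[-1]
        if self.out_activation == "logistic":
            p1 = 1.0 / (1.0 + np.exp(-z[:, 0]))
            return np.column_stack([1.0 - p1, p1])
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


@dataclass
class EnsemblePhenotypeClassifier:
    marker: str
    classes: tuple[str, ...]
    members: list[MemberNetwork]
    none_threshold: float
    n_features: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean class probabilities across members, columns in ``self.classes`` order."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise DataError(
                f"feature count mismatch: model expects {self.n_features}, got {X.shape[1]}"
            )
        acc = np.zeros((X.shape[0], len(self.classes)))
        col_of = {c: i for i, c in enumerate(self.classes)}
        for m in self.members:
            p = m.predict_proba(X)
            for j, c in enumerate(m.class_order):
                acc[:, col_of[c]] += p[:, j]
        return acc / len(self.members)

    # -- persistence: config as JSON, weights as one npz per member --------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "marker": self.marker,
            "classes": list(self.classes),
            "none_threshold": self.none_threshold,
            "n_features": self.n_features,
            "n_members": len(self.members),
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=1))
        for i, m in enumerate(self.members):
            arrays = {"class_order": np.array(m.class_order)}
            arrays["out_activation"] = np.array(m.out_activation)
            for k, W in enumerate(m.coefs):
                arrays[f"coef_{k}"] = W
            for k, b in enumerate(m.intercepts):
                arrays[f"intercept_{k}"] = b
            np.savez(directory / f"member_{i}.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "EnsemblePhenotypeClassifier":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        members = []
        for i in range(meta["n_members"]):
            with np.load(directory / f"member_{i}.npz") as z:
                n_layers = sum(1 for k in z.files if k.startswith("coef_"))
                members.append(
                    MemberNetwork(
                        coefs=[z[f"coef_{k}"] for k in range(n_layers)],
                        intercepts=[z[f"intercept_{k}"] for k in range(n_layers)],
                        class_order=tuple(z["class_order"]),
                        out_activation=str(z["out_activation"]),
                    )
                )
        return cls(
            marker=meta["marker"],
            classes=tuple(meta["classes"]),
            members=members,
            none_threshold=meta["none_threshold"],
            n_features=meta["n_features"],
        )


def _fit_member(X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig, seed: int) -> MemberNetwork:
    clf = MLPClassifier(
        hidden_layer_sizes=(cfg.hidden1, cfg.hidden2),
        activation="relu",
        solver="sgd",
        learning_rate_init=cfg.learning_rate,
        momentum=cfg.momentum,
        max_iter=cfg.epochs,
        batch_size=min(cfg.batch_size, len(y)),
        early_stopping=cfg.early_stopping,
        validation_fraction=cfg.validation_fraction_of_train,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return MemberNetwork(
        coefs=[np.asarray(c) for c in clf.coefs_],
        intercepts=[np.asarray(b) for b in clf.intercepts_],
        class_order=tuple(str(c) for c in clf.classes_),
        out_activation=str(clf.out_activation_),
    )


@dataclass
class CvResult:
    """Cross-validated ensemble evaluation of a training set."""

    confusion: pd.DataFrame          # rows = true class, cols = predicted
    per_class_accuracy: pd.Series
    misclass_counts: pd.Series       # per cell_id, in [0, n_inits]
    mean_probs: pd.DataFrame         # per cell, mean held-out probabilities
    predicted: pd.Series             # per cell, argmax of mean probabilities

    @property
    def overall_accuracy(self) -> float:
        diag = np.diag(self.confusion.to_numpy()).sum()
        return float(diag / self.confusion.to_numpy().sum())


def evaluate_cv(ts: TrainingSet, cfg: ClassifierConfig | None = None) -> CvResult:
    """Stratified k-fold cross-validation of the ensemble.

    Each cell is in the test fold exactly once and receives ``n_inits``
    held-out predictions (one per random initialization of that fold's
    networks). The confusion matrix aggregates the mean-probability argmax of
    the test predictions; the per-cell misclassification count is the number
    of initializations whose individual prediction disagreed with the label.
    """
    cfg = cfg or ClassifierConfig()
    counts = pd.Series(ts.labels).value_counts()
    present = [c for c in ts.classes if c in counts.index]
    if len(present) < len(ts.classes):
        missing = set(ts.classes) - set(present)
        raise DataError(f"classes with no labeled cells: {sorted(missing)}")
    if (counts < cfg.n_folds).any():
        small = counts[counts < cfg.n_folds]
        warnings.warn(f"classes with fewer cells than folds: {dict(small)}")
    if (counts < 2).any():
        raise InsufficientDataError("every class needs >= 2 labeled cells for stratified CV")
    n_folds = min(cfg.n_folds, int(counts.min()))

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed)
    n = len(ts)
    classes = list(ts.classes)
    prob_sum = np.zeros((n, len(classes)))
    miss = np.zeros(n, dtype=int)
    col_of = {c: i for i, c in enumerate(classes)}
    for fold_i, (tr, te) in enumerate(skf.split(ts.X, ts.labels)):
        train_classes = set(ts.labels[tr])
        if train_classes != set(classes):
            raise DataError(
                f"fold {fold_i}: classes absent from training data: "
                f"{sorted(set(classes) - train_classes)}"
            )
        for init in range(cfg.n_inits):
            member = _fit_member(
                ts.X[tr], ts.labels[tr], cfg, seed=cfg.seed + 1000 * fold_i + init
            )
            p = member.predict_proba(ts.X[te])
            pred = np.array(member.class_order)[p.argmax(axis=1)]
            miss[te] += (pred != ts.labels[te]).astype(int)
            for j, c in enumerate(member.class_order):
                prob_sum[te, col_of[c]] += p[:, j]
    mean_probs = prob_sum / cfg.n_inits
    predicted = np.array(classes)[mean_probs.argmax(axis=1)]
    confusion = pd.crosstab(
        pd.Categorical(ts.labels, categories=classes),
        pd.Categorical(predicted, categories=classes),
        dropna=False,
    )
    confusion.index = classes
    confusion.columns = classes
    row_sums = confusion.sum(axis=1).replace(0, np.nan)
    per_class_acc = pd.Series(np.diag(confusion), index=classes) / row_sums
    ids = pd.Index(ts.cell_ids, name="cell_id")
    return CvResult(
        confusion=confusion,
        per_class_accuracy=per_class_acc,
        misclass_counts=pd.Series(miss, index=ids),
        mean_probs=pd.DataFrame(mean_probs, index=ids, columns=classes),
        predicted=pd.Series(predicted, index=ids),
    )


def clean_training_set(
    ts: TrainingSet, cv_result: CvResult, cfg: ClassifierConfig | None = None
) -> tuple[np.ndarray, TrainingSet]:
    """Flag candidate mislabeled cells and optionally remove them.

    A cell misclassified in ``misclass_flag_min`` (default 2) or more random
    initializations is flagged for inspection. The cleaned set excludes
    flagged cells only when ``auto_remove`` is enabled, mirroring a workflow
    where flagged cells are inspected before removal.
    """
    cfg = cfg or ClassifierConfig()
    flagged_mask = (cv_result.misclass_counts.loc[ts.cell_ids] >= cfg.misclass_flag_min).to_numpy()
    flagged_ids = ts.cell_ids[flagged_mask]
    cleaned = ts.subset(~flagged_mask) if cfg.auto_remove else ts
    return flagged_ids, cleaned


def train_final(ts: TrainingSet, cfg: ClassifierConfig | None = None) -> EnsemblePhenotypeClassifier:
    """Train the final ensemble on the full (cleaned) training set."""
    cfg = cfg or ClassifierConfig()
    counts = pd.Series(ts.labels).value_counts()
    empty = [c for c in ts.classes if c not in counts.index]
    if empty:
        raise DataError(f"classes with zero training cells: {empty}")
    members = [
        _fit_member(ts.X, ts.labels, cfg, seed=cfg.seed + i) for i in range(cfg.n_inits)
    ]
    return EnsemblePhenotypeClassifier(
        marker=ts.marker,
        classes=tuple(ts.classes),
        members=members,
        none_threshold=cfg.none_threshold(len(ts.classes)),
        n_features=ts.X.shape[1],
    )


def classify_cells(
    data: FeatureTable | np.ndarray,
    model: EnsemblePhenotypeClassifier,
    cell_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Assign each good cell a phenotype class (or "None") with mean probabilities.

    Returns a DataFrame with ``cell_id``, one probability column per class,
    ``max_prob`` and ``assigned``. The assigned class is the argmax of the
    mean probabilities (ties broken by lowest class index) unless
    ``max_prob`` is strictly below the model's 2/N threshold, in which case
    the cell goes to "None".
    """
    if isinstance(data, FeatureTable):
        good = data.good_cells()
        X = good[list(data.schema.feature_names)].to_numpy(dtype=float)
        ids = good["cell_id"].to_numpy()
    else:
        X = np.asarray(data, dtype=float)
        ids = np.asarray(cell_ids) if cell_ids is not None else np.arange(len(X))
    probs = model.predict_proba(X)
    max_prob = probs.max(axis=1)
    assigned = np.array(model.classes, dtype=object)[probs.argmax(axis=1)]
    assigned[max_prob < model.none_threshold] = NONE_CLASS
    out = pd.DataFrame(probs, columns=[f"prob_{c}" for c in model.classes])
    out.insert(0, "cell_id", ids)
    out["max_prob"] = max_prob
    out["assigned"] = assigned
    return out
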