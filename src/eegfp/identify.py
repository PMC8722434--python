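"""Subject identification from connectivity features.

Closed-set identification with a one-against-one RBF-kernel SVM (one binary
classifier per subject pair, majority vote), on z-scored features.  Two
evaluation designs:

* intra-session: stratified ten-fold cross-validation within one session —
  how *specific* each subject's connectivity is;
* cross-session: train on session A, test on each later session in
  nominal-day order — how *permanent* the fingerprint is over time.

Accuracy is pooled epoch-level (correct epochs / total epochs).
Standardisation parameters and hyperparameters are always derived from
training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .connectivity import features_to_matrix

__all__ = [
    "IdentifierModel",
    "PermanenceResult",
    "train_identifier",
    "intra_session_cv",
    "cross_session_eval",
]

DEFAULT_C = 1.0
GRID_C = (0.1, 1.0, 10.0)


@dataclass
class IdentifierModel:
    """A fitted scaler + one-against-one RBF-SVM identifier."""

    pipeline: Pipeline
    classes: np.ndarray

    def predict(self, x) -> np.ndarray:
        return self.pipeline.predict(np.asarray(x, dtype=float))

    def score(self, x, labels) -> float:
        return float(np.mean(self.predict(x) == np.asarray(labels)))


@dataclass
class PermanenceResult:
    """Cross-session identification accuracies, in nominal-day order."""

    train_session: str
    per_session_accuracy: dict
    index_kind: str
    n_subjects: int
    seed: int
    confusion: dict = field(default_factory=dict)

    def accuracies(self) -> np.ndarray:
        return np.array(list(self.per_session_accuracy.values()))


def _make_pipeline(c: float) -> Pipeline:
    # gamma="scale" = 1 / (n_features * Var(X)); OAO voting is SVC's native
    # multiclass strategy
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=c, gamma="scale")),
        ]
    )


def train_identifier(
    features,
    *,
    c: float = DEFAULT_C,
    grid_search: bool = False,
    seed: int = 0,
) -> IdentifierModel:
    """Fit the identifier on feature records (or on (X, labels) directly).

    ``grid_search=True`` picks C from a small grid by 3-fold CV inside the
    training data.  The fit is deterministic given its inputs.
    """
    if isinstance(features, tuple):
        x, labels = features
        x = np.asarray(x, dtype=float)
        labels = np.asarray(labels)
    else:
        x, labels, _ = features_to_matrix(features)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 subjects to train an identifier")
    counts = np.array([(labels == cl).sum() for cl in classes])
    if counts.min() < 2:
        raise ValueError("every subject needs at least 2 epochs")
    if grid_search:
        inner = StratifiedKFold(3, shuffle=True, random_state=seed)
        search = GridSearchCV(
            _make_pipeline(DEFAULT_C), {"svm__C": list(GRID_C)}, cv=inner
        )
        search.fit(x, labels)
        pipe = search.best_estimator_
    else:
        pipe = _make_pipeline(c)
        pipe.fit(x, labels)
    return IdentifierModel(pipeline=pipe, classes=classes)


def intra_session_cv(
    features,
    k: int = 10,
    *,
    c: float = DEFAULT_C,
    grid_search: bool = False,
    seed: int = 0,
) -> float:
    """Stratified k-fold CV accuracy within one session (pooled over folds)."""
    x, labels, sessions = features_to_matrix(features)
    if np.unique(sessions).size > 1:
        raise ValueError(
            f"features span sessions {sorted(set(sessions))}; "
            "intra_session_cv expects one"
        )
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        short = classes[counts < k].tolist()
        raise ValueError(f"subjects {short} have fewer than k={k} epochs")
    folds = StratifiedKFold(k, shuffle=True, random_state=seed)
    correct = total = 0
    for train_idx, test_idx in folds.split(x, labels):
        model = train_identifier(
            (x[train_idx], labels[train_idx]),
            c=c, grid_search=grid_search, seed=seed,
        )
        pred = model.predict(x[test_idx])
        correct += int((pred == labels[test_idx]).sum())
        total += test_idx.size
    return correct / total


def cross_session_eval(
    train_features,
    test_features_by_session: dict,
    *,
    session_days: dict | None = None,
    c: float = DEFAULT_C,
    grid_search: bool = False,
    seed: int = 0,
) -> PermanenceResult:
    """Train on one session, score each test session in nominal-day order.

    ``test_features_by_session`` maps session label -> feature records.
    The scaler and hyperparameters come from the training session only.
    """
    x_train, y_train, sess_train = features_to_matrix(train_features)
    train_session = str(sess_train[0])
    train_subjects = set(np.unique(y_train))
    kind = train_features[0].kind

    if session_days is None:
        from .cohort import SESSION_DAYS

        session_days = SESSION_DAYS
    order = sorted(
        test_features_by_session, key=lambda s: session_days.get(s, float("inf"))
    )

    model = train_identifier((x_train, y_train), c=c, grid_search=grid_search, seed=seed)
    accuracies, confusions = {}, {}
    for sess in order:
        x_test, y_test, _ = features_to_matrix(test_features_by_session[sess])
        if set(np.unique(y_test)) != train_subjects:
            raise ValueError(
                f"session {sess!r} subject set differs from training session"
            )
        if x_test.shape[1] != x_train.shape[1]:
            raise ValueError("feature length mismatch between train and test")
        pred = model.predict(x_test)
        accuracies[sess] = float(np.mean(pred == y_test))
        confusions[sess] = confusion_matrix(y_test, pred, labels=model.classes)
    return PermanenceResult(
        train_session=train_session,
        per_session_accuracy=accuracies,
        index_kind=kind,
        n_subjects=len(train_subjects),
        seed=seed,
        confusion=confusions,
    )
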