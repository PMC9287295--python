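"""Text classifiers for statin use/nonuse and reasons for nonuse.

Three models operate on the statin-mention document:

* a binary classifier separating documented statin use from nonuse;
* a two-step multiclass classifier for the reason for nonuse — five
  one-vs-rest probability models whose 5-vector of probabilities is
  reconciled to a single final category by a random-forest ensemble;
* a simple multilabel classifier — the same five heads read independently
  with a 0.5 threshold per head.

All three are written against a pluggable :class:`EncoderBackend` contract so
the text representation can be swapped (e.g. for a fine-tuned contextual
encoder) without touching the pipeline.  The default backend is fully
self-contained: lowercased word 1–2-gram TF-IDF features feeding a linear
model trained by SGD on the logistic loss, where the learning rate, epoch
count, and weight decay hyperparameters map directly onto the SGD schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import HashingVectorizer, TfidfTransformer, TfidfVectorizer
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline

from .taxonomy import Reason, REASON_ORDER, primary_reason


@dataclass(frozen=True)
class Hyperparameters:
    """Training hyperparameters.

    ``learning_rate``, ``n_epochs`` and ``weight_decay`` control the SGD
    schedule of the default backend (initial step size, passes over the data,
    L2 penalty).  ``adam_epsilon`` is carried for backends with an Adam
    optimizer and is ignored by SGD-trained backends.
    """

    learning_rate: float = 0.5
    n_epochs: int = 150
    weight_decay: float = 1e-5
    adam_epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "weight_decay", "adam_epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


class EncoderBackend(Protocol):
    """Contract for a text scoring backend: fit on texts and binary labels,
    then produce P(positive) per text; deterministic given the seed."""

    name: str

    def fit(self, texts: Sequence[str], labels: Sequence[int], hp: Hyperparameters):
        ...


class _SklearnProbModel:
    """A fitted backend head exposing ``score(texts) -> P(positive)``."""

    def __init__(self, pipeline: Pipeline, positive_index: int):
        self._pipeline = pipeline
        self._pos = positive_index

    def score(self, texts: Sequence[str]) -> np.ndarray:
        _check_texts(texts)
        return self._pipeline.predict_proba(list(texts))[:, self._pos]


class _ConstantProbModel:
    """Degenerate head used when a cross-validation fold has one class."""

    def __init__(self, p: float):
        self._p = float(p)

    def score(self, texts: Sequence[str]) -> np.ndarray:
        return np.full(len(texts), self._p)


def _check_texts(texts: Sequence[str]) -> None:
    for t in texts:
        if not str(t).strip():
            raise ValueError("empty document text")


def _sgd(hp: Hyperparameters) -> SGDClassifier:
    return SGDClassifier(
        loss="log_loss",
        penalty="l2",
        alpha=hp.weight_decay,
        learning_rate="adaptive",
        eta0=hp.learning_rate,
        max_iter=hp.n_epochs,
        tol=None,
        shuffle=True,
        random_state=hp.seed,
    )


class TfidfLinearBackend:
    """Default self-contained backend: word 1–2-gram TF-IDF + SGD logistic."""

    name = "fallback"

    def fit(self, texts, labels, hp: Hyperparameters) -> _SklearnProbModel:
        _check_texts(texts)
        pipe = Pipeline([
            ("tfidf", TfidfVectorizer(lowercase=True, ngram_range=(1, 2),
                                      sublinear_tf=True)),
            ("clf", _sgd(hp)),
        ])
        pipe.fit(list(texts), np.asarray(labels))
        classes = list(pipe.named_steps["clf"].classes_)
        return _SklearnProbModel(pipe, classes.index(max(classes)))


class HashingLinearBackend:
    """Alternative self-contained backend (hashed word n-grams); exists to
    exercise the backend-swap contract."""

    name = "hashing"

    def fit(self, texts, labels, hp: Hyperparameters) -> _SklearnProbModel:
        _check_texts(texts)
        pipe = Pipeline([
            ("hash", HashingVectorizer(lowercase=True, ngram_range=(1, 2),
                                       n_features=2**18, alternate_sign=False)),
            ("tfidf", TfidfTransformer(sublinear_tf=True)),
            ("clf", _sgd(hp)),
        ])
        pipe.fit(list(texts), np.asarray(labels))
        classes = list(pipe.named_steps["clf"].classes_)
        return _SklearnProbModel(pipe, classes.index(max(classes)))


class PretrainedEncoderBackend:
    """Adapter slot for a fine-tuned contextual encoder (e.g. a clinical
    BERT variant).  Requires the optional ``transformers``/``torch`` stack;
    raises at construction when it is unavailable."""

    name = "pretrained"

    def __init__(self, model_name: str = "emilyalsentzer/Bio_ClinicalBERT"):
        try:
            import torch  # noqa: F401
            import transformers  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the 'pretrained' backend requires torch and transformers"
            ) from exc
        self.model_name = model_name  # pragma: no cover

    def fit(self, texts, labels, hp: Hyperparameters):  # pragma: no cover
        raise NotImplementedError(
            "fine-tuning hook: plug a sequence-classification head here"
        )


_BACKENDS = {
    "fallback": TfidfLinearBackend,
    "hashing": HashingLinearBackend,
    "pretrained": PretrainedEncoderBackend,
}


def get_backend(name: str) -> EncoderBackend:
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise ValueError(f"unknown backend {name!r}; choose from {sorted(_BACKENDS)}")


class BackendCvModel:
    """Adapter giving a backend the fit/score surface the cross-validated
    hyperparameter search expects."""

    def __init__(self, hp: Hyperparameters, backend_name: str = "fallback"):
        self.hp = hp
        self.backend_name = backend_name
        self._head = None

    def fit(self, texts, labels):
        self._head = get_backend(self.backend_name).fit(texts, labels, self.hp)
        return self

    def score_texts(self, texts):
        return self._head.score(texts)


# ---------------------------------------------------------------------------
# Binary use/nonuse model


@dataclass
class BinaryUseModel:
    backend_name: str
    hp: Hyperparameters
    head: object  # fitted backend head; score() -> P(USE_DOCUMENTED)


def fit_binary_use(
    texts: Sequence[str],
    use_labels: Sequence[int],
    hp: Hyperparameters | None = None,
    backend: EncoderBackend | None = None,
) -> BinaryUseModel:
    """Fit the binary classifier: documented use (label 1, positive) vs
    nonuse (label 0)."""
    hp = hp or Hyperparameters()
    backend = backend or TfidfLinearBackend()
    y = np.asarray(use_labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("degenerate training set: only one class present")
    if len(texts) != len(y):
        raise ValueError("texts and labels differ in length")
    return BinaryUseModel(backend.name, hp, backend.fit(texts, y, hp))


def predict_use(model: BinaryUseModel, text: str) -> float:
    """P(USE_DOCUMENTED) for one mention document; the final label is USE
    when the probability is >= 0.5."""
    if not str(text).strip():
        raise ValueError("empty document text")
    return float(model.head.score([text])[0])


def predict_use_batch(model: BinaryUseModel, texts: Sequence[str]) -> np.ndarray:
    _check_texts(texts)
    return model.head.score(list(texts))


# ---------------------------------------------------------------------------
# Two-step reason model: one-vs-rest heads + random-forest reconciler


def _labels_matrix(reason_labels: Sequence) -> np.ndarray:
    """(n, 5) 0/1 matrix in canonical category order; multi-category
    annotations are positive for each of their categories."""
    mat = np.zeros((len(reason_labels), len(REASON_ORDER)), dtype=int)
    for i, labels in enumerate(reason_labels):
        labset = {Reason(l) for l in labels}
        if not labset:
            raise ValueError(f"annotation {i} has no reason category")
        for j, r in enumerate(REASON_ORDER):
            mat[i, j] = int(r in labset)
    return mat


def _check_all_categories(mat: np.ndarray) -> None:
    missing = [r.value for j, r in enumerate(REASON_ORDER) if mat[:, j].sum() == 0]
    if missing:
        raise ValueError(f"categories absent from training labels: {missing}")


def _fit_ovr_heads(texts, mat, hp, backend) -> list:
    heads = []
    for j, r in enumerate(REASON_ORDER):
        y = mat[:, j]
        if len(set(y.tolist())) < 2:
            heads.append(_ConstantProbModel(float(y.mean())))
        else:
            heads.append(backend.fit(texts, y, replace(hp, seed=hp.seed + j)))
    return heads


def _score_heads(heads, texts) -> np.ndarray:
    return np.column_stack([h.score(list(texts)) for h in heads])


@dataclass
class TwoStepReasonModel:
    backend_name: str
    hp: Hyperparameters
    heads: list            # five one-vs-rest probability heads
    reconciler: RandomForestClassifier
    classes: tuple[Reason, ...]


def fit_two_step(
    texts: Sequence[str],
    reason_labels: Sequence,
    hp: Hyperparameters | None = None,
    backend: EncoderBackend | None = None,
    oof_folds: int = 5,
) -> TwoStepReasonModel:
    """Fit the two-step reason classifier.

    Stage 1 fits five independent one-vs-rest heads (multi-category
    annotations count as positive for each category).  Stage 2 fits a random
    forest on *out-of-fold* stage-1 probability vectors against the primary
    annotated category, so the reconciler never sees optimistically in-sample
    probabilities.
    """
    hp = hp or Hyperparameters()
    backend = backend or TfidfLinearBackend()
    _check_texts(texts)
    mat = _labels_matrix(reason_labels)
    _check_all_categories(mat)
    primary = np.array([primary_reason(l).value for l in reason_labels])

    texts = list(texts)
    n = len(texts)
    min_class = int(np.unique(primary, return_counts=True)[1].min())
    k = max(2, min(oof_folds, min_class))
    oof = np.zeros((n, len(REASON_ORDER)))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=hp.seed)
    for tr, va in skf.split(np.zeros(n), primary):
        fold_heads = _fit_ovr_heads([texts[i] for i in tr], mat[tr], hp, backend)
        oof[va] = _score_heads(fold_heads, [texts[i] for i in va])

    reconciler = RandomForestClassifier(n_estimators=300, random_state=hp.seed)
    reconciler.fit(oof, primary)
    heads = _fit_ovr_heads(texts, mat, hp, backend)
    classes = tuple(Reason(c) for c in reconciler.classes_)
    return TwoStepReasonModel(backend.name, hp, heads, reconciler, classes)


def _argmax_in_order(probs: np.ndarray, classes: Sequence[Reason]) -> Reason:
    # ties broken by the canonical category order, not array position
    best = probs.max()
    tied = [c for c, p in zip(classes, probs) if p == best]
    for r in REASON_ORDER:
        if r in tied:
            return r
    raise AssertionError("unreachable")


def predict_reason_two_step(
    model: TwoStepReasonModel, text: str
) -> tuple[Reason, np.ndarray]:
    """Predict the single final reason and return the stage-1 5-vector."""
    if not str(text).strip():
        raise ValueError("empty document text")
    probs5 = _score_heads(model.heads, [text])[0]
    rf_probs = model.reconciler.predict_proba(probs5.reshape(1, -1))[0]
    return _argmax_in_order(rf_probs, model.classes), probs5


def predict_reason_two_step_batch(
    model: TwoStepReasonModel, texts: Sequence[str]
) -> tuple[list[Reason], np.ndarray]:
    _check_texts(texts)
    probs5 = _score_heads(model.heads, list(texts))
    rf_probs = model.reconciler.predict_proba(probs5)
    finals = [_argmax_in_order(row, model.classes) for row in rf_probs]
    return finals, probs5


# ---------------------------------------------------------------------------
# Simple multilabel model: the five heads read independently


@dataclass
class MultilabelReasonModel:
    backend_name: str
    hp: Hyperparameters
    heads: list
    threshold: float = 0.5

    def predict(self, texts: Sequence[str]) -> tuple[np.ndarray, list[tuple[Reason, ...]]]:
        """Per-document 5 probabilities and the thresholded label set; an
        empty set falls back to the argmax head."""
        _check_texts(texts)
        probs = _score_heads(self.heads, list(texts))
        sets: list[tuple[Reason, ...]] = []
        for row in probs:
            chosen = [r for r, p in zip(REASON_ORDER, row) if p >= self.threshold]
            if not chosen:
                chosen = [_argmax_in_order(row, REASON_ORDER)]
            sets.append(tuple(chosen))
        return probs, sets


def fit_multilabel(
    texts: Sequence[str],
    reason_labels: Sequence,
    hp: Hyperparameters | None = None,
    backend: EncoderBackend | None = None,
) -> MultilabelReasonModel:
    hp = hp or Hyperparameters()
    backend = backend or TfidfLinearBackend()
    _check_texts(texts)
    mat = _labels_matrix(reason_labels)
    _check_all_categories(mat)
    return MultilabelReasonModel(backend.name, hp, _fit_ovr_heads(list(texts), mat, hp, backend))


def fit_predict_multilabel(
    texts: Sequence[str],
    reason_labels: Sequence,
    hp: Hyperparameters | None = None,
    backend: EncoderBackend | None = None,
    predict_texts: Sequence[str] | None = None,
) -> tuple[MultilabelReasonModel, np.ndarray, list[tuple[Reason, ...]]]:
    """Fit the multilabel model and score ``predict_texts`` (defaults to the
    training documents)."""
    model = fit_multilabel(texts, reason_labels, hp, backend)
    probs, sets = model.predict(list(predict_texts if predict_texts is not None else texts))
    return model, probs, sets
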