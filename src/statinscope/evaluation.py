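"""Evaluation protocol and biostatistics.

Implements the study-style evaluation: a stratified 80/20 patient split,
10-fold cross-validated hyperparameter tuning on mean fold AUC, per-class and
support-weighted macro-averaged precision/recall/F1/AUC, percentile-bootstrap
confidence intervals, Cohen's kappa for annotator concordance, chi-square /
Fisher contingency tests, and unadjusted/adjusted logistic odds ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold, train_test_split
import statsmodels.api as sm


# ---------------------------------------------------------------------------
# Splits and tuning


@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple
    test_ids: tuple
    seed: int


def split_train_test(
    ids: Sequence, labels: Sequence, seed: int, train_frac: float = 0.8
) -> SplitPlan:
    """Stratified train/test split with train = floor(train_frac * n)."""
    ids = list(ids)
    if len(ids) < 5:
        raise ValueError(f"need at least 5 ids to split, got {len(ids)}")
    if len(ids) != len(labels):
        raise ValueError("ids and labels differ in length")
    train, test = train_test_split(
        ids,
        test_size=1.0 - train_frac,
        stratify=list(labels),
        random_state=seed,
        shuffle=True,
    )
    return SplitPlan(tuple(train), tuple(test), seed)


def cv_tune(
    X: Sequence,
    y: Sequence,
    grid: Sequence,
    model_factory: Callable,
    k: int = 10,
    seed: int = 0,
) -> tuple[object, dict]:
    """Grid search by k-fold cross-validated AUC.

    ``model_factory(hp)`` must return an object with ``fit(X, y)`` and a
    scoring method (``score_texts`` or ``predict_proba``).  Folds are
    stratified and identical across grid points; selection maximizes mean
    fold AUC, ties resolved by grid order.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    y = np.asarray(y)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    X = list(X)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(n), y))
    fold_scores: dict[int, list[float]] = {}
    for gi, hp in enumerate(grid):
        scores = []
        for tr, va in folds:
            model = model_factory(hp)
            model.fit([X[i] for i in tr], y[tr])
            s = model.score_texts([X[i] for i in va])
            if len(set(y[va].tolist())) < 2:
                continue
            scores.append(skm.roc_auc_score(y[va], s))
        fold_scores[gi] = scores
    means = [float(np.mean(fold_scores[gi])) if fold_scores[gi] else float("-inf")
             for gi in range(len(grid))]
    best = int(np.argmax(means))  # argmax keeps the first of tied maxima
    return grid[best], {
        "mean_auc": means,
        "fold_aucs": fold_scores,
        "best_index": best,
    }


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class MetricRow:
    precision: float
    recall: float
    f1: float
    auc: float  # NaN when undefined (single-class truth)
    n: int

    def as_dict(self) -> dict:
        return {
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "auc": self.auc, "n": self.n,
        }


def binary_metrics(
    truth: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> MetricRow:
    """Precision/recall/F1 at ``threshold`` plus rank-statistic AUC (ties
    credited 0.5).  AUC is NaN when only one class is present."""
    y = np.asarray(truth, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(y) == 0 or len(y) != len(s):
        raise ValueError("truth and scores must have equal positive length")
    pred = (s >= threshold).astype(int)
    precision = skm.precision_score(y, pred, zero_division=0)
    recall = skm.recall_score(y, pred, zero_division=0)
    f1 = skm.f1_score(y, pred, zero_division=0)
    auc = float("nan") if len(set(y.tolist())) < 2 else float(skm.roc_auc_score(y, s))
    return MetricRow(float(precision), float(recall), float(f1), auc, len(y))


@dataclass(frozen=True)
class EvalReport:
    """Per-class one-vs-rest metrics plus the support-weighted aggregate."""

    per_class: Mapping[str, MetricRow]
    weighted: MetricRow
    n: int

    def as_dict(self) -> dict:
        return {
            "per_class": {k: v.as_dict() for k, v in self.per_class.items()},
            "weighted": self.weighted.as_dict(),
            "n": self.n,
        }


def weighted_multiclass_metrics(
    truth: Sequence, proba: np.ndarray, classes: Sequence
) -> EvalReport:
    """One-vs-rest metrics per class, aggregated by support weighting.

    ``proba[:, j]`` scores class ``classes[j]``; the predicted label is the
    argmax (first class on exact ties).  The aggregate for every metric,
    including AUC, is the mean over classes weighted by class support; a
    class with zero support gets weight 0.
    """
    truth = np.asarray([str(t) for t in truth])
    classes = [str(c) for c in classes]
    proba = np.asarray(proba, dtype=float)
    present = [c for c in classes if (truth == c).any()]
    if len(present) < 2:
        raise ValueError("need at least two categories present in truth")
    pred_idx = proba.argmax(axis=1)
    pred = np.array([classes[i] for i in pred_idx])
    per_class: dict[str, MetricRow] = {}
    n = len(truth)
    weights, rows = [], []
    for j, c in enumerate(classes):
        y = (truth == c).astype(int)
        support = int(y.sum())
        p = (pred == c).astype(int)
        precision = skm.precision_score(y, p, zero_division=0)
        recall = skm.recall_score(y, p, zero_division=0)
        f1 = skm.f1_score(y, p, zero_division=0)
        auc = float("nan") if support in (0, n) else float(skm.roc_auc_score(y, proba[:, j]))
        row = MetricRow(float(precision), float(recall), float(f1), auc, support)
        per_class[c] = row
        weights.append(support / n)
        rows.append(row)
    def _wmean(attr: str) -> float:
        vals = [(getattr(r, attr), w) for r, w in zip(rows, weights) if w > 0]
        return float(sum(v * w for v, w in vals) / sum(w for _, w in vals))
    weighted = MetricRow(
        _wmean("precision"), _wmean("recall"), _wmean("f1"), _wmean("auc"), n
    )
    return EvalReport(per_class, weighted, n)


# ---------------------------------------------------------------------------
# Bootstrap confidence intervals


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    truth: Sequence,
    scores: Sequence,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for ``metric_fn(truth, scores)``.

    Resamples (truth, scores) pairs with replacement.  Resamples on which the
    metric is undefined (raises, or returns NaN — e.g. one-class AUC
    resamples) are redrawn; if undefined draws ever outnumber ``B``, the
    metric is considered undefined on the data and an error is raised.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    y = np.asarray(truth)
    s = np.asarray(scores)
    n = len(y)
    rng = np.random.default_rng(seed)
    values: list[float] = []
    bad = 0
    while len(values) < B:
        idx = rng.integers(0, n, size=n)
        try:
            v = float(metric_fn(y[idx], s[idx]))
        except Exception:
            v = float("nan")
        if np.isnan(v):
            bad += 1
            if bad > B:
                raise ValueError("metric undefined on more than half of resamples")
            continue
        values.append(v)
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Agreement and contingency statistics


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa from the contingency marginals.

    Returns 1.0 on perfect agreement even when chance agreement is also 1
    (single shared label); NaN when chance agreement is 1 without perfect
    observed agreement.
    """
    a = np.asarray([str(x) for x in labels_a])
    b = np.asarray([str(x) for x in labels_b])
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("label vectors must be nonempty and equal length")
    labels = sorted(set(a) | set(b))
    index = {l: i for i, l in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    n = table.sum()
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if p_o == 1.0:
        return 1.0
    if p_e == 1.0:
        return float("nan")
    return float((p_o - p_e) / (1 - p_e))


@dataclass(frozen=True)
class ContingencyResult:
    statistic: float
    p_value: float
    method: str  # "chi2" | "fisher" | "chi2_small_expected"


def contingency_test(table: np.ndarray | Sequence[Sequence[int]]) -> ContingencyResult:
    """Pearson chi-square (no continuity correction), switching to Fisher's
    exact test for 2x2 tables with any expected count < 5.  Larger tables
    with small expected counts keep the chi-square but are flagged."""
    t = np.asarray(table, dtype=float)
    if t.sum() <= 0:
        raise ValueError("contingency table total must be positive")
    chi2, p, dof, expected = stats.chi2_contingency(t, correction=False)
    if (expected < 5).any():
        if t.shape == (2, 2):
            odds, p_f = stats.fisher_exact(t, alternative="two-sided")
            return ContingencyResult(float(odds), float(p_f), "fisher")
        warnings.warn("expected count < 5 in a non-2x2 table; chi-square may be unreliable")
        return ContingencyResult(float(chi2), float(p), "chi2_small_expected")
    return ContingencyResult(float(chi2), float(p), "chi2")


# ---------------------------------------------------------------------------
# Logistic odds ratios


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise ValueError(f"logistic fit failed for covariates {list(X.columns)}: {exc}")
    if not np.isfinite(res.params).all() or (np.abs(res.params[1:]) > 20).any():
        offender = X.columns[int(np.abs(res.params[1:]).argmax())]
        raise ValueError(f"perfect separation detected for covariate {offender!r}")
    ci = res.conf_int()
    out = pd.DataFrame({
        "odds_ratio": np.exp(res.params),
        "ci_lower": np.exp(ci[0]),
        "ci_upper": np.exp(ci[1]),
    })
    return out.drop(index="const")


def logistic_or(
    outcome: Sequence[int], covariates: pd.DataFrame
) -> pd.DataFrame:
    """Unadjusted and adjusted odds ratios with Wald 95% CIs.

    Unadjusted ORs come from one single-covariate logistic fit per column;
    adjusted ORs from the joint multivariable fit.  Constant covariates are
    dropped with a warning; perfect separation raises, naming the covariate.
    """
    y = np.asarray(outcome, dtype=int)
    if set(y.tolist()) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    X = pd.DataFrame(covariates).astype(float)
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than covariates")
    keep = []
    for c in X.columns:
        if X[c].nunique() <= 1:
            warnings.warn(f"dropping constant covariate {c!r}")
        else:
            keep.append(c)
    X = X[keep]
    if X.empty:
        raise ValueError("no non-constant covariates to fit")
    unadj = pd.concat([_fit_logit(y, X[[c]]) for c in X.columns])
    adj = _fit_logit(y, X)
    return pd.DataFrame({
        "or_unadjusted": unadj["odds_ratio"],
        "or_unadjusted_lo": unadj["ci_lower"],
        "or_unadjusted_hi": unadj["ci_upper"],
        "or_adjusted": adj["odds_ratio"],
        "or_adjusted_lo": adj["ci_lower"],
        "or_adjusted_hi": adj["ci_upper"],
    })
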