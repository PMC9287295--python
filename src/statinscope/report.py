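"""Cohort-level reporting: apply trained models across the NLP dataset,
cross-tabulate predicted reasons by stratum, and format the outputs with
small-cell suppression.

Counts at or below the suppression minimum are collapsed into a pooled
column, mirroring privacy rules that forbid reporting small groups; pooling
never changes a table's grand total.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import ContingencyResult, contingency_test
from .taxonomy import Reason, REASON_ORDER

POOLED_LABEL = "POOLED_SMALL_CELLS"


def percent(numerator: int, denominator: int, decimals: int = 1) -> str:
    """Format ``100*numerator/denominator`` rounded half-up, e.g. "81.7%"."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be within [0, denominator]")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(q, ROUND_HALF_UP)
    return f"{value}%"


@dataclass(frozen=True)
class PatientPrediction:
    patient_id: str
    use_probability: float
    use_label: str  # "USE_DOCUMENTED" | "NONUSE"
    final_reason: Reason | None = None
    reason_probabilities: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        nonuse = self.use_label == "NONUSE"
        if nonuse != (self.final_reason is not None):
            raise ValueError(
                f"{self.patient_id}: reason fields present iff label is NONUSE"
            )


def apply_pipeline(
    bundles: Sequence,
    binary_model,
    two_step_model,
    dictionary,
) -> list[PatientPrediction]:
    """Run the trained models over every NLP-dataset patient.

    Each bundle is routed through the cascade; patients in the NLP dataset
    get a use probability and, when classified as nonusers, a final reason.
    A NLP-dataset patient without a buildable mention document is a pipeline
    inconsistency and raises with the offending patient ids.
    """
    from .cohort import Bucket, classify_disposition
    from .models import predict_reason_two_step_batch, predict_use_batch
    from .notes import build_mention_document

    nlp_ids: list[str] = []
    docs: list[str] = []
    missing: list[str] = []
    for b in bundles:
        disp = classify_disposition(b, dictionary)
        if disp.bucket is not Bucket.NLP_DATASET:
            continue
        doc = build_mention_document(b.notes, disp.index.index_date, dictionary)
        if doc is None:
            missing.append(b.patient_id)
            continue
        nlp_ids.append(b.patient_id)
        docs.append(doc.text)
    if missing:
        raise ValueError(f"missing mention documents for patients: {missing}")
    if not nlp_ids:
        return []
    use_p = predict_use_batch(binary_model, docs)
    nonuse_idx = [i for i, p in enumerate(use_p) if p < 0.5]
    reasons: dict[int, tuple[Reason, np.ndarray]] = {}
    if nonuse_idx:
        finals, probs5 = predict_reason_two_step_batch(
            two_step_model, [docs[i] for i in nonuse_idx]
        )
        reasons = {i: (f, p) for i, f, p in zip(nonuse_idx, finals, probs5)}
    preds: list[PatientPrediction] = []
    for i, pid in enumerate(nlp_ids):
        if i in reasons:
            final, p5 = reasons[i]
            preds.append(PatientPrediction(pid, float(use_p[i]), "NONUSE",
                                           final, tuple(float(x) for x in p5)))
        else:
            preds.append(PatientPrediction(pid, float(use_p[i]), "USE_DOCUMENTED"))
    return preds


@dataclass(frozen=True)
class StratifiedTable:
    """Reason-by-stratum counts with column percentages and a chi-square p."""

    counts: pd.DataFrame           # rows = strata, columns = reason categories
    column_percents: pd.DataFrame  # formatted strings, percent of column total
    test: ContingencyResult

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def stratify_reasons(
    predictions: Sequence[PatientPrediction],
    strata: Mapping[str, str],
    known_strata: Sequence[str] | None = None,
) -> StratifiedTable:
    """Cross-tabulate predicted final reasons by stratum.

    ``strata`` maps patient id to a stratum label; labels outside
    ``known_strata`` (when given) are bucketed as OTHER.  Percentages are by
    column (share of each reason across strata); association is tested with
    the chi-square/Fisher rule.
    """
    nonusers = [p for p in predictions if p.use_label == "NONUSE"]
    if not nonusers:
        raise ValueError("no nonuser predictions to stratify")
    rows: dict[tuple[str, str], int] = {}
    labels_seen: list[str] = []
    for p in nonusers:
        label = strata.get(p.patient_id, "OTHER")
        if known_strata is not None and label not in known_strata:
            label = "OTHER"
        if label not in labels_seen:
            labels_seen.append(label)
        key = (label, p.final_reason.value)
        rows[key] = rows.get(key, 0) + 1
    row_order = list(known_strata) if known_strata is not None else sorted(labels_seen)
    if "OTHER" in labels_seen and "OTHER" not in row_order:
        row_order.append("OTHER")
    row_order = [r for r in row_order if r in labels_seen]
    cols = [r.value for r in REASON_ORDER]
    counts = pd.DataFrame(
        [[rows.get((s, c), 0) for c in cols] for s in row_order],
        index=row_order, columns=cols, dtype=int,
    )
    col_totals = counts.sum(axis=0)
    pct = counts.copy().astype(object)
    for c in cols:
        for s in row_order:
            pct.loc[s, c] = (
                percent(int(counts.loc[s, c]), int(col_totals[c]), 1)
                if col_totals[c] > 0 else ""
            )
    nz = counts.loc[:, (counts.sum(axis=0) > 0)]
    nz = nz.loc[nz.sum(axis=1) > 0, :]
    if nz.shape[0] >= 2 and nz.shape[1] >= 2:
        test = contingency_test(nz.to_numpy())
    else:
        test = ContingencyResult(float("nan"), float("nan"), "not_applicable")
    return StratifiedTable(counts, pct, test)


def suppress_small_cells(table: pd.DataFrame, minimum: int = 11) -> pd.DataFrame:
    """Collapse cells below ``minimum`` (i.e. <= minimum-1) into a pooled
    column, preserving row and grand totals."""
    t = table.copy()
    if not np.issubdtype(np.asarray(t.to_numpy()).dtype, np.integer):
        raise ValueError("suppression requires integer counts")
    mask = t < minimum
    if not mask.to_numpy().any():
        return t
    pooled = t.where(mask, 0).sum(axis=1)
    out = t.where(~mask, 0)
    out[POOLED_LABEL] = pooled.astype(int)
    return out
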