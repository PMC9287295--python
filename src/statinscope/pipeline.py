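"""End-to-end orchestration: simulate → cascade → extract → train →
evaluate → apply → report.

This module strings the library pieces together the way the CLI (and the
acceptance machinery) runs them, writing deterministic text artifacts at
every stage so a fixed seed yields byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from . import evaluation as ev
from .cohort import Bucket, CascadeTable, PatientBundle, cascade_accounting, classify_disposition
from .models import (
    Hyperparameters,
    fit_binary_use,
    fit_multilabel,
    fit_two_step,
    get_backend,
    predict_use_batch,
)
from .notes import StatinDictionary, build_mention_document, default_dictionary
from .report import (
    PatientPrediction,
    apply_pipeline,
    percent,
    stratify_reasons,
    suppress_small_cells,
)
from .synthetic_ehr import SimConfig, TruthRecord, generate_bundle, read_bundle, write_bundle
from .taxonomy import Reason, REASON_ORDER, UseStatus, primary_reason


def _round(x: float, nd: int = 6) -> float | None:
    """Round for stable serialization; non-finite values become None/null."""
    return float(round(float(x), nd)) if np.isfinite(x) else None


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=False) + "\n",
                    encoding="utf-8")


def save_model(model, directory: str | Path, task: str) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, d / "model.joblib")
    _json_dump(
        {"task": task, "backend": model.backend_name, "hyperparameters": asdict(model.hp)},
        d / "meta.json",
    )


def load_model(directory: str | Path):
    return joblib.load(Path(directory) / "model.joblib")


def extract_documents(
    bundles: Sequence[PatientBundle], dictionary: StatinDictionary
) -> tuple[dict[str, str], dict[str, Bucket], dict[str, str]]:
    """Classify every bundle and build mention documents for the NLP dataset.

    Returns (patient_id -> document text, patient_id -> bucket,
    patient_id -> ASCVD category of the index diagnosis)."""
    docs: dict[str, str] = {}
    buckets: dict[str, Bucket] = {}
    ascvd: dict[str, str] = {}
    for b in bundles:
        disp = classify_disposition(b, dictionary)
        buckets[b.patient_id] = disp.bucket
        if disp.index is not None:
            ascvd[b.patient_id] = disp.index.ascvd_category.value
        if disp.bucket is Bucket.NLP_DATASET:
            doc = build_mention_document(b.notes, disp.index.index_date, dictionary)
            if doc is not None:
                docs[b.patient_id] = doc.text
    return docs, buckets, ascvd


def _ovr_weighted_auc(label_sets: Sequence, probs: np.ndarray) -> float:
    """Support-weighted one-vs-rest AUC against (possibly multi-label)
    annotation sets."""
    from sklearn.metrics import roc_auc_score

    aucs, weights = [], []
    for j, r in enumerate(REASON_ORDER):
        y = np.array([int(r in set(s)) for s in label_sets])
        if y.sum() in (0, len(y)):
            continue
        aucs.append(roc_auc_score(y, probs[:, j]))
        weights.append(y.sum())
    if not aucs:
        return float("nan")
    return float(np.average(aucs, weights=weights))


def _metric_block(row: ev.MetricRow, truth, scores, B: int, seed: int) -> dict:
    """Point metrics plus percentile-bootstrap CIs."""
    out = {"n": row.n}
    fns = {
        "precision": lambda y, s: ev.binary_metrics(y, s).precision,
        "recall": lambda y, s: ev.binary_metrics(y, s).recall,
        "f1": lambda y, s: ev.binary_metrics(y, s).f1,
        "auc": lambda y, s: ev.binary_metrics(y, s).auc,
    }
    for i, (name, fn) in enumerate(fns.items()):
        lo, hi = ev.bootstrap_ci(fn, truth, scores, B=B, seed=seed + i)
        out[name] = {
            "value": _round(getattr(row, name)),
            "ci_lower": _round(lo), "ci_upper": _round(hi),
        }
    return out


def run_end_to_end(
    n_patients: int,
    seed: int,
    out_dir: str | Path,
    bootstrap_B: int = 200,
    dictionary: StatinDictionary | None = None,
) -> dict:
    """Run the full pipeline on a synthetic cohort and write all report
    artifacts under ``out_dir``.  Returns the summary dict it wrote."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dictionary = dictionary or default_dictionary()

    # --- simulate -----------------------------------------------------------
    config = SimConfig(n_patients=n_patients, seed=seed)
    bundles, truths = generate_bundle(config)
    write_bundle(bundles, truths, out / "data")
    truth_by_id = {t.patient_id: t for t in truths}

    # --- cascade ------------------------------------------------------------
    docs, buckets, ascvd = extract_documents(bundles, dictionary)
    dispositions = [classify_disposition(b, dictionary) for b in bundles]
    cascade = cascade_accounting(dispositions)
    pd.DataFrame(
        [[r.label, r.count, r.denominator, r.percent] for r in cascade.rows],
        columns=["label", "count", "denominator", "percent"],
    ).to_csv(out / "cascade.csv", index=False)
    (out / "cascade.txt").write_text(cascade.to_text(), encoding="utf-8")
    pd.DataFrame(
        sorted((pid, b.value) for pid, b in buckets.items()),
        columns=["patient_id", "bucket"],
    ).to_csv(out / "dispositions.csv", index=False)
    with (out / "mention_docs.jsonl").open("w", encoding="utf-8") as fh:
        for pid in sorted(docs):
            fh.write(json.dumps({"patient_id": pid, "text": docs[pid]},
                                sort_keys=True) + "\n")

    # --- train on the annotated split --------------------------------------
    nlp_ids = sorted(docs)
    use_labels = {
        pid: int(truth_by_id[pid].true_use_status is UseStatus.USE_DOCUMENTED)
        for pid in nlp_ids
    }
    split = ev.split_train_test(nlp_ids, [use_labels[p] for p in nlp_ids], seed=seed)
    hp = Hyperparameters(seed=seed)
    train_ids, test_ids = list(split.train_ids), list(split.test_ids)
    binary = fit_binary_use([docs[p] for p in train_ids],
                            [use_labels[p] for p in train_ids], hp)

    def _nonusers(ids):
        return [p for p in ids
                if truth_by_id[p].true_use_status is UseStatus.NONUSE]

    train_nonusers, test_nonusers = _nonusers(train_ids), _nonusers(test_ids)
    reason_sets = {p: truth_by_id[p].true_reasons for p in train_nonusers + test_nonusers}
    two_step = fit_two_step([docs[p] for p in train_nonusers],
                            [reason_sets[p] for p in train_nonusers], hp)
    multilabel = fit_multilabel([docs[p] for p in train_nonusers],
                                [reason_sets[p] for p in train_nonusers], hp)
    save_model(binary, out / "models" / "use", "use")
    save_model(two_step, out / "models" / "reason_two_step", "reason-two-step")
    save_model(multilabel, out / "models" / "reason_multilabel", "reason-multilabel")

    # --- evaluate on the held-out test set ----------------------------------
    y_test = np.array([use_labels[p] for p in test_ids])
    s_test = predict_use_batch(binary, [docs[p] for p in test_ids])
    binary_row = ev.binary_metrics(y_test, s_test)
    report: dict = {
        "binary": _metric_block(binary_row, y_test, s_test, bootstrap_B, seed),
    }
    if test_nonusers:
        texts = [docs[p] for p in test_nonusers]
        primary = [primary_reason(reason_sets[p]).value for p in test_nonusers]
        from .models import predict_reason_two_step_batch

        _, probs5 = predict_reason_two_step_batch(two_step, texts)
        multi = ev.weighted_multiclass_metrics(primary, probs5,
                                               [r.value for r in REASON_ORDER])
        ml_probs, _ = multilabel.predict(texts)
        report["two_step"] = {
            "n": multi.n,
            "weighted": {k: _round(v) for k, v in multi.weighted.as_dict().items()},
            "per_class": {c: {k: _round(v) for k, v in r.as_dict().items()}
                          for c, r in multi.per_class.items()},
            "weighted_ovr_auc": _round(_ovr_weighted_auc(
                [reason_sets[p] for p in test_nonusers], probs5)),
        }
        report["multilabel"] = {
            "n": len(texts),
            "weighted_ovr_auc": _round(_ovr_weighted_auc(
                [reason_sets[p] for p in test_nonusers], ml_probs)),
        }
    report["split"] = {"n_train": len(train_ids), "n_test": len(test_ids)}
    _json_dump(report, out / "eval_report.json")

    # --- apply across the full NLP dataset ----------------------------------
    preds = apply_pipeline(bundles, binary, two_step, dictionary)
    pd.DataFrame(
        [[p.patient_id, f"{p.use_probability:.6f}", p.use_label,
          p.final_reason.value if p.final_reason else ""] for p in preds],
        columns=["patient_id", "use_probability", "use_label", "final_reason"],
    ).to_csv(out / "predictions.csv", index=False)

    nonusers = [p for p in preds if p.use_label == "NONUSE"]
    prevalence = {
        "n_nlp_dataset": len(preds),
        "n_use_documented": len(preds) - len(nonusers),
        "n_nonuse": len(nonusers),
    }
    if preds:
        prevalence["pct_use_documented"] = percent(
            prevalence["n_use_documented"], len(preds), 0)
    if nonusers:
        counts = {r.value: 0 for r in REASON_ORDER}
        for p in nonusers:
            counts[p.final_reason.value] += 1
        prevalence["reason_counts"] = counts
        prevalence["reason_percents"] = {
            k: percent(v, len(nonusers), 0) for k, v in counts.items()
        }
    _json_dump(prevalence, out / "reason_prevalence.json")

    if nonusers:
        race = {b.patient_id: b.race_ethnicity for b in bundles}
        for name, strata in (("ascvd", ascvd), ("race", race)):
            table = stratify_reasons(preds, strata)
            table.counts.to_csv(out / f"reasons_by_{name}.csv")
            suppress_small_cells(table.counts).to_csv(
                out / f"reasons_by_{name}_suppressed.csv")

    summary = {
        "cascade": {r.label: {"count": r.count, "denominator": r.denominator,
                              "percent": r.percent} for r in cascade.rows},
        "evaluation": report,
        "prevalence": prevalence,
    }
    _json_dump(summary, out / "summary.json")
    return summary
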