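"""Synthetic EHR generator with ground truth at every cascade stage.

The study population this package targets — ASCVD patients whose statin use
or nonuse is documented only in free-text notes — is private by nature, so
every downstream module is exercised on generated records.  The generator
draws a *true disposition* for each patient (which cascade bucket they should
land in) and then constructs structured events and notes that make that
disposition unambiguous:

* prescribed patients get a statin prescription satisfying the activity rule
  (including deliberate ±1-day boundary cases around the 30- and 183-day
  limits, and deliberately *inactive* statin prescriptions for other
  dispositions);
* allergy patients get a statin substance in the structured allergy field;
* note-screened patients get notes within 30 days of the index diagnosis
  whose sentences are drawn from reason-specific template families seeded by
  real chart language ("Declines statins", "intolerant of low dose statins
  (started with high CK)"), mixed with statin-free distractor sentences and,
  at a configurable rate, "nystatin"-style trap sentences that contain the
  substring "statin" without mentioning a statin.

Note text is template-based, not generative: the acceptance surface is label
recovery, so the ground truth must be exact.  One RNG stream is keyed by
(seed, patient index) so per-patient output is stable under reordering.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    AllergyRecord,
    AscvdCategory,
    ClinicalNote,
    DiagnosisEvent,
    ICD_ASCVD_MAP,
    PatientBundle,
    PrescriptionEvent,
)
from .taxonomy import Reason, REASON_ORDER, UseStatus


class TrueDisposition(str, enum.Enum):
    EXCLUDED_LT2 = "excluded_lt2"
    RX_PRESENT = "rx_present"
    STRUCTURED_ALLERGY = "structured_allergy"
    NO_STATIN_TERMS = "no_statin_terms"
    NLP_USE_DOCUMENTED = "nlp_use_documented"
    NLP_NONUSE = "nlp_nonuse"


DISPOSITION_ORDER: tuple[TrueDisposition, ...] = tuple(TrueDisposition)


def expected_bucket(disposition: TrueDisposition):
    """The cascade bucket the cohort module should assign for a given true
    disposition (both NLP dispositions land in the NLP dataset)."""
    from .cohort import Bucket

    return {
        TrueDisposition.EXCLUDED_LT2: Bucket.EXCLUDED_LT2,
        TrueDisposition.RX_PRESENT: Bucket.RX_PRESENT,
        TrueDisposition.STRUCTURED_ALLERGY: Bucket.STRUCTURED_ALLERGY,
        TrueDisposition.NO_STATIN_TERMS: Bucket.NO_STATIN_TERMS,
        TrueDisposition.NLP_USE_DOCUMENTED: Bucket.NLP_DATASET,
        TrueDisposition.NLP_NONUSE: Bucket.NLP_DATASET,
    }[disposition]

# Printed cohort-cascade counts used to derive the default disposition mix.
_ELIGIBLE = 56530
_RX_PRESENT = 34234
_ALLERGY = 788
_NO_TERMS = 17579
_NLP = 3929
_NLP_USERS = 1534
_NLP_NONUSERS = 2395
# Reason prevalence among NLP-identified nonusers (reason-category totals).
_REASON_TOTALS = {
    Reason.MUSCLE: 385,
    Reason.OTHER_SIDE_EFFECT: 404,
    Reason.PERCEIVED_LIPID_CONTROL: 274,
    Reason.PATIENT_PREFERENCE: 321,
    Reason.NONSPECIFIC: 1011,
}
#: fraction of screened patients failing the two-encounter engagement rule
_EXCLUDED_FRAC = 0.15


def default_disposition_mix() -> dict[TrueDisposition, float]:
    """Default mix: reported cascade proportions conditional on inclusion,
    scaled by the engagement-screen pass rate."""
    inc = 1.0 - _EXCLUDED_FRAC
    nlp = inc * _NLP / _ELIGIBLE
    mix = {
        TrueDisposition.EXCLUDED_LT2: _EXCLUDED_FRAC,
        TrueDisposition.RX_PRESENT: inc * _RX_PRESENT / _ELIGIBLE,
        TrueDisposition.STRUCTURED_ALLERGY: inc * _ALLERGY / _ELIGIBLE,
        TrueDisposition.NO_STATIN_TERMS: inc * _NO_TERMS / _ELIGIBLE,
        TrueDisposition.NLP_USE_DOCUMENTED: nlp * _NLP_USERS / _NLP,
        TrueDisposition.NLP_NONUSE: nlp * _NLP_NONUSERS / _NLP,
    }
    return mix


def default_reason_mix() -> dict[Reason, float]:
    total = sum(_REASON_TOTALS.values())
    return {r: _REASON_TOTALS[r] / total for r in REASON_ORDER}


def default_demographics_mix() -> dict[str, dict[str, float]]:
    return {
        "gender": {"female": 0.45, "male": 0.55},
        "race_ethnicity": {
            "Non-Hispanic White": 0.584,
            "Non-Hispanic Black": 0.058,
            "Hispanic": 0.096,
            "Non-Hispanic Asian": 0.136,
            "Other": 0.126,
        },
        "site": {"SHC": 0.50, "UHA": 0.44, "ValleyCare": 0.06},
        "ascvd_category": {
            "CORONARY": 0.40,
            "CEREBROVASCULAR": 0.25,
            "PERIPHERAL": 0.14,
            "POLYVASCULAR": 0.21,
        },
    }


@dataclass
class SimConfig:
    """Generator configuration.

    ``disposition_mix`` and ``reason_mix`` must each sum to 1; rates are
    probabilities.  Defaults reproduce the reported cascade and reason
    prevalences, so report-stage output on large n resembles the published
    cohort.
    """

    n_patients: int = 2000
    seed: int = 7
    disposition_mix: dict[TrueDisposition, float] = field(
        default_factory=default_disposition_mix
    )
    reason_mix: dict[Reason, float] = field(default_factory=default_reason_mix)
    distractor_rate: float = 3.0
    trap_rate: float = 0.15
    multi_reason_rate: float = 0.10
    demographics_mix: dict[str, dict[str, float]] = field(
        default_factory=default_demographics_mix
    )

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        for name, mix, keys in (
            ("disposition_mix", self.disposition_mix, set(TrueDisposition)),
            ("reason_mix", self.reason_mix, set(Reason)),
        ):
            if set(mix) != keys:
                raise ValueError(f"{name} keys must be exactly {sorted(k.value for k in keys)}")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{name} has negative probabilities")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {sum(mix.values())!r})")
        for name in ("trap_rate", "multi_reason_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.distractor_rate < 0:
            raise ValueError(f"distractor_rate must be >= 0, got {self.distractor_rate}")
        for key, dist in self.demographics_mix.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"demographics_mix[{key!r}] must sum to 1")


@dataclass(frozen=True)
class TruthRecord:
    patient_id: str
    true_disposition: TrueDisposition
    true_use_status: UseStatus
    true_reasons: tuple[Reason, ...] = ()

    def __post_init__(self) -> None:
        nonuse = self.true_use_status is UseStatus.NONUSE
        if nonuse != bool(self.true_reasons):
            raise ValueError(
                f"{self.patient_id}: true_reasons nonempty iff status is NONUSE"
            )
        nlp = self.true_disposition in (
            TrueDisposition.NLP_USE_DOCUMENTED,
            TrueDisposition.NLP_NONUSE,
        )
        if (self.true_use_status is UseStatus.NA) == nlp:
            raise ValueError(
                f"{self.patient_id}: use status NA iff disposition is not NLP-stage"
            )


# ---------------------------------------------------------------------------
# Template families.  Every reason/use template contains >=1 dictionary statin
# term; distractors contain none; traps contain "statin" only inside excluded
# tokens.  Reason families are seeded by real chart excerpts.

REASON_TEMPLATES: dict[Reason, tuple[str, ...]] = {
    Reason.MUSCLE: (
        "Intolerant of low dose statins (started with high CK).",
        "Statin discontinued due to myalgias and diffuse muscle aches.",
        "Stopped atorvastatin after muscle pain and elevated CK.",
        "Reports leg cramps on simvastatin; statin held for possible myopathy.",
    ),
    Reason.OTHER_SIDE_EFFECT: (
        "Has been intolerant to 3 different statin drugs... they cause diarrhea and nausea.",
        "Statin stopped due to elevated liver enzymes and transaminitis.",
        "Rosuvastatin caused nausea and GI upset, not restarted.",
        "Statin discontinued after headaches and memory complaints.",
    ),
    Reason.PERCEIVED_LIPID_CONTROL: (
        "If LDL < 100, no indication for statin at this time.",
        "LDL is well controlled, statin deferred.",
        "Lipid panel at goal, holding off on statin.",
        "Will recheck lipids; statin not indicated given LDL at goal.",
    ),
    Reason.PATIENT_PREFERENCE: (
        "Declines statins.",
        "Patient declines statin therapy despite extensive counseling.",
        "Patient refuses statin, prefers to avoid prescription medication.",
        "Not willing to start a statin, per patient preference.",
    ),
    Reason.NONSPECIFIC: (
        "OK for no statin at this time.",
        "Discuss statin next visit.",
        "No statin currently, will readdress at follow up.",
        "Statin not on med list, plan to revisit.",
    ),
}

USE_TEMPLATES: tuple[str, ...] = (
    "Continues atorvastatin 40 mg daily from outside pharmacy.",
    "Patient is on rosuvastatin 20 mg daily, tolerating well.",
    "Taking simvastatin nightly, filled at an outside pharmacy.",
    "On atorvastatin 40 mg daily per outside records.",
    "Compliant with statin therapy, refills are current.",
)

DISTRACTOR_TEMPLATES: tuple[str, ...] = (
    "Blood pressure well controlled on lisinopril.",
    "Continue aspirin 81 mg daily.",
    "Follow up in 3 months.",
    "A1c 7.2, continue metformin.",
    "Patient ambulating without difficulty.",
    "Echo shows preserved ejection fraction.",
    "Counseled on diet and exercise.",
    "No chest pain since last visit.",
    "Renal function stable.",
)

TRAP_TEMPLATES: tuple[str, ...] = (
    "Nystatin swish and swallow for oral thrush.",
    "Started nystatin powder for intertriginous rash.",
    "GI considering sandostatin for recurrent bleeding.",
)

_STATIN_DRUGS: tuple[tuple[str, str, tuple[int, ...]], ...] = (
    # (RxNorm-like code, generic name, plausible doses in mg)
    ("83367", "atorvastatin", (10, 20, 40, 80)),
    ("36567", "simvastatin", (10, 20, 40)),
    ("301542", "rosuvastatin", (5, 10, 20, 40)),
    ("42463", "pravastatin", (10, 20, 40, 80)),
    ("6472", "lovastatin", (20, 40)),
)

_OTHER_DRUGS: tuple[tuple[str, str], ...] = (
    ("1191", "aspirin"),
    ("29046", "lisinopril"),
    ("6809", "metformin"),
    ("6918", "metoprolol"),
)

_CODES_BY_CATEGORY: dict[AscvdCategory, tuple[str, ...]] = {
    cat: tuple(sorted(c for c, v in ICD_ASCVD_MAP.items() if v is cat))
    for cat in (
        AscvdCategory.CORONARY,
        AscvdCategory.CEREBROVASCULAR,
        AscvdCategory.PERIPHERAL,
    )
}

_BASE_DATE = date(2014, 1, 1)
_NOTE_TYPES = ("progress note", "discharge summary", "clinic letter", "consult note")


def _choice(rng: np.random.Generator, dist: Mapping) -> object:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _pick(rng: np.random.Generator, seq: Sequence):
    return seq[int(rng.integers(0, len(seq)))]


def _draw_reasons(rng: np.random.Generator, config: SimConfig) -> tuple[Reason, ...]:
    first = _choice(rng, config.reason_mix)
    reasons = {first}
    if len(config.reason_mix) > 1 and rng.random() < config.multi_reason_rate:
        rest = {r: p for r, p in config.reason_mix.items() if r is not first}
        reasons.add(_choice(rng, rest))
    return tuple(r for r in REASON_ORDER if r in reasons)


def _gen_diagnoses(
    rng: np.random.Generator,
    pid: str,
    index_date: date,
    category: str,
    excluded: bool,
) -> tuple[DiagnosisEvent, ...]:
    if category == "POLYVASCULAR":
        base = [AscvdCategory.CORONARY, AscvdCategory.CEREBROVASCULAR, AscvdCategory.PERIPHERAL]
        picks = rng.permutation(len(base))[:2]
        cats = [base[int(i)] for i in picks]
    else:
        cats = [AscvdCategory(category)]
    events = [DiagnosisEvent(pid, index_date, _pick(rng, _CODES_BY_CATEGORY[cats[0]]))]
    if excluded:
        # a single encounter date; same-day duplicates still count once
        if rng.random() < 0.3:
            events.append(
                DiagnosisEvent(pid, index_date, _pick(rng, _CODES_BY_CATEGORY[cats[0]]))
            )
        return tuple(events)
    n_more = int(rng.integers(1, 4))
    offsets = sorted(set(int(o) for o in rng.integers(7, 240, size=n_more)))
    if not offsets:
        offsets = [30]
    for k, off in enumerate(offsets):
        cat = cats[1] if (len(cats) > 1 and k == 0) else _pick(rng, cats)
        events.append(
            DiagnosisEvent(pid, index_date + timedelta(days=off), _pick(rng, _CODES_BY_CATEGORY[cat]))
        )
    if len(cats) > 1 and len(offsets) == 1:
        # guarantee the second base category appears for polyvascular truth
        events.append(
            DiagnosisEvent(pid, index_date + timedelta(days=offsets[0]),
                           _pick(rng, _CODES_BY_CATEGORY[cats[1]]))
        )
    return tuple(events)


def _active_statin_rx(
    rng: np.random.Generator, pid: str, index_date: date
) -> PrescriptionEvent:
    code, name, doses = _pick(rng, _STATIN_DRUGS)
    dose = int(_pick(rng, doses))
    clause = int(rng.integers(0, 6))
    if clause == 0:  # interval covers the index date
        start = index_date - timedelta(days=int(rng.integers(10, 300)))
        end = index_date + timedelta(days=int(rng.integers(10, 300)))
    elif clause == 1:  # new prescription shortly after the index date
        start = index_date + timedelta(days=int(rng.integers(1, 31)))
        end = start + timedelta(days=int(rng.integers(30, 365))) if rng.random() < 0.5 else None
    elif clause == 2:  # boundary: exactly 30 days after index
        start = index_date + timedelta(days=30)
        end = None
    elif clause == 3:  # open-ended, started within the lookback
        start = index_date - timedelta(days=int(rng.integers(0, 183)))
        end = None
    elif clause == 4:  # boundary: open-ended, exactly 183 days before index
        start = index_date - timedelta(days=183)
        end = None
    else:  # boundary: interval ending exactly on the index date
        start = index_date - timedelta(days=int(rng.integers(30, 300)))
        end = index_date
    return PrescriptionEvent(pid, code, name, start, end, dose)


def _inactive_statin_rx(
    rng: np.random.Generator, pid: str, index_date: date
) -> PrescriptionEvent:
    code, name, doses = _pick(rng, _STATIN_DRUGS)
    dose = int(_pick(rng, doses))
    variant = int(rng.integers(0, 6))
    if variant == 0:  # boundary: starts 31 days after index
        start = index_date + timedelta(days=31)
        end = None
    elif variant == 1:
        start = index_date + timedelta(days=int(rng.integers(32, 120)))
        end = None
    elif variant == 2:  # boundary: open-ended, 184 days before index
        start = index_date - timedelta(days=184)
        end = None
    elif variant == 3:
        start = index_date - timedelta(days=int(rng.integers(185, 400)))
        end = None
    elif variant == 4:  # boundary: ended the day before index
        end = index_date - timedelta(days=1)
        start = end - timedelta(days=int(rng.integers(30, 300)))
    else:
        end = index_date - timedelta(days=int(rng.integers(2, 200)))
        start = end - timedelta(days=int(rng.integers(30, 300)))
    return PrescriptionEvent(pid, code, name, start, end, dose)


def _other_rx(rng: np.random.Generator, pid: str, index_date: date) -> PrescriptionEvent:
    code, name = _pick(rng, _OTHER_DRUGS)
    start = index_date - timedelta(days=int(rng.integers(0, 400)))
    return PrescriptionEvent(pid, code, name, start, None, None)


def _compose_note(
    rng: np.random.Generator,
    pid: str,
    note_id: str,
    note_date: date,
    config: SimConfig,
    payload: Sequence[str],
    allow_trap: bool = True,
) -> ClinicalNote:
    n_distract = int(rng.poisson(config.distractor_rate))
    sentences = [str(_pick(rng, DISTRACTOR_TEMPLATES)) for _ in range(n_distract)]
    sentences.extend(payload)
    if allow_trap and rng.random() < config.trap_rate:
        sentences.append(str(_pick(rng, TRAP_TEMPLATES)))
    rng.shuffle(sentences)
    if not sentences:
        sentences = [str(_pick(rng, DISTRACTOR_TEMPLATES))]
    return ClinicalNote(
        note_id=note_id,
        patient_id=pid,
        date=note_date,
        note_type=str(_pick(rng, _NOTE_TYPES)),
        text=" ".join(sentences),
    )


def render_note(
    truth: TruthRecord,
    config: SimConfig,
    rng: np.random.Generator,
    index_date: date,
    note_id: str = "n0",
) -> ClinicalNote:
    """Render one in-window clinical note consistent with ``truth``.

    NONUSE patients get one template sentence per true reason; USE patients
    get a use-documentation sentence; NO_STATIN_TERMS patients get only
    distractors plus (at ``trap_rate``) a trap sentence.
    """
    disp = truth.true_disposition
    if disp in (TrueDisposition.EXCLUDED_LT2,):
        raise ValueError(f"disposition {disp.value} carries no note")
    note_date = index_date + timedelta(days=int(rng.integers(0, 29)))
    if truth.true_use_status is UseStatus.NONUSE:
        payload = [str(_pick(rng, REASON_TEMPLATES[r])) for r in truth.true_reasons]
    elif truth.true_use_status is UseStatus.USE_DOCUMENTED:
        payload = [str(_pick(rng, USE_TEMPLATES))]
        if rng.random() < 0.3:
            payload.append(str(_pick(rng, USE_TEMPLATES)))
    else:
        payload = []
    return _compose_note(rng, truth.patient_id, note_id, note_date, config, payload)


def _gen_patient(
    i: int, config: SimConfig
) -> tuple[PatientBundle, TruthRecord]:
    rng = np.random.default_rng([config.seed % (2**31), i])
    pid = f"P{i:06d}"
    disp = _choice(rng, config.disposition_mix)
    demo = {k: str(_choice(rng, v)) for k, v in config.demographics_mix.items()}
    index_date = _BASE_DATE + timedelta(days=int(rng.integers(0, 1800)))

    if disp is TrueDisposition.NLP_NONUSE:
        status, reasons = UseStatus.NONUSE, _draw_reasons(rng, config)
    elif disp is TrueDisposition.NLP_USE_DOCUMENTED:
        status, reasons = UseStatus.USE_DOCUMENTED, ()
    else:
        status, reasons = UseStatus.NA, ()
    truth = TruthRecord(pid, disp, status, reasons)

    diagnoses = _gen_diagnoses(
        rng, pid, index_date, demo["ascvd_category"],
        excluded=disp is TrueDisposition.EXCLUDED_LT2,
    )

    prescriptions: list[PrescriptionEvent] = []
    if disp is TrueDisposition.RX_PRESENT:
        prescriptions.append(_active_statin_rx(rng, pid, index_date))
    elif disp is not TrueDisposition.EXCLUDED_LT2 and rng.random() < 0.25:
        prescriptions.append(_inactive_statin_rx(rng, pid, index_date))
    if rng.random() < 0.5:
        prescriptions.append(_other_rx(rng, pid, index_date))

    allergies: list[AllergyRecord] = []
    if disp is TrueDisposition.STRUCTURED_ALLERGY:
        allergies.append(AllergyRecord(pid, _pick(rng, _STATIN_DRUGS)[1]))
    elif disp is TrueDisposition.RX_PRESENT and rng.random() < 0.05:
        # prescription screen precedes the allergy screen in the cascade
        allergies.append(AllergyRecord(pid, _pick(rng, _STATIN_DRUGS)[1]))
    if rng.random() < 0.08:
        allergies.append(AllergyRecord(pid, "penicillin"))
    if disp is not TrueDisposition.STRUCTURED_ALLERGY and rng.random() < 0.05:
        allergies.append(AllergyRecord(pid, "nystatin"))

    notes: list[ClinicalNote] = []
    if disp in (TrueDisposition.NLP_USE_DOCUMENTED, TrueDisposition.NLP_NONUSE):
        notes.append(render_note(truth, config, rng, index_date, note_id=f"{pid}-n0"))
        if rng.random() < 0.4:
            note_date = index_date + timedelta(days=int(rng.integers(0, 31)))
            notes.append(
                _compose_note(rng, pid, f"{pid}-n1", note_date, config, [])
            )
    elif disp is TrueDisposition.NO_STATIN_TERMS:
        for k in range(int(rng.integers(1, 4))):
            note_date = index_date + timedelta(days=int(rng.integers(0, 31)))
            notes.append(
                _compose_note(rng, pid, f"{pid}-n{k}", note_date, config, [])
            )
    elif disp in (TrueDisposition.RX_PRESENT, TrueDisposition.STRUCTURED_ALLERGY):
        note_date = index_date + timedelta(days=int(rng.integers(0, 31)))
        payload = []
        if rng.random() < 0.4:
            family = USE_TEMPLATES if disp is TrueDisposition.RX_PRESENT else \
                REASON_TEMPLATES[Reason.OTHER_SIDE_EFFECT]
            payload = [str(_pick(rng, family))]
        notes.append(
            _compose_note(rng, pid, f"{pid}-n0", note_date, config, payload)
        )

    bundle = PatientBundle(
        patient_id=pid,
        gender=demo["gender"],
        race_ethnicity=demo["race_ethnicity"],
        site=demo["site"],
        diagnoses=diagnoses,
        prescriptions=tuple(prescriptions),
        allergies=tuple(allergies),
        notes=tuple(notes),
    )
    return bundle, truth


def generate_bundle(
    config: SimConfig,
) -> tuple[list[PatientBundle], list[TruthRecord]]:
    """Generate ``config.n_patients`` patients with ground truth.

    Deterministic given ``config.seed``; each patient is drawn from an RNG
    stream keyed by (seed, patient index) so regeneration of any subset is
    stable.
    """
    bundles: list[PatientBundle] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_patients):
        b, t = _gen_patient(i, config)
        bundles.append(b)
        truths.append(t)
    return bundles, truths


# ---------------------------------------------------------------------------
# Flat-file round trip: CSV for structured tables, JSONL for notes and truth.

_PATIENT_COLS = ["patient_id", "gender", "race_ethnicity", "site"]
_DX_COLS = ["patient_id", "date", "code"]
_RX_COLS = ["patient_id", "drug_code", "drug_name", "start_date", "end_date", "dose_mg"]
_ALLERGY_COLS = ["patient_id", "substance"]


def _iso(d: date | None) -> str:
    return "" if d is None else d.isoformat()


def write_bundle(
    bundles: Sequence[PatientBundle],
    truths: Sequence[TruthRecord],
    directory: str | Path,
) -> dict[str, Path]:
    """Write bundles/truth to ``directory`` as CSV + JSONL; returns the file
    map.  Empty collections yield valid headers-only files."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / name for name in (
        "patients.csv", "diagnoses.csv", "prescriptions.csv",
        "allergies.csv", "notes.jsonl", "truth.jsonl",
    )}
    pd.DataFrame(
        [[b.patient_id, b.gender, b.race_ethnicity, b.site] for b in bundles],
        columns=_PATIENT_COLS,
    ).to_csv(paths["patients.csv"], index=False)
    pd.DataFrame(
        [[d.patient_id, _iso(d.date), d.code] for b in bundles for d in b.diagnoses],
        columns=_DX_COLS,
    ).to_csv(paths["diagnoses.csv"], index=False)
    pd.DataFrame(
        [
            [p.patient_id, p.drug_code, p.drug_name, _iso(p.start_date),
             _iso(p.end_date), "" if p.dose_mg is None else p.dose_mg]
            for b in bundles for p in b.prescriptions
        ],
        columns=_RX_COLS,
    ).to_csv(paths["prescriptions.csv"], index=False)
    pd.DataFrame(
        [[a.patient_id, a.substance] for b in bundles for a in b.allergies],
        columns=_ALLERGY_COLS,
    ).to_csv(paths["allergies.csv"], index=False)
    with paths["notes.jsonl"].open("w", encoding="utf-8") as fh:
        for b in bundles:
            for n in b.notes:
                fh.write(json.dumps({
                    "note_id": n.note_id, "patient_id": n.patient_id,
                    "date": _iso(n.date), "note_type": n.note_type, "text": n.text,
                }, sort_keys=True) + "\n")
    with paths["truth.jsonl"].open("w", encoding="utf-8") as fh:
        for t in truths:
            fh.write(json.dumps({
                "patient_id": t.patient_id,
                "true_disposition": t.true_disposition.value,
                "true_use_status": t.true_use_status.value,
                "true_reasons": [r.value for r in t.true_reasons],
            }, sort_keys=True) + "\n")
    return paths


def read_bundle(
    directory: str | Path,
) -> tuple[list[PatientBundle], list[TruthRecord]]:
    """Read back the flat-file schema written by :func:`write_bundle`."""
    d = Path(directory)
    if not (d / "patients.csv").exists():
        raise FileNotFoundError(f"no patients.csv under {d}")

    def _date(s: str) -> date:
        return date.fromisoformat(s)

    patients = pd.read_csv(d / "patients.csv", dtype=str, keep_default_na=False)
    dx = pd.read_csv(d / "diagnoses.csv", dtype=str, keep_default_na=False)
    rx = pd.read_csv(d / "prescriptions.csv", dtype=str, keep_default_na=False)
    al = pd.read_csv(d / "allergies.csv", dtype=str, keep_default_na=False)

    dx_by: dict[str, list[DiagnosisEvent]] = {}
    for row in dx.itertuples(index=False):
        dx_by.setdefault(row.patient_id, []).append(
            DiagnosisEvent(row.patient_id, _date(row.date), row.code)
        )
    rx_by: dict[str, list[PrescriptionEvent]] = {}
    for row in rx.itertuples(index=False):
        rx_by.setdefault(row.patient_id, []).append(PrescriptionEvent(
            row.patient_id, row.drug_code, row.drug_name, _date(row.start_date),
            _date(row.end_date) if row.end_date else None,
            int(row.dose_mg) if row.dose_mg else None,
        ))
    al_by: dict[str, list[AllergyRecord]] = {}
    for row in al.itertuples(index=False):
        al_by.setdefault(row.patient_id, []).append(
            AllergyRecord(row.patient_id, row.substance)
        )
    notes_by: dict[str, list[ClinicalNote]] = {}
    notes_path = d / "notes.jsonl"
    if notes_path.exists():
        with notes_path.open(encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                o = json.loads(line)
                notes_by.setdefault(o["patient_id"], []).append(ClinicalNote(
                    o["note_id"], o["patient_id"], _date(o["date"]),
                    o["note_type"], o["text"],
                ))
    bundles = [
        PatientBundle(
            patient_id=row.patient_id,
            gender=row.gender,
            race_ethnicity=row.race_ethnicity,
            site=row.site,
            diagnoses=tuple(dx_by.get(row.patient_id, ())),
            prescriptions=tuple(rx_by.get(row.patient_id, ())),
            allergies=tuple(al_by.get(row.patient_id, ())),
            notes=tuple(notes_by.get(row.patient_id, ())),
        )
        for row in patients.itertuples(index=False)
    ]
    truths: list[TruthRecord] = []
    truth_path = d / "truth.jsonl"
    if truth_path.exists():
        with truth_path.open(encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                o = json.loads(line)
                truths.append(TruthRecord(
                    o["patient_id"],
                    TrueDisposition(o["true_disposition"]),
                    UseStatus(o["true_use_status"]),
                    tuple(Reason(r) for r in o["true_reasons"]),
                ))
    return bundles, truths
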