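"""The structured-EHR phenotyping cascade for statin nonuse in ASCVD.

Every patient is routed, in a fixed order, through:

1. an engagement screen — at least two distinct encounter dates carrying an
   ASCVD diagnosis, the earliest of which is the *index diagnosis*;
2. a prescription screen — an active statin prescription at or shortly after
   the index date removes the patient from the nonuse pathway;
3. a structured-allergy screen;
4. a note screen — any statin term in a clinical note within 30 days after
   the index date places the patient in the NLP dataset, otherwise the
   patient has no statin documentation at all.

The order matters and mirrors a CONSORT-style selection diagram: a patient
with both an active prescription and a statin allergy is counted as
prescribed, not allergic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

from .notes import (
    NOTE_WINDOW_DAYS,
    StatinDictionary,
    has_statin_term,
    match_statin_terms,
)

#: "1 month" and "6 months" as fixed day counts, boundary day inclusive.
NEW_RX_WINDOW_DAYS = 30
OPEN_RX_LOOKBACK_DAYS = 183


class AscvdCategory(str, enum.Enum):
    CORONARY = "CORONARY"
    CEREBROVASCULAR = "CEREBROVASCULAR"
    PERIPHERAL = "PERIPHERAL"
    POLYVASCULAR = "POLYVASCULAR"
    NONE = "NONE"


class Bucket(str, enum.Enum):
    """Cascade dispositions, in evaluation order."""

    EXCLUDED_LT2 = "EXCLUDED_LT2"
    RX_PRESENT = "RX_PRESENT"
    STRUCTURED_ALLERGY = "STRUCTURED_ALLERGY"
    NO_STATIN_TERMS = "NO_STATIN_TERMS"
    NLP_DATASET = "NLP_DATASET"


class Intensity(str, enum.Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    UNKNOWN = "UNKNOWN"


#: Representative ICD-like code -> ASCVD category map. The real study used
#: comprehensive ICD-9/10 lists; this stand-in covers the three base
#: categories with common codes from both revisions.
ICD_ASCVD_MAP: dict[str, AscvdCategory] = {
    "I25.10": AscvdCategory.CORONARY,
    "I21.9": AscvdCategory.CORONARY,
    "I20.9": AscvdCategory.CORONARY,
    "414.01": AscvdCategory.CORONARY,
    "410.90": AscvdCategory.CORONARY,
    "I63.9": AscvdCategory.CEREBROVASCULAR,
    "I65.29": AscvdCategory.CEREBROVASCULAR,
    "G45.9": AscvdCategory.CEREBROVASCULAR,
    "434.91": AscvdCategory.CEREBROVASCULAR,
    "433.10": AscvdCategory.CEREBROVASCULAR,
    "I70.213": AscvdCategory.PERIPHERAL,
    "I73.9": AscvdCategory.PERIPHERAL,
    "443.9": AscvdCategory.PERIPHERAL,
    "440.21": AscvdCategory.PERIPHERAL,
}

#: drug name (lowercase) + dose threshold -> intensity, per the usual
#: high/moderate/low statin intensity classification.
STATIN_INTENSITY_MAP: dict[tuple[str, int], Intensity] = {
    ("atorvastatin", 40): Intensity.HIGH,
    ("atorvastatin", 80): Intensity.HIGH,
    ("atorvastatin", 10): Intensity.MODERATE,
    ("atorvastatin", 20): Intensity.MODERATE,
    ("rosuvastatin", 20): Intensity.HIGH,
    ("rosuvastatin", 40): Intensity.HIGH,
    ("rosuvastatin", 5): Intensity.MODERATE,
    ("rosuvastatin", 10): Intensity.MODERATE,
    ("simvastatin", 20): Intensity.MODERATE,
    ("simvastatin", 40): Intensity.MODERATE,
    ("simvastatin", 10): Intensity.LOW,
    ("pravastatin", 40): Intensity.MODERATE,
    ("pravastatin", 80): Intensity.MODERATE,
    ("pravastatin", 10): Intensity.LOW,
    ("pravastatin", 20): Intensity.LOW,
    ("lovastatin", 40): Intensity.MODERATE,
    ("lovastatin", 20): Intensity.LOW,
    ("fluvastatin", 80): Intensity.MODERATE,
    ("fluvastatin", 20): Intensity.LOW,
    ("fluvastatin", 40): Intensity.LOW,
    ("pitavastatin", 2): Intensity.MODERATE,
    ("pitavastatin", 4): Intensity.MODERATE,
    ("pitavastatin", 1): Intensity.LOW,
}


def classify_intensity(drug_name: str, dose_mg: int | None) -> Intensity:
    if dose_mg is None:
        return Intensity.UNKNOWN
    return STATIN_INTENSITY_MAP.get((drug_name.lower(), dose_mg), Intensity.UNKNOWN)


@dataclass(frozen=True)
class DiagnosisEvent:
    patient_id: str
    date: date
    code: str

    @property
    def ascvd_category(self) -> AscvdCategory:
        return ICD_ASCVD_MAP.get(self.code, AscvdCategory.NONE)


@dataclass(frozen=True)
class PrescriptionEvent:
    patient_id: str
    drug_code: str
    drug_name: str
    start_date: date
    end_date: date | None = None
    dose_mg: int | None = None

    def __post_init__(self) -> None:
        if self.end_date is not None and self.end_date < self.start_date:
            raise ValueError(
                f"prescription {self.drug_code} for {self.patient_id}: "
                f"end_date {self.end_date} precedes start_date {self.start_date}"
            )

    @property
    def intensity(self) -> Intensity:
        return classify_intensity(self.drug_name, self.dose_mg)


@dataclass(frozen=True)
class AllergyRecord:
    patient_id: str
    substance: str


@dataclass(frozen=True)
class ClinicalNote:
    note_id: str
    patient_id: str
    date: date
    note_type: str
    text: str


@dataclass(frozen=True)
class PatientBundle:
    """One patient's structured events and notes — the unit of processing."""

    patient_id: str
    gender: str
    race_ethnicity: str
    site: str
    diagnoses: tuple[DiagnosisEvent, ...] = ()
    prescriptions: tuple[PrescriptionEvent, ...] = ()
    allergies: tuple[AllergyRecord, ...] = ()
    notes: tuple[ClinicalNote, ...] = ()


@dataclass(frozen=True)
class IndexDiagnosis:
    patient_id: str
    index_date: date
    ascvd_category: AscvdCategory


@dataclass(frozen=True)
class CohortDisposition:
    patient_id: str
    bucket: Bucket
    evidence: tuple[str, ...] = ()
    index: IndexDiagnosis | None = None


def find_index_diagnosis(events: Sequence[DiagnosisEvent]) -> IndexDiagnosis | None:
    """Locate the index (first) ASCVD diagnosis.

    Returns ``None`` (→ EXCLUDED_LT2) unless at least two *distinct* encounter
    dates carry an ASCVD diagnosis code; same-day duplicates count once.  The
    category is POLYVASCULAR when ASCVD events span two or more base
    categories, otherwise the single category.
    """
    ascvd = [e for e in events if e.ascvd_category is not AscvdCategory.NONE]
    if not ascvd:
        return None
    dates = {e.date for e in ascvd}
    if len(dates) < 2:
        return None
    categories = {e.ascvd_category for e in ascvd}
    cat = AscvdCategory.POLYVASCULAR if len(categories) >= 2 else next(iter(categories))
    return IndexDiagnosis(ascvd[0].patient_id, min(dates), cat)


def is_statin(drug_name: str, dictionary: StatinDictionary) -> bool:
    return bool(match_statin_terms(drug_name, dictionary))


def statin_rx_active(
    rx: Sequence[PrescriptionEvent], index_date: date
) -> bool:
    """Is any statin prescription active per the cascade rule?

    A prescription counts when (a) its closed interval covers the index date,
    (b) it is a new prescription starting within 30 days after the index
    date, or (c) it has no end date and started within 183 days before (or
    on) the index date. ``rx`` must already be filtered to statins.
    """
    for p in rx:
        if p.end_date is not None:
            if p.start_date <= index_date <= p.end_date:
                return True
        else:
            if index_date - timedelta(days=OPEN_RX_LOOKBACK_DAYS) <= p.start_date <= index_date:
                return True
        if index_date < p.start_date <= index_date + timedelta(days=NEW_RX_WINDOW_DAYS):
            return True
    return False


def has_structured_statin_allergy(
    allergies: Sequence[AllergyRecord], dictionary: StatinDictionary
) -> bool:
    """True iff any structured allergy substance matches the statin dictionary
    (trap exclusions such as "nystatin" do not count)."""
    return any(match_statin_terms(a.substance, dictionary) for a in allergies)


def classify_disposition(
    bundle: PatientBundle, dictionary: StatinDictionary
) -> CohortDisposition:
    """Assign the patient's cascade bucket, applying the screens in order:
    engagement → prescription → structured allergy → note term screen."""
    idx = find_index_diagnosis(bundle.diagnoses)
    if idx is None:
        return CohortDisposition(bundle.patient_id, Bucket.EXCLUDED_LT2)
    statin_rx = [p for p in bundle.prescriptions if is_statin(p.drug_name, dictionary)]
    if statin_rx_active(statin_rx, idx.index_date):
        ev = tuple(f"rx:{p.drug_code}" for p in statin_rx)
        return CohortDisposition(bundle.patient_id, Bucket.RX_PRESENT, ev, idx)
    if has_structured_statin_allergy(bundle.allergies, dictionary):
        ev = tuple(
            f"allergy:{a.substance}"
            for a in bundle.allergies
            if match_statin_terms(a.substance, dictionary)
        )
        return CohortDisposition(bundle.patient_id, Bucket.STRUCTURED_ALLERGY, ev, idx)
    lo, hi = idx.index_date, idx.index_date + timedelta(days=NOTE_WINDOW_DAYS)
    hits = tuple(
        f"note:{n.note_id}"
        for n in bundle.notes
        if lo <= n.date <= hi and has_statin_term(n.text, dictionary)
    )
    if hits:
        return CohortDisposition(bundle.patient_id, Bucket.NLP_DATASET, hits, idx)
    return CohortDisposition(bundle.patient_id, Bucket.NO_STATIN_TERMS, (), idx)


@dataclass(frozen=True)
class CascadeRow:
    label: str
    count: int
    denominator: int
    percent: str


@dataclass(frozen=True)
class CascadeTable:
    """CONSORT-style cascade accounting.

    Percentages use the parent denominator at each split: prescription rows
    over the eligible cohort, the allergy row over patients without
    prescriptions, and the note-screen rows over patients with neither
    prescriptions nor allergies.  Printed precision is mixed on purpose —
    whole percents for the large splits, one decimal for the allergy and
    note-screen rows — matching how such diagrams are usually reported.
    """

    rows: tuple[CascadeRow, ...]

    def as_dict(self) -> dict[str, CascadeRow]:
        return {r.label: r for r in self.rows}

    def to_text(self) -> str:
        width = max(len(r.label) for r in self.rows)
        lines = [
            f"{r.label:<{width}}  {r.count:>8,}  /{r.denominator:>8,}  {r.percent:>6}"
            for r in self.rows
        ]
        return "\n".join(lines) + "\n"


def build_cascade_table(
    eligible: int,
    rx_present: int,
    structured_allergy: int,
    no_statin_terms: int,
    nlp_dataset: int,
    excluded_lt2: int = 0,
) -> CascadeTable:
    """Build the cascade table from bucket counts, validating that child
    counts sum to the parent denominator at every split."""
    from .report import percent as _percent  # report depends on cohort types; keep one-way at import time

    def percent(n: int, d: int, decimals: int) -> str:
        # an empty parent bucket renders its (necessarily empty) children as 0
        if d == 0:
            return "0%" if decimals == 0 else f"0.{'0' * decimals}%"
        return _percent(n, d, decimals)

    rx_absent = eligible - rx_present
    remaining = rx_absent - structured_allergy
    if no_statin_terms + nlp_dataset != remaining:
        raise ValueError(
            f"note-screen counts {no_statin_terms}+{nlp_dataset} do not sum to {remaining}"
        )
    rows = [
        CascadeRow("screened", eligible + excluded_lt2, eligible + excluded_lt2,
                   percent(eligible + excluded_lt2, eligible + excluded_lt2, 0)),
        CascadeRow("excluded: <2 ASCVD encounters", excluded_lt2,
                   eligible + excluded_lt2, percent(excluded_lt2, eligible + excluded_lt2, 0)),
        CascadeRow("ASCVD cohort", eligible, eligible + excluded_lt2,
                   percent(eligible, eligible + excluded_lt2, 0)),
        CascadeRow("statin prescription present", rx_present, eligible,
                   percent(rx_present, eligible, 0)),
        CascadeRow("no statin prescription", rx_absent, eligible,
                   percent(rx_absent, eligible, 0)),
        CascadeRow("structured statin allergy", structured_allergy, rx_absent,
                   percent(structured_allergy, rx_absent, 1)),
        CascadeRow("no prescription, no allergy", remaining, rx_absent,
                   percent(remaining, rx_absent, 1)),
        CascadeRow("no statin terms in notes", no_statin_terms, remaining,
                   percent(no_statin_terms, remaining, 1)),
        CascadeRow("statin terms present (NLP dataset)", nlp_dataset, remaining,
                   percent(nlp_dataset, remaining, 0)),
    ]
    return CascadeTable(tuple(rows))


def cascade_accounting(dispositions: Iterable[CohortDisposition]) -> CascadeTable:
    """Tally dispositions into the cascade table."""
    counts = {b: 0 for b in Bucket}
    for d in dispositions:
        counts[d.bucket] += 1
    eligible = sum(v for b, v in counts.items() if b is not Bucket.EXCLUDED_LT2)
    return build_cascade_table(
        eligible=eligible,
        rx_present=counts[Bucket.RX_PRESENT],
        structured_allergy=counts[Bucket.STRUCTURED_ALLERGY],
        no_statin_terms=counts[Bucket.NO_STATIN_TERMS],
        nlp_dataset=counts[Bucket.NLP_DATASET],
        excluded_lt2=counts[Bucket.EXCLUDED_LT2],
    )
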