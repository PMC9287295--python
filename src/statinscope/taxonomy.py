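"""The reason-for-nonuse taxonomy shared across the generator, the models,
and the reports."""

from __future__ import annotations

import enum


class Reason(str, enum.Enum):
    """Documented reasons for statin nonuse.

    The fixed declaration order is the canonical tie-break order everywhere a
    single category must be chosen from several (primary-label reduction,
    reconciler ties, argmax fallbacks).
    """

    MUSCLE = "MUSCLE"
    OTHER_SIDE_EFFECT = "OTHER_SIDE_EFFECT"
    PERCEIVED_LIPID_CONTROL = "PERCEIVED_LIPID_CONTROL"
    PATIENT_PREFERENCE = "PATIENT_PREFERENCE"
    NONSPECIFIC = "NONSPECIFIC"


REASON_ORDER: tuple[Reason, ...] = tuple(Reason)


class UseStatus(str, enum.Enum):
    USE_DOCUMENTED = "USE_DOCUMENTED"
    NONUSE = "NONUSE"
    NA = "NA"


def primary_reason(reasons) -> Reason:
    """Reduce a non-mutually-exclusive annotation to a single primary label:
    the first category in the canonical order that is present."""
    present = set(reasons)
    if not present:
        raise ValueError("empty reason set has no primary reason")
    for r in REASON_ORDER:
        if r in present:
            return r
    raise ValueError(f"unknown reasons: {present}")
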