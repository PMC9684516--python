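"""Binary clinical endpoint labels from toxicity records and IPSS scores.

Three endpoints are modeled: acute GU toxicity (during treatment, bin
dependent), sub-acute GU toxicity (after treatment, bin invariant) and
change in IPSS.  Category 1 means maximum CTCAE grade >= 2 for the toxicity
endpoints and IPSS improvement (delta < 0) for the IPSS endpoint.
"""
from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GU_SYMPTOMS",
    "ToxicityEvent",
    "label_acute_gu",
    "label_subacute_gu",
    "label_delta_ipss",
]

GU_SYMPTOMS = ("frequency", "nocturia", "dysuria", "urgency", "obstruction", "incontinence")
PHASES = ("during_RT", "post_RT")


@dataclass(frozen=True)
class ToxicityEvent:
    gu_symptom: str
    grade: int
    onset_bed: float
    phase: str

    def __post_init__(self) -> None:
        if self.gu_symptom not in GU_SYMPTOMS:
            raise ValueError(f"unknown GU symptom {self.gu_symptom!r}")
        if not 1 <= self.grade <= 5:
            raise ValueError(f"CTCAE grade must be 1..5, got {self.grade}")
        if self.onset_bed < 0:
            raise ValueError("onset BED must be non-negative")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")


def label_acute_gu(events: list[ToxicityEvent], bin_bed: float) -> int:
    """1 iff any during-treatment event of grade >= 2 started strictly after
    the bin's accumulated BED; events at or before the bin do not count.
    """
    grades = [e.grade for e in events if e.phase == "during_RT" and e.onset_bed > bin_bed]
    return int(max(grades, default=0) >= 2)


def label_subacute_gu(events: list[ToxicityEvent]) -> int:
    """1 iff any post-treatment event reaches grade >= 2 (bin invariant)."""
    grades = [e.grade for e in events if e.phase == "post_RT"]
    return int(max(grades, default=0) >= 2)


def label_delta_ipss(ipss_initial: int, ipss_final: int) -> tuple[int, int]:
    """Return (delta, category): delta = final - initial; category 1 encodes
    improvement (delta < 0), category 0 no change or worsening.
    """
    for name, score in (("initial", ipss_initial), ("final", ipss_final)):
        if not 0 <= score <= 35:
            raise ValueError(f"IPSS {name} score {score} outside 0..35")
    delta = int(ipss_final) - int(ipss_initial)
    return delta, int(delta < 0)
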