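"""ASRS symptom-checklist scoring.

The 18-item adult ADHD self-report checklist is scored by counting
positive symptoms: an item rated 2 ("often") or 3 ("very often") counts
as one positive symptom.  Items split 9/9 into inattention and
hyperactivity-impulsivity domains; by default items 1-9 are inattention
and 10-18 hyperactivity-impulsivity, overridable via ``domain_map``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "AsrsResponse",
    "SymptomScores",
    "AsrsValidationError",
    "DEFAULT_DOMAIN_MAP",
    "score_asrs",
]

N_ITEMS = 18
POSITIVE_THRESHOLD = 2

INATTENTION = "inattention"
HYPERACTIVITY = "hyperactivity-impulsivity"

# item index (0-based) -> domain; first nine inattention, last nine
# hyperactivity-impulsivity (DSM symptom ordering)
DEFAULT_DOMAIN_MAP: tuple[str, ...] = (INATTENTION,) * 9 + (HYPERACTIVITY,) * 9


class AsrsValidationError(ValueError):
    """Raised for malformed ASRS responses."""


@dataclass(frozen=True)
class AsrsResponse:
    subject_id: str
    items: tuple[int, ...]
    domain_map: tuple[str, ...] = DEFAULT_DOMAIN_MAP

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise AsrsValidationError(
                f"expected {N_ITEMS} items, got {len(self.items)}"
            )
        for i, v in enumerate(self.items):
            if v not in (0, 1, 2, 3):
                raise AsrsValidationError(
                    f"item {i + 1} value {v!r} outside 0..3"
                )
        if len(self.domain_map) != N_ITEMS:
            raise AsrsValidationError("domain_map must cover all 18 items")
        counts = {d: self.domain_map.count(d) for d in (INATTENTION, HYPERACTIVITY)}
        if counts[INATTENTION] != 9 or counts[HYPERACTIVITY] != 9:
            raise AsrsValidationError(
                f"domain_map must partition items 9/9, got {counts}"
            )


@dataclass(frozen=True)
class SymptomScores:
    total: int
    inattention: int
    hyperactivity_impulsivity: int

    def as_dict(self) -> dict[str, int]:
        return {
            "symptoms_total": self.total,
            "symptoms_inattention": self.inattention,
            "symptoms_hyperactivity": self.hyperactivity_impulsivity,
        }


def score_asrs(resp: AsrsResponse) -> SymptomScores:
    """Count positive symptoms (item value >= 2) per domain."""
    inatt = sum(
        1
        for v, d in zip(resp.items, resp.domain_map)
        if v >= POSITIVE_THRESHOLD and d == INATTENTION
    )
    hyper = sum(
        1
        for v, d in zip(resp.items, resp.domain_map)
        if v >= POSITIVE_THRESHOLD and d == HYPERACTIVITY
    )
    return SymptomScores(
        total=inatt + hyper,
        inattention=inatt,
        hyperactivity_impulsivity=hyper,
    )
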