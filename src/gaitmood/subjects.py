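"""Subject records: questionnaire scores and demographics.

A subject carries a GAD-7 anxiety total (0-21) and, when the depression
questionnaire was completed in full, a PHQ-9 total (0-27) together with its
nine item scores (each 0-3).  The PHQ-9 total must equal the item sum; rows
violating that are treated as missing depression data rather than dropped,
so a subject can be usable for the anxiety analysis but not the depression
one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

GAD7_MAX = 21
PHQ9_MAX = 27
N_PHQ9_ITEMS = 9
ITEM_COLUMNS = tuple(f"phq9_item{i}" for i in range(1, N_PHQ9_ITEMS + 1))
SUBJECT_COLUMNS = ("subject_id", "gender", "age", "gad7", "phq9") + ITEM_COLUMNS

GENDERS = ("male", "female")


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: id, demographics and questionnaire scores."""

    subject_id: str
    gender: str
    age: float
    gad7_total: int
    phq9_total: Optional[int] = None
    phq9_items: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if not 0 <= self.gad7_total <= GAD7_MAX:
            raise ValueError(f"gad7_total out of range [0, {GAD7_MAX}]: {self.gad7_total}")
        if (self.phq9_total is None) != (self.phq9_items is None):
            raise ValueError("phq9_total and phq9_items must be both present or both absent")
        if self.phq9_items is not None:
            items = tuple(int(v) for v in self.phq9_items)
            if len(items) != N_PHQ9_ITEMS:
                raise ValueError(f"expected {N_PHQ9_ITEMS} PHQ-9 items, got {len(items)}")
            if any(not 0 <= v <= 3 for v in items):
                raise ValueError(f"PHQ-9 item scores must lie in 0..3: {items}")
            if sum(items) != self.phq9_total:
                raise ValueError(
                    f"phq9_total ({self.phq9_total}) != item sum ({sum(items)})"
                )

    @property
    def has_phq9(self) -> bool:
        return self.phq9_total is not None


def subjects_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subjects with the canonical column set (missing PHQ-9 -> NA)."""
    rows = []
    for s in subjects:
        row: dict = {
            "subject_id": s.subject_id,
            "gender": s.gender,
            "age": s.age,
            "gad7": s.gad7_total,
            "phq9": s.phq9_total if s.has_phq9 else pd.NA,
        }
        items = s.phq9_items if s.has_phq9 else (pd.NA,) * N_PHQ9_ITEMS
        row.update(dict(zip(ITEM_COLUMNS, items)))
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(SUBJECT_COLUMNS))
    for col in ("phq9",) + ITEM_COLUMNS:
        frame[col] = frame[col].astype("Int64")
    return frame
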