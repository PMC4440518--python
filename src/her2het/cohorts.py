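"""Clinico-pathologic contingency comparisons against reference cohorts.

Ships the printed ER-positivity counts of the study cohort and four published
reference cohorts so the comparisons run with no external data: all 12
microdissected HER2-heterogeneous cases were ER-positive, versus 56/79 (TCGA
HER2-positive), 40/72 and 24/61 (METABRIC discovery / validation) and
1,536/3,383 (HERA trial).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .stats import ContingencyTable2x2, fisher_two_tailed

__all__ = ["CohortCount", "REFERENCE_COHORTS", "STUDY_COHORT",
           "compare_to_reference", "er_comparison_table"]


@dataclass(frozen=True)
class CohortCount:
    name: str
    positives: int
    total: int

    def __post_init__(self):
        if not (0 <= self.positives <= self.total):
            raise ValueError(f"{self.name}: need 0 <= positives <= total")

    @property
    def percent(self) -> int:
        return round(100 * self.positives / self.total)


STUDY_COHORT = CohortCount("HER2-heterogeneous", 12, 12)

REFERENCE_COHORTS = (
    CohortCount("TCGA", 56, 79),
    CohortCount("METABRIC-discovery", 40, 72),
    CohortCount("METABRIC-validation", 24, 61),
    CohortCount("HERA", 1536, 3383),
)


def compare_to_reference(study: CohortCount, reference: CohortCount):
    """2x2 table of ER-positive vs ER-negative counts and its two-tailed
    Fisher p-value."""
    if study.total == 0 or reference.total == 0:
        raise ValueError("cohort totals must be positive")
    table = ContingencyTable2x2(
        study.positives, study.total - study.positives,
        reference.positives, reference.total - reference.positives,
    )
    return table, fisher_two_tailed(table)


def er_comparison_table(study: CohortCount = STUDY_COHORT,
                        references=REFERENCE_COHORTS) -> pd.DataFrame:
    rows = []
    for ref in references:
        _, p = compare_to_reference(study, ref)
        rows.append({
            "cohort": ref.name,
            "er_positive": ref.positives,
            "total": ref.total,
            "percent": ref.percent,
            "study_positive": study.positives,
            "study_total": study.total,
            "fisher_p": p,
        })
    return pd.DataFrame(rows)
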