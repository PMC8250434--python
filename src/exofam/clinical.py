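"""Per-family clinical summaries and the high-myopia inclusion predicate.

Sign convention: myopic spherical equivalent (SE) is negative
throughout; "worse" means more negative. A reference clinical table for
a 27-family high-myopia cohort ships with the package
(``data/hm_cohort_clinical.tsv``) and is used by tests and the
acceptance report.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

from .config import Thresholds
from .model import Individual, Status, ValidationError
from .segregation import phenotype_status
from .variant_io import ClinicalRow, read_clinical_table


@dataclass(frozen=True)
class FamilyClinicalSummary:
    family_id: str
    affected_count: int
    se_range: tuple[float, float]
    se_median: float
    al_range: tuple[float, float]
    al_median: float

    def to_clinical_row(self, proband_age: Optional[int] = None) -> ClinicalRow:
        return ClinicalRow(
            family_id=self.family_id,
            proband_age=proband_age,
            affected_count=self.affected_count,
            se_range=self.se_range,
            se_median=self.se_median,
            al_range=self.al_range,
            al_median=self.al_median,
        )


def is_high_myopia(
    se_worst: Optional[float],
    al_longest: Optional[float],
    t: Optional[Thresholds] = None,
) -> bool:
    """Inclusion predicate: SE at or below the high-myopia bound and/or
    AL strictly above the axial bound.

    A missing measurement never qualifies on its own; both missing is an
    error.
    """
    t = t or Thresholds()
    if se_worst is None and al_longest is None:
        raise ValidationError("is_high_myopia needs at least one measurement")
    if se_worst is not None and se_worst <= t.hm_se_max:
        return True
    if al_longest is not None and al_longest > t.hm_al_min:
        return True
    return False


def family_summary(
    members: Sequence[Individual],
    t: Optional[Thresholds] = None,
) -> FamilyClinicalSummary:
    """Summarize one family over the pooled per-eye values of its
    affected members.

    Ranges are (min, max) and medians are taken over the same pooled
    per-eye values (even counts average the middle two).
    """
    t = t or Thresholds()
    if not members:
        raise ValidationError("family_summary requires at least one member")
    affected = [m for m in members if phenotype_status(m, t) is Status.AFFECTED]
    se_values = [v for m in affected for v in m.se_values]
    al_values = [v for m in affected for v in m.al_values]
    if not se_values or not al_values:
        raise ValidationError(
            f"family {members[0].family_id}: no measured affected eyes to summarize"
        )
    return FamilyClinicalSummary(
        family_id=members[0].family_id,
        affected_count=len(affected),
        se_range=(min(se_values), max(se_values)),
        se_median=statistics.median(se_values),
        al_range=(min(al_values), max(al_values)),
        al_median=statistics.median(al_values),
    )


def count_hm_families(rows: Sequence[ClinicalRow], t: Optional[Thresholds] = None) -> int:
    """Number of clinical rows whose medians satisfy the inclusion
    predicate."""
    t = t or Thresholds()
    return sum(1 for r in rows if is_high_myopia(r.se_median, r.al_median, t))


def row_consistency_problems(row: ClinicalRow) -> list[str]:
    """Internal-consistency check of one clinical row: each printed
    median must lie within its printed range."""
    problems: list[str] = []
    lo, hi = row.se_range
    if not (lo <= row.se_median <= hi):
        problems.append(
            f"SE median {row.se_median} outside range [{lo}, {hi}]"
        )
    lo, hi = row.al_range
    if not (lo <= row.al_median <= hi):
        problems.append(
            f"AL median {row.al_median} outside range [{lo}, {hi}]"
        )
    return problems


def load_reference_clinical_table() -> list[ClinicalRow]:
    """Load the bundled 27-family reference clinical table."""
    ref = resources.files("exofam.data") / "hm_cohort_clinical.tsv"
    with resources.as_file(ref) as path:
        return read_clinical_table(str(path))
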