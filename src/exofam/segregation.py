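"""Phenotype-based affection status and within-family cosegregation.

Status rules: a member is affected when the worse eye's spherical
equivalent is at or below the high-myopia bound, or the longer eye's
axial length strictly exceeds the axial bound; unaffected when every
measured eye's |SE| lies strictly below the unaffected bound; otherwise
unknown (e.g., an SE between −2 and −6 D). An explicit declared status
always overrides the measurements.

Cosegregation rules per model — AD: every genotyped affected member is
heterozygous and no genotyped unaffected member carries the alternate
allele; AR: every genotyped affected member is homozygous-alternate and
no genotyped unaffected member is homozygous-alternate (heterozygous
carriers are permitted: parents of a homozygous proband are obligate
carriers). Members with missing genotypes or unknown status never veto.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .config import Thresholds
from .model import (
    CandidateVariant,
    GenotypeMatrix,
    Genotype,
    InheritanceModel,
    Individual,
    Pedigree,
    Status,
    ValidationError,
)


@dataclass
class SegregationResult:
    cosegregates: bool
    violating_members: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cosegregates != (len(self.violating_members) == 0):
            raise ValidationError(
                "cosegregates flag inconsistent with violating_members"
            )


def phenotype_status(ind: Individual, t: Thresholds) -> Status:
    """Resolve affection status from declared status or eye measurements."""
    if ind.declared_status is not Status.UNKNOWN:
        return ind.declared_status
    se = ind.se_values
    al = ind.al_values
    if (se and min(se) <= t.hm_se_max) or (al and max(al) > t.hm_al_min):
        return Status.AFFECTED
    if se and all(abs(v) < t.unaffected_se_max_abs for v in se):
        return Status.UNAFFECTED
    return Status.UNKNOWN


def cosegregates(
    vkey: str,
    genotypes: GenotypeMatrix,
    ped: Pedigree,
    model: InheritanceModel,
    t: Thresholds,
) -> SegregationResult:
    """Test one variant's cosegregation with disease in one family."""
    violations: list[tuple[str, str]] = []
    for member in ped.members:
        status = phenotype_status(member, t)
        gt = genotypes.get(vkey, member.id)
        if gt is Genotype.MISSING or status is Status.UNKNOWN:
            continue
        if model is InheritanceModel.AD:
            if status is Status.AFFECTED and gt is not Genotype.HET:
                violations.append((member.id, "affected not heterozygous"))
            elif status is Status.UNAFFECTED and gt.carries_alt:
                violations.append((member.id, "unaffected carrier"))
        else:  # AR
            if status is Status.AFFECTED and gt is not Genotype.HOM_ALT:
                violations.append((member.id, "affected not homozygous"))
            elif status is Status.UNAFFECTED and gt is Genotype.HOM_ALT:
                violations.append((member.id, "unaffected homozygous"))
    return SegregationResult(cosegregates=not violations, violating_members=violations)


def partition_by_segregation(
    candidates: Sequence[CandidateVariant],
    genotypes: GenotypeMatrix,
    pedigrees: dict[str, Pedigree],
    t: Thresholds,
) -> tuple[list[CandidateVariant], list[CandidateVariant]]:
    """Split candidates into (cosegregating, non-cosegregating) lists.

    Both lists preserve input order; each candidate's segregation result
    is attached for downstream scoring and audit output.
    """
    keep: list[CandidateVariant] = []
    drop: list[CandidateVariant] = []
    for cand in candidates:
        ped = pedigrees[cand.family_id]
        result = cosegregates(cand.variant.key, genotypes, ped, cand.model, t)
        cand.segregation = result
        (keep if result.cosegregates else drop).append(cand)
    return keep, drop
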