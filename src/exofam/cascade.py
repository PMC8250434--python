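"""The four-step variant filter with inheritance-model assignment,
de novo exclusion and a per-stage audit funnel.

Stages, applied in order to every (family, variant) candidate pair:

1. ``non_exonic``      — drop variants outside exonic/splice classes
2. ``synonymous``      — drop synonymous variants
3. ``frequency``       — drop variants with any database MAF at or
                         above the exclusion cutoff
4. ``genotype_model``  — drop variants whose genotypes contradict the
                         family's inheritance model (AD: every genotyped
                         affected heterozygous; AR: homozygous)
5. ``de_novo``         — drop apparent de novo variants (affected
                         non-founder carries the allele while both
                         genotyped parents are homozygous reference)

A candidate enters the cascade for a family only if at least one family
member carries the alternate allele. Every removed candidate records
exactly one (earliest) removal stage and reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from .config import RunConfig, Thresholds
from .model import (
    CandidateVariant,
    Consequence,
    GenotypeMatrix,
    Genotype,
    InheritanceModel,
    KEPT_CONSEQUENCES,
    Pedigree,
    PopulationFrequencies,
    Status,
    ValidationError,
    Variant,
)
from .segregation import phenotype_status
from .variant_io import AnnotationRecord

STAGE_NON_EXONIC = "non_exonic"
STAGE_SYNONYMOUS = "synonymous"
STAGE_FREQUENCY = "frequency"
STAGE_GENOTYPE_MODEL = "genotype_model"
STAGE_DE_NOVO = "de_novo"
STAGES = (
    STAGE_NON_EXONIC,
    STAGE_SYNONYMOUS,
    STAGE_FREQUENCY,
    STAGE_GENOTYPE_MODEL,
    STAGE_DE_NOVO,
)

_NON_EXONIC = frozenset(
    {Consequence.INTRONIC, Consequence.UTR, Consequence.INTERGENIC, Consequence.OTHER}
)


@dataclass(frozen=True)
class FunnelStage:
    name: str
    input: int
    kept: int
    removed: int

    def __post_init__(self) -> None:
        if self.kept + self.removed != self.input:
            raise ValidationError(
                f"funnel stage {self.name}: kept ({self.kept}) + removed "
                f"({self.removed}) != input ({self.input})"
            )


@dataclass
class FilterFunnel:
    stages: list[FunnelStage] = field(default_factory=list)

    def add(self, name: str, input: int, kept: int) -> None:
        if self.stages and input != self.stages[-1].kept:
            raise ValidationError(
                f"funnel stage {name}: input ({input}) != previous kept "
                f"({self.stages[-1].kept})"
            )
        self.stages.append(FunnelStage(name=name, input=input, kept=kept, removed=input - kept))

    @property
    def initial(self) -> int:
        return self.stages[0].input if self.stages else 0

    @property
    def final_kept(self) -> int:
        return self.stages[-1].kept if self.stages else 0

    @property
    def total_removed(self) -> int:
        return sum(s.removed for s in self.stages)

    def to_rows(self) -> list[tuple[str, int, int, int]]:
        return [(s.name, s.input, s.kept, s.removed) for s in self.stages]


def filter_consequence(
    variants: Sequence[Variant],
) -> tuple[list[Variant], list[Variant]]:
    """Keep exonic protein-relevant and splice-site variants.

    Composite of cascade stages 1 and 2; synonymous, intronic, UTR,
    intergenic and 'other' variants are removed.
    """
    kept: list[Variant] = []
    removed: list[Variant] = []
    for v in variants:
        if v.consequence is None:
            raise ValidationError(f"variant {v.key} has no consequence class")
        (kept if v.consequence in KEPT_CONSEQUENCES else removed).append(v)
    return kept, removed


def filter_frequency(freqs: PopulationFrequencies, t: Thresholds) -> bool:
    """True (keep) unless any present database MAF is >= the exclusion
    cutoff; absent values never trigger removal."""
    return all(maf < t.maf_exclusion for maf in freqs.present_mafs)


def assign_inheritance_model(
    ped: Pedigree,
    t: Thresholds,
    override: Optional[InheritanceModel] = None,
) -> InheritanceModel:
    """AD when any affected member has an affected parent, else AR.

    An explicit per-family override wins. A family with no resolvable
    affected member is an error.
    """
    if override is not None:
        return override
    statuses = {m.id: phenotype_status(m, t) for m in ped.members}
    affected = [m for m in ped.members if statuses[m.id] is Status.AFFECTED]
    if not affected:
        raise ValidationError(f"family {ped.family_id} has no affected members")
    for m in affected:
        for parent in ped.parents(m.id):
            if parent is not None and statuses[parent.id] is Status.AFFECTED:
                return InheritanceModel.AD
    return InheritanceModel.AR


def filter_genotype_model(
    vkey: str,
    genotypes: GenotypeMatrix,
    ped: Pedigree,
    model: InheritanceModel,
    t: Thresholds,
) -> tuple[bool, Optional[str]]:
    """Test model-consistency over genotyped affected members.

    Returns (keep, reason); missing genotypes never veto, but a variant
    with no genotyped affected member at all is removed as "untyped".
    """
    required = Genotype.HET if model is InheritanceModel.AD else Genotype.HOM_ALT
    n_typed = 0
    for member in ped.members:
        if phenotype_status(member, t) is not Status.AFFECTED:
            continue
        gt = genotypes.get(vkey, member.id)
        if gt is Genotype.MISSING:
            continue
        n_typed += 1
        if gt is not required:
            return False, f"affected {member.id} not {required.value} under {model.value}"
    if n_typed == 0:
        return False, "untyped"
    return True, None


def detect_de_novo(
    vkey: str,
    genotypes: GenotypeMatrix,
    ped: Pedigree,
    t: Thresholds,
) -> bool:
    """True iff some affected non-founder carries the alternate allele
    while both parents are genotyped homozygous reference.

    A missing parental genotype prevents the de novo call (conservative:
    absence of parental data is not evidence of absence)."""
    for member in ped.members:
        if member.is_founder:
            continue
        if phenotype_status(member, t) is not Status.AFFECTED:
            continue
        gt = genotypes.get(vkey, member.id)
        if not gt.carries_alt:
            continue
        father, mother = ped.parents(member.id)
        parent_gts = [
            genotypes.get(vkey, p.id) for p in (father, mother) if p is not None
        ]
        if len(parent_gts) == 2 and all(g is Genotype.HOM_REF for g in parent_gts):
            return True
    return False


@dataclass
class CascadeResult:
    candidates: list[CandidateVariant]  # all, including removed (audit)
    survivors_by_family: dict[str, list[CandidateVariant]]
    funnel: FilterFunnel

    @property
    def survivors(self) -> list[CandidateVariant]:
        return [c for c in self.candidates if not c.removed]


def _family_candidates(
    variants: Sequence[Variant],
    genotypes: GenotypeMatrix,
    ped: Pedigree,
    model: InheritanceModel,
    annotations: Mapping[str, AnnotationRecord],
) -> list[CandidateVariant]:
    out: list[CandidateVariant] = []
    member_ids = ped.member_ids
    for v in variants:
        vkey = v.key
        if not any(genotypes.get(vkey, mid).carries_alt for mid in member_ids):
            continue
        rec = annotations.get(vkey)
        if rec is None:
            # No annotation row: absent frequencies, all-missing profile,
            # unclassifiable consequence.
            cand = CandidateVariant(
                variant=v,
                family_id=ped.family_id,
                model=model,
                consequence=v.consequence or Consequence.OTHER,
            )
        else:
            enriched = replace(
                v,
                gene=v.gene or rec.gene,
                transcript=v.transcript or rec.transcript,
                cdna_hgvs=v.cdna_hgvs or rec.cdna_hgvs,
                consequence=rec.consequence,
            )
            cand = CandidateVariant(
                variant=enriched,
                family_id=ped.family_id,
                model=model,
                consequence=rec.consequence,
                frequencies=rec.frequencies,
                profile=rec.profile,
            )
        out.append(cand)
    return out


def run_cascade(
    variants: Sequence[Variant],
    genotypes: GenotypeMatrix,
    pedigrees: Sequence[Pedigree],
    annotations: Mapping[str, AnnotationRecord],
    config: Optional[RunConfig] = None,
) -> CascadeResult:
    """Run the full per-family filter cascade over a cohort.

    The funnel counts (family, variant) candidate pairs; kept + removed
    equals the stage input at every stage and the final kept count
    equals the number of surviving candidates.
    """
    cfg = config or RunConfig()
    t = cfg.thresholds
    candidates: list[CandidateVariant] = []
    models: dict[str, InheritanceModel] = {}
    for ped in pedigrees:
        model = assign_inheritance_model(
            ped, t, override=cfg.inheritance_overrides.get(ped.family_id)
        )
        models[ped.family_id] = model
        candidates.extend(_family_candidates(variants, genotypes, ped, model, annotations))

    peds_by_id = {p.family_id: p for p in pedigrees}
    funnel = FilterFunnel()
    live = list(candidates)

    def apply_stage(name: str, keep_fn) -> None:
        nonlocal live
        kept: list[CandidateVariant] = []
        for cand in live:
            keep, reason = keep_fn(cand)
            if keep:
                kept.append(cand)
            else:
                cand.removal_stage = name
                cand.removal_reason = reason
        funnel.add(name, input=len(live), kept=len(kept))
        live = kept

    apply_stage(
        STAGE_NON_EXONIC,
        lambda c: (
            c.consequence not in _NON_EXONIC,
            f"consequence {c.consequence.value}" if c.consequence in _NON_EXONIC else None,
        ),
    )
    apply_stage(
        STAGE_SYNONYMOUS,
        lambda c: (
            c.consequence is not Consequence.SYNONYMOUS,
            "synonymous" if c.consequence is Consequence.SYNONYMOUS else None,
        ),
    )
    apply_stage(
        STAGE_FREQUENCY,
        lambda c: (
            filter_frequency(c.frequencies, t),
            None
            if filter_frequency(c.frequencies, t)
            else f"MAF >= {t.maf_exclusion}",
        ),
    )

    def genotype_stage(c: CandidateVariant):
        keep, reason = filter_genotype_model(
            c.variant.key, genotypes, peds_by_id[c.family_id], c.model, t
        )
        return keep, reason

    apply_stage(STAGE_GENOTYPE_MODEL, genotype_stage)
    apply_stage(
        STAGE_DE_NOVO,
        lambda c: (
            not detect_de_novo(c.variant.key, genotypes, peds_by_id[c.family_id], t),
            "de novo"
            if detect_de_novo(c.variant.key, genotypes, peds_by_id[c.family_id], t)
            else None,
        ),
    )

    survivors_by_family: dict[str, list[CandidateVariant]] = {
        p.family_id: [] for p in pedigrees
    }
    for cand in live:
        survivors_by_family[cand.family_id].append(cand)
    return CascadeResult(
        candidates=candidates,
        survivors_by_family=survivors_by_family,
        funnel=funnel,
    )
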