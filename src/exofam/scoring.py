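"""Eleven-category evidence matrix, candidate ranking and a minimal
ACMG-style evidence label.

The matrix holds five category groups: gene filter condition (known
high-myopia gene, HM-related gene, ocular disease gene, MYP locus),
pathogenicity (more than two prediction tools damaging), annotation
(exonic protein-altering vs. not, mutually exclusive), ocular
expression (adult, embryonic), and population frequency (novel vs.
rare, mutually exclusive, both false for low-frequency variants).
Because each of the two exclusive pairs can contribute at most one
bit, no candidate can have more than nine true bits.

Weights are configuration, not constants of nature; the defaults give
1.0 to every informative bit, 0.0 to non_protein_altering and 0.5 to
freq_rare.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .config import (
    CATEGORY_ORDER,
    DEFAULT_ACMG_FALLBACK,
    DEFAULT_ACMG_TABLE,
    DEFAULT_WEIGHTS,
    Thresholds,
)
from .model import (
    CandidateVariant,
    PROTEIN_ALTERING,
    PopulationFrequencies,
    PredictionProfile,
    ToolCall,
    ValidationError,
    CATEGORICAL_TOOLS,
)
from .segregation import SegregationResult

FREQ_NOVEL = "novel"
FREQ_RARE = "rare"
FREQ_LOW = "low_frequency"


@dataclass(frozen=True)
class EvidenceScore:
    known_hm_gene: bool
    hm_related_gene: bool
    ocular_disease_gene: bool
    at_myp_locus: bool
    multi_tool_damaging: bool
    exonic_protein_altering: bool
    non_protein_altering: bool
    expressed_adult_ocular: bool
    expressed_embryonic_ocular: bool
    freq_novel: bool
    freq_rare: bool
    weighted_total: float

    def __post_init__(self) -> None:
        if self.exonic_protein_altering == self.non_protein_altering:
            raise ValidationError(
                "exactly one of exonic_protein_altering / non_protein_altering "
                "must be true"
            )
        if self.freq_novel and self.freq_rare:
            raise ValidationError("freq_novel and freq_rare are mutually exclusive")

    @property
    def bits(self) -> tuple[bool, ...]:
        return tuple(getattr(self, cat) for cat in CATEGORY_ORDER)

    @property
    def frequency_class(self) -> str:
        if self.freq_novel:
            return FREQ_NOVEL
        if self.freq_rare:
            return FREQ_RARE
        return FREQ_LOW


@dataclass(frozen=True)
class AcmgResult:
    tags: frozenset[str]
    classification: str


def damaging_call_count(
    p: PredictionProfile,
    t: Thresholds,
    collapse_polyphen: bool = True,
) -> int:
    """Number of tools calling the variant damaging.

    DANN counts as damaging at or above the configured score threshold.
    With ``collapse_polyphen`` the two PolyPhen-2 models (HDIV, HVAR)
    count as a single tool that is damaging if either model is.
    """
    count = 0
    for tool in CATEGORICAL_TOOLS:
        if collapse_polyphen and tool == "polyphen2_hvar":
            continue  # folded into polyphen2_hdiv below
        call = p.call(tool)
        if collapse_polyphen and tool == "polyphen2_hdiv":
            if (
                p.polyphen2_hdiv is ToolCall.DAMAGING
                or p.polyphen2_hvar is ToolCall.DAMAGING
            ):
                count += 1
            continue
        if call is ToolCall.DAMAGING:
            count += 1
    if p.dann_score is not None and p.dann_score >= t.dann_damaging:
        count += 1
    return count


def frequency_class(f: PopulationFrequencies, t: Thresholds) -> str:
    """novel (absent from all three databases), rare (every reported
    MAF strictly below the rare cutoff) or low_frequency."""
    max_maf = f.max_maf
    if max_maf is None:
        return FREQ_NOVEL
    if max_maf < t.rare_maf:
        return FREQ_RARE
    return FREQ_LOW


def evidence_matrix(
    c: CandidateVariant,
    t: Thresholds,
    weights: Optional[Mapping[str, float]] = None,
    collapse_polyphen: bool = True,
) -> EvidenceScore:
    """Compute the 11-category evidence matrix for one candidate.

    Pure function of the candidate's own annotations; the weighted
    total is the dot product of the category bits with the weight
    vector.
    """
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    ge = c.gene_evidence
    fclass = frequency_class(c.frequencies, t)
    protein_altering = c.consequence in PROTEIN_ALTERING
    bits = {
        "known_hm_gene": ge.is_known_hm_gene,
        "hm_related_gene": ge.is_hm_related,
        "ocular_disease_gene": ge.is_ocular_disease_gene,
        "at_myp_locus": ge.myp_locus is not None,
        "multi_tool_damaging": damaging_call_count(c.profile, t, collapse_polyphen)
        >= t.min_damaging_tools,
        "exonic_protein_altering": protein_altering,
        "non_protein_altering": not protein_altering,
        "expressed_adult_ocular": ge.expressed_adult_ocular,
        "expressed_embryonic_ocular": ge.expressed_embryonic_ocular,
        "freq_novel": fclass == FREQ_NOVEL,
        "freq_rare": fclass == FREQ_RARE,
    }
    total = sum(w[cat] for cat, on in bits.items() if on)
    return EvidenceScore(weighted_total=total, **bits)


def _rank_key(c: CandidateVariant) -> tuple:
    assert c.evidence is not None
    max_maf = c.frequencies.max_maf
    return (
        -c.evidence.weighted_total,
        -1.0 if max_maf is None else max_maf,
        c.variant.gene or "",
        c.variant.key,
    )


def rank_candidates(candidates: Sequence[CandidateVariant]) -> list[CandidateVariant]:
    """Order by descending weighted total; ties break by ascending
    maximum reported MAF (absent sorts first), then gene symbol, then
    variant key. Deterministic under input permutation."""
    for c in candidates:
        if c.evidence is None:
            raise ValidationError(
                f"candidate {c.variant.key} in family {c.family_id} has no evidence score"
            )
    return sorted(candidates, key=_rank_key)


def acmg_evidence(
    c: CandidateVariant,
    t: Thresholds,
    seg: Optional[SegregationResult] = None,
    collapse_polyphen: bool = True,
) -> frozenset[str]:
    """Minimal evidence tags: PM2 (absent/rare in controls), PP1
    (cosegregation), PP3 (computational support)."""
    seg = seg if seg is not None else c.segregation
    tags = set()
    if frequency_class(c.frequencies, t) in (FREQ_NOVEL, FREQ_RARE):
        tags.add("PM2")
    if seg is not None and seg.cosegregates:
        tags.add("PP1")
    if damaging_call_count(c.profile, t, collapse_polyphen) >= t.min_damaging_tools:
        tags.add("PP3")
    return frozenset(tags)


def acmg_classify(
    tags: frozenset[str],
    table: Optional[Mapping[frozenset[str], str]] = None,
    fallback: str = DEFAULT_ACMG_FALLBACK,
) -> str:
    """Map a tag set to a classification via the combining table.

    With only one moderate (PM2) and two supporting (PP1, PP3) tags
    available, the published combining rules cannot reach
    likely_pathogenic, so the default table sends any non-empty tag set
    to uncertain_significance and the empty set to likely_benign. The
    table is overridable via configuration.
    """
    tbl = DEFAULT_ACMG_TABLE if table is None else table
    return tbl.get(frozenset(tags), fallback)


def score_candidate(
    c: CandidateVariant,
    t: Thresholds,
    weights: Optional[Mapping[str, float]] = None,
    collapse_polyphen: bool = True,
) -> CandidateVariant:
    """Attach evidence matrix and ACMG result to a candidate in place."""
    c.evidence = evidence_matrix(c, t, weights, collapse_polyphen)
    tags = acmg_evidence(c, t, collapse_polyphen=collapse_polyphen)
    c.acmg = AcmgResult(tags=tags, classification=acmg_classify(tags))
    return c
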