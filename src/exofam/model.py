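"""Shared domain types for the prioritization pipeline.

All genomic coordinates are 1-based (VCF convention); no half-open
intervals are used anywhere in the package. One :class:`Variant` carries
exactly one alternate allele — multi-allelic VCF records are decomposed
on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional


class ExofamError(Exception):
    """Base class for all package errors."""


class FormatError(ExofamError):
    """A file could not be parsed in its declared dialect."""


class ValidationError(ExofamError):
    """Parsed data violates a domain invariant."""


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def dosage(self) -> Optional[int]:
        """Number of alternate alleles, or None when untyped."""
        return {
            Genotype.HOM_REF: 0,
            Genotype.HET: 1,
            Genotype.HOM_ALT: 2,
            Genotype.MISSING: None,
        }[self]

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)


class Consequence(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    UTR = "utr"
    INTERGENIC = "intergenic"
    OTHER = "other"


#: Consequence classes retained by the cascade (exonic protein-relevant
#: plus predicted splice sites).
KEPT_CONSEQUENCES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
        Consequence.SPLICE_SITE,
    }
)

#: Consequence classes counted as exonic protein-altering in the
#: evidence matrix (splice_site is retained by the cascade but scored
#: as non-protein-altering).
PROTEIN_ALTERING = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
    }
)


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Status(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class InheritanceModel(str, Enum):
    AD = "AD"
    AR = "AR"


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix; X/Y kept as letters."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    transcript: Optional[str] = None
    cdna_hgvs: Optional[str] = None
    consequence: Optional[Consequence] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(
                f"ref and alt must differ at {self.chrom}:{self.pos} ({self.ref})"
            )

    @property
    def key(self) -> str:
        return variant_key(self)


def variant_key(v: Variant) -> str:
    """Canonical, deterministic ``chrom:pos:ref:alt`` key.

    Chromosome labels are normalized so "chr8" and "8" map to the same
    key.
    """
    return f"{normalize_chrom(v.chrom)}:{v.pos}:{v.ref}:{v.alt}"


@dataclass
class Individual:
    id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    se_right: Optional[float] = None
    se_left: Optional[float] = None
    al_right: Optional[float] = None
    al_left: Optional[float] = None
    declared_status: Status = Status.UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def se_values(self) -> list[float]:
        return [v for v in (self.se_right, self.se_left) if v is not None]

    @property
    def al_values(self) -> list[float]:
        return [v for v in (self.al_right, self.al_left) if v is not None]


@dataclass
class Pedigree:
    family_id: str
    members: list[Individual]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(
                f"duplicate member id(s) in family {self.family_id}: {sorted(dupes)}"
            )
        self._by_id = {m.id: m for m in self.members}
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in self._by_id:
                    raise ValidationError(
                        f"family {self.family_id}: parent {pid!r} of {m.id!r} "
                        "is not a member of the family"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Iterative DFS over parent links; any back edge is a cycle.
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {m.id: WHITE for m in self.members}
        for start in self._by_id:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, Iterable[str]]] = [(start, iter(self._parents_of(start)))]
            color[start] = GRAY
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent in it:
                    if color[parent] == GRAY:
                        raise ValidationError(
                            f"family {self.family_id}: cyclic parentage involving {parent!r}"
                        )
                    if color[parent] == WHITE:
                        color[parent] = GRAY
                        stack.append((parent, iter(self._parents_of(parent))))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()

    def _parents_of(self, member_id: str) -> list[str]:
        m = self._by_id[member_id]
        return [p for p in (m.father_id, m.mother_id) if p is not None]

    def member(self, member_id: str) -> Individual:
        return self._by_id[member_id]

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]

    def parents(self, member_id: str) -> tuple[Optional[Individual], Optional[Individual]]:
        m = self._by_id[member_id]
        father = self._by_id.get(m.father_id) if m.father_id else None
        mother = self._by_id.get(m.mother_id) if m.mother_id else None
        return father, mother

    def topological_order(self) -> list[Individual]:
        """Members ordered founders-first (parents before children)."""
        done: dict[str, int] = {}
        order: list[Individual] = []

        def visit(mid: str) -> None:
            if done.get(mid):
                return
            done[mid] = 1
            for pid in self._parents_of(mid):
                visit(pid)
            order.append(self._by_id[mid])

        for m in self.members:
            visit(m.id)
        return order


class GenotypeMatrix:
    """Mapping from (canonical variant key, individual id) to genotype.

    Absent entries read back as :attr:`Genotype.MISSING`.
    """

    def __init__(self) -> None:
        self._data: dict[tuple[str, str], Genotype] = {}
        self._samples: set[str] = set()
        self._variant_keys: set[str] = set()

    def set(self, vkey: str, sample: str, gt: Genotype) -> None:
        self._data[(vkey, sample)] = gt
        self._samples.add(sample)
        self._variant_keys.add(vkey)

    def get(self, vkey: str, sample: str) -> Genotype:
        return self._data.get((vkey, sample), Genotype.MISSING)

    @property
    def samples(self) -> frozenset[str]:
        return frozenset(self._samples)

    @property
    def variant_keys(self) -> frozenset[str]:
        return frozenset(self._variant_keys)

    def __len__(self) -> int:
        return len(self._data)


def _check_fraction(name: str, value: Optional[float]) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class PopulationFrequencies:
    maf_exac: Optional[float] = None
    maf_1000g: Optional[float] = None
    maf_gnomad: Optional[float] = None
    popmax_filtering_af: Optional[float] = None

    def __post_init__(self) -> None:
        _check_fraction("maf_exac", self.maf_exac)
        _check_fraction("maf_1000g", self.maf_1000g)
        _check_fraction("maf_gnomad", self.maf_gnomad)
        _check_fraction("popmax_filtering_af", self.popmax_filtering_af)

    @property
    def present_mafs(self) -> list[float]:
        return [
            v for v in (self.maf_exac, self.maf_1000g, self.maf_gnomad) if v is not None
        ]

    @property
    def max_maf(self) -> Optional[float]:
        present = self.present_mafs
        return max(present) if present else None


class ToolCall(str, Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    MISSING = "missing"


#: Categorical predictor slots, in canonical column order.
CATEGORICAL_TOOLS = (
    "sift",
    "polyphen2_hdiv",
    "polyphen2_hvar",
    "mutation_taster",
    "lrt",
    "mutation_assessor",
    "fathmm",
    "radialsvm",
    "lr",
)


@dataclass(frozen=True)
class PredictionProfile:
    """Calls from nine categorical predictors plus a DANN score.

    Exactly these ten tool slots exist; absent annotations are
    ``missing`` (calls) or ``None`` (DANN).
    """

    sift: ToolCall = ToolCall.MISSING
    polyphen2_hdiv: ToolCall = ToolCall.MISSING
    polyphen2_hvar: ToolCall = ToolCall.MISSING
    mutation_taster: ToolCall = ToolCall.MISSING
    lrt: ToolCall = ToolCall.MISSING
    mutation_assessor: ToolCall = ToolCall.MISSING
    fathmm: ToolCall = ToolCall.MISSING
    radialsvm: ToolCall = ToolCall.MISSING
    lr: ToolCall = ToolCall.MISSING
    dann_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dann_score is not None and not (0.0 <= self.dann_score <= 1.0):
            raise ValidationError(
                f"dann_score must be in [0, 1], got {self.dann_score}"
            )

    def call(self, tool: str) -> ToolCall:
        if tool not in CATEGORICAL_TOOLS:
            raise ValueError(f"unknown tool {tool!r}")
        return getattr(self, tool)


@dataclass(frozen=True)
class GeneEvidence:
    is_known_hm_gene: bool = False
    is_hm_related: bool = False
    is_ocular_disease_gene: bool = False
    myp_locus: Optional[str] = None
    expressed_adult_ocular: bool = False
    expressed_embryonic_ocular: bool = False


NO_GENE_EVIDENCE = GeneEvidence()


@dataclass
class CandidateVariant:
    """A variant considered within one family, carrying its pipeline state."""

    variant: Variant
    family_id: str
    model: InheritanceModel
    consequence: Consequence
    frequencies: PopulationFrequencies = field(default_factory=PopulationFrequencies)
    profile: PredictionProfile = field(default_factory=PredictionProfile)
    gene_evidence: GeneEvidence = NO_GENE_EVIDENCE
    removal_stage: Optional[str] = None
    removal_reason: Optional[str] = None
    segregation: Optional["SegregationResult"] = None  # noqa: F821
    evidence: Optional["EvidenceScore"] = None  # noqa: F821
    acmg: Optional["AcmgResult"] = None  # noqa: F821

    @property
    def removed(self) -> bool:
        return self.removal_stage is not None
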