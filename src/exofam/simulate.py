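"""Gene-drop cohort simulator with known ground truth.

Generates multi-family WES-like cohorts: pedigrees with phenotypes, one
spiked causal variant per family (constructed to satisfy the family's
inheritance model and cosegregate), and a configurable number of
background variants whose genotypes are gene-dropped through every
pedigree at their simulated cohort allele frequency.

All randomness flows from a single ``numpy.random.Generator`` seeded
explicitly; outputs are byte-identical for identical seeds.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .clinical import family_summary
from .model import (
    Consequence,
    GeneEvidence,
    Genotype,
    GenotypeMatrix,
    InheritanceModel,
    Individual,
    Pedigree,
    Sex,
    Status,
    ValidationError,
    Variant,
    variant_key,
    CATEGORICAL_TOOLS,
)
from .variant_io import (
    AnnotationRecord,
    write_annotation_table,
    write_clinical_table,
    write_gene_sets,
    write_ped,
    write_vcf,
)
from .model import PopulationFrequencies, PredictionProfile, ToolCall

PEDIGREE_TEMPLATES = ("trio", "quartet", "three_generation")

#: Consequence mixture for background variants.
_BG_CONSEQUENCES = (
    (Consequence.MISSENSE, 0.40),
    (Consequence.SYNONYMOUS, 0.15),
    (Consequence.INTRONIC, 0.15),
    (Consequence.UTR, 0.05),
    (Consequence.SPLICE_SITE, 0.05),
    (Consequence.NONSENSE, 0.05),
    (Consequence.FRAMESHIFT, 0.05),
    (Consequence.INFRAME_INDEL, 0.05),
    (Consequence.OTHER, 0.05),
)


@dataclass
class SimulationParams:
    n_families: int = 27
    n_ad_families: int = 9
    n_ar_families: int = 18
    pedigree_templates: tuple[str, ...] = PEDIGREE_TEMPLATES
    n_background_variants: int = 200
    # database-frequency class mixture for background variants
    freq_class_weights: dict[str, float] = field(
        default_factory=lambda: {"novel": 0.30, "rare": 0.30, "low": 0.25, "common": 0.15}
    )
    causal_tool_damaging_p: float = 0.9
    background_tool_damaging_p: float = 0.1
    causal_novel_p: float = 0.75
    background_gene_evidence_p: float = 0.05
    background_myp_p: float = 0.02
    affected_se_mean: float = -10.0
    affected_se_sd: float = 3.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_ad_families + self.n_ar_families != self.n_families:
            raise ValidationError(
                "model mix must sum to n_families: "
                f"{self.n_ad_families} AD + {self.n_ar_families} AR != {self.n_families}"
            )
        total = sum(self.freq_class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"freq_class_weights must sum to 1, got {total}")
        for tmpl in self.pedigree_templates:
            if tmpl not in PEDIGREE_TEMPLATES:
                raise ValidationError(f"unknown pedigree template {tmpl!r}")


@dataclass(frozen=True)
class TruthRecord:
    family_id: str
    variant_key: str
    model: InheritanceModel
    expected_to_survive: bool = True


@dataclass
class Cohort:
    params: SimulationParams
    pedigrees: list[Pedigree]
    models: dict[str, InheritanceModel]
    variants: list[Variant]
    genotypes: GenotypeMatrix
    annotations: dict[str, AnnotationRecord]
    gene_evidence: dict[str, GeneEvidence]
    truth: list[TruthRecord]


# ---------------------------------------------------------------------------
# Phenotypes and pedigrees


def _affected_eyes(params: SimulationParams, rng: np.random.Generator) -> tuple[float, float, float, float]:
    # Truncated normal via rejection: person-level SE <= -6 D.
    while True:
        base = rng.normal(params.affected_se_mean, params.affected_se_sd)
        if base <= -6.0:
            break
    se_r = min(base + rng.normal(0.0, 0.25), -6.0)
    se_l = min(base + rng.normal(0.0, 0.25), -6.0)
    al_r = 23.5 - 0.3 * se_r + rng.normal(0.0, 0.3)
    al_l = 23.5 - 0.3 * se_l + rng.normal(0.0, 0.3)
    return se_r, se_l, al_r, al_l


def _unaffected_eyes(rng: np.random.Generator) -> tuple[float, float, float, float]:
    base = rng.uniform(-1.5, 1.5)
    se_r = float(np.clip(base + rng.normal(0.0, 0.2), -1.9, 1.9))
    se_l = float(np.clip(base + rng.normal(0.0, 0.2), -1.9, 1.9))
    al_r = min(23.5 - 0.3 * se_r + rng.normal(0.0, 0.3), 25.9)
    al_l = min(23.5 - 0.3 * se_l + rng.normal(0.0, 0.3), 25.9)
    return se_r, se_l, al_r, al_l


def _make_member(
    family_id: str,
    mid: str,
    sex: Sex,
    affected: bool,
    params: SimulationParams,
    rng: np.random.Generator,
    father: Optional[str] = None,
    mother: Optional[str] = None,
) -> Individual:
    se_r, se_l, al_r, al_l = (
        _affected_eyes(params, rng) if affected else _unaffected_eyes(rng)
    )
    return Individual(
        id=mid,
        family_id=family_id,
        father_id=father,
        mother_id=mother,
        sex=sex,
        se_right=se_r,
        se_left=se_l,
        al_right=al_r,
        al_left=al_l,
        declared_status=Status.AFFECTED if affected else Status.UNAFFECTED,
    )


def simulate_pedigree(
    family_id: str,
    template: str,
    model: InheritanceModel,
    params: SimulationParams,
    rng: np.random.Generator,
) -> Pedigree:
    """Build one pedigree with phenotypes matching the model.

    AD templates show vertical transmission (affected parent and
    child); AR templates have unaffected carrier parents and affected
    children only.
    """
    ad = model is InheritanceModel.AD
    m = lambda *a, **kw: _make_member(family_id, *a, params=params, rng=rng, **kw)  # noqa: E731
    F, M = f"{family_id}_F", f"{family_id}_M"
    if template == "trio":
        members = [
            m(F, Sex.MALE, ad),
            m(M, Sex.FEMALE, False),
            m(f"{family_id}_C1", Sex.MALE, True, father=F, mother=M),
        ]
    elif template == "quartet":
        members = [
            m(F, Sex.MALE, ad),
            m(M, Sex.FEMALE, False),
            m(f"{family_id}_C1", Sex.MALE, True, father=F, mother=M),
            m(f"{family_id}_C2", Sex.FEMALE, not ad, father=F, mother=M),
        ]
    elif template == "three_generation":
        GF, GM = f"{family_id}_GF", f"{family_id}_GM"
        members = [
            m(GF, Sex.MALE, ad),
            m(GM, Sex.FEMALE, False),
            m(F, Sex.MALE, ad, father=GF, mother=GM),
            m(M, Sex.FEMALE, False),
            m(f"{family_id}_C1", Sex.FEMALE, True, father=F, mother=M),
        ]
    else:
        raise ValidationError(f"unknown pedigree template {template!r}")
    return Pedigree(family_id=family_id, members=members)


# ---------------------------------------------------------------------------
# Genotype generation


def gene_drop(
    ped: Pedigree,
    founder_allele_freq: float,
    rng: np.random.Generator,
) -> dict[str, Genotype]:
    """Drop one biallelic variant through a pedigree.

    Founders draw two alleles from Hardy–Weinberg at the given
    frequency; each child allele is copied from a uniformly chosen
    allele of the corresponding parent.
    """
    if not (0.0 <= founder_allele_freq <= 1.0):
        raise ValidationError(
            f"founder allele frequency must be in [0, 1], got {founder_allele_freq}"
        )
    alleles: dict[str, tuple[int, int]] = {}
    for member in ped.topological_order():
        if member.is_founder:
            a = (
                int(rng.random() < founder_allele_freq),
                int(rng.random() < founder_allele_freq),
            )
        else:
            inherited = []
            for pid in (member.father_id, member.mother_id):
                if pid is None:
                    inherited.append(int(rng.random() < founder_allele_freq))
                else:
                    inherited.append(alleles[pid][int(rng.random() < 0.5)])
            a = (inherited[0], inherited[1])
        alleles[member.id] = a
    out: dict[str, Genotype] = {}
    for mid, (a0, a1) in alleles.items():
        dosage = a0 + a1
        out[mid] = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[dosage]
    return out


def _causal_genotypes(ped: Pedigree, model: InheritanceModel) -> dict[str, Genotype]:
    """Construct spike genotypes consistent with the model: AD — every
    affected heterozygous, every unaffected homozygous reference; AR —
    affected homozygous-alternate with heterozygous carrier parents
    (ancestor carriers filled in to keep transmission Mendelian)."""
    gts: dict[str, Genotype] = {}
    statuses = {m.id: m.declared_status for m in ped.members}
    if model is InheritanceModel.AD:
        for m in ped.members:
            gts[m.id] = (
                Genotype.HET if statuses[m.id] is Status.AFFECTED else Genotype.HOM_REF
            )
        return gts
    for m in ped.members:
        gts[m.id] = Genotype.HOM_REF
    for m in ped.members:
        if statuses[m.id] is Status.AFFECTED:
            gts[m.id] = Genotype.HOM_ALT
            for parent in ped.parents(m.id):
                if parent is not None and gts[parent.id] is Genotype.HOM_REF:
                    gts[parent.id] = Genotype.HET
    # ensure every carrier non-founder has a carrier parent
    for m in ped.topological_order():
        if gts[m.id].carries_alt and not m.is_founder:
            parents = [p for p in ped.parents(m.id) if p is not None]
            if parents and not any(gts[p.id].carries_alt for p in parents):
                gts[parents[0].id] = Genotype.HET
    return gts


def _causal_profile(params: SimulationParams, rng: np.random.Generator) -> PredictionProfile:
    calls = {
        tool: (
            ToolCall.DAMAGING
            if rng.random() < params.causal_tool_damaging_p
            else ToolCall.TOLERATED
        )
        for tool in CATEGORICAL_TOOLS
    }
    return PredictionProfile(dann_score=float(rng.uniform(0.91, 0.999)), **calls)


def _background_profile(params: SimulationParams, rng: np.random.Generator) -> PredictionProfile:
    calls = {}
    for tool in CATEGORICAL_TOOLS:
        u = rng.random()
        if u < params.background_tool_damaging_p:
            calls[tool] = ToolCall.DAMAGING
        elif u < 0.9:
            calls[tool] = ToolCall.TOLERATED
        else:
            calls[tool] = ToolCall.MISSING
    dann = float(rng.uniform(0.0, 1.0)) if rng.random() < 0.8 else None
    return PredictionProfile(dann_score=dann, **calls)


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def spike_causal(
    ped: Pedigree,
    model: InheritanceModel,
    params: SimulationParams,
    rng: np.random.Generator,
    family_index: int = 0,
) -> tuple[Variant, dict[str, Genotype], AnnotationRecord, TruthRecord]:
    """Create one causal variant for a family, with genotypes, novel or
    rare frequencies, a mostly-damaging prediction profile and a truth
    record."""
    gene = f"HMG{ped.family_id}"
    variant = Variant(
        chrom=str(family_index % 22 + 1),
        pos=1_000_000 + family_index * 1_000,
        ref="A",
        alt="G",
        gene=gene,
        consequence=Consequence.MISSENSE,
    )
    if rng.random() < params.causal_novel_p:
        freqs = PopulationFrequencies()
    else:
        maf = _loguniform(rng, 1e-5, 9e-4)
        freqs = PopulationFrequencies(maf_exac=maf)
    rec = AnnotationRecord(
        frequencies=freqs,
        profile=_causal_profile(params, rng),
        consequence=Consequence.MISSENSE,
        gene=gene,
        cdna_hgvs=f"c.{family_index * 3 + 1}A>G",
    )
    truth = TruthRecord(
        family_id=ped.family_id,
        variant_key=variant_key(variant),
        model=model,
        expected_to_survive=True,
    )
    return variant, _causal_genotypes(ped, model), rec, truth


# ---------------------------------------------------------------------------
# Cohort assembly


def _background_variant(
    index: int,
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[Variant, AnnotationRecord, GeneEvidence, float]:
    gene = f"BG{index:05d}"
    consequences, weights = zip(*_BG_CONSEQUENCES)
    consequence = consequences[rng.choice(len(consequences), p=np.array(weights))]
    classes = list(params.freq_class_weights)
    probs = np.array([params.freq_class_weights[c] for c in classes])
    fclass = classes[rng.choice(len(classes), p=probs)]
    if fclass == "novel":
        maf = None
    elif fclass == "rare":
        maf = _loguniform(rng, 1e-5, 9.9e-4)
    elif fclass == "low":
        maf = _loguniform(rng, 1e-3, 9.9e-3)
    else:
        maf = _loguniform(rng, 1e-2, 0.5)
    if maf is None:
        freqs = PopulationFrequencies()
    else:
        kwargs = {"maf_exac": maf}
        if rng.random() < 0.5:
            kwargs["maf_1000g"] = maf * float(rng.uniform(0.3, 1.0))
        if rng.random() < 0.5:
            kwargs["maf_gnomad"] = maf * float(rng.uniform(0.3, 1.0))
        freqs = PopulationFrequencies(**kwargs)
    # cohort allele frequency used for gene drop: database-rare variants
    # can still segregate in this cohort
    drop_freq = maf if (maf is not None and maf >= 2e-3) else _loguniform(rng, 2e-3, 2e-2)
    variant = Variant(
        chrom=str(index % 22 + 1),
        pos=2_000_000 + index * 10,
        ref="C",
        alt="T",
        gene=gene,
        consequence=consequence,
    )
    rec = AnnotationRecord(
        frequencies=freqs,
        profile=_background_profile(params, rng),
        consequence=consequence,
        gene=gene,
    )
    evidence = GeneEvidence(
        is_known_hm_gene=rng.random() < params.background_gene_evidence_p,
        is_hm_related=rng.random() < params.background_gene_evidence_p,
        is_ocular_disease_gene=rng.random() < params.background_gene_evidence_p,
        myp_locus=(
            f"MYP{int(rng.integers(1, 27))}"
            if rng.random() < params.background_myp_p
            else None
        ),
        expressed_adult_ocular=rng.random() < params.background_gene_evidence_p,
        expressed_embryonic_ocular=rng.random() < params.background_gene_evidence_p,
    )
    return variant, rec, evidence, drop_freq


CAUSAL_GENE_EVIDENCE = GeneEvidence(
    is_known_hm_gene=True,
    is_ocular_disease_gene=True,
    expressed_adult_ocular=True,
    expressed_embryonic_ocular=True,
)


def simulate_cohort(params: Optional[SimulationParams] = None) -> Cohort:
    """Generate a full in-memory cohort from one seeded random stream."""
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)

    pedigrees: list[Pedigree] = []
    models: dict[str, InheritanceModel] = {}
    for i in range(params.n_families):
        family_id = f"FAM{i + 1:03d}"
        model = (
            InheritanceModel.AD if i < params.n_ad_families else InheritanceModel.AR
        )
        template = params.pedigree_templates[i % len(params.pedigree_templates)]
        pedigrees.append(simulate_pedigree(family_id, template, model, params, rng))
        models[family_id] = model

    variants: list[Variant] = []
    matrix = GenotypeMatrix()
    annotations: dict[str, AnnotationRecord] = {}
    gene_evidence: dict[str, GeneEvidence] = {}
    truth: list[TruthRecord] = []

    # one causal spike per family; homozygous-reference elsewhere
    for i, ped in enumerate(pedigrees):
        variant, gts, rec, rec_truth = spike_causal(
            ped, models[ped.family_id], params, rng, family_index=i
        )
        vkey = variant_key(variant)
        variants.append(variant)
        annotations[vkey] = rec
        gene_evidence[rec.gene] = CAUSAL_GENE_EVIDENCE
        truth.append(rec_truth)
        for other in pedigrees:
            if other.family_id == ped.family_id:
                for mid, gt in gts.items():
                    matrix.set(vkey, mid, gt)
            else:
                for m in other.members:
                    matrix.set(vkey, m.id, Genotype.HOM_REF)

    # background variants, gene-dropped through every pedigree
    n_background = params.n_background_variants * params.n_families
    for j in range(n_background):
        variant, rec, evidence, drop_freq = _background_variant(j, params, rng)
        vkey = variant_key(variant)
        variants.append(variant)
        annotations[vkey] = rec
        if (
            evidence != GeneEvidence()
        ):  # only record genes with some evidence; rest default to all-false
            gene_evidence[rec.gene] = evidence
        for ped in pedigrees:
            for mid, gt in gene_drop(ped, drop_freq, rng).items():
                matrix.set(vkey, mid, gt)

    return Cohort(
        params=params,
        pedigrees=pedigrees,
        models=models,
        variants=variants,
        genotypes=matrix,
        annotations=annotations,
        gene_evidence=gene_evidence,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Emission


@dataclass(frozen=True)
class CohortFiles:
    vcf: str
    ped: str
    annotations: str
    clinical: str
    truth: str
    gene_sets_dir: str


def write_truth_table(path: str, truth: Sequence[TruthRecord]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("family\tvariant_key\tmodel\texpected_to_survive\n")
        for t in truth:
            fh.write(
                f"{t.family_id}\t{t.variant_key}\t{t.model.value}\t"
                f"{int(t.expected_to_survive)}\n"
            )


def read_truth_table(path: str) -> list[TruthRecord]:
    records: list[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("family\t"):
            raise ValidationError(f"{path}: not a truth table")
        for line in fh:
            fam, vkey, model, survive = line.rstrip("\n").split("\t")
            records.append(
                TruthRecord(
                    family_id=fam,
                    variant_key=vkey,
                    model=InheritanceModel(model),
                    expected_to_survive=bool(int(survive)),
                )
            )
    return records


def emit_cohort(
    params: Optional[SimulationParams] = None,
    outdir: str = ".",
    cohort: Optional[Cohort] = None,
) -> CohortFiles:
    """Simulate (or take) a cohort and write every pipeline input file.

    Outputs: ``cohort.vcf``, ``cohort.ped``, ``annotations.tsv``,
    ``clinical.tsv``, ``truth.tsv`` and a ``gene_sets/`` directory, all
    in the dialects the readers in :mod:`exofam.variant_io` expect.
    """
    cohort = cohort or simulate_cohort(params)
    try:
        os.makedirs(outdir, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {outdir}: {exc}") from exc

    files = CohortFiles(
        vcf=os.path.join(outdir, "cohort.vcf"),
        ped=os.path.join(outdir, "cohort.ped"),
        annotations=os.path.join(outdir, "annotations.tsv"),
        clinical=os.path.join(outdir, "clinical.tsv"),
        truth=os.path.join(outdir, "truth.tsv"),
        gene_sets_dir=os.path.join(outdir, "gene_sets"),
    )
    samples = [m.id for ped in cohort.pedigrees for m in ped.members]
    write_vcf(files.vcf, cohort.variants, cohort.genotypes, samples)
    write_ped(files.ped, cohort.pedigrees)
    write_annotation_table(
        files.annotations,
        [(v, cohort.annotations[variant_key(v)]) for v in cohort.variants],
    )
    rows = []
    for i, ped in enumerate(cohort.pedigrees):
        age_rng = np.random.default_rng(cohort.params.seed + 10_000 + i)
        rows.append(
            family_summary(ped.members).to_clinical_row(
                proband_age=int(age_rng.integers(15, 41))
            )
        )
    write_clinical_table(files.clinical, rows)
    write_truth_table(files.truth, cohort.truth)
    write_gene_sets(files.gene_sets_dir, cohort.gene_evidence)
    return files
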