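"""End-to-end orchestration: cascade -> cosegregation -> scoring -> ranking,
with an audit funnel and file reports.

Every count printed by :func:`funnel_report` is re-derivable from the
emitted per-stage TSVs.
"""

from __future__ import annotations

import datetime
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .cascade import CascadeResult, FilterFunnel, run_cascade
from .config import RunConfig
from .model import CandidateVariant, NO_GENE_EVIDENCE, Pedigree
from .scoring import rank_candidates, score_candidate
from .segregation import partition_by_segregation
from .variant_io import (
    read_annotation_table,
    read_gene_sets_dir,
    read_ped,
    read_vcf,
    write_ranked_table,
)

logger = logging.getLogger("exofam")


@dataclass
class PipelineRun:
    config: RunConfig
    inputs: dict[str, str]
    funnel: FilterFunnel
    cosegregating: list[CandidateVariant]
    non_cosegregating: list[CandidateVariant]
    ranked: list[CandidateVariant]
    cascade: CascadeResult
    warnings: list[str] = field(default_factory=list)
    started: str = field(
        default_factory=lambda: datetime.datetime.now().isoformat(timespec="seconds")
    )


def write_funnel_table(path: str, funnel: FilterFunnel) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("stage\tinput\tkept\tremoved\n")
        for name, inp, kept, removed in funnel.to_rows():
            fh.write(f"{name}\t{inp}\t{kept}\t{removed}\n")


def write_non_cosegregating_table(path: str, candidates: Sequence[CandidateVariant]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("family\tgene\tvariant_key\tmodel\tviolations\n")
        for c in candidates:
            violations = (
                ";".join(f"{mid}:{reason}" for mid, reason in c.segregation.violating_members)
                if c.segregation
                else "."
            )
            fh.write(
                f"{c.family_id}\t{c.variant.gene or '.'}\t{c.variant.key}\t"
                f"{c.model.value}\t{violations}\n"
            )


def run_pipeline(
    vcf: str,
    ped: str,
    annotations: str,
    gene_sets_dir: Optional[str] = None,
    config: Optional[RunConfig] = None,
    outdir: Optional[str] = None,
) -> PipelineRun:
    """Run the whole prioritization pipeline from files.

    VCF samples absent from every pedigree are ignored with a warning;
    candidates are filtered per family, tested for cosegregation,
    scored on the 11-category evidence matrix and ranked. When
    ``outdir`` is given, ``funnel.tsv``, ``non_cosegregating.tsv`` and
    ``ranked_report.tsv`` are written there.
    """
    cfg = config or RunConfig()
    warnings: list[str] = []

    logger.info("[io] reading VCF %s", vcf)
    variants, matrix = read_vcf(vcf)
    logger.info("[io] reading PED %s", ped)
    pedigrees: list[Pedigree] = read_ped(ped)
    known_samples = {m.id for p in pedigrees for m in p.members}
    stray = sorted(matrix.samples - known_samples)
    if stray:
        msg = f"[io] {len(stray)} VCF sample(s) absent from all pedigrees: {stray[:5]}"
        warnings.append(msg)
        logger.warning(msg)
    logger.info("[io] reading annotations %s", annotations)
    annotation_map = read_annotation_table(annotations)
    gene_evidence = read_gene_sets_dir(gene_sets_dir) if gene_sets_dir else {}
    if not gene_evidence:
        warnings.append("[io] no gene-set evidence loaded; all gene bits false")

    logger.info("[cascade] filtering %d variants in %d families", len(variants), len(pedigrees))
    cascade = run_cascade(variants, matrix, pedigrees, annotation_map, cfg)
    for cand in cascade.candidates:
        if cand.variant.gene:
            cand.gene_evidence = gene_evidence.get(cand.variant.gene, NO_GENE_EVIDENCE)

    peds_by_id = {p.family_id: p for p in pedigrees}
    logger.info("[segregation] testing %d surviving candidates", len(cascade.survivors))
    cosegregating, non_cosegregating = partition_by_segregation(
        cascade.survivors, matrix, peds_by_id, cfg.thresholds
    )
    logger.info(
        "[segregation] %d cosegregating / %d not",
        len(cosegregating),
        len(non_cosegregating),
    )

    for cand in cosegregating:
        score_candidate(cand, cfg.thresholds, cfg.weights, cfg.collapse_polyphen)
    ranked = rank_candidates(cosegregating)

    run = PipelineRun(
        config=cfg,
        inputs={
            "vcf": vcf,
            "ped": ped,
            "annotations": annotations,
            "gene_sets_dir": gene_sets_dir or "",
        },
        funnel=cascade.funnel,
        cosegregating=cosegregating,
        non_cosegregating=non_cosegregating,
        ranked=ranked,
        cascade=cascade,
        warnings=warnings,
    )
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_funnel_table(os.path.join(outdir, "funnel.tsv"), cascade.funnel)
        write_non_cosegregating_table(
            os.path.join(outdir, "non_cosegregating.tsv"), non_cosegregating
        )
        write_ranked_table(os.path.join(outdir, "ranked_report.tsv"), ranked)
        logger.info("[report] wrote reports to %s", outdir)
    return run


def funnel_report(run: PipelineRun, top_k: Optional[int] = None) -> str:
    """Human-readable run summary: per-stage funnel, cosegregation
    partition and the top-k ranked candidates."""
    k = run.config.top_k if top_k is None else top_k
    lines = ["stage            input   kept  removed"]
    for name, inp, kept, removed in run.funnel.to_rows():
        lines.append(f"{name:<16} {inp:>6} {kept:>6} {removed:>8}")
    lines.append("")
    lines.append(
        f"cosegregating: {len(run.cosegregating)}   "
        f"non-cosegregating: {len(run.non_cosegregating)}"
    )
    lines.append("")
    lines.append("rank  family   gene            score  freq_class      acmg")
    for i, c in enumerate(run.ranked[:k], start=1):
        assert c.evidence is not None and c.acmg is not None
        lines.append(
            f"{i:<5} {c.family_id:<8} {(c.variant.gene or '.'):<15} "
            f"{c.evidence.weighted_total:<6g} {c.evidence.frequency_class:<15} "
            f"{c.acmg.classification}"
        )
    return "\n".join(lines)
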