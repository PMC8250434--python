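import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exofam.config import Thresholds
from exofam.model import (
    Consequence,
    FormatError,
    GeneEvidence,
    Genotype,
    Individual,
    Pedigree,
    PopulationFrequencies,
    PredictionProfile,
    Status,
    ToolCall,
    ValidationError,
    Variant,
    variant_key,
)
from exofam.scoring import AcmgResult, evidence_matrix
from exofam.model import CandidateVariant, InheritanceModel
from exofam import variant_io


def write_vcf_text(path, records, samples=("P", "F")):
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in dict.fromkeys(r[0] for r in records):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for chrom, pos, ref, alt, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return str(path)


class TestReadVcf:
    def test_single_record(self, tmp_path):
        path = write_vcf_text(tmp_path / "a.vcf", [("1", 100, "A", "G", ["0/1", "0/0"])])
        variants, matrix = variant_io.read_vcf(path)
        assert len(variants) == 1
        key = variant_key(variants[0])
        assert matrix.get(key, "P") is Genotype.HET
        assert matrix.get(key, "F") is Genotype.HOM_REF

    def test_multiallelic_decomposition(self, tmp_path):
        path = write_vcf_text(tmp_path / "a.vcf", [("1", 100, "A", "G,T", ["1/2", "0/0"])])
        variants, matrix = variant_io.read_vcf(path)
        assert [v.alt for v in variants] == ["G", "T"]
        for v in variants:
            assert matrix.get(variant_key(v), "P") is Genotype.HET

    def test_missing_genotype(self, tmp_path):
        path = write_vcf_text(tmp_path / "a.vcf", [("1", 100, "A", "G", ["./.", "0/1"])])
        variants, matrix = variant_io.read_vcf(path)
        assert matrix.get(variant_key(variants[0]), "P") is Genotype.MISSING

    def test_malformed_vcf_raises(self, tmp_path):
        bad = tmp_path / "bad.vcf"
        bad.write_text("this is not a vcf\n")
        with pytest.raises(FormatError):
            variant_io.read_vcf(str(bad))

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=2),
                st.integers(min_value=0, max_value=2),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_decomposition_conserves_alt_observations(self, tmp_path_factory, gts):
        # one record with two alts; non-reference allele calls summed over
        # decomposed records must equal those of the original record
        tmp = tmp_path_factory.mktemp("vcf")
        samples = [f"S{i}" for i in range(len(gts))]
        gt_strings = [f"{a}/{b}" for a, b in gts]
        path = write_vcf_text(
            tmp / "m.vcf", [("1", 500, "A", "G,T", gt_strings)], samples=samples
        )
        variants, matrix = variant_io.read_vcf(path)
        original_nonref = sum((a != 0) + (b != 0) for a, b in gts)
        decomposed = 0
        for v in variants:
            for s in samples:
                d = matrix.get(variant_key(v), s).dosage
                decomposed += d or 0
        assert decomposed == original_nonref


class TestReadPed:
    def test_trio(self, tmp_path):
        p = tmp_path / "t.ped"
        p.write_text("FAM1 F 0 0 1 2\nFAM1 M 0 0 2 1\nFAM1 C F M 1 2\n")
        peds = variant_io.read_ped(str(p))
        assert len(peds) == 1
        child = peds[0].member("C")
        assert child.father_id == "F" and child.mother_id == "M"
        assert child.declared_status is Status.AFFECTED
        assert peds[0].member("M").declared_status is Status.UNAFFECTED

    def test_zero_parent_is_founder(self, tmp_path):
        p = tmp_path / "t.ped"
        p.write_text("FAM1 F 0 0 1 2\n")
        peds = variant_io.read_ped(str(p))
        assert peds[0].member("F").is_founder

    def test_own_father_rejected(self, tmp_path):
        p = tmp_path / "t.ped"
        p.write_text("FAM1 A A 0 1 2\n")
        with pytest.raises(ValidationError):
            variant_io.read_ped(str(p))

    def test_duplicate_rejected(self, tmp_path):
        p = tmp_path / "t.ped"
        p.write_text("FAM1 A 0 0 1 2\nFAM1 A 0 0 1 2\n")
        with pytest.raises(ValidationError):
            variant_io.read_ped(str(p))

    def test_cycle_rejected(self, tmp_path):
        p = tmp_path / "t.ped"
        p.write_text("FAM1 A B 0 1 2\nFAM1 B A 0 1 2\n")
        with pytest.raises(ValidationError):
            variant_io.read_ped(str(p))


class TestPedigreeGraphProperty:
    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_acyclic_accepted_cyclic_rejected(self, data):
        n = data.draw(st.integers(min_value=2, max_value=8))
        ids = [f"I{i}" for i in range(n)]
        graph = nx.DiGraph()
        graph.add_nodes_from(ids)
        members = []
        for i, mid in enumerate(ids):
            father = data.draw(
                st.one_of(st.none(), st.sampled_from([x for x in ids if x != mid]))
            )
            mother = data.draw(
                st.one_of(st.none(), st.sampled_from([x for x in ids if x != mid]))
            )
            members.append(
                Individual(id=mid, family_id="FAM", father_id=father, mother_id=mother)
            )
            for parent in (father, mother):
                if parent is not None:
                    graph.add_edge(mid, parent)
        if nx.is_directed_acyclic_graph(graph):
            Pedigree(family_id="FAM", members=members)  # must not raise
        else:
            with pytest.raises(ValidationError):
                Pedigree(family_id="FAM", members=members)


ANNOT_HEADER = "\t".join(variant_io.ANNOTATION_COLUMNS)


def annot_row(**overrides):
    row = {col: "" for col in variant_io.ANNOTATION_COLUMNS}
    row.update(chrom="8", pos="2913", ref="C", alt="T", consequence="missense")
    row.update(overrides)
    return "\t".join(row[col] for col in variant_io.ANNOTATION_COLUMNS)


class TestAnnotationTable:
    def test_single_database_frequency(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(ANNOT_HEADER + "\n" + annot_row(maf_exac="0.0014") + "\n")
        records = variant_io.read_annotation_table(str(p))
        rec = records["8:2913:C:T"]
        assert rec.frequencies.maf_exac == pytest.approx(0.0014)
        assert rec.frequencies.maf_1000g is None
        assert rec.frequencies.maf_gnomad is None

    def test_all_empty_frequencies_is_novel(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(ANNOT_HEADER + "\n" + annot_row() + "\n")
        rec = variant_io.read_annotation_table(str(p))["8:2913:C:T"]
        assert rec.frequencies.present_mafs == []

    def test_dann_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(ANNOT_HEADER + "\n" + annot_row(dann="1.3") + "\n")
        with pytest.raises(ValidationError):
            variant_io.read_annotation_table(str(p))

    def test_frequency_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(ANNOT_HEADER + "\n" + annot_row(maf_exac="2.0") + "\n")
        with pytest.raises(ValidationError):
            variant_io.read_annotation_table(str(p))

    def test_unknown_column_rejected(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(ANNOT_HEADER + "\tcadd\n" + annot_row() + "\t25\n")
        with pytest.raises(FormatError):
            variant_io.read_annotation_table(str(p))

    def test_tool_calls_parsed(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(
            ANNOT_HEADER + "\n" + annot_row(sift="D", lrt="T", dann="0.999") + "\n"
        )
        rec = variant_io.read_annotation_table(str(p))["8:2913:C:T"]
        assert rec.profile.sift is ToolCall.DAMAGING
        assert rec.profile.lrt is ToolCall.TOLERATED
        assert rec.profile.fathmm is ToolCall.MISSING
        assert rec.profile.dann_score == pytest.approx(0.999)


class TestGeneSets:
    def test_known_hm_only(self, tmp_path):
        (tmp_path / "known.txt").write_text("ZNF644\n")
        ev = variant_io.read_gene_sets(known_hm=str(tmp_path / "known.txt"))
        assert ev["ZNF644"] == GeneEvidence(is_known_hm_gene=True)

    def test_myp_locus(self, tmp_path):
        (tmp_path / "myp.tsv").write_text("CSMD1\tMYP10\n")
        ev = variant_io.read_gene_sets(myp_map=str(tmp_path / "myp.tsv"))
        assert ev["CSMD1"].myp_locus == "MYP10"

    def test_absent_gene_has_no_entry(self, tmp_path):
        (tmp_path / "known.txt").write_text("ZNF644\n")
        ev = variant_io.read_gene_sets(known_hm=str(tmp_path / "known.txt"))
        assert "NOTAGENE" not in ev

    def test_roundtrip_via_directory(self, tmp_path):
        evidence = {
            "A1": GeneEvidence(is_known_hm_gene=True, myp_locus="MYP3"),
            "B2": GeneEvidence(expressed_adult_ocular=True, is_hm_related=True),
        }
        variant_io.write_gene_sets(str(tmp_path / "gs"), evidence)
        back = variant_io.read_gene_sets_dir(str(tmp_path / "gs"))
        assert back == evidence


class TestClinicalTable:
    HEADER = "\t".join(variant_io.CLINICAL_COLUMNS)

    def test_parse_row(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(
            self.HEADER + "\n85\t57\t2\t-19.50/-23.75\t-20.25\t29.61/31.72\t30.85\n"
        )
        rows = variant_io.read_clinical_table(str(p))
        assert rows[0].se_range == (-23.75, -19.50)
        assert rows[0].se_median == pytest.approx(-20.25)
        assert rows[0].al_median == pytest.approx(30.85)
        assert rows[0].affected_count == 2

    def test_degenerate_range(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(self.HEADER + "\n102\t17\t1\t-7.50/-7.50\t-7.50\t27.46/27.50\t27.48\n")
        rows = variant_io.read_clinical_table(str(p))
        assert rows[0].se_range == (-7.50, -7.50)

    def test_non_numeric_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(self.HEADER + "\n99\t19\t1\tx/-7\t-7\t27/28\t27.5\n")
        with pytest.raises(FormatError, match="family 99"):
            variant_io.read_clinical_table(str(p))

    def test_unicode_minus_accepted(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(self.HEADER + "\n85\t57\t2\t−19.50/−23.75\t−20.25\t29.61/31.72\t30.85\n")
        rows = variant_io.read_clinical_table(str(p))
        assert rows[0].se_median == pytest.approx(-20.25)


class TestVariantKey:
    def test_chr_prefix_normalized(self):
        a = Variant(chrom="chr8", pos=2913, ref="C", alt="T")
        b = Variant(chrom="8", pos=2913, ref="C", alt="T")
        assert variant_key(a) == variant_key(b) == "8:2913:C:T"

    def test_distinct_alts_distinct_keys(self):
        a = Variant(chrom="1", pos=100, ref="A", alt="G")
        b = Variant(chrom="1", pos=100, ref="A", alt="T")
        assert variant_key(a) != variant_key(b)

    def test_stable(self):
        v = Variant(chrom="chrX", pos=5, ref="A", alt="C")
        assert variant_key(v) == variant_key(v) == "X:5:A:C"


def _scored_candidate(i: int, seed: int = 0) -> CandidateVariant:
    rng = random.Random(seed + i)
    variant = Variant(
        chrom=str(rng.randint(1, 22)),
        pos=1000 + i,
        ref="A",
        alt="G",
        gene=f"G{i}",
        cdna_hgvs=f"c.{i + 1}A>G",
    )
    cand = CandidateVariant(
        variant=variant,
        family_id=f"FAM{i}",
        model=InheritanceModel.AD,
        consequence=Consequence.MISSENSE,
        frequencies=PopulationFrequencies(maf_exac=rng.choice([None, 0.0005, 0.005])),
        profile=PredictionProfile(
            sift=rng.choice([ToolCall.DAMAGING, ToolCall.TOLERATED]),
            dann_score=rng.random(),
        ),
        gene_evidence=GeneEvidence(
            is_known_hm_gene=rng.random() < 0.5,
            expressed_adult_ocular=rng.random() < 0.5,
        ),
    )
    cand.evidence = evidence_matrix(cand, Thresholds())
    cand.acmg = AcmgResult(tags=frozenset({"PM2"}), classification="uncertain_significance")
    return cand


class TestRankedTable:
    def test_empty_list_header_only(self, tmp_path):
        p = tmp_path / "r.tsv"
        variant_io.write_ranked_table(str(p), [])
        lines = p.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t") == list(variant_io.RANKED_COLUMNS)

    def test_two_rows_in_order(self, tmp_path):
        p = tmp_path / "r.tsv"
        cands = [_scored_candidate(0), _scored_candidate(1)]
        variant_io.write_ranked_table(str(p), cands)
        records = variant_io.read_ranked_table(str(p))
        assert [r["family"] for r in records] == ["FAM0", "FAM1"]

    def test_round_trip_preserves_bits(self, tmp_path):
        from exofam.config import CATEGORY_ORDER

        cands = [_scored_candidate(i, seed=7) for i in range(5)]
        p1 = tmp_path / "r1.tsv"
        variant_io.write_ranked_table(str(p1), cands)
        records = variant_io.read_ranked_table(str(p1))
        for cand, rec in zip(cands, records):
            for cat in CATEGORY_ORDER:
                assert rec[cat] == getattr(cand.evidence, cat)
            assert rec["weighted_total"] == pytest.approx(cand.evidence.weighted_total)
            assert rec["variant_key"] == cand.variant.key
        # write->read->write is byte-stable
        p2 = tmp_path / "r2.tsv"
        variant_io.write_ranked_table(str(p2), cands)
        assert p1.read_bytes() == p2.read_bytes()
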