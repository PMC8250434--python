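import filecmp
import math
import os

import numpy as np
import pytest

from exofam.cascade import run_cascade
from exofam.config import Thresholds
from exofam.model import (
    Genotype,
    InheritanceModel,
    Pedigree,
    Status,
    ValidationError,
)
from exofam.segregation import cosegregates, phenotype_status
from exofam.simulate import (
    SimulationParams,
    emit_cohort,
    gene_drop,
    read_truth_table,
    simulate_cohort,
    simulate_pedigree,
    spike_causal,
)
from exofam.variant_io import read_ped


def small_params(seed=1, families=6, ad=2, background=30):
    return SimulationParams(
        n_families=families,
        n_ad_families=ad,
        n_ar_families=families - ad,
        n_background_variants=background,
        seed=seed,
    )


class TestParams:
    def test_model_mix_must_sum(self):
        with pytest.raises(ValidationError):
            SimulationParams(n_families=5, n_ad_families=2, n_ar_families=2)

    def test_defaults_mirror_cohort_mix(self):
        p = SimulationParams()
        assert (p.n_families, p.n_ad_families, p.n_ar_families) == (27, 9, 18)


class TestSimulatePedigree:
    def test_ad_trio_vertical_transmission(self):
        rng = np.random.default_rng(1)
        ped = simulate_pedigree("FAM1", "trio", InheritanceModel.AD, SimulationParams(), rng)
        affected = [m for m in ped.members if m.declared_status is Status.AFFECTED]
        assert len(ped.members) == 3 and len(affected) == 2
        child = ped.member("FAM1_C1")
        assert child.declared_status is Status.AFFECTED
        assert ped.member(child.father_id).declared_status is Status.AFFECTED

    def test_ar_quartet_parents_unaffected(self):
        rng = np.random.default_rng(1)
        ped = simulate_pedigree("FAM1", "quartet", InheritanceModel.AR, SimulationParams(), rng)
        for pid in ("FAM1_F", "FAM1_M"):
            assert ped.member(pid).declared_status is Status.UNAFFECTED

    def test_affected_members_meet_inclusion_criteria(self, thresholds):
        rng = np.random.default_rng(2)
        for template in ("trio", "quartet", "three_generation"):
            ped = simulate_pedigree("FAM1", template, InheritanceModel.AD,
                                    SimulationParams(), rng)
            for m in ped.members:
                if m.declared_status is Status.AFFECTED:
                    assert min(m.se_values) <= -6.0
                # phenotype-derived status agrees with the declared label
                relabeled = Individual_copy_without_declared(m)
                assert phenotype_status(relabeled, thresholds) is m.declared_status


def Individual_copy_without_declared(m):
    from dataclasses import replace

    return replace(m, declared_status=Status.UNKNOWN)


def genotype_compatible(child, father, mother):
    """Genotype-level Mendelian compatibility (independent checker)."""
    options = {
        Genotype.HOM_REF: [(0, 0)],
        Genotype.HET: [(0, 1), (1, 0)],
        Genotype.HOM_ALT: [(1, 1)],
    }

    def can_give(parent_gt, allele):
        return {
            Genotype.HOM_REF: allele == 0,
            Genotype.HET: True,
            Genotype.HOM_ALT: allele == 1,
        }[parent_gt]

    return any(
        can_give(father, a) and can_give(mother, b) for a, b in options[child]
    )


def count_mendelian_violations(ped: Pedigree, genotypes: dict[str, Genotype]) -> int:
    n = 0
    for m in ped.members:
        if m.father_id is None or m.mother_id is None:
            continue
        trio = (genotypes[m.id], genotypes[m.father_id], genotypes[m.mother_id])
        if Genotype.MISSING in trio:
            continue
        if not genotype_compatible(*trio):
            n += 1
    return n


class TestGeneDrop:
    def test_freq_zero_all_hom_ref(self, ad_trio):
        rng = np.random.default_rng(0)
        gts = gene_drop(ad_trio, 0.0, rng)
        assert all(gt is Genotype.HOM_REF for gt in gts.values())

    def test_freq_one_all_hom_alt(self, ad_trio):
        rng = np.random.default_rng(0)
        gts = gene_drop(ad_trio, 1.0, rng)
        assert all(gt is Genotype.HOM_ALT for gt in gts.values())

    def test_invalid_freq_rejected(self, ad_trio):
        with pytest.raises(ValidationError):
            gene_drop(ad_trio, 1.5, np.random.default_rng(0))

    def test_child_heterozygosity_at_half(self, ad_trio):
        # P(child het) = 0.5 under Hardy-Weinberg founders at p = 0.5
        rng = np.random.default_rng(123)
        n = 10_000
        hets = sum(gene_drop(ad_trio, 0.5, rng)["C"] is Genotype.HET for _ in range(n))
        p = 0.5
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(hets - n * p) < 3 * sigma

    def test_founder_frequency_recovery(self, ad_trio):
        # estimate founder allele frequency from >= 500 founders
        rng = np.random.default_rng(7)
        p_true = 0.3
        n_founders = 600
        alt_alleles = 0
        for _ in range(n_founders // 2):  # two founders per drop
            gts = gene_drop(ad_trio, p_true, rng)
            for founder in ("F", "M"):
                alt_alleles += gts[founder].dosage
        n_alleles = n_founders * 2
        sigma = math.sqrt(n_alleles * p_true * (1 - p_true))
        assert abs(alt_alleles - n_alleles * p_true) < 3 * sigma

    def test_mendelian_consistency_exhaustive(self):
        cohort = simulate_cohort(small_params(seed=5))
        total = 0
        for ped in cohort.pedigrees:
            for vkey in cohort.annotations:
                gts = {m.id: cohort.genotypes.get(vkey, m.id) for m in ped.members}
                total += count_mendelian_violations(ped, gts)
        assert total == 0


class TestSpikeCausal:
    @pytest.mark.parametrize("template,model", [
        ("trio", InheritanceModel.AD),
        ("quartet", InheritanceModel.AD),
        ("three_generation", InheritanceModel.AD),
        ("trio", InheritanceModel.AR),
        ("quartet", InheritanceModel.AR),
        ("three_generation", InheritanceModel.AR),
    ])
    def test_spike_is_model_consistent_and_cosegregates(self, template, model, thresholds):
        rng = np.random.default_rng(11)
        params = SimulationParams()
        ped = simulate_pedigree("FAM1", template, model, params, rng)
        variant, gts, rec, truth = spike_causal(ped, model, params, rng)
        assert count_mendelian_violations(ped, gts) == 0
        from conftest import matrix_for

        matrix = matrix_for(variant.key, gts)
        assert cosegregates(variant.key, matrix, ped, model, thresholds).cosegregates
        if model is InheritanceModel.AR:
            for m in ped.members:
                if m.declared_status is Status.AFFECTED:
                    assert gts[m.id] is Genotype.HOM_ALT
                    for parent in ped.parents(m.id):
                        if parent is not None:
                            assert gts[parent.id] is Genotype.HET

    def test_spike_survives_cascade(self):
        cohort = simulate_cohort(small_params(seed=9))
        result = run_cascade(
            cohort.variants, cohort.genotypes, cohort.pedigrees, cohort.annotations
        )
        surviving = {(c.family_id, c.variant.key) for c in result.survivors}
        for truth in cohort.truth:
            assert (truth.family_id, truth.variant_key) in surviving


class TestSignalSanity:
    @staticmethod
    def _mean_margin(background_tool_damaging_p, tmp_path, label):
        import statistics

        from exofam.pipeline import run_pipeline

        params = SimulationParams(
            n_families=10, n_ad_families=4, n_ar_families=6,
            n_background_variants=150,
            background_tool_damaging_p=background_tool_damaging_p,
            seed=42,
        )
        files = emit_cohort(params, str(tmp_path / label))
        result = run_pipeline(
            vcf=files.vcf, ped=files.ped, annotations=files.annotations,
            gene_sets_dir=files.gene_sets_dir,
        )
        truth = {t.family_id: t.variant_key for t in read_truth_table(files.truth)}
        by_family: dict[str, list] = {}
        for c in result.ranked:
            by_family.setdefault(c.family_id, []).append(c)
        margins = []
        for fam, vkey in truth.items():
            cands = by_family.get(fam, [])
            causal = [c for c in cands if c.variant.key == vkey]
            background = [c for c in cands if c.variant.key != vkey]
            if causal and background:
                margins.append(
                    causal[0].evidence.weighted_total
                    - max(c.evidence.weighted_total for c in background)
                )
        assert margins, "no family had a surviving background competitor"
        return statistics.mean(margins)

    def test_noisier_background_tools_shrink_score_margin(self, tmp_path):
        clean = self._mean_margin(0.1, tmp_path, "clean")
        noisy = self._mean_margin(0.9, tmp_path, "noisy")
        assert noisy < clean


class TestEmitCohort:
    def test_byte_identical_for_same_seed(self, tmp_path):
        f1 = emit_cohort(small_params(seed=42), str(tmp_path / "a"))
        f2 = emit_cohort(small_params(seed=42), str(tmp_path / "b"))
        for attr in ("vcf", "ped", "annotations", "clinical", "truth"):
            p1, p2 = getattr(f1, attr), getattr(f2, attr)
            assert open(p1, "rb").read() == open(p2, "rb").read(), attr
        cmp = filecmp.dircmp(f1.gene_sets_dir, f2.gene_sets_dir)
        assert not cmp.diff_files and not cmp.left_only and not cmp.right_only

    def test_different_seed_differs(self, tmp_path):
        f1 = emit_cohort(small_params(seed=1), str(tmp_path / "a"))
        f2 = emit_cohort(small_params(seed=2), str(tmp_path / "b"))
        assert open(f1.vcf, "rb").read() != open(f2.vcf, "rb").read()

    def test_ped_contains_all_families_and_truth_rows(self, tmp_path):
        params = small_params(seed=3, families=8, ad=3)
        files = emit_cohort(params, str(tmp_path / "c"))
        peds = read_ped(files.ped)
        assert len(peds) == 8
        truth = read_truth_table(files.truth)
        assert len(truth) == 8
        assert all(t.expected_to_survive for t in truth)

    def test_outputs_are_text(self, tmp_path):
        files = emit_cohort(small_params(seed=4), str(tmp_path / "d"))
        for attr in ("vcf", "ped", "annotations", "clinical", "truth"):
            with open(getattr(files, attr), encoding="utf-8") as fh:
                fh.read()
        assert os.path.isdir(files.gene_sets_dir)
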