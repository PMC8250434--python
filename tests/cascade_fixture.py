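"""A hand-constructed 10-variant, one-family cascade fixture.

Composition (all variants carried by at least one family member):
2 intronic, 2 synonymous, 2 missense with gnomAD MAF 0.05, 2 missense
novel but model-inconsistent (affected child homozygous in an AD
family), 2 clean missense. Hand-computed funnel:
10 -> 8 -> 6 -> 4 -> 2 -> 2 survivors.
"""

from exofam.model import (
    Consequence,
    Genotype,
    GenotypeMatrix,
    PopulationFrequencies,
    PredictionProfile,
    Variant,
    variant_key,
)
from exofam.variant_io import AnnotationRecord

from conftest import make_trio

CLEAN_KEYS = {"1:900:A:G", "1:1000:A:G"}


def build_funnel_fixture():
    ped = make_trio("FAM1")
    specs = [
        (Consequence.INTRONIC, None, Genotype.HET),
        (Consequence.INTRONIC, None, Genotype.HET),
        (Consequence.SYNONYMOUS, None, Genotype.HET),
        (Consequence.SYNONYMOUS, None, Genotype.HET),
        (Consequence.MISSENSE, 0.05, Genotype.HET),
        (Consequence.MISSENSE, 0.05, Genotype.HET),
        (Consequence.MISSENSE, None, Genotype.HOM_ALT),  # breaks AD model
        (Consequence.MISSENSE, None, Genotype.HOM_ALT),
        (Consequence.MISSENSE, None, Genotype.HET),  # clean
        (Consequence.MISSENSE, None, Genotype.HET),
    ]
    variants = []
    matrix = GenotypeMatrix()
    annotations = {}
    for i, (consequence, gnomad, child_gt) in enumerate(specs, start=1):
        v = Variant(chrom="1", pos=100 * i, ref="A", alt="G", gene=f"G{i}")
        variants.append(v)
        key = variant_key(v)
        matrix.set(key, "F", Genotype.HET)
        matrix.set(key, "M", Genotype.HOM_REF)
        matrix.set(key, "C", child_gt)
        annotations[key] = AnnotationRecord(
            frequencies=PopulationFrequencies(maf_gnomad=gnomad),
            profile=PredictionProfile(),
            consequence=consequence,
            gene=f"G{i}",
        )
    return variants, matrix, [ped], annotations
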