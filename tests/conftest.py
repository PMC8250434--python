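import pytest

from exofam.config import Thresholds
from exofam.model import (
    Genotype,
    GenotypeMatrix,
    Individual,
    Pedigree,
    Sex,
    Status,
)


@pytest.fixture
def thresholds() -> Thresholds:
    return Thresholds()


def make_trio(
    family_id: str = "FAM1",
    father_status: Status = Status.AFFECTED,
    mother_status: Status = Status.UNAFFECTED,
    child_status: Status = Status.AFFECTED,
) -> Pedigree:
    return Pedigree(
        family_id=family_id,
        members=[
            Individual(id="F", family_id=family_id, sex=Sex.MALE, declared_status=father_status),
            Individual(id="M", family_id=family_id, sex=Sex.FEMALE, declared_status=mother_status),
            Individual(
                id="C",
                family_id=family_id,
                father_id="F",
                mother_id="M",
                sex=Sex.MALE,
                declared_status=child_status,
            ),
        ],
    )


@pytest.fixture
def ad_trio() -> Pedigree:
    """Affected father and child, unaffected mother (vertical transmission)."""
    return make_trio()


@pytest.fixture
def ar_trio() -> Pedigree:
    """Single affected child with unaffected parents."""
    return make_trio(father_status=Status.UNAFFECTED, child_status=Status.AFFECTED)


def matrix_for(vkey: str, genotypes: dict[str, Genotype]) -> GenotypeMatrix:
    m = GenotypeMatrix()
    for sample, gt in genotypes.items():
        m.set(vkey, sample, gt)
    return m
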